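"""Derive per-cell score cutoffs and attribution classes.

The count-vs-score curve of each cell drops steeply past the bulk of
loosely attributed proteins; the cutoff sits at the most negative first
derivative of the (smoothed) score histogram.  Proteins above it are
strongly attributed, those below a quarter of it loosely.
"""

from litcube.lexicon import count_corpus_mentions
from litcube.prioritize import classify_attributions, derive_cutoffs, overlap_sets
from litcube.scoring import score_corpus
from litcube.synthetic import SyntheticCorpusSpec, generate_corpus

corpus = generate_corpus(SyntheticCorpusSpec(n_cells=3, seed=7))
mentions = count_corpus_mentions(corpus.documents, corpus.lexicon)
table = score_corpus(mentions, corpus.cells)

cutoffs = derive_cutoffs(table)
classes = classify_attributions(table, cutoffs)

for cell, r in cutoffs.items():
    sub = classes[classes.cell == cell]
    counts = sub.attribution.value_counts()
    planted = corpus.truth.planted_by_cell[cell]
    strong = set(sub.loc[sub.attribution == "strong", "uniprot_id"])
    print(f"{cell}: cutoff={r.cutoff:.3f} "
          f"(degenerate={r.degenerate})  "
          f"strong={counts.get('strong', 0)}  "
          f"moderate={counts.get('moderate', 0)}  "
          f"loose={counts.get('loose', 0)}  "
          f"planted-strong={sum(p in strong for p in planted)}/{len(planted)}")
print("\nevery planted cell-exclusive protein classifies strong; the "
      "cutoff sits at the steepest drop of the count-vs-score curve, "
      "inside the low-score background bulk")

regions, shared = overlap_sets(table)
all_cells = frozenset(c.domain for c in corpus.cells)
print(f"\nproteins scored in all {len(all_cells)} cells: "
      f"{regions[all_cells]}; pairwise shared matrix:\n{shared}")
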