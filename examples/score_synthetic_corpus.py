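"""Score a synthetic literature corpus and recover the planted proteins.

Generates a small six-cell corpus in which each cell has 20 planted
proteins mentioned only there at ten times the background rate, counts
dictionary mentions, computes the composite integrity x popularity x
distinctiveness score for every protein-cell pair, and shows the top of
one cell's ranking against the known ground truth.
"""

from litcube.lexicon import count_corpus_mentions
from litcube.prioritize import top_k
from litcube.scoring import score_corpus
from litcube.synthetic import SyntheticCorpusSpec, generate_corpus

corpus = generate_corpus(SyntheticCorpusSpec(seed=42))
mentions = count_corpus_mentions(corpus.documents, corpus.lexicon)
table = score_corpus(mentions, corpus.cells)

cell = corpus.cells[0].domain
planted = set(corpus.truth.planted_by_cell[cell])
ranking = top_k(table, cell, 10)

print(f"corpus: {len(corpus.documents)} documents, "
      f"{table.uniprot_id.nunique()} scored proteins, "
      f"{len(corpus.cells)} cells")
print(f"\ntop 10 proteins in {cell} (score = popularity x distinctiveness,"
      " integrity = 1):")
for uid in ranking:
    row = table[(table.uniprot_id == uid) & (table.cell == cell)].iloc[0]
    tag = "planted" if uid in planted else "background"
    print(f"  {uid}  score={row.score:.4f}  pop={row.popularity:.3f}  "
          f"dist={row.distinctiveness:.3f}  [{tag}]")
hits = sum(u in planted for u in top_k(table, cell, 30))
print(f"\nplanted proteins recovered in top 30: {hits}/20 — a high count "
      "means exclusive high-rate mentions dominate the cell's ranking")
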