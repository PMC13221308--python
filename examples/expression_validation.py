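"""Validate a literature ranking against expression data.

Emulates a case/control biopsy proteomics table (9 controls, 10 cases)
with 20 proteins shifted by five noise standard deviations in the case
group, ranks proteins by KS test and mean difference, tests the overlap
of the true planted set with the top of the ranking by an exact
hypergeometric tail, and assigns proteins to their tissue of maximal
expression.
"""

from litcube.synthetic import (
    SyntheticExpressionSpec,
    generate_expression,
    generate_tissue_table,
)
from litcube.validate import (
    differential_rank,
    overlap_enrichment,
    tissue_max_assignment,
)

spec = SyntheticExpressionSpec(n_proteins=500, n_planted=20, delta=5.0, seed=1)
table, truth = generate_expression(spec)
ranked = differential_rank(table, top_m=100)

planted = set(truth.planted_differential)
hits = sum(p in planted for p in ranked.head(20).protein)
print(f"differential ranking over {spec.n_proteins} proteins "
      f"({spec.n_control} controls vs {spec.n_case} cases):")
print(ranked.head(5).to_string(index=False))
print(f"\nplanted proteins among top 20: {hits}/20 — a 5-sigma group "
      "shift is essentially always detected at this cohort size")

enr = overlap_enrichment(
    list(planted), list(ranked.head(100).protein), background_n=spec.n_proteins
)
print(f"\nenrichment of the planted list in the top-100 ranking: "
      f"k={enr.k} observed vs {enr.expected:.2f} expected "
      f"({enr.enrichment:.1f}x), hypergeometric p={enr.p_value:.3g}")

tissue, ttruth = generate_tissue_table(
    20, ["liver", "heart", "lung", "pancreas"], seed=1
)
prof = tissue_max_assignment(tissue, list(ttruth.dominant_tissue))
print(f"\ntissue-of-maximal-expression counts:\n{prof.tissue_counts}")
print("each protein lands in its generated dominant tissue")
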