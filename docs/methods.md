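# Methods

## Corpus model

A document is an article record (PMID, title, abstract, keywords, MeSH
descriptor ids, optional date). Domains are defined extensionally by root
MeSH descriptors; a document joins a domain's cell iff one of its
descriptors' tree numbers equals, or extends at a dot boundary, a tree
number of one of the roots. The dot-boundary rule mirrors MeSH tree
semantics: `C14.280` is an ancestor of `C14.280.434` but unrelated to
`C14.2801`. Assignment uses MeSH descriptors only — keywords and free text
never decide membership, so cell composition is exactly as curated by the
indexers. Documents without descriptors stay in the corpus but belong to
no cell; since scoring aggregates per cell, they contribute nothing.
Deduplication keeps the first record per PMID in input order
(deterministic and auditable); dates are parsed leniently (year-only
accepted) and carried for provenance only.

## Mention counting

The dictionary is assumed curated: synonyms are normalized (Unicode NFKC,
lower-case, hyphen variants to spaces, whitespace collapsed — an
idempotent map) and compiled into a token trie. Matching over the
normalized concatenation of title, abstract and keywords is
leftmost-longest, non-overlapping, and anchored at alphanumeric token
boundaries, so "cat" never matches inside "catalase" and "bnp receptor"
beats "bnp" when both apply. Counts are per occurrence, not per document:
popularity is driven by total phrase frequency, and occurrence counting
preserves the within-cell frequency signal that document-level counting
would flatten. A synonym claimed by two accessions is ambiguous and
dropped from the index (listed in `dropped_ambiguous`, surfaced in the run
manifest); a flag multi-assigns instead for users who prefer recall over
precision with paralog abbreviations.

## Composite score

Per protein p and cell c, with tf(p,c) the cell-total occurrence count and
cntP(c) the cell's total phrase traffic:

- integrity = 1.0 (curated phrases are already integral semantic units; a
  per-accession mapping is accepted for phrase-mining-derived values),
- popularity = log(1+tf)/log(1+cntP), 0 when cntP = 0,
- rel = tf/cntP, 0 when cntP = 0,
- distinctiveness = rel(p,c)/Σ_{c'∈S} rel(p,c') over the explicit
  comparison set S; undefined (pair unscored) when the denominator is 0.

The composite is the product, computed at full precision. Records exist
only for pairs with tf > 0; one mention suffices. Both popularity and rel
are injectable strategy functions, so alternative algebraic forms can be
swapped without touching callers. The comparison set is always an explicit
argument — it is a modelling choice (e.g. six diseases vs a
comorbidity panel), never inferred from the data.

Consequences worth knowing: distinctiveness is a zero-sum share, so a
protein mentioned at a uniform rate everywhere gets 1/|S| in each cell,
and cross-cell score correlations of shared proteins are biased slightly
negative; a protein mentioned in exactly one cell gets distinctiveness 1
there regardless of rate.

## Cutoffs and attribution classes

Within a cell the score histogram (uniform bins over (0, max score],
half-open with the last bin closed; default width 0.005) is smoothed by a
centered moving average (window 3; zero-padded, so appending empty bins
beyond the maximum never changes the result). The cutoff is the shared
edge of the bin pair with the most negative forward difference — the right
edge of the drop, so proteins sitting in the drop are not called strong;
ties resolve to the smallest score; monotone-flat histograms are flagged
degenerate with cutoff = max score. Bin width and window are configuration
keys: the defaults give stable derivative estimates on corpora with a few
hundred scored proteins per cell, the scale these analyses target.

Classes: strong ⇔ score > cutoff; loose ⇔ score < loose_fraction ×
cutoff (default 0.25, echoed in output metadata); moderate otherwise. The
loose boundary is a reporting convention, not an estimate.

Top-k ranking sorts by descending score with ties broken by accession, so
rankings are deterministic. Venn membership ("scored in a cell") means a
record exists, i.e. the protein is mentioned there at least once — the
inclusive reading that keeps single-publication proteins visible.

## Cross-domain statistics

Regression of one cell's scores on another's is OLS over the proteins
scored in *both* cells (attribution to both is the quantity being
correlated); Pearson r with a two-sided p from the t distribution on n−2
degrees of freedom; zero-variance inputs return a degenerate flag instead
of NaNs. Clustering treats each protein as its score vector over the cell
set with unscored coordinates imputed as 0 — unscored means *no literature
attribution*, a genuine zero, not missing-at-random. "Normalized
Euclidean" is read as per-dimension z-scoring before Euclidean distance
(the alternative, per-vector unit-norm scaling, is a config option);
agglomeration is complete-linkage via the standard linkage matrix, leaf
labels sorted by accession so input order never changes the tree. The
dendrogram serializes to Newick.

## Validation stage

The KS statistic is the maximum absolute ECDF difference (sorted sweep);
the p-value uses the asymptotic two-sided Kolmogorov distribution at
√(ne)·D, ne = nm/(n+m), even at biopsy-cohort sizes (n ≈ 9/10) — the
standard large-sample convention; an exact-null option exists for
n·m ≤ 10⁴. Differential ranking sorts by (−|mean difference|, p, id),
using raw unstandardized group means with missing values dropped per
group; proteins lacking ≥2 values in a group are excluded with a warning.
The reference arm is the group labelled "control" when present, else the
alphabetically first label, overridable.

Enrichment is the exact hypergeometric upper tail P(X ≥ k) — the standard
over-representation convention — with expected = nK/N and enrichment
factor k/expected. The background N defaults to 20,428 (the dictionary
size), overridable. Tissue assignment is argmax over an atlas-style long
table; ties go to the alphabetically first tissue with a logged warning,
and absent proteins land in a "not detected" bucket so counts always sum
to the query size.

## Synthetic data

The corpus generator emulates: multi-label documents drawn per cell (a
configurable fraction carries a second cell's descriptor), background
phrase traffic shared by all cells, planted cell-exclusive proteins at a
rate multiplier, optional cell-shared proteins, and Poisson
mentions-per-document. Defaults — 6 cells, 200 documents/cell, 100
background proteins, 20 planted exclusive proteins per cell at 10× the
mean background rate, Poisson mean 8 mentions/document,
multilabel fraction 0 — are the recovery-benchmark conditions; background
per-protein rates are log-uniform over [0.1, 1] to mimic the heavy right
tail of real mention frequencies. The vocabulary is closed (one unique
token per protein plus filler), which makes brute-force oracle counting
trivial and is the deliberate opposite of linguistically realistic text:
passing recovery tests shows the *pipeline arithmetic* recovers planted
structure, not that dictionary NER works on real prose (no spelling
variation, no ambiguity beyond what tests construct, no section
structure). The expression generator plants a group mean shift of
δ·noise_sd (defaults: 2,180 proteins, 9 controls vs 10 cases, 20 planted,
δ = 5, noise sd 1 — a small clinical cohort); the tissue generator gives
each protein one dominant tissue at 5× its background maximum. All
generators are pure functions of spec + seed.

The `stress_corpus` benchmark (6 cells, ~2,000 documents, 500 proteins)
rewrites one cell so a single protein carries all of its phrase traffic:
that protein attains popularity = distinctiveness = 1, so the maximum
composite score reaches the upper bound exactly and the bound check is
sharp rather than vacuous.

## Numerical choices and degenerate inputs

Zero denominators: popularity and rel are defined as 0 when cntP = 0;
distinctiveness is undefined (pair dropped) when total rel = 0. Histogram
edges are multiples of the bin width so cutoffs are reproducible decimals.
All tie-breaks (top-k, cutoff, tissue, linkage input order) are
deterministic and documented above. Scores are float64 throughout;
distinctiveness normalization holds to 1e-12.

## Problem sizes

Tests and the acceptance script run on corpora of 10²–10³ documents and
10²–10³ proteins with 10–20 seeds per stochastic claim — sizes chosen so
planted-signal recovery rates estimate stably while the whole suite stays
interactive. Real literature-scale runs (10⁶ abstracts, 2×10⁴ proteins)
exercise the same code paths; only the counting stage's runtime grows
materially (linear in total text length).

## Known limitations

- Dictionary-only matching: no context disambiguation, abbreviation
  expansion, or ML NER; ambiguous synonyms are dropped, trading recall
  for precision.
- Integrity is constant; true phrase-mining integrity estimation is out
  of scope.
- The cutoff derivative is a histogram heuristic; on cells with few
  scored proteins it degrades (degenerate flag) rather than failing.
- MeSH qualifiers (subheadings) are ignored; assignment uses descriptors
  only.
- The asymptotic KS p-value is conservative at n ≈ 10; rankings (which
  depend mostly on mean differences) are insensitive to this, but
  absolute p-values near the significance boundary should be read with
  the exact option.
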