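"""Validation of literature-ranked proteins against expression data.

Three stages mirror how a text-mining protein ranking is checked against a
clinical proteomics cohort and a tissue atlas:

* per-protein two-sample Kolmogorov-Smirnov tests between case and control
  expression values, ranked by descending absolute group-mean difference
  then ascending p-value;
* hypergeometric enrichment of the overlap between the literature top-k
  list and the expression dataset's proteins (exact upper-tail
  P(X >= k) against a dictionary-sized background, 20,428 by default);
* assignment of each query protein to its tissue of maximal expression in
  a Human Protein Atlas-style long table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats as sps

logger = logging.getLogger(__name__)

DEFAULT_BACKGROUND_N = 20_428


@dataclass
class ExpressionTable:
    """Samples × proteins abundance matrix with per-sample group labels.

    ``values``: DataFrame indexed by sample id, columns are protein ids.
    ``groups``: Series mapping sample id -> group label (two groups, e.g.
    control / case).
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.values.index)
            if self.groups.isna().any():
                raise ValueError("every sample needs a group label")

    @classmethod
    def from_tsv(cls, values_path: str, groups_path: str) -> "ExpressionTable":
        """Load a wide TSV (rows = proteins, columns = samples) and a
        two-column (sample, group) label TSV."""
        wide = pd.read_csv(values_path, sep="\t", index_col=0)
        labels = pd.read_csv(groups_path, sep="\t", dtype=str)
        groups = labels.set_index(labels.columns[0])[labels.columns[1]]
        return cls(values=wide.T, groups=groups)


@dataclass
class EnrichmentResult:
    """Observed/expected overlap and exact hypergeometric tail probability.

    N: background size; K: literature list size; n: expression dataset
    size; k: observed overlap.  expected = n*K/N; enrichment = k/expected;
    p_value = P(X >= k) under the hypergeometric null.
    """

    N: int
    K: int
    n: int
    k: int
    expected: float
    enrichment: float
    p_value: float


@dataclass
class TissueProfile:
    """Per-protein argmax tissue and per-tissue assignment counts."""

    assignments: dict[str, str]
    tissue_counts: pd.Series
    not_detected: list[str] = field(default_factory=list)


def ks_two_sample(
    a: np.ndarray, b: np.ndarray, mode: str = "asymptotic"
) -> tuple[float, float]:
    """Two-sample KS statistic and p-value.

    The statistic is the maximum absolute difference between the two
    empirical CDFs, computed by a sorted sweep.  The p-value comes from the
    asymptotic two-sided Kolmogorov distribution evaluated at
    sqrt(ne) * D with effective size ne = |a||b|/(|a|+|b|) — the standard
    large-sample approximation, used even at biopsy-cohort sizes.  Set
    ``mode="exact"`` for the exact null distribution (sensible when
    |a|*|b| <= 1e4).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("ks_two_sample requires >= 2 values per sample")
    if mode == "exact":
        res = sps.ks_2samp(a, b, method="exact")
        return float(res.statistic), float(res.pvalue)
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
    cdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
    d = float(np.abs(cdf_a - cdf_b).max())
    ne = a.size * b.size / (a.size + b.size)
    p = float(special.kolmogorov(np.sqrt(ne) * d))
    return d, min(1.0, p)


def differential_rank(
    x: ExpressionTable,
    top_m: int | None = None,
    mode: str = "asymptotic",
    control_label: str | None = None,
) -> pd.DataFrame:
    """Rank proteins by case-control differential expression.

    Per protein: group means, absolute mean difference, KS statistic and
    p-value.  Sorted by (-abs_mean_diff, p_value, protein id).  Proteins
    with all-missing values in either group are excluded with a warning;
    missing values are otherwise dropped per group.  ``top_m`` slices the
    head of the ranking (the conventional figure shows the top 100).
    ``control_label`` names the reference arm; when omitted, a group
    literally labelled "control" is used if present, else the
    alphabetically first label.
    """
    labels = x.groups
    names = sorted(labels.unique())
    if len(names) != 2:
        raise ValueError(f"expected exactly two groups, got {names}")
    if control_label is None:
        control_label = "control" if "control" in names else names[0]
    elif control_label not in names:
        raise ValueError(f"control label {control_label!r} not in {names}")
    g_control = control_label
    g_case = next(n for n in names if n != g_control)
    rows = []
    for protein in x.values.columns:
        col = x.values[protein]
        a = col[labels == g_control].dropna().to_numpy()
        b = col[labels == g_case].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            logger.warning(
                "differential_rank: %r lacks values in a group; excluded",
                protein,
            )
            continue
        d, p = ks_two_sample(a, b, mode=mode)
        rows.append(
            (
                protein,
                float(b.mean()),
                float(a.mean()),
                abs(float(b.mean()) - float(a.mean())),
                d,
                p,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "protein", "mean_case", "mean_control", "abs_mean_diff",
            "ks_stat", "p_value",
        ],
    )
    out = out.sort_values(
        ["abs_mean_diff", "p_value", "protein"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out.head(top_m) if top_m is not None else out


def hypergeom_enrichment(
    N: int, K: int, n: int, k: int
) -> EnrichmentResult:
    """Exact over-representation test of an observed overlap.

    Drawing n proteins from a background of N containing K listed ones,
    the p-value is the exact upper tail P(X >= k); the enrichment factor
    is observed/expected with expected = n*K/N.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"infeasible sizes: N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"infeasible overlap k={k} for K={K}, n={n}")
    expected = n * K / N
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(
        N=N, K=K, n=n, k=k,
        expected=expected,
        enrichment=(k / expected) if expected > 0 else float("nan"),
        p_value=min(1.0, p),
    )


def overlap_enrichment(
    literature_list: list[str],
    dataset_proteins: list[str],
    background_n: int = DEFAULT_BACKGROUND_N,
) -> EnrichmentResult:
    """Enrichment of a literature top-k list within an expression dataset."""
    K = len(set(literature_list))
    n = len(set(dataset_proteins))
    k = len(set(literature_list) & set(dataset_proteins))
    return hypergeom_enrichment(background_n, K, n, k)


def tissue_max_assignment(
    tissue_table: pd.DataFrame, proteins: list[str]
) -> TissueProfile:
    """Assign each query protein to its tissue of maximal expression.

    ``tissue_table`` is an HPA-style long table with columns protein_id,
    tissue, value (e.g. nTPM).  Ties resolve to the alphabetically first
    tissue with a warning; proteins absent from the table land in the
    "not detected" bucket.  Tissue counts plus not-detected equal the
    number of query proteins.
    """
    if tissue_table.empty:
        raise ValueError("tissue table is empty")
    required = {"protein_id", "tissue", "value"}
    missing = required - set(tissue_table.columns)
    if missing:
        raise ValueError(f"tissue table missing columns: {sorted(missing)}")
    assignments: dict[str, str] = {}
    not_detected: list[str] = []
    by_protein = dict(tuple(tissue_table.groupby("protein_id")))
    for protein in proteins:
        sub = by_protein.get(protein)
        if sub is None or sub["value"].isna().all():
            not_detected.append(protein)
            continue
        vmax = sub["value"].max()
        best = sorted(sub.loc[sub["value"] == vmax, "tissue"])
        if len(best) > 1:
            logger.warning(
                "tissue tie for %r among %s; assigning %r",
                protein, best, best[0],
            )
        assignments[protein] = best[0]
    counts = pd.Series(assignments, dtype=str).value_counts().sort_index()
    return TissueProfile(
        assignments=assignments,
        tissue_counts=counts,
        not_detected=not_detected,
    )
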