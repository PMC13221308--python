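"""Cross-domain statistics over score tables: regression of one cell's
scores on another's, distribution summaries, and hierarchical clustering of
proteins as score vectors.

The regression mirrors the comparison of a focal disease against one of its
comorbidities or mechanisms: only proteins scored in BOTH cells enter the
fit (literature attribution to both is what is being correlated).  For
clustering, each protein becomes a vector of composite scores over the cell
set — an unscored coordinate is a genuine zero (no literature attribution),
not missing-at-random — each dimension is standardized to zero mean and
unit variance ("normalized Euclidean"), and complete-linkage agglomeration
is applied to the pairwise Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy


@dataclass
class RegressionResult:
    """OLS fit of cell_y scores on cell_x scores over shared proteins."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n_shared: int
    degenerate: bool = False


@dataclass
class DistributionSummary:
    mean: float
    median: float
    q1: float
    q3: float
    min: float
    max: float
    n: int


@dataclass
class ClusterTree:
    """Complete-linkage merge sequence over proteins as score vectors.

    ``linkage`` is the standard (n-1) × 4 linkage matrix (pair indices,
    merge height, cluster size); heights are non-decreasing under complete
    linkage.  ``labels`` gives the protein accession for each leaf index.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def to_newick(self) -> str:
        """Serialize the dendrogram as a Newick string."""
        tree = hierarchy.to_tree(self.linkage)

        def build(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = build(node.left, node.dist)
            right = build(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return build(tree, tree.dist) + ";"


def _shared_scores(
    table: pd.DataFrame, cell_x: str, cell_y: str
) -> pd.DataFrame:
    wide = table.pivot(index="uniprot_id", columns="cell", values="score")
    for c in (cell_x, cell_y):
        if c not in wide.columns:
            raise KeyError(f"cell {c!r} absent from score table")
    return wide[[cell_x, cell_y]].dropna()


def cross_domain_regression(
    table: pd.DataFrame, cell_x: str, cell_y: str
) -> RegressionResult:
    """OLS of cell_y scores on cell_x scores over the shared protein set.

    Pearson r and a two-sided p from the t distribution with n-2 degrees
    of freedom.  Zero-variance input yields slope 0, r reported as 0, and
    the degenerate flag.
    """
    shared = _shared_scores(table, cell_x, cell_y)
    n = len(shared)
    if n < 2:
        raise ValueError(
            f"need >= 2 proteins scored in both {cell_x!r} and {cell_y!r}; "
            f"got {n}"
        )
    x = shared[cell_x].to_numpy(dtype=float)
    y = shared[cell_y].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        slope = 0.0
        intercept = float(y.mean())
        return RegressionResult(
            slope=slope, intercept=intercept, pearson_r=0.0, p_value=1.0,
            n_shared=n, degenerate=True,
        )
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n_shared=n,
    )


def summarize_scores(table: pd.DataFrame, cell: str) -> DistributionSummary:
    """Mean, median, quartiles and range of one cell's composite scores."""
    s = table.loc[table["cell"] == cell, "score"].to_numpy(dtype=float)
    if s.size == 0:
        raise ValueError(f"no scored proteins in cell {cell!r}")
    q1, med, q3 = np.percentile(s, [25, 50, 75])
    return DistributionSummary(
        mean=float(s.mean()), median=float(med), q1=float(q1), q3=float(q3),
        min=float(s.min()), max=float(s.max()), n=int(s.size),
    )


def cluster_proteins(
    table: pd.DataFrame,
    cells: list[str] | None = None,
    normalization: str = "zscore",
) -> ClusterTree:
    """Complete-linkage clustering of proteins as score vectors over cells.

    Missing (unscored) coordinates become 0.  ``normalization`` is
    "zscore" (per-dimension standardization, the default reading of
    normalized Euclidean distance) or "unit" (each protein vector scaled
    to unit norm).  Constant dimensions are left unscaled under zscore.
    Proteins are ordered by accession before distance computation so the
    tree is invariant to input row order.
    """
    if cells is None:
        cells = sorted(table["cell"].unique())
    wide = (
        table.pivot(index="uniprot_id", columns="cell", values="score")
        .reindex(columns=cells)
        .fillna(0.0)
        .sort_index()
    )
    if len(wide) < 2:
        raise ValueError("clustering requires >= 2 scored proteins")
    X = wide.to_numpy(dtype=float)
    if normalization == "zscore":
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    elif normalization == "unit":
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        X = X / norms
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    return ClusterTree(linkage=Z, labels=list(wide.index))
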