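"""Score-distribution characterization, cutoff detection, attribution
classes, top-k ranking and multi-domain overlap sets.

Within each cell the composite scores are heavily right-skewed: most
proteins score low, and the count-vs-score curve shows a steep drop past
which proteins are largely exclusive to the cell.  The per-cell cutoff is
placed at that drop — the most negative first derivative of the (smoothed)
score histogram — and splits attributions into strong (above the cutoff),
moderate, and loose (below a configurable fraction of the cutoff).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.005
DEFAULT_SMOOTH_WINDOW = 3
DEFAULT_LOOSE_FRACTION = 0.25


@dataclass
class ScoreHistogram:
    """Fixed-width histogram of one cell's composite scores.

    Bins are half-open [edge, edge + w) with the last bin closed; counts
    conserve the number of scored proteins in the cell.
    """

    cell: str
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts/edges length mismatch")


@dataclass
class CutoffResult:
    """Per-cell score threshold at the steepest histogram drop."""

    cell: str
    cutoff: float
    derivative: np.ndarray = field(default_factory=lambda: np.array([]))
    degenerate: bool = False


def _cell_scores(table: pd.DataFrame, cell: str) -> np.ndarray:
    s = table.loc[table["cell"] == cell, "score"].to_numpy(dtype=float)
    if s.size == 0:
        raise ValueError(f"no scored proteins in cell {cell!r}")
    return s


def score_histogram(
    table: pd.DataFrame, cell: str, bin_width: float = DEFAULT_BIN_WIDTH
) -> ScoreHistogram:
    """Histogram the cell's scores into uniform bins over (0, max score]."""
    scores = _cell_scores(table, cell)
    smax = float(scores.max())
    n_bins = max(1, int(np.ceil(smax / bin_width))) if smax > 0 else 1
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    # np.histogram uses half-open bins with the last bin closed, matching
    # the contract.
    counts, _ = np.histogram(scores, bins=edges)
    return ScoreHistogram(cell=cell, bin_edges=edges, counts=counts)


def detect_cutoff(
    h: ScoreHistogram, smooth_window: int = DEFAULT_SMOOTH_WINDOW
) -> CutoffResult:
    """Place the cutoff at the steepest drop of the score histogram.

    Counts are smoothed by a centered moving average (window 3 by default;
    1 disables smoothing), forward differences taken, and the cutoff set to
    the shared edge of the bin pair with the most negative difference —
    the right edge of the drop's upper bin, so proteins sitting in the
    drop itself are not called strong.  Ties resolve to the smallest
    score.  Monotone-flat (no negative difference) histograms are flagged
    degenerate with cutoff = max score, as are single-bin histograms.
    """
    edges, counts = h.bin_edges, h.counts.astype(float)
    if len(counts) < 2:
        return CutoffResult(
            cell=h.cell, cutoff=float(edges[-1]), degenerate=True
        )
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        smoothed = np.convolve(counts, kernel, mode="same")
    else:
        smoothed = counts
    diffs = np.diff(smoothed)
    if diffs.min() >= 0:
        return CutoffResult(
            cell=h.cell,
            cutoff=float(edges[-1]),
            derivative=diffs,
            degenerate=True,
        )
    i = int(np.argmin(diffs))  # argmin takes the first (smallest score) tie
    return CutoffResult(
        cell=h.cell, cutoff=float(edges[i + 1]), derivative=diffs,
        degenerate=False,
    )


def derive_cutoffs(
    table: pd.DataFrame,
    bin_width: float = DEFAULT_BIN_WIDTH,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> dict[str, CutoffResult]:
    """Convenience: per-cell cutoff for every cell present in the table."""
    return {
        cell: detect_cutoff(score_histogram(table, cell, bin_width), smooth_window)
        for cell in sorted(table["cell"].unique())
    }


def classify_attributions(
    table: pd.DataFrame,
    cutoffs: dict[str, CutoffResult],
    loose_fraction: float = DEFAULT_LOOSE_FRACTION,
) -> pd.DataFrame:
    """Label every scored pair strong / moderate / loose.

    strong ⇔ score > cutoff(c); loose ⇔ score < loose_fraction × cutoff(c);
    moderate otherwise.
    """
    missing = set(table["cell"].unique()) - set(cutoffs)
    if missing:
        raise KeyError(f"no cutoff for cell(s): {sorted(missing)}")
    cut = table["cell"].map({c: r.cutoff for c, r in cutoffs.items()})
    out = table.copy()
    out["attribution"] = np.select(
        [out["score"] > cut, out["score"] < loose_fraction * cut],
        ["strong", "loose"],
        default="moderate",
    )
    return out


def top_k(table: pd.DataFrame, cell: str, k: int) -> list[str]:
    """The k highest-scoring proteins of a cell, ties by accession order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = table[table["cell"] == cell]
    ranked = sub.sort_values(
        ["score", "uniprot_id"], ascending=[False, True]
    )["uniprot_id"].tolist()
    if k > len(ranked):
        logger.warning(
            "top_k: k=%d exceeds %d scored proteins in %r; returning all",
            k, len(ranked), cell,
        )
    return ranked[:k]


def overlap_sets(
    table: pd.DataFrame, cells: list[str] | None = None
) -> tuple[dict[frozenset[str], int], pd.DataFrame]:
    """Venn region counts and the pairwise shared-protein matrix.

    A protein is "in" a cell iff a score record exists for the pair (i.e.
    it is mentioned at least once there).  For each non-empty subset S of
    cells the region count is the number of proteins present in exactly
    the cells of S; the counts partition the union.
    """
    if cells is None:
        cells = sorted(table["cell"].unique())
    if len(cells) < 2:
        raise ValueError("overlap_sets requires at least two cells")
    membership: dict[str, set[str]] = {
        c: set(table.loc[table["cell"] == c, "uniprot_id"]) for c in cells
    }
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(cells) + 1):
        for combo in itertools.combinations(cells, r):
            inside = set.intersection(*(membership[c] for c in combo))
            outside = set.union(
                *(membership[c] for c in cells if c not in combo), set()
            )
            regions[frozenset(combo)] = len(inside - outside)
    n = len(cells)
    mat = np.zeros((n, n), dtype=int)
    for i, a in enumerate(cells):
        for j, b in enumerate(cells):
            mat[i, j] = len(membership[a] & membership[b])
    return regions, pd.DataFrame(mat, index=cells, columns=cells)
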