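"""CaseOLAP-style composite scoring of protein-cell pairs.

Every protein p mentioned anywhere in the comparison cell set receives, per
cell c, three component scores in [0, 1]:

* integrity — how coherent a semantic unit the phrase is; for a curated
  protein-name dictionary every phrase is already an integral unit, so
  integrity is the constant 1.0 (a hook accepts per-protein values should
  phrase-mining-derived integrities become available);
* popularity — prevalence of p inside c, log(1 + tf(p,c)) / log(1 + cntP(c)),
  where tf(p,c) is the total occurrence count of p over the documents of c
  and cntP(c) = Σ_p tf(p,c) is the cell's total phrase traffic;
* distinctiveness — exclusivity of p's relevance to c against the
  comparison cells, rel(p,c) / Σ_{c'} rel(p,c') with rel(p,c) =
  tf(p,c) / cntP(c); distinctiveness sums to one over the cell set.

The composite score is the product of the three, in [0, 1]; higher means a
stronger literature attribution of the protein to the domain.  Proteins
never mentioned in any comparison cell carry no record at all (unscored),
and a single supporting mention is enough to be scored.

The algebraic forms of popularity and relevance are injectable strategy
hooks so variants can be swapped in without touching callers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from litcube.corpus import Cell

PopularityFn = Callable[[float, float], float]
RelevanceFn = Callable[[float, float], float]

SCORE_COLUMNS = [
    "uniprot_id", "cell", "integrity", "popularity", "distinctiveness", "score",
]


@dataclass
class CellStats:
    """Per-cell phrase-frequency aggregates.

    ``tf`` is a proteins × cells DataFrame of total occurrence counts;
    ``cntP`` the per-cell column sums (total phrase traffic); ``doc_count``
    the per-cell document count.
    """

    tf: pd.DataFrame
    cntP: pd.Series
    doc_count: pd.Series

    def __post_init__(self) -> None:
        if not np.allclose(self.tf.sum(axis=0), self.cntP):
            raise ValueError("cntP inconsistent with tf column sums")


def aggregate_cell_stats(
    mentions: pd.DataFrame, cells: Iterable[Cell]
) -> CellStats:
    """Aggregate per-document mention counts into per-cell tf and cntP.

    ``mentions`` is the long table (pmid, uniprot_id, tf).  A document in
    several cells contributes its counts to each.  Cells referencing a pmid
    absent from the mention table's corpus are permitted only when the
    document simply had no dictionary hits; the caller vouches for corpus
    membership via the mention table itself, so an unknown pmid is an error
    only if the cell set references ids never seen by the counter — callers
    pass ``known_pmids`` through the mention table attrs when available.
    """
    cells = list(cells)
    known: set[str] | None = mentions.attrs.get("known_pmids")
    if known is not None:
        for c in cells:
            stray = c.doc_ids - known
            if stray:
                raise KeyError(
                    f"cell {c.domain!r} references unknown pmid(s): "
                    f"{sorted(stray)[:5]}"
                )
    names = [c.domain for c in cells]
    proteins = sorted(mentions["uniprot_id"].unique())
    tf = pd.DataFrame(0, index=proteins, columns=names, dtype=int)
    by_pmid = mentions.groupby("pmid")
    groups = dict(tuple(by_pmid)) if len(mentions) else {}
    for c in cells:
        hit = [p for p in c.doc_ids if p in groups]
        if not hit:
            continue
        sub = pd.concat([groups[p] for p in hit])
        agg = sub.groupby("uniprot_id")["tf"].sum()
        tf.loc[agg.index, c.domain] = tf.loc[agg.index, c.domain] + agg
    cntP = tf.sum(axis=0)
    doc_count = pd.Series(
        {c.domain: len(c.doc_ids) for c in cells}, dtype=int
    )[names]
    return CellStats(tf=tf, cntP=cntP, doc_count=doc_count)


def default_popularity(tf: float, cntP: float) -> float:
    """log(1+tf)/log(1+cntP); 0 when the cell has no phrase traffic."""
    if cntP <= 0 or tf <= 0:
        return 0.0
    return float(np.log1p(tf) / np.log1p(cntP))


def default_relevance(tf: float, cntP: float) -> float:
    """tf/cntP; 0 when the cell has no phrase traffic."""
    if cntP <= 0:
        return 0.0
    return float(tf / cntP)


def popularity(
    protein: str,
    cell: str,
    stats: CellStats,
    fn: PopularityFn = default_popularity,
) -> float:
    tf = float(stats.tf.at[protein, cell]) if protein in stats.tf.index else 0.0
    return fn(tf, float(stats.cntP[cell]))


def relevance(
    protein: str,
    cell: str,
    stats: CellStats,
    fn: RelevanceFn = default_relevance,
) -> float:
    tf = float(stats.tf.at[protein, cell]) if protein in stats.tf.index else 0.0
    return fn(tf, float(stats.cntP[cell]))


def distinctiveness(
    protein: str,
    cell: str,
    stats: CellStats,
    cell_set: list[str],
    rel_fn: RelevanceFn = default_relevance,
) -> float:
    """rel(p,c) normalized over the comparison cell set.

    Raises KeyError if ``cell`` is outside the comparison set and
    ValueError when total relevance is zero (the pair is unscored).
    """
    if cell not in cell_set:
        raise KeyError(f"cell {cell!r} not in comparison set {cell_set}")
    rels = {c: relevance(protein, c, stats, rel_fn) for c in cell_set}
    total = sum(rels.values())
    if total == 0:
        raise ValueError(
            f"protein {protein!r} has zero relevance in every comparison cell"
        )
    return rels[cell] / total


def score_corpus(
    mentions: pd.DataFrame,
    cells: Iterable[Cell],
    integrity: float | Mapping[str, float] = 1.0,
    popularity_fn: PopularityFn = default_popularity,
    relevance_fn: RelevanceFn = default_relevance,
) -> pd.DataFrame:
    """Score every mentioned protein against every cell of the set.

    Returns the long-format score table (uniprot_id, cell, integrity,
    popularity, distinctiveness, score) with score = integrity × popularity
    × distinctiveness at full precision.  A record exists only for pairs
    with tf(p,c) > 0; proteins never mentioned in any comparison cell are
    absent entirely.  ``integrity`` is a constant (curated dictionary
    default 1.0) or a per-accession mapping.
    """
    cells = list(cells)
    stats = aggregate_cell_stats(mentions, cells)
    names = [c.domain for c in cells]
    tf = stats.tf[names].to_numpy(dtype=float)
    cntP = stats.cntP[names].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pop = np.array(
            [[popularity_fn(t, c) for t, c in zip(row, cntP)] for row in tf]
        )
        rel = np.array(
            [[relevance_fn(t, c) for t, c in zip(row, cntP)] for row in tf]
        )
    rel_total = rel.sum(axis=1)
    scored = rel_total > 0
    rows = []
    for i, protein in enumerate(stats.tf.index):
        if not scored[i]:
            continue
        integ_p = (
            float(integrity.get(protein, 1.0))
            if isinstance(integrity, Mapping)
            else float(integrity)
        )
        dist = rel[i] / rel_total[i]
        for j, cell in enumerate(names):
            if tf[i, j] == 0:
                continue  # a record exists only where the protein is mentioned
            rows.append(
                (
                    protein,
                    cell,
                    integ_p,
                    pop[i, j],
                    dist[j],
                    integ_p * pop[i, j] * dist[j],
                )
            )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def write_score_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_score_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"uniprot_id": str, "cell": str})
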