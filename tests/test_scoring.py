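"""Scoring module: cell aggregation, component scores, composite table,
and oracle equivalence against a naive reimplementation."""

import math

import numpy as np
import pandas as pd
import pytest

from litcube.corpus import Cell
from litcube.scoring import (
    CellStats,
    aggregate_cell_stats,
    distinctiveness,
    popularity,
    relevance,
    score_corpus,
)
from conftest import naive_scores


def mention_table(rows):
    df = pd.DataFrame(rows, columns=["pmid", "uniprot_id", "tf"])
    return df


def stats_from(tf_by_cell: dict[str, dict[str, int]]) -> CellStats:
    cells = sorted(tf_by_cell)
    proteins = sorted({p for d in tf_by_cell.values() for p in d})
    tf = pd.DataFrame(
        [[tf_by_cell[c].get(p, 0) for c in cells] for p in proteins],
        index=proteins,
        columns=cells,
    )
    return CellStats(
        tf=tf,
        cntP=tf.sum(axis=0),
        doc_count=pd.Series(1, index=cells),
    )


class TestAggregateCellStats:
    def test_summation_within_cell(self):
        m = mention_table([("1", "P1", 2), ("2", "P1", 3)])
        st = aggregate_cell_stats(m, [Cell("c", {"1", "2"})])
        assert st.tf.at["P1", "c"] == 5
        assert st.cntP["c"] == 5

    def test_multilabel_doc_contributes_to_both(self):
        m = mention_table([("1", "P1", 2)])
        st = aggregate_cell_stats(m, [Cell("a", {"1"}), Cell("b", {"1"})])
        assert st.tf.at["P1", "a"] == st.tf.at["P1", "b"] == 2

    def test_empty_cell_all_zero(self):
        m = mention_table([("1", "P1", 2)])
        st = aggregate_cell_stats(m, [Cell("a", {"1"}), Cell("b", set())])
        assert st.cntP["b"] == 0

    def test_unknown_pmid_error_when_corpus_known(self):
        m = mention_table([("1", "P1", 2)])
        m.attrs["known_pmids"] = {"1"}
        with pytest.raises(KeyError, match="unknown pmid"):
            aggregate_cell_stats(m, [Cell("a", {"1", "99"})])


class TestComponents:
    def test_popularity_log_ratio(self):
        st = stats_from({"c": {"P1": 9, "Pz": 90}})
        assert popularity("P1", "c", st) == pytest.approx(
            math.log(10) / math.log(100), abs=1e-15
        )

    def test_popularity_zero_tf(self):
        st = stats_from({"c": {"P1": 0, "Pz": 5}})
        assert popularity("P1", "c", st) == 0.0

    def test_popularity_upper_bound_when_tf_equals_cntP(self):
        st = stats_from({"c": {"P1": 7}})
        assert popularity("P1", "c", st) == 1.0

    def test_relevance_ratio_and_normalization(self):
        st = stats_from({"c": {"P1": 5, "P2": 45}})
        assert relevance("P1", "c", st) == pytest.approx(0.1)
        total = relevance("P1", "c", st) + relevance("P2", "c", st)
        assert total == pytest.approx(1.0)

    def test_relevance_empty_cell_zero(self):
        st = stats_from({"c": {}, "d": {"P1": 1}})
        assert relevance("P1", "c", st) == 0.0

    def test_distinctiveness_direct_ratio(self):
        # rels 0.1 and 0.01 -> 0.90909... for the first cell
        st = stats_from({"a": {"P1": 1, "Pz": 9}, "b": {"P1": 1, "Pz": 99}})
        d = distinctiveness("P1", "a", st, ["a", "b"])
        assert d == pytest.approx(0.1 / 0.11, abs=1e-12)

    def test_exclusive_protein_distinctiveness_one(self):
        st = stats_from({"a": {"P1": 3, "Pz": 9}, "b": {"Pz": 99}})
        assert distinctiveness("P1", "a", st, ["a", "b"]) == 1.0

    def test_equal_relevance_symmetric_share(self):
        cells = {f"c{i}": {"P1": 2, "Pz": 8} for i in range(6)}
        st = stats_from(cells)
        for c in cells:
            assert distinctiveness("P1", c, st, sorted(cells)) == pytest.approx(
                1 / 6
            )

    def test_cell_outside_comparison_set_errors(self):
        st = stats_from({"a": {"P1": 1}, "b": {"P1": 1}})
        with pytest.raises(KeyError):
            distinctiveness("P1", "a", st, ["b"])


class TestScoreCorpus:
    def test_composite_is_product(self):
        m = mention_table([("1", "P1", 9), ("1", "Pz", 90), ("2", "P1", 1),
                           ("2", "Pz", 99)])
        cells = [Cell("a", {"1"}), Cell("b", {"2"})]
        t = score_corpus(m, cells)
        row = t[(t.uniprot_id == "P1") & (t.cell == "a")].iloc[0]
        assert row.score == row.integrity * row.popularity * row.distinctiveness
        assert row.integrity == 1.0

    def test_unmentioned_protein_absent(self):
        m = mention_table([("1", "P1", 1)])
        t = score_corpus(m, [Cell("a", {"1"})])
        assert set(t.uniprot_id) == {"P1"}

    def test_single_mention_still_scored(self):
        m = mention_table([("1", "P1", 1), ("2", "Pz", 50)])
        cells = [Cell("a", {"1"}), Cell("b", {"2"})]
        t = score_corpus(m, cells)
        assert "P1" in set(t.uniprot_id)

    def test_distinctiveness_sums_to_one_per_protein(self):
        rng = np.random.default_rng(7)
        rows = [
            (str(d), f"P{p}", int(rng.integers(1, 5)))
            for d in range(30)
            for p in rng.choice(10, size=3, replace=False)
        ]
        cells = [Cell(f"c{i}", {str(d) for d in range(i * 10, (i + 1) * 10)})
                 for i in range(3)]
        t = score_corpus(mention_table(rows), cells)
        sums = t.groupby("uniprot_id")["distinctiveness"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_monotone_in_tf(self):
        base = {"a": {"P1": 3, "Pz": 50}, "b": {"P1": 2, "Pz": 50}}
        bumped = {"a": {"P1": 4, "Pz": 50}, "b": {"P1": 2, "Pz": 50}}
        st0, st1 = stats_from(base), stats_from(bumped)
        assert popularity("P1", "a", st1) >= popularity("P1", "a", st0)
        assert distinctiveness("P1", "a", st1, ["a", "b"]) >= distinctiveness(
            "P1", "a", st0, ["a", "b"]
        )

    def test_integrity_mapping_hook(self):
        m = mention_table([("1", "P1", 2), ("2", "P2", 3)])
        cells = [Cell("a", {"1"}), Cell("b", {"2"})]
        t = score_corpus(m, cells, integrity={"P1": 0.5})
        p1 = t[t.uniprot_id == "P1"].iloc[0]
        p2 = t[t.uniprot_id == "P2"].iloc[0]
        assert p1.integrity == 0.5 and p2.integrity == 1.0
        assert p1.score == pytest.approx(
            0.5 * p1.popularity * p1.distinctiveness
        )

    def test_matches_naive_oracle_on_random_corpus(self):
        rng = np.random.default_rng(42)
        n_docs, n_prot = 40, 12
        per_doc = {}
        rows = []
        for d in range(n_docs):
            counts = {}
            for p in rng.choice(n_prot, size=rng.integers(0, 4), replace=False):
                counts[f"P{p}"] = int(rng.integers(1, 6))
            per_doc[str(d)] = counts
            rows += [(str(d), u, c) for u, c in counts.items()]
        members = {
            "a": {str(d) for d in range(0, 25)},
            "b": {str(d) for d in range(15, 40)},  # overlapping cells
        }
        cells = [Cell(n, s) for n, s in members.items()]
        t = score_corpus(mention_table(rows), cells)
        oracle = naive_scores(per_doc, members)
        got = {
            (r.uniprot_id, r.cell): r for r in t.itertuples(index=False)
        }
        assert set(got) == set(oracle)
        for key, exp in oracle.items():
            assert got[key].popularity == pytest.approx(
                exp["popularity"], abs=1e-12
            )
            assert got[key].distinctiveness == pytest.approx(
                exp["distinctiveness"], abs=1e-12
            )
            assert got[key].score == pytest.approx(exp["score"], abs=1e-12)
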