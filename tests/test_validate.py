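"""Validate module: KS tests, differential ranking, hypergeometric
enrichment (vs exhaustive enumeration), tissue assignment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from litcube.validate import (
    ExpressionTable,
    differential_rank,
    hypergeom_enrichment,
    ks_two_sample,
    tissue_max_assignment,
)


def brute_ks(a, b):
    """Double-loop ECDF oracle for the two-sample KS statistic."""
    best = 0.0
    for t in list(a) + list(b):
        fa = sum(x <= t for x in a) / len(a)
        fb = sum(x <= t for x in b) / len(b)
        best = max(best, abs(fa - fb))
    return best


class TestKsTwoSample:
    def test_disjoint_supports_full_separation(self):
        d, _ = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == pytest.approx(1.0)

    def test_identical_samples_zero(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_interleaved_half(self):
        d, _ = ks_two_sample([1, 3], [2, 4])
        assert d == pytest.approx(0.5)

    def test_statistic_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.normal(size=rng.integers(2, 12))
            b = rng.normal(rng.uniform(-1, 1), size=rng.integers(2, 12))
            d, _ = ks_two_sample(a, b)
            assert d == pytest.approx(brute_ks(a, b), abs=1e-12)

    def test_pvalue_matches_kolmogorov_series_oracle(self):
        # independent oracle: Q(x) = 2 sum_{j>=1} (-1)^(j-1) exp(-2 j^2 x^2)
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=9), rng.normal(0.5, size=10)
        d, p = ks_two_sample(a, b)
        ne = len(a) * len(b) / (len(a) + len(b))
        x = math.sqrt(ne) * d
        series = 2 * sum(
            (-1) ** (j - 1) * math.exp(-2 * j * j * x * x)
            for j in range(1, 101)
        )
        assert p == pytest.approx(series, abs=1e-12)

    def test_insufficient_samples_error(self):
        with pytest.raises(ValueError):
            ks_two_sample([1], [2, 3])


def expr_table(values: dict[str, list[float]], n_control: int):
    df = pd.DataFrame(values)
    samples = [f"s{i}" for i in range(len(df))]
    df.index = samples
    groups = pd.Series(
        ["control"] * n_control + ["case"] * (len(df) - n_control),
        index=samples,
    )
    return ExpressionTable(values=df, groups=groups)


class TestDifferentialRank:
    def test_hand_computed_three_protein_order(self):
        t = expr_table(
            {
                "A": [1.0, 1.0, 5.0, 5.0],   # diff 4
                "B": [1.0, 1.0, 2.0, 2.0],   # diff 1
                "C": [1.0, 2.0, 7.0, 8.0],   # diff 6
            },
            n_control=2,
        )
        out = differential_rank(t)
        assert list(out.protein) == ["C", "A", "B"]
        assert out.iloc[0].abs_mean_diff == pytest.approx(6.0)
        assert out.iloc[0].mean_control == pytest.approx(1.5)
        assert out.iloc[0].mean_case == pytest.approx(7.5)

    def test_identical_groups_ordered_by_p_then_id(self):
        t = expr_table(
            {"B": [1.0, 2.0, 1.0, 2.0], "A": [3.0, 4.0, 3.0, 4.0]},
            n_control=2,
        )
        out = differential_rank(t)
        assert (out.abs_mean_diff == 0).all()
        assert list(out.protein) == ["A", "B"]  # equal p -> id order

    def test_planted_five_sigma_shift_ranks_first(self):
        from litcube.synthetic import (
            SyntheticExpressionSpec,
            generate_expression,
        )

        wins = 0
        for seed in range(10):
            spec = SyntheticExpressionSpec(
                n_proteins=60, n_case=10, n_control=9, n_planted=1,
                delta=5.0, seed=seed,
            )
            table, truth = generate_expression(spec)
            out = differential_rank(table)
            if out.iloc[0].protein == truth.planted_differential[0]:
                wins += 1
        assert wins >= 9

    def test_sample_column_order_invariance(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            rng.normal(size=(8, 5)), index=[f"s{i}" for i in range(8)],
            columns=[f"P{i}" for i in range(5)],
        )
        groups = pd.Series(["control"] * 4 + ["case"] * 4, index=df.index)
        t1 = ExpressionTable(df, groups)
        perm = rng.permutation(8)
        t2 = ExpressionTable(df.iloc[perm], groups.iloc[perm])
        pd.testing.assert_frame_equal(
            differential_rank(t1), differential_rank(t2)
        )

    def test_all_missing_protein_excluded_with_warning(self, caplog):
        t = expr_table(
            {"A": [1, 2, 5, 6], "B": [np.nan] * 4}, n_control=2
        )
        with caplog.at_level("WARNING"):
            out = differential_rank(t)
        assert list(out.protein) == ["A"]
        assert any("excluded" in r.message for r in caplog.records)

    def test_top_m_slice(self):
        t = expr_table(
            {f"P{i}": list(np.arange(4) + i) for i in range(6)}, n_control=2
        )
        assert len(differential_rank(t, top_m=3)) == 3


def enum_hypergeom_tail(N, K, n, k):
    """Exhaustive enumeration of draws: P(overlap >= k)."""
    universe = range(N)
    listed = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(listed & set(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeomEnrichment:
    def test_small_exact_value(self):
        r = hypergeom_enrichment(N=10, K=3, n=4, k=2)
        assert r.p_value == pytest.approx(1 / 3, abs=1e-12)
        assert r.expected == pytest.approx(1.2)
        assert r.enrichment == pytest.approx(2 / 1.2)

    def test_zero_overlap_p_one(self):
        assert hypergeom_enrichment(10, 3, 4, 0).p_value == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        for N in (5, 8, 10):
            for K in (0, 2, N // 2):
                for n in (2, N // 2):
                    for k in range(0, min(K, n) + 1):
                        r = hypergeom_enrichment(N, K, n, k)
                        assert r.p_value == pytest.approx(
                            enum_hypergeom_tail(N, K, n, k), abs=1e-12
                        ), (N, K, n, k)

    def test_dictionary_scale_inputs_self_consistent(self):
        # clinical-cohort sized call: background 20,428, list 20,
        # dataset 2,180, overlap 7
        r = hypergeom_enrichment(20428, 20, 2180, 7)
        assert r.expected == pytest.approx(2180 * 20 / 20428)
        assert r.enrichment == pytest.approx(7 / r.expected)
        assert 0 < r.p_value < 0.01
        # cross-check the tail against a direct pmf sum
        from scipy.stats import hypergeom as hg

        tail = sum(hg.pmf(i, 20428, 20, 2180) for i in range(7, 21))
        assert r.p_value == pytest.approx(tail, rel=1e-9)

    def test_infeasible_counts_error(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(10, 3, 4, 5)
        with pytest.raises(ValueError):
            hypergeom_enrichment(10, 11, 4, 2)


class TestTissueMaxAssignment:
    def tissue_table(self, rows):
        return pd.DataFrame(rows, columns=["protein_id", "tissue", "value"])

    def test_argmax_assignment(self):
        t = self.tissue_table([("P1", "liver", 10.0), ("P1", "heart", 2.0)])
        prof = tissue_max_assignment(t, ["P1"])
        assert prof.assignments["P1"] == "liver"
        assert prof.tissue_counts["liver"] == 1

    def test_absent_protein_not_detected(self):
        t = self.tissue_table([("P1", "liver", 1.0)])
        prof = tissue_max_assignment(t, ["P1", "P9"])
        assert prof.not_detected == ["P9"]
        assert prof.tissue_counts.sum() + len(prof.not_detected) == 2

    def test_tie_alphabetical_with_warning(self, caplog):
        t = self.tissue_table([("P1", "liver", 5.0), ("P1", "heart", 5.0)])
        with caplog.at_level("WARNING"):
            prof = tissue_max_assignment(t, ["P1"])
        assert prof.assignments["P1"] == "heart"
        assert any("tie" in r.message for r in caplog.records)

    def test_empty_table_error(self):
        with pytest.raises(ValueError):
            tissue_max_assignment(pd.DataFrame(), ["P1"])
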