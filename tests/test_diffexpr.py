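import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest, nbinom

from tissuespec.diffexpr import (
    DiffExprConfig,
    call_degs,
    cross_tabulate_degs,
    deg_sets,
    nb_exact_test,
    tmm_factors,
)
from tissuespec.expression import ExpressionMatrix
from tissuespec.specificity import GeneSet, classify_abundance_series


def enumeration_oracle(a, b, phi):
    """Independent NB-product enumeration of the two-sided conditional test."""
    n = a + b
    if n == 0:
        return 1.0
    mu, r = n / 2.0, 1.0 / phi
    pmf = nbinom.pmf(np.arange(n + 1), r, r / (r + mu))
    joint = pmf * pmf[::-1]
    obs = joint[a]
    return float(joint[joint <= obs * (1 + 1e-10)].sum() / joint.sum())


class TestNbExactTest:
    def test_equal_counts_give_p_one(self):
        assert nb_exact_test(7, 7, phi=0.09) == 1.0
        assert nb_exact_test(0, 0, phi=0.09) == 1.0

    def test_symmetric_under_sample_swap(self):
        assert nb_exact_test(5, 0, phi=0.09) == nb_exact_test(0, 5, phi=0.09)
        assert nb_exact_test(12, 3, phi=0.2) == nb_exact_test(3, 12, phi=0.2)

    def test_binomial_limit_at_vanishing_dispersion(self):
        # phi -> 0: the conditional null becomes Binomial(n, 1/2)
        for a, b in [(8, 1), (15, 5), (30, 10)]:
            p_nb = nb_exact_test(a, b, phi=1e-12)
            p_binom = binomtest(a, a + b, 0.5).pvalue
            assert p_nb == pytest.approx(p_binom, rel=1e-4)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 51))
            a = int(rng.integers(0, n + 1))
            p = nb_exact_test(a, n - a, phi=0.09)
            assert p == pytest.approx(enumeration_oracle(a, n - a, 0.09), abs=1e-12)

    def test_monotone_in_imbalance_at_fixed_total(self):
        for n in (10, 25, 40):
            ps = [nb_exact_test(a, n - a, phi=0.09) for a in range(n // 2 + 1)]
            assert all(ps[i] <= ps[i + 1] + 1e-12 for i in range(len(ps) - 1))

    def test_unequal_libraries_interpolate_deterministically(self):
        p = nb_exact_test(30, 10, lib_a=1.3e6, lib_b=1.0e6, phi=0.09)
        assert p == nb_exact_test(30, 10, lib_a=1.3e6, lib_b=1.0e6, phi=0.09)
        # interpolated p lies within the span of the integer-corner p-values
        common = math.sqrt(1.3e6 * 1.0e6)
        za, zb = 30 * common / 1.3e6, 10 * common / 1.0e6
        corners = [
            nb_exact_test(a, b, phi=0.09)
            for a in (math.floor(za), math.ceil(za))
            for b in (math.floor(zb), math.ceil(zb))
        ]
        assert min(corners) - 1e-12 <= p <= max(corners) + 1e-12

    def test_enumeration_cap(self):
        with pytest.raises(ValueError, match="enumeration_cap"):
            nb_exact_test(80, 40, phi=0.09, enumeration_cap=100)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nb_exact_test(1, 1, phi=0.0)
        with pytest.raises(ValueError):
            nb_exact_test(1, 1, lib_a=0.0, phi=0.09)


class TestTmmFactors:
    def test_identical_columns(self, rng):
        c = pd.DataFrame({"a": rng.poisson(100, 300), "b": 0})
        c["b"] = c["a"]
        np.testing.assert_allclose(tmm_factors(c), 1.0, atol=1e-12)

    def test_pure_depth_difference(self, rng):
        a = rng.poisson(100, 300) + 1
        c = pd.DataFrame({"a": a, "b": 2 * a})
        np.testing.assert_allclose(tmm_factors(c), 1.0, atol=1e-12)

    def test_matches_direct_formula_oracle(self, rng):
        # 200 genes, 20 inflated 8x in sample b
        a = rng.poisson(200, 200) + 1
        b = a.copy()
        b[:20] *= 8
        counts = pd.DataFrame({"ref": a, "b": b})
        factors = tmm_factors(counts, ref_column="ref")

        # independent straight-line reimplementation
        na, nb = a.sum(), b.sum()
        pa, pb = a / na, b / nb
        m = np.log2(pb / pa)
        av = 0.5 * np.log2(pb * pa)
        n = len(m)
        from scipy.stats import rankdata

        lo_m, lo_a = math.floor(n * 0.3) + 1, math.floor(n * 0.05) + 1
        keep = (
            (rankdata(m) >= lo_m)
            & (rankdata(m) <= n + 1 - lo_m)
            & (rankdata(av) >= lo_a)
            & (rankdata(av) <= n + 1 - lo_a)
        )
        w = 1.0 / ((nb - b[keep]) / (nb * b[keep]) + (na - a[keep]) / (na * a[keep]))
        f_b = 2.0 ** (np.sum(w * m[keep]) / np.sum(w))
        expected = np.array([1.0, f_b])
        expected /= np.exp(np.log(expected).mean())
        np.testing.assert_allclose(factors.to_numpy(), expected, rtol=1e-10)

    def test_geometric_mean_is_one(self, rng):
        for _ in range(5):
            c = pd.DataFrame(rng.poisson(rng.uniform(20, 200), (150, 4)) + 1)
            assert np.exp(np.log(tmm_factors(c)).mean()) == pytest.approx(1.0, rel=1e-12)


def counts_matrix(a, b):
    genes = [f"g{i}" for i in range(len(a))]
    return ExpressionMatrix(
        pd.DataFrame({"A": a, "B": b}, index=genes, dtype=float), "counts"
    )


class TestCallDegs:
    def test_equal_counts_give_no_degs(self, rng):
        a = rng.poisson(50, 100)
        degs = call_degs(counts_matrix(a, a))
        assert (degs["direction"] == "ns").all()
        assert (degs["p_value"] == 1.0).all()

    def test_count_filter_drops_all_zero_genes(self):
        degs = call_degs(counts_matrix([0, 5, 0], [0, 5, 1]))
        assert list(degs.index) == ["g1", "g2"]

    def test_planted_fold_changes_dominate_p_ranking(self):
        # 3-fold up genes at high counts crowd the top of the p-ranking;
        # with BCV 0.3 noise on both libraries the occasional planted gene
        # ranks low, so dominance is asserted in aggregate over 10 seeds
        n, n_planted = 300, 15
        in_top_n, in_top_50 = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mean = rng.uniform(100, 400, n)
            r = 1 / 0.09
            a = rng.negative_binomial(r, r / (r + mean))
            mean_b = mean.copy()
            mean_b[:n_planted] *= 3
            b = rng.negative_binomial(r, r / (r + mean_b))
            degs = call_degs(counts_matrix(a, b), DiffExprConfig(enumeration_cap=10**6))
            ranked = degs.sort_values("p_value").index
            planted = {f"g{i}" for i in range(n_planted)}
            in_top_n.append(len(set(ranked[:n_planted]) & planted))
            in_top_50.append(len(set(ranked[:50]) & planted))
        # chance level for the top-15 slots is 15 * 15/300 = 0.75 genes
        assert np.mean(in_top_n) >= 7.0
        assert np.mean(in_top_50) >= 11.0

    def test_direction_counts_are_consistent(self, small_sim):
        degs = call_degs(small_sim.deg_counts, DiffExprConfig(enumeration_cap=10**7))
        groups = deg_sets(degs)
        assert len(groups["up"]) + len(groups["down"]) == len(groups["all"])
        up = degs[degs["direction"] == "up"]
        assert (up["log2_fold_change"] > 0).all() and (up["p_value"] < 0.05).all()


class TestCrossTabulate:
    def test_counts_match_brute_force(self, rng):
        genes = [f"g{i}" for i in range(200)]
        degs = pd.DataFrame(
            {
                "p_value": rng.uniform(0, 0.2, 200),
                "log2_fold_change": rng.normal(0, 1, 200),
            },
            index=genes,
        )
        degs["direction"] = np.where(
            degs["p_value"] < 0.05, np.where(degs["log2_fold_change"] > 0, "up", "down"), "ns"
        )
        tiers = classify_abundance_series(
            pd.Series(rng.lognormal(1, 3, 200), index=genes)
        )
        gs = GeneSet("S", frozenset(rng.choice(genes, 50, replace=False)), "test")
        report = cross_tabulate_degs(degs, tiers, {"S": gs})
        called = degs[degs["direction"] != "ns"]
        for tier in report["by_tier"].index:
            expected = sum(1 for g in called.index if tiers[g] == tier)
            assert report["by_tier"].loc[tier, "total"] == expected
        expected_set = sum(1 for g in called.index if g in gs.genes)
        assert report["by_set"].loc["S", "total"] == expected_set

    def test_empty_deg_table(self):
        degs = pd.DataFrame(columns=["p_value", "log2_fold_change", "direction"])
        tiers = classify_abundance_series(pd.Series([5.0, 500.0], index=["a", "b"]))
        report = cross_tabulate_degs(degs, tiers)
        assert (report["by_tier"]["total"] == 0).all()


def test_config_validation():
    with pytest.raises(ValueError):
        DiffExprConfig(bcv=0.0)
    with pytest.raises(ValueError):
        DiffExprConfig(p_cutoff=1.5)
    assert DiffExprConfig().dispersion == pytest.approx(0.09)
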