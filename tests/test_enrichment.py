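import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pgcmasc.diffexpr import RankedDEGList, SexDEGSets
from pgcmasc.enrichment import (
    EnrichmentNull,
    ExpressedUniverse,
    call_enrichment,
    enrichment_curve,
    expressed_universe,
    gamma_fit_mme,
    hypergeom_tail,
    permutation_null,
)

from conftest import make_cm


def exact_tail(n, k, s, q):
    """Brute-force hypergeometric tail P(X/s > q) via binomial coefficients."""
    kmin = math.floor(q * s) + 1
    tot = math.comb(n, s)
    return sum(
        math.comb(k, x) * math.comb(n - k, s - x)
        for x in range(kmin, min(k, s) + 1)
        if s - x <= n - k
    ) / tot


def make_universe(n):
    genes = {f"g{i:05d}" for i in range(n)}
    return ExpressedUniverse(genes=genes, max_counts=pd.Series(dtype=float), threshold=100)


def make_ranked(gene_ids, label="test"):
    tab = pd.DataFrame(
        {"log2fc": 0.0, "lrt": 0.0, "pvalue": np.linspace(0, 1, len(gene_ids)),
         "fdr": 1.0, "rank": np.arange(1, len(gene_ids) + 1)},
        index=pd.Index(gene_ids),
    )
    return RankedDEGList(contrast=label, table=tab)


def make_sets(male=(), female=()):
    return SexDEGSets(male_specific=set(male), female_specific=set(female),
                      table=pd.DataFrame())


class TestUniverse:
    def test_strictly_greater_than_threshold(self):
        mat = np.array([[101, 0], [100, 5], [0, 0], [1, 0]])
        uni = expressed_universe(make_cm(mat), threshold=100)
        assert uni.genes == {"g0000"}

    def test_threshold_zero_keeps_any_expressed_gene(self):
        mat = np.array([[1, 0], [0, 0]])
        uni = expressed_universe(make_cm(mat), threshold=0)
        assert uni.genes == {"g0000"}


class TestCurve:
    def test_all_male_prefix(self):
        uni = make_universe(100)
        genes = sorted(uni.genes)
        ranked = make_ranked(genes)
        sets = make_sets(male=genes[:10])
        curve = enrichment_curve(ranked, sets, uni, k_max=20)
        assert curve.table.loc[10, "frac_male"] == 1.0
        assert curve.table.loc[20, "frac_male"] == 0.5

    def test_disjoint_sets_give_zero_curves(self):
        uni = make_universe(50)
        ranked = make_ranked(sorted(uni.genes))
        curve = enrichment_curve(ranked, make_sets(male={"zz"}, female={"yy"}), uni, k_max=30)
        assert (curve.table[["frac_male", "frac_female"]] == 0).all().all()

    def test_short_list_truncates_with_warning(self, caplog):
        uni = make_universe(30)
        ranked = make_ranked(sorted(uni.genes))
        curve = enrichment_curve(ranked, make_sets(), uni, k_max=200)
        assert curve.k_max == 30

    def test_counts_are_integer_cumulative(self):
        rng = np.random.default_rng(5)
        uni = make_universe(200)
        genes = sorted(uni.genes)
        sets = make_sets(male=rng.choice(genes, 40, replace=False))
        order = list(rng.permutation(genes))
        curve = enrichment_curve(make_ranked(order), sets, uni, k_max=150)
        n_male = (curve.table["frac_male"] * curve.table.index).round(9)
        assert np.allclose(n_male, n_male.round())
        steps = np.diff(n_male.to_numpy())
        assert ((steps == 0) | (steps == 1)).all()

    def test_random_ranking_matches_hypergeometric_mean(self):
        # mean fraction over many random rankings equals the base rate K/N
        rng = np.random.default_rng(7)
        n, k_set = 200, 20
        uni = make_universe(n)
        genes = sorted(uni.genes)
        sets = make_sets(male=genes[:k_set])
        ks = [5, 20, 80]
        acc = {k: [] for k in ks}
        n_rank = 1000
        for _ in range(n_rank):
            order = list(rng.permutation(genes))
            curve = enrichment_curve(make_ranked(order), sets, uni, k_max=max(ks))
            for k in ks:
                acc[k].append(curve.table.loc[k, "frac_male"])
        base = k_set / n
        for k in ks:
            vals = np.array(acc[k])
            se = vals.std(ddof=1) / np.sqrt(n_rank)
            assert abs(vals.mean() - base) < 3 * se + 1e-9


class TestPermutationNull:
    def test_empty_set_degenerate_zeros(self):
        uni = make_universe(100)
        null = permutation_null(uni, set(), s=10, n_iter=50, seed=0)
        assert null.degenerate
        assert (null.draws == 0).all()

    def test_full_set_degenerate_ones(self):
        uni = make_universe(50)
        null = permutation_null(uni, uni.genes, s=10, n_iter=50, seed=0)
        assert null.degenerate
        assert (null.draws == 1).all()

    def test_seeded_reproducibility(self):
        uni = make_universe(300)
        sets = set(sorted(uni.genes)[:30])
        a = permutation_null(uni, sets, s=50, n_iter=200, seed=42)
        b = permutation_null(uni, sets, s=50, n_iter=200, seed=42)
        assert np.array_equal(a.draws, b.draws)

    def test_matches_exact_hypergeometric_tail(self):
        n, k_set, s = 3100, 140, 50
        uni = make_universe(n)
        sex_set = set(sorted(uni.genes)[:k_set])
        null = permutation_null(uni, sex_set, s=s, n_iter=5000, seed=1)
        p_exact = exact_tail(n, k_set, s, 0.10)
        emp = null.tail_empirical(0.10)
        mc = 3 * np.sqrt(p_exact * (1 - p_exact) / 5000)
        assert abs(emp - p_exact) < mc + 1e-9

    def test_mean_matches_base_rate(self):
        n, k_set, s = 1000, 80, 100
        uni = make_universe(n)
        sex_set = set(sorted(uni.genes)[:k_set])
        null = permutation_null(uni, sex_set, s=s, n_iter=3000, seed=3)
        base = k_set / n
        sd = np.sqrt(base * (1 - base) / s) / np.sqrt(3000)
        assert abs(null.draws.mean() - base) < 3 * sd * np.sqrt(1 + s / n)

    def test_empirical_cdf_close_to_hypergeometric(self):
        n, k_set = 3100, 140
        uni = make_universe(n)
        sex_set = set(sorted(uni.genes)[:k_set])
        for s in (50, 100, 200):
            null = permutation_null(uni, sex_set, s=s, n_iter=5000, seed=s)
            xs = np.arange(0, 30)
            emp_cdf = np.array([(null.draws * s <= x + 0.5).mean() for x in xs])
            exact_cdf = stats.hypergeom.cdf(xs, n, k_set, s)
            assert np.max(np.abs(emp_cdf - exact_cdf)) < 0.03


class TestGammaFit:
    def test_exact_two_point_example(self):
        alpha, beta = gamma_fit_mme(np.array([0.025, 0.075]))
        assert alpha == pytest.approx(2.0, abs=1e-12)
        assert beta == pytest.approx(40.0, abs=1e-12)

    def test_recovery_from_gamma_samples(self):
        rng = np.random.default_rng(11)
        draws = rng.gamma(2.0, 1.0 / 40.0, size=5000)
        alpha, beta = gamma_fit_mme(draws)
        assert 1.8 <= alpha <= 2.2

    def test_constant_draws_rejected(self):
        with pytest.raises(ValueError):
            gamma_fit_mme(np.full(10, 0.3))

    def test_moment_identities_hold_exactly(self):
        rng = np.random.default_rng(2)
        draws = rng.uniform(0, 0.2, 500)
        alpha, beta = gamma_fit_mme(draws)
        assert alpha / beta == pytest.approx(draws.mean(), abs=1e-10)
        assert alpha / beta**2 == pytest.approx(draws.var(ddof=1), abs=1e-10)


class TestHypergeomTail:
    def test_empty_set_zero(self):
        assert hypergeom_tail(100, 0, 10, 0.0) == 0.0

    def test_forced_draw(self):
        assert hypergeom_tail(10, 5, 10, 0.4) == pytest.approx(1.0)

    def test_matches_brute_force_summation(self):
        expected = exact_tail(3100, 140, 100, 0.10)
        assert expected == pytest.approx(0.004789664665007017, rel=1e-12)
        assert hypergeom_tail(3100, 140, 100, 0.10) == pytest.approx(expected, rel=1e-10)
        assert hypergeom_tail(3100, 140, 100, 0.10) < 0.05


class TestCalls:
    def _null(self, s, seed=0):
        uni = make_universe(1000)
        sets = set(sorted(uni.genes)[:80])
        return permutation_null(uni, sets, s=s, n_iter=2000, seed=seed)

    def test_zero_curve_never_flagged(self):
        uni = make_universe(1000)
        ranked = make_ranked(sorted(uni.genes)[200:400])
        curve = enrichment_curve(ranked, make_sets(), uni, k_max=100)
        calls = call_enrichment(curve, {50: self._null(50)}, alpha=0.05)
        assert not calls.table["flag_male"].any()
        assert not calls.table["flag_female"].any()

    def test_degenerate_null_uses_empirical_quantile(self):
        uni = make_universe(100)
        genes = sorted(uni.genes)
        null = permutation_null(uni, set(), s=10, n_iter=100, seed=0)
        curve = enrichment_curve(make_ranked(genes), make_sets(male=genes[:5]), uni, k_max=10)
        calls = call_enrichment(curve, {10: null}, alpha=0.05)
        assert np.isnan(calls.table["null_q_gamma"]).all()
        assert calls.table["flag_male"].any()  # any positive fraction beats an all-zero null

    def test_null_configured_flag_rate_near_alpha(self):
        # random rankings, flags evaluated at the calibrated sizes only
        rng = np.random.default_rng(21)
        n, k_set = 1000, 80
        uni = make_universe(n)
        genes = sorted(uni.genes)
        sets = make_sets(male=genes[:k_set])
        nulls = {s: self._null(s, seed=s) for s in (50, 100, 200)}
        flags = []
        for _ in range(200):
            order = list(rng.permutation(genes))
            curve = enrichment_curve(make_ranked(order), sets, uni, k_max=200)
            calls = call_enrichment(curve, nulls, alpha=0.05)
            flags.append(calls.table.loc[[50, 100, 200], "flag_male"].mean())
        rate = float(np.mean(flags))
        assert 0.01 <= rate <= 0.10
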