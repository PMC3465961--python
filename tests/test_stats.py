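"""Correlation statistics and the randomization null."""
import itertools

import numpy as np
import pytest

from odornet import (histogram_bins, kendall_tau, pearson_r2,
                     randomization_null, simulate_ortholog_pool, spearman)
from odornet.simulate import gamma_omega_law


def brute_spearman(x, y):
    def midranks(v):
        v = np.asarray(v, dtype=float)
        ranks = np.empty(len(v))
        for i, value in enumerate(v):
            less = (v < value).sum()
            equal = (v == value).sum()
            ranks[i] = less + (equal + 1) / 2
        return ranks
    rx, ry = midranks(x), midranks(y)
    return np.corrcoef(rx, ry)[0, 1]


def brute_kendall_tau_b(x, y):
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            continue
        if dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom


class TestSpearman:
    def test_perfect_agreement(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).estimate == \
            pytest.approx(1.0)

    def test_perfect_reversal(self):
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]).estimate == \
            pytest.approx(-1.0)

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(100):
            x = rng.integers(0, 5, size=10).astype(float)
            y = rng.integers(0, 5, size=10).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y).estimate == pytest.approx(brute_spearman(x, y))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestKendall:
    def test_perfect_concordance(self):
        assert kendall_tau([1, 2, 3, 4], [2, 4, 6, 8]).estimate == \
            pytest.approx(1.0)

    def test_matches_brute_force_pair_counting(self, rng):
        for _ in range(60):
            x = rng.integers(0, 5, size=9).astype(float)
            y = rng.integers(0, 5, size=9).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert kendall_tau(x, y).estimate == \
                pytest.approx(brute_kendall_tau_b(x, y))

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_single_adjacent_swap_closed_form(self, n):
        x = np.arange(n, dtype=float)
        y = x.copy()
        y[0], y[1] = y[1], y[0]
        assert kendall_tau(x, y).estimate == \
            pytest.approx(1 - 4 / (n * (n - 1)))

    def test_sign_agreement_with_spearman(self, rng):
        for _ in range(30):
            x = rng.normal(size=10)
            y = 0.8 * x + rng.normal(size=10) * 0.2
            assert np.sign(kendall_tau(x, y).estimate) == \
                np.sign(spearman(x, y).estimate)


class TestExactPValues:
    def test_exact_p_within_permutation_support(self):
        res = spearman([1, 2, 3, 4, 5], [1, 2, 3, 5, 4], exact="always")
        # p is a multiple of 1/120 and positive
        assert res.p_value > 0
        assert (res.p_value * 120) == pytest.approx(round(res.p_value * 120))

    def test_perfectly_concordant_small_sample(self):
        res = kendall_tau([1, 2, 3, 4], [1, 2, 3, 4], exact="always")
        # only the 2 strictly monotone orderings reach |tau| = 1
        assert res.p_value == pytest.approx(2 / 24)


class TestPearson:
    def test_linear_function(self):
        x = np.arange(5, dtype=float)
        r, r2 = pearson_r2(x, 2 * x + 1)
        assert (r, r2) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_negative_slope(self):
        x = np.arange(5, dtype=float)
        r, r2 = pearson_r2(x, -x)
        assert r == pytest.approx(-1.0) and r2 == pytest.approx(1.0)

    def test_matches_textbook_formula(self, rng):
        for _ in range(100):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            num = ((x - x.mean()) * (y - y.mean())).sum()
            den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            r, r2 = pearson_r2(x, y)
            assert r == pytest.approx(num / den)
            assert r2 == pytest.approx((num / den) ** 2)


class TestRandomizationNull:
    def test_degenerate_pool_constant_null(self):
        pool = simulate_ortholog_pool(100, omega_law=0.3, seed=0)
        res = randomization_null(pool, observed_mean=0.3, set_size=16,
                                 n_reps=500, seed=1)
        assert np.allclose(res.null_means, 0.3)
        assert res.empirical_p == 1.0

    def test_null_mean_matches_pool_mean(self):
        pool = simulate_ortholog_pool(2000, seed=2)
        res = randomization_null(pool, observed_mean=0.0, set_size=16,
                                 n_reps=5000, seed=3)
        se = res.null_means.std(ddof=1) / np.sqrt(res.n_reps)
        assert abs(res.null_mean_of_means - pool.omegas().mean()) < 3 * se

    def test_constrained_null_shifts_toward_tagged_mean(self):
        pool = simulate_ortholog_pool(
            2000, tag_fraction=0.05, seed=4,
            tagged_omega_law=gamma_omega_law(mean=0.05))
        base = randomization_null(pool, 0.0, n_reps=3000, seed=5)
        cons = randomization_null(pool, 0.0, n_reps=3000, seed=5,
                                  constraint=("Galpha", 6))
        assert pool.omegas("Galpha").mean() < pool.omegas("Galpha", True).mean()
        assert cons.null_mean_of_means < base.null_mean_of_means

    def test_bit_reproducible(self):
        pool = simulate_ortholog_pool(500, seed=6)
        a = randomization_null(pool, 0.1, n_reps=200, seed=7)
        b = randomization_null(pool, 0.1, n_reps=200, seed=7)
        assert np.array_equal(a.null_means, b.null_means)

    def test_empirical_p_never_zero(self):
        pool = simulate_ortholog_pool(500, seed=8)
        res = randomization_null(pool, observed_mean=-1.0, n_reps=100, seed=9)
        assert res.empirical_p == pytest.approx(1 / 101)

    def test_unsatisfiable_constraint_rejected(self):
        pool = simulate_ortholog_pool(50, tag_fraction=0.0, seed=10)
        with pytest.raises(ValueError):
            randomization_null(pool, 0.0, n_reps=10, seed=0,
                               constraint=("Galpha", 6))


class TestHistogram:
    def test_single_value_one_bin(self):
        bins = histogram_bins([0.3], 0.1)
        assert len(bins) == 1
        lo, hi, count = bins[0]
        assert count == 1 and lo <= 0.3 < hi
        assert hi - lo == pytest.approx(0.1)

    def test_counts_conserved(self, rng):
        values = rng.normal(size=1234)
        bins = histogram_bins(values, 0.25)
        assert sum(c for _, _, c in bins) == 1234

    def test_matches_direct_counting(self, rng):
        values = rng.uniform(0, 1, size=500)
        for lo, hi, count in histogram_bins(values, 0.1):
            assert count == ((values >= lo) & (values < hi)).sum()

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError):
            histogram_bins([1.0], 0.0)
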