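import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cavicorr.coupling import (
    CSC,
    CouplingResult,
    analyze_pairs,
    cavity_ca_correlation,
    compare_correlation_distributions,
    fdr_adjust,
    identify_cscs,
    mi_correlation,
    n_bins_for,
    null_distribution,
    pearson_correlation,
    permutation_pvalue,
    rank_bins,
)
from cavicorr.errors import ConsistencyError, DegeneracyError, ParameterError
from cavicorr.synthetic import generate_series_set


def exact_mi_r(joint_counts):
    """Plug-in normalized MI straight from a contingency table (oracle)."""
    joint = np.asarray(joint_counts, float)
    p = joint / joint.sum()
    px, py = p.sum(axis=1), p.sum(axis=0)
    hx = -sum(q * np.log(q) for q in px if q > 0)
    hy = -sum(q * np.log(q) for q in py if q > 0)
    mi = sum(
        p[i, j] * np.log(p[i, j] / (px[i] * py[j]))
        for i in range(p.shape[0])
        for j in range(p.shape[1])
        if p[i, j] > 0
    )
    return mi / np.sqrt(hx * hy)


class TestMiCorrelation:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=100)
        assert mi_correlation(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_exact_contingency_table_oracle_n20(self):
        # B = 2 at n = 20; perfectly aligned halves -> r = 1
        x = np.arange(20, dtype=float)
        y_aligned = np.arange(20, dtype=float)
        assert mi_correlation(x, y_aligned) == pytest.approx(
            exact_mi_r([[10, 0], [0, 10]]), abs=1e-12
        )
        assert mi_correlation(x, y_aligned) == pytest.approx(1.0)
        # balanced 2x2 -> r = 0: low x half split evenly over y halves
        y_balanced = np.array([0, 10, 1, 11, 2, 12, 3, 13, 4, 14,
                               5, 15, 6, 16, 7, 17, 8, 18, 9, 19], dtype=float)
        assert mi_correlation(x, y_balanced) == pytest.approx(
            exact_mi_r([[5, 5], [5, 5]]), abs=1e-12
        )
        assert mi_correlation(x, y_balanced) == pytest.approx(0.0, abs=1e-12)

    def test_null_mean_below_quarter(self, rng):
        rs = [
            mi_correlation(rng.uniform(size=100), rng.uniform(size=100))
            for _ in range(200)
        ]
        assert np.mean(rs) < 0.25

    def test_invariant_to_strictly_monotone_transforms(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        base = mi_correlation(x, y)
        assert mi_correlation(x, np.exp(y)) == pytest.approx(base, abs=1e-12)
        assert mi_correlation(-np.expm1(-x), y) == pytest.approx(base, abs=1e-12)

    def test_symmetric(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert mi_correlation(x, y) == pytest.approx(mi_correlation(y, x), abs=1e-12)

    def test_constant_series_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert mi_correlation(np.ones(30), np.arange(30.0)) == 0.0

    def test_short_series_rejected(self):
        with pytest.raises(ParameterError):
            mi_correlation(np.arange(10.0), np.arange(10.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 150))
        x = rng.normal(size=n)
        y = x * rng.uniform(-1, 1) + rng.normal(size=n) * rng.uniform(0, 2)
        r = mi_correlation(x, y)
        assert 0.0 <= r <= 1.0

    def test_bin_count_rule(self):
        assert n_bins_for(100) == 4
        assert n_bins_for(20) == 2
        assert n_bins_for(21) == 2

    def test_rank_binning_equal_frequency(self, rng):
        labels = rank_bins(rng.normal(size=100), 4)
        assert np.bincount(labels).tolist() == [25, 25, 25, 25]


class TestPermutationPvalue:
    def test_floor_when_observed_tops_all_permutations(self, rng):
        x = rng.normal(size=40)
        assert permutation_pvalue(x, x, n_perm=999, seed=1) == pytest.approx(0.001)

    def test_self_pair_small_n_perm(self, rng):
        x = rng.normal(size=20)
        assert permutation_pvalue(x, x, n_perm=99, seed=2) == pytest.approx(0.01)

    def test_uniform_under_independence(self, rng):
        null = null_distribution(100, n_perm=2000, seed=rng)
        ps = [
            permutation_pvalue(rng.normal(size=100), rng.normal(size=100), null=null)
            for _ in range(500)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_shared_null_agrees_with_per_pair_permutation(self, rng):
        null = null_distribution(40, n_perm=2000, seed=123)
        for _ in range(3):
            x = rng.normal(size=40)
            y = 0.5 * x + rng.normal(size=40)
            p_shared = permutation_pvalue(x, y, null=null)
            p_direct = permutation_pvalue(x, y, n_perm=2000, seed=rng)
            tol = 2 * np.sqrt(max(p_direct * (1 - p_direct), 1e-4) / 2000)
            assert abs(p_shared - p_direct) <= tol + 2e-3

    def test_small_n_perm_rejected(self, rng):
        with pytest.raises(ParameterError):
            permutation_pvalue(rng.normal(size=30), rng.normal(size=30), n_perm=10)


class TestNullDistribution:
    def test_support_in_unit_interval(self):
        null = null_distribution(50, n_perm=500, seed=0)
        assert null.values.min() >= 0.0 and null.values.max() <= 1.0

    def test_stable_across_seeds_within_monte_carlo_error(self):
        a = null_distribution(100, n_perm=10_000, seed=1).values
        b = null_distribution(100, n_perm=10_000, seed=2).values
        se = np.sqrt(a.var() / a.size + b.var() / b.size)
        assert abs(a.mean() - b.mean()) <= 3 * se
        assert stats.ks_2samp(a, b).pvalue > 1e-3


class TestFdrAdjust:
    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_tied_values(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(fdr_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_matches_step_up_formula_on_random_inputs(self, rng):
        p = rng.uniform(0.001, 1.0, size=25)
        # independent hand implementation: sort, p_(i)*m/i, cumulative min
        order = np.argsort(p)
        m = len(p)
        scaled = p[order] * m / np.arange(1, m + 1)
        adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adjusted_sorted, 1.0)
        np.testing.assert_allclose(fdr_adjust(p), expected, atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ParameterError):
            fdr_adjust([0.0, 0.5])


class TestIdentifyCscs:
    @staticmethod
    def result(pair, p_adj, replica="r1", r=0.5):
        return CouplingResult(pair, r, min(p_adj, 0.5), p_adj, replica)

    def test_replica_conservation_filter(self):
        r1 = [self.result(("a", "b"), 0.01), self.result(("a", "c"), 0.01)]
        r2 = [self.result(("a", "b"), 0.02, "r2"), self.result(("a", "c"), 0.5, "r2")]
        cscs = identify_cscs(r1, r2, alpha=0.05)
        assert [c.pair for c in cscs] == [("a", "b")]
        assert not cscs[0].single_replica

    def test_single_replica_mode_flags_results(self):
        r1 = [self.result(("a", "b"), 0.01)]
        cscs = identify_cscs(r1, None)
        assert cscs and cscs[0].single_replica

    def test_pair_set_mismatch_rejected(self):
        r1 = [self.result(("a", "b"), 0.01)]
        r2 = [self.result(("a", "c"), 0.01, "r2")]
        with pytest.raises(ConsistencyError):
            identify_cscs(r1, r2)

    def test_monotone_in_alpha_and_subset_of_each_replica(self, rng):
        pairs = list(itertools.combinations("abcdef", 2))
        r1 = [self.result(p, float(x)) for p, x in zip(pairs, rng.uniform(0.001, 1, 15))]
        r2 = [self.result(p, float(x), "r2") for p, x in zip(pairs, rng.uniform(0.001, 1, 15))]
        previous = None
        for alpha in (0.2, 0.1, 0.05, 0.01):
            current = {c.pair for c in identify_cscs(r1, r2, alpha)}
            if previous is not None:
                assert current <= previous
            assert current <= {c.pair for c in identify_cscs(r1, None, alpha)}
            previous = current

    def test_ten_cavities_produce_45_tested_pairs(self, rng):
        series = {f"c{i:02d}": rng.normal(size=50) for i in range(10)}
        results = analyze_pairs(series, n_perm=200, seed=1)
        assert len(results) == 45


class TestCaCorrelation:
    def test_identical_series_significant(self, rng):
        x = rng.normal(size=80)
        sig, r, p = cavity_ca_correlation(x, x, n_perm=200, seed=3)
        assert sig and r == pytest.approx(1.0) and p == pytest.approx(1 / 201)

    def test_independent_series_rarely_significant(self, rng):
        null = null_distribution(80, n_perm=1000, seed=rng)
        hits = sum(
            cavity_ca_correlation(
                rng.normal(size=80), rng.normal(size=80), null=null
            )[0]
            for _ in range(100)
        )
        assert hits <= 10  # non-significant in >= 90% of null simulations

    def test_csc_class_counts_member_cavities(self):
        res = CouplingResult(("a", "b"), 0.6, 0.001, 0.004)
        assert CSC(("a", "b"), (res,), ca_class=2).ca_class == 2


class TestDistributionComparison:
    def test_identical_samples_d_zero(self):
        d, _ = compare_correlation_distributions([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert d == 0.0

    def test_fully_separated_samples_d_one(self):
        d, p = compare_correlation_distributions([0.1, 0.2], [0.8, 0.9])
        assert d == 1.0

    def test_matches_ecdf_max_gap_enumeration(self, rng):
        a = rng.uniform(size=7)
        b = rng.uniform(size=5)
        grid = np.concatenate([a, b])
        gaps = [
            abs(np.mean(a <= v) - np.mean(b <= v)) for v in grid
        ]
        d, _ = compare_correlation_distributions(a, b)
        assert d == pytest.approx(max(gaps), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            compare_correlation_distributions([], [0.5])


class TestPearson:
    def test_linear_relations(self):
        x = np.arange(5.0)
        assert pearson_correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        assert pearson_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.raises(DegeneracyError):
            pearson_correlation(np.ones(5), np.arange(5.0))


class TestFdrControlUnderExchangeableNull:
    def test_mixture_fdp_at_nominal_level_without_autocorrelation(self, rng):
        """With exchangeable (white) null series the permutation null is
        exact and BH keeps the realized FDP at its nominal level; the
        autocorrelated stress case is exercised by the acceptance suite."""
        from cavicorr.synthetic import PlantedCoupling

        planted = [
            PlantedCoupling(("c01", "c02"), 0.95),
            PlantedCoupling(("c03", "c04"), 0.95),
            PlantedCoupling(("c05", "c06"), 0.95),
        ]
        pp = {p.pair for p in planted}
        null = null_distribution(100, n_perm=1000, seed=rng)
        fdps = []
        for _ in range(200):
            series = generate_series_set(planted=planted, phi=0.0, seed=rng)
            res = analyze_pairs(series, n_perm=1000, seed=rng, null=null)
            kept = [r for r in res if r.p_adj <= 0.05]
            fdps.append(sum(r.pair not in pp for r in kept) / max(len(kept), 1))
        mean = np.mean(fdps)
        se = np.std(fdps) / np.sqrt(len(fdps))
        assert mean <= 0.05 + 2 * se
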