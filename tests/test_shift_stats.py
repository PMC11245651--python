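"""Two-sample shift statistics against independent oracles and invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as st

from driftwatch.datamodel import FeatureSpec
from driftwatch.shift_stats import (
    DegenerateStatisticError,
    WindowDriftTest,
    chi_square_presence,
    compare_window,
    daily_standardized_differences,
    ks_two_sample,
    pooled_window_values,
    standardized_difference,
)
from driftwatch.synthetic import ShiftInjection, make_reference, simulate_stream

from conftest import small_generator


def oracle_std_diff(a, b):
    """Independent one-liner for (m1-m2)/sqrt((s1^2+s2^2)/2)."""
    import statistics

    return (statistics.fmean(a) - statistics.fmean(b)) / (
        (statistics.variance(a) + statistics.variance(b)) / 2
    ) ** 0.5


class TestStandardizedDifference:
    def test_identical_samples_give_zero(self, rng):
        a = rng.normal(size=40)
        assert standardized_difference(a, a) == 0.0

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(50):
            n, m = rng.integers(5, 40, size=2)
            a = rng.lognormal(0, 1, n)
            b = rng.gamma(2.0, 1.5, m)
            assert standardized_difference(a, b) == pytest.approx(
                oracle_std_diff(a, b), abs=1e-10
            )

    @pytest.mark.parametrize("c", [-2.0, -0.5, 0.25, 1.0, 3.0])
    def test_constant_shift_in_pooled_sd_units(self, rng, c):
        """Shifting one sample by c pooled SDs yields exactly c."""
        b = rng.normal(size=200)
        a = b + c * b.std(ddof=1)
        assert standardized_difference(a, b) == pytest.approx(c, abs=1e-10)

    def test_binary_proportion_form(self, rng):
        a = (rng.random(300) < 0.4).astype(float)
        b = (rng.random(250) < 0.2).astype(float)
        p, q = a.mean(), b.mean()
        # sample variance of 0/1 data is n/(n-1) * p(1-p); the Bernoulli form
        # used for proportions drops that correction
        expected = (p - q) / np.sqrt((p * (1 - p) + q * (1 - q)) / 2)
        test = WindowDriftTest(kind="binary").fit(b)
        assert test.compare(a).standardized_difference == pytest.approx(expected, abs=1e-10)

    def test_antisymmetric_and_affine_invariant(self, rng):
        for _ in range(20):
            a = rng.normal(2, 3, 30)
            b = rng.normal(1, 2, 25)
            d = standardized_difference(a, b)
            assert standardized_difference(b, a) == pytest.approx(-d, abs=1e-12)
            assert standardized_difference(5 * a - 7, 5 * b - 7) == pytest.approx(d, abs=1e-9)

    def test_missing_values_ignored_and_all_missing_rejected(self):
        a = np.array([1.0, np.nan, 2.0, np.nan, 3.0])
        b = np.array([1.0, 2.0, 3.0])
        assert standardized_difference(a, b) == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(DegenerateStatisticError):
            standardized_difference(np.array([np.nan, np.nan]), b)

    def test_zero_variance_equal_means_is_zero(self):
        assert standardized_difference([2.0, 2.0, 2.0], [2.0, 2.0]) == 0.0

    sample = hst.lists(
        hst.floats(min_value=-100, max_value=100, allow_nan=False),
        min_size=2, max_size=25,
    )

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(a=sample, b=sample)
    def test_antisymmetry_holds_for_arbitrary_samples(self, a, b):
        d = standardized_difference(a, b)
        d_rev = standardized_difference(b, a)
        if np.isinf(d):
            assert d_rev == -d
        else:
            assert d_rev == pytest.approx(-d, abs=1e-12)


class TestKolmogorovSmirnov:
    def test_identical_samples_statistic_zero(self, rng):
        a = rng.normal(size=30)
        stat, _ = ks_two_sample(a, a)
        assert stat == 0.0

    def test_disjoint_supports_statistic_one(self, rng):
        a = rng.uniform(0, 1, 20)
        b = rng.uniform(5, 6, 25)
        stat, p = ks_two_sample(a, b)
        assert stat == 1.0
        assert p < 1e-6

    def test_small_sample_p_matches_exact_enumeration(self, rng):
        """At n=(5,5) the p-value equals the proportion of the 252 label
        assignments of the pooled sample whose KS statistic is at least the
        observed one."""
        def ks_stat(x, y):
            grid = np.sort(np.concatenate([x, y]))
            cx = np.searchsorted(np.sort(x), grid, side="right") / len(x)
            cy = np.searchsorted(np.sort(y), grid, side="right") / len(y)
            return np.max(np.abs(cx - cy))

        for _ in range(5):
            a = rng.normal(size=5)
            b = rng.normal(0.8, 1.3, size=5)
            stat, p = ks_two_sample(a, b)
            pooled = np.concatenate([a, b])
            stats = []
            for idx in itertools.combinations(range(10), 5):
                mask = np.zeros(10, bool)
                mask[list(idx)] = True
                stats.append(ks_stat(pooled[mask], pooled[~mask]))
            exact = np.mean(np.array(stats) >= stat - 1e-12)
            assert stat == pytest.approx(ks_stat(a, b), abs=1e-12)
            assert p == pytest.approx(exact, abs=1e-10)

    def test_invariant_under_increasing_transform_and_bounded(self, rng):
        for _ in range(20):
            a = rng.lognormal(0, 1, 35)
            b = rng.lognormal(0.3, 1, 40)
            stat, p = ks_two_sample(a, b)
            assert 0.0 <= stat <= 1.0
            stat2, p2 = ks_two_sample(np.log(a), np.log(b))
            assert stat2 == pytest.approx(stat, abs=1e-12)
            assert p2 == pytest.approx(p, rel=1e-9)

    def test_heavily_tied_samples_handled(self):
        a = np.array([0.0] * 10 + [1.0] * 10)
        b = np.array([0.0] * 15 + [1.0] * 5)
        stat, p = ks_two_sample(a, b)
        assert stat == pytest.approx(0.25, abs=1e-12)
        assert 0.0 <= p <= 1.0


class TestChiSquare:
    def test_equal_proportions_statistic_zero(self):
        a = np.array([1.0] * 10 + [0.0] * 10)
        b = np.array([1.0] * 10 + [0.0] * 10)
        stat, p, degen = chi_square_presence(a, b)
        assert stat == 0.0 and p == 1.0 and not degen

    def test_matches_closed_form_oracle_on_random_tables(self, rng):
        """Pearson X^2 = sum (O-E)^2 / E over the 2x2 presence table."""
        for _ in range(50):
            n1, n2 = rng.integers(10, 80, 2)
            a = (rng.random(n1) < rng.uniform(0.1, 0.9)).astype(float)
            b = (rng.random(n2) < rng.uniform(0.1, 0.9)).astype(float)
            table = np.array(
                [[a.sum(), len(a) - a.sum()], [b.sum(), len(b) - b.sum()]]
            )
            if (table.sum(axis=0) == 0).any():
                continue
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            oracle = ((table - expected) ** 2 / expected).sum()
            stat, p, degen = chi_square_presence(a, b)
            assert not degen
            assert stat == pytest.approx(oracle, abs=1e-10)
            assert p == pytest.approx(st.chi2.sf(oracle, df=1), abs=1e-10)

    def test_invariant_under_group_swap(self, rng):
        a = (rng.random(60) < 0.3).astype(float)
        b = (rng.random(40) < 0.5).astype(float)
        assert chi_square_presence(a, b)[0] == pytest.approx(
            chi_square_presence(b, a)[0], abs=1e-12
        )

    def test_zero_margin_degenerate(self):
        a = np.zeros(20)
        b = np.zeros(30)
        stat, p, degen = chi_square_presence(a, b)
        assert (stat, p, degen) == (0.0, 1.0, True)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            chi_square_presence(np.array([0.0, 2.0]), np.array([0.0, 1.0]))

    def test_null_p_values_approximately_uniform(self, rng):
        """Under H0 (both groups Bernoulli(0.3), n=200) the p-values are
        approximately uniform (Kolmogorov check, allowing for the mild
        discreteness of the statistic)."""
        ps = []
        for _ in range(400):
            a = (rng.random(200) < 0.3).astype(float)
            b = (rng.random(200) < 0.3).astype(float)
            ps.append(chi_square_presence(a, b)[1])
        assert st.kstest(ps, "uniform").statistic < 0.12
        assert abs(np.mean(np.array(ps) < 0.05) - 0.05) < 0.03


class TestCompareWindow:
    def _stream_and_ref(self, seed, injections=()):
        cfg = small_generator(seed=seed, n_days=14, calls_per_day=100, n_reference=400)
        return make_reference(cfg), simulate_stream(cfg, injections)

    def test_null_window_rarely_significant(self):
        """A window resampled from the reference law is non-significant for
        most seeds and features."""
        hits = trials = 0
        for seed in range(12):
            ref, stream = self._stream_and_ref(seed)
            for feature in ref.catalogue:
                cs = compare_window(feature, stream, ref)
                trials += 1
                hits += cs.p_value < 0.05
        assert hits / trials <= 0.10

    def test_mean_shift_detected_with_near_certain_power(self):
        """+1 pooled-SD mean shift, daily n=100 over a 14-day window."""
        for seed in range(5):
            ref, stream = self._stream_and_ref(
                seed, (ShiftInjection("lab_01", "mean_shift", onset_day=1, magnitude=1.0),)
            )
            feature = next(f for f in ref.catalogue if f.name == "lab_01")
            cs = compare_window(feature, stream, ref)
            assert cs.test_name == "ks"
            assert cs.p_value < 0.05

    def test_binary_prevalence_shift_detected(self):
        for seed in range(5):
            ref, stream = self._stream_and_ref(
                seed,
                (ShiftInjection("flag_01", "prevalence_shift", onset_day=1, magnitude=0.25),),
            )
            feature = next(f for f in ref.catalogue if f.name == "flag_01")
            cs = compare_window(feature, stream, ref)
            assert cs.test_name == "chi_square"
            assert cs.p_value < 0.05

    def test_all_missing_window_yields_degenerate_row(self):
        ref, stream = self._stream_and_ref(
            3, (ShiftInjection("lab_02", "code_change", onset_day=1),)
        )
        feature = next(f for f in ref.catalogue if f.name == "lab_02")
        cs = compare_window(feature, stream, ref)
        assert cs.degenerate
        assert cs.n_incoming == 0

    def test_type_one_error_calibrated(self, rng):
        """Null rejection rate of the window test sits near alpha."""
        test = WindowDriftTest(kind="continuous", alpha=0.05)
        hits = 0
        reps = 400
        for _ in range(reps):
            test.fit(rng.lognormal(0, 1, 400))
            hits += test.predict(rng.lognormal(0, 1, 600))
        assert 0.02 <= hits / reps <= 0.08


class TestDailyStandardizedDifferences:
    def test_series_length_matches_present_days(self, reference, null_stream):
        feature = reference.catalogue[0]
        series = daily_standardized_differences(feature, null_stream, reference)
        assert len(series) == len(null_stream)
        assert list(series.index) == [s.date for s in null_stream]

    def test_stationary_stream_fluctuates_around_zero(self, reference, null_stream):
        feature = reference.catalogue[0]
        series = daily_standardized_differences(feature, null_stream, reference)
        assert abs(series.mean()) < 0.2

    def test_step_shift_raises_later_days(self):
        cfg = small_generator(seed=42, n_days=14, calls_per_day=100)
        ref = make_reference(cfg)
        stream = simulate_stream(
            cfg, (ShiftInjection("lab_01", "mean_shift", onset_day=8, magnitude=1.5),)
        )
        feature = next(f for f in ref.catalogue if f.name == "lab_01")
        series = daily_standardized_differences(feature, stream, ref)
        before = series.iloc[:7].abs().mean()
        after = series.iloc[7:].abs().mean()
        assert after > before + 0.5

    def test_sparse_day_yields_nan(self, reference):
        cfg = small_generator(seed=9, n_days=3, calls_per_day=1.0)
        ref = make_reference(cfg)
        stream = simulate_stream(cfg)
        feature = ref.catalogue[0]
        series = daily_standardized_differences(feature, stream, ref)
        sparse = [s.date for s in stream if len(s.feature_values(feature.name)) < 2]
        for day in sparse:
            assert np.isnan(series[day])


def test_pooled_window_values_concatenates_non_missing(reference, null_stream):
    feature = reference.catalogue[0]
    pooled = pooled_window_values(feature, null_stream)
    assert len(pooled) == sum(len(s.feature_values(feature.name)) for s in null_stream)
    assert not np.isnan(pooled).any()
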