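"""Distribution specs: validation, inverse-CDF sampling, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tuberoot import (
    DistributionSpec,
    ValidationError,
    fit_distribution,
    interval_for_u,
    sample_parameter,
)
from tuberoot.distributions import sample_nonnegative


def brute_force_interval(probs, u):
    """Reference cumulative-sum walk: u in (cum[i-1], cum[i]]."""
    cum = np.concatenate([[0.0], np.cumsum(probs)])
    for i in range(len(probs)):
        if cum[i] < u <= cum[i + 1]:
            return i
    return len(probs) - 1


class TestIntervalSelection:
    def test_matches_cumulative_sum_walk(self, zspec):
        # cum = 0.12, 0.48, 0.62, 0.78, 0.94, 1.00
        for u in np.linspace(0.001, 0.999, 997):
            assert interval_for_u(zspec, u) == brute_force_interval(
                zspec.probs, u
            )

    def test_half_falls_in_third_interval(self, zspec):
        # 0.48 < 0.50 <= 0.62 selects [101, 115], not [86, 100]
        i = interval_for_u(zspec, 0.50)
        assert i == 2
        assert zspec.intervals[i] == (101, 115)

    def test_boundary_u_goes_to_lower_interval(self, zspec):
        assert interval_for_u(zspec, 0.12) == 0
        assert interval_for_u(zspec, 0.12 + 1e-12) == 1

    def test_zero_probability_interval_never_selected(self):
        spec = DistributionSpec(
            kind="empirical",
            intervals=((0, 1), (2, 3), (4, 5)),
            probs=(0.5, 0.0, 0.5),
        )
        rng = np.random.default_rng(7)
        x = sample_parameter(spec, rng, size=2000)
        assert not np.any((x >= 2) & (x <= 3))


class TestSampling:
    def test_degenerate_interval_is_constant(self):
        spec = DistributionSpec(kind="empirical", intervals=((5, 5),),
                                probs=(1.0,))
        rng = np.random.default_rng(0)
        assert all(sample_parameter(spec, rng) == 5 for _ in range(20))

    def test_zero_variance_normal_is_constant(self):
        spec = DistributionSpec(kind="normal", mu=100, sigma=0)
        rng = np.random.default_rng(0)
        assert all(sample_parameter(spec, rng) == 100 for _ in range(20))

    def test_empirical_samples_stay_inside_intervals(self, zspec):
        rng = np.random.default_rng(3)
        x = sample_parameter(zspec, rng, size=5000)
        inside = np.zeros(len(x), bool)
        for a, b in zspec.intervals:
            inside |= (x >= a) & (x <= b)
        assert inside.all()

    def test_empirical_frequencies_match_probs(self, zspec):
        n = 100_000
        rng = np.random.default_rng(42)
        x = sample_parameter(zspec, rng, size=n)
        for (a, b), p in zip(zspec.intervals, zspec.probs):
            f = np.mean((x >= a) & (x <= b))
            assert abs(f - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_nonnegative_sampler_clamps_hopeless_specs(self):
        spec = DistributionSpec(kind="normal", mu=-50, sigma=0.1)
        rng = np.random.default_rng(0)
        assert sample_nonnegative(spec, rng) == 0.0


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(kind="normal", mu=0, sigma=-1),
            dict(kind="empirical", intervals=((0, 1),), probs=(0.9,)),
            dict(kind="empirical", intervals=((0, 1), (0.5, 2)),
                 probs=(0.5, 0.5)),
            dict(kind="empirical", intervals=((1, 0),), probs=(1.0,)),
            dict(kind="empirical", intervals=((0, 1),), probs=(0.5, 0.5)),
            dict(kind="empirical", intervals=((0, 1), (2, 3)),
                 probs=(1.5, -0.5)),
            dict(kind="lognormal", mu=0, sigma=1),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            DistributionSpec(**kwargs)

    def test_mean_of_empirical_is_prob_weighted_midpoints(self, zspec):
        expected = sum(
            p * (a + b) / 2 for (a, b), p in zip(zspec.intervals, zspec.probs)
        )
        assert zspec.mean() == pytest.approx(expected)

    def test_interval_prob_recovers_printed_probs(self, zspec):
        for (a, b), p in zip(zspec.intervals, zspec.probs):
            assert zspec.interval_prob(a, b) == pytest.approx(p)


class TestFitting:
    def test_normal_data_fits_normal(self):
        rng = np.random.default_rng(11)
        spec = fit_distribution(rng.normal(100, 10, size=500))
        assert spec.kind == "normal"
        assert abs(spec.mu - 100) < 2
        assert abs(spec.sigma - 10) < 2

    def test_bimodal_data_fits_empirical(self):
        rng = np.random.default_rng(12)
        x = np.concatenate(
            [rng.normal(75, 3, 250), rng.normal(140, 3, 250)]
        )
        spec = fit_distribution(x)
        assert spec.kind == "empirical"
        assert sum(spec.probs) == pytest.approx(1.0, abs=1e-6)

    def test_constant_sample_degenerates(self):
        spec = fit_distribution([7.0] * 12)
        assert spec.kind == "empirical"
        assert spec.intervals == ((7.0, 7.0),)
        assert spec.probs == (1.0,)

    def test_too_few_samples_error(self):
        with pytest.raises(ValidationError, match=">= 8"):
            fit_distribution([1, 2, 3])

    def test_non_finite_samples_error(self):
        with pytest.raises(ValidationError):
            fit_distribution([1, 2, 3, 4, 5, 6, 7, np.nan])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=-1e4, max_value=1e4), min_size=8,
                 max_size=200),
        st.integers(0, 2 ** 31 - 1),
    )
    def test_fitted_probs_always_normalized(self, base, seed):
        # jitter avoids hypothesis shrinking to all-equal lists
        rng = np.random.default_rng(seed)
        x = np.asarray(base) + rng.normal(0, 1e-3, len(base))
        spec = fit_distribution(x)
        if spec.kind == "empirical":
            assert abs(sum(spec.probs) - 1) < 1e-6
            assert all(p >= 0 for p in spec.probs)
            assert all(a <= b for a, b in spec.intervals)
        else:
            assert spec.sigma >= 0

    def test_cdf_is_monotone(self, zspec):
        xs = np.linspace(60, 170, 400)
        cs = [zspec.cdf(x) for x in xs]
        assert all(b >= a for a, b in zip(cs, cs[1:]))
        assert cs[0] == 0.0
        assert cs[-1] == pytest.approx(1.0)
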