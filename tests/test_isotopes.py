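"""Unit and property tests for the two-endmember oxygen-isotope mixing model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nitrokit import (
    ATMOSPHERIC,
    BIOLOGICAL,
    ApportionConfig,
    ConfigurationError,
    DegenerateEndmemberError,
    Endmember,
    InvalidMeasurementError,
    InvalidUncertaintyError,
    IsotopeMeasurement,
    NoDataError,
    SampleType,
    Tracer,
    aggregate_observations,
    apportion_dataset,
    biological_endmember_d18O,
    delta17O_anomaly,
    monte_carlo_fraction,
    two_endmember_fraction,
)

finite_delta = st.floats(-100, 150, allow_nan=False, allow_infinity=False)


class TestAnomaly:
    @pytest.mark.parametrize(
        "d17O, d18O, lam, expected",
        [
            (0.52 * 40.0, 40.0, 0.52, 0.0),  # on the mass-dependent line
            (10.0, 0.0, 0.52, 10.0),
            (18.0, 20.0, 0.52, 7.6),
        ],
    )
    def test_examples(self, d17O, d18O, lam, expected):
        assert delta17O_anomaly(d17O, d18O, lam) == pytest.approx(expected, abs=1e-12)

    @given(finite_delta)
    def test_mass_dependent_line_is_zero(self, d18O):
        assert delta17O_anomaly(0.52 * d18O, d18O) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("bad", [float("nan"), float("inf")])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(InvalidMeasurementError):
            delta17O_anomaly(bad, 1.0)
        with pytest.raises(InvalidMeasurementError):
            delta17O_anomaly(1.0, bad)

    @pytest.mark.parametrize("lam", [0.0, 1.0, -0.5, 2.0])
    def test_lambda_bounds(self, lam):
        with pytest.raises(ConfigurationError):
            delta17O_anomaly(1.0, 1.0, lam)


class TestBiologicalEndmember:
    def test_study_system_inputs(self):
        # 2/3 water at -12.7 permil, 1/3 O2 at 23.9 permil
        assert biological_endmember_d18O(-12.7, 23.9) == pytest.approx(-0.5, abs=1e-9)

    def test_zero_pools(self):
        assert biological_endmember_d18O(0.0, 0.0) == 0.0

    @given(finite_delta, st.floats(0, 1))
    def test_identical_pools_pass_through(self, x, w):
        assert biological_endmember_d18O(x, x, w) == pytest.approx(x, abs=1e-9)

    def test_weight_bounds(self):
        with pytest.raises(ConfigurationError):
            biological_endmember_d18O(0.0, 0.0, w_water=1.5)


class TestTwoEndmemberFraction:
    def test_sediment_d18O(self):
        r = two_endmember_fraction(4.6, em_bio=0.6, em_atm=92.0)
        assert r.f_bio == pytest.approx(0.9562, abs=5e-4)
        assert r.f_atm + r.f_bio == 1.0
        assert not r.clipped

    def test_sediment_anomaly(self):
        r = two_endmember_fraction(1.3, em_bio=0.0, em_atm=32.0, tracer=Tracer.D17O)
        assert r.f_bio == pytest.approx(0.9594, abs=5e-4)
        assert r.tracer is Tracer.D17O

    def test_endpoint_identity(self):
        r = two_endmember_fraction(0.6, em_bio=0.6, em_atm=92.0)
        assert r.f_atm == 0.0 and r.f_bio == 1.0

    def test_degenerate_endmembers(self):
        with pytest.raises(DegenerateEndmemberError):
            two_endmember_fraction(1.0, em_bio=5.0, em_atm=5.0)

    def test_out_of_hull_flagged_without_clip(self):
        r = two_endmember_fraction(-3.0, 0.6, 92.0, clip=False)
        assert r.out_of_hull and not r.clipped and r.f_atm < 0

    def test_clip_flags_and_bounds(self):
        r = two_endmember_fraction(-3.0, 0.6, 92.0, clip=True)
        assert r.clipped and r.f_atm == 0.0 and r.f_bio == 1.0

    @given(
        st.floats(0, 1),
        st.floats(-30, 30, allow_nan=False),
        st.floats(1, 120, allow_nan=False),
    )
    def test_inversion_recovers_mixture(self, f, em_bio, separation):
        """Forward-mix then apportion is the identity on the fraction."""
        em_atm = em_bio + separation
        obs = f * em_atm + (1 - f) * em_bio
        r = two_endmember_fraction(obs, em_bio, em_atm)
        assert r.f_atm == pytest.approx(f, abs=1e-12)
        assert r.f_atm + r.f_bio == 1.0

    @given(
        st.floats(-30, 30), st.floats(1, 120),
        st.floats(0, 1), st.floats(0, 1),
    )
    def test_monotone_in_observation(self, em_bio, separation, f1, f2):
        em_atm = em_bio + separation
        lo, hi = sorted((f1, f2))
        if hi - lo < 1e-9:
            return
        obs_lo = lo * em_atm + (1 - lo) * em_bio
        obs_hi = hi * em_atm + (1 - hi) * em_bio
        assert (
            two_endmember_fraction(obs_hi, em_bio, em_atm).f_atm
            > two_endmember_fraction(obs_lo, em_bio, em_atm).f_atm
        )


class TestAggregate:
    def test_single(self, sediment_measurements):
        assert aggregate_observations(sediment_measurements[1:2]) == 4.6

    def test_mean_first(self, sediment_measurements):
        assert aggregate_observations(sediment_measurements) == pytest.approx(4.6)

    def test_per_sample_passthrough(self, sediment_measurements):
        vals = aggregate_observations(sediment_measurements, mode="per_sample")
        assert vals == [3.6, 4.6, 5.6]

    def test_empty_raises(self):
        with pytest.raises(NoDataError):
            aggregate_observations([])

    def test_measured_anomaly_takes_precedence(self):
        m = IsotopeMeasurement("x", SampleType.soil, d18O=10.0, d17O=7.0, D17O=2.5)
        assert m.anomaly() == 2.5

    def test_computed_anomaly_fallback(self):
        m = IsotopeMeasurement("x", SampleType.soil, d18O=10.0, d17O=7.0)
        assert m.anomaly() == pytest.approx(7.0 - 5.2)


class TestMonteCarlo:
    def test_zero_sigma_collapses_to_point(self):
        bio = Endmember("b", d18O=0.6)
        atm = Endmember("a", d18O=92.0)
        r = monte_carlo_fraction(4.6, 0.0, bio, atm, n_draws=5000, seed=1)
        assert r.ci_high - r.ci_low == pytest.approx(0.0, abs=1e-15)
        assert r.median == pytest.approx(r.f_atm, abs=1e-15)

    def test_median_matches_closed_form(self):
        r = monte_carlo_fraction(
            4.6, 0.3, BIOLOGICAL, ATMOSPHERIC, n_draws=100_000, seed=7
        )
        assert r.median == pytest.approx(1 - 0.9562, abs=0.005)
        assert r.ci_low <= r.f_atm <= r.ci_high

    def test_independent_resimulation_oracle(self):
        """Cross-check the percentile interval against a legacy-generator
        re-simulation of the identical Gaussian model."""
        rs = np.random.RandomState(123)
        f = np.clip((rs.normal(4.6, 0.3, 100_000) - 0.6) / (92.0 - 0.6), 0, 1)
        expected = np.percentile(f, [2.5, 50, 97.5])
        r = monte_carlo_fraction(
            4.6, 0.3, BIOLOGICAL, ATMOSPHERIC, n_draws=100_000, seed=99
        )
        assert r.ci_low == pytest.approx(expected[0], abs=2e-3)
        assert r.median == pytest.approx(expected[1], abs=2e-3)
        assert r.ci_high == pytest.approx(expected[2], abs=2e-3)

    def test_deterministic_given_seed(self):
        a = monte_carlo_fraction(4.6, 0.3, BIOLOGICAL, ATMOSPHERIC, n_draws=2000, seed=5)
        b = monte_carlo_fraction(4.6, 0.3, BIOLOGICAL, ATMOSPHERIC, n_draws=2000, seed=5)
        assert a == b

    def test_negative_sigma_rejected(self):
        with pytest.raises(InvalidUncertaintyError):
            monte_carlo_fraction(4.6, -0.1, BIOLOGICAL, ATMOSPHERIC, seed=1)

    def test_seed_required(self):
        with pytest.raises(ConfigurationError):
            monte_carlo_fraction(4.6, 0.3, BIOLOGICAL, ATMOSPHERIC, seed=None)


class TestApportionDataset:
    def test_sediment_rows(self, sediment_measurements):
        df = apportion_dataset(
            sediment_measurements, config=ApportionConfig(seed=3)
        )
        d18 = df[(df.group == "sediment") & (df.tracer == "d18O")].iloc[0]
        assert d18.f_bio == pytest.approx(0.956, abs=1e-3)
        d17 = df[(df.group == "sediment") & (df.tracer == "D17O")].iloc[0]
        assert d17.f_bio == pytest.approx(1 - 1.3 / 32, abs=1e-9)
        # both tracers reported side by side, never averaged
        assert len(df) == 2

    def test_anomaly_only_group(self):
        m = IsotopeMeasurement("w1", SampleType.lake_water, d18O=10.0, D17O=16.0)
        df = apportion_dataset([m], config=ApportionConfig(monte_carlo=False))
        assert set(df.tracer) == {"d18O", "D17O"}
        m2 = IsotopeMeasurement("w2", SampleType.lake_water, d18O=10.0)
        df2 = apportion_dataset([m2], config=ApportionConfig(monte_carlo=False))
        assert list(df2.tracer) == ["d18O"]

    def test_empty_input_empty_output(self):
        df = apportion_dataset([], config=ApportionConfig(monte_carlo=False))
        assert df.empty

    def test_per_sample_mode_matches_mean_for_linear_model(
        self, sediment_measurements
    ):
        a = apportion_dataset(
            sediment_measurements,
            config=ApportionConfig(monte_carlo=False, aggregation="mean_first"),
        )
        b = apportion_dataset(
            sediment_measurements,
            config=ApportionConfig(monte_carlo=False, aggregation="per_sample"),
        )
        # mixing is affine in the observation, so mean-of-fractions equals
        # fraction-of-mean when nothing clips
        fa = a[a.tracer == "d18O"].f_atm.iloc[0]
        fb = b[b.tracer == "d18O"].f_atm.iloc[0]
        assert fa == pytest.approx(fb, abs=1e-12)

    def test_seed_required_for_monte_carlo(self, sediment_measurements):
        with pytest.raises(ConfigurationError):
            apportion_dataset(sediment_measurements, config=ApportionConfig(seed=None))


def test_measurement_validation():
    with pytest.raises(InvalidMeasurementError):
        IsotopeMeasurement("x", SampleType.soil, d18O=math.nan)
    with pytest.raises(InvalidUncertaintyError):
        IsotopeMeasurement("x", SampleType.soil, d18O=1.0, sigma_d18O=-0.2)
    with pytest.raises(InvalidMeasurementError):
        IsotopeMeasurement("x", SampleType.soil, d18O=1.0).anomaly()
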