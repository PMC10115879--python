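"""Planning equations, posterior transformations, trials-required curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conflictrt import (
    Estimate,
    ReliabilitySummary,
    eta_required,
    reliability_coefficient,
    reliability_curve,
    seconds_equivalents,
    state_variance,
    summarize_reliability,
    trait_precision,
    trait_state_ratio,
    trials_required,
)
from conflictrt.inference import PosteriorDraws
from conflictrt.reliability import _interpolate_crossing


def point_mass_draws(sigma_T=0.05, sigma_N=0.25, mu=-0.7, theta=0.1, n=50):
    """PosteriorDraws with every draw equal, for deterministic transforms."""
    shape = (1, n)
    params = {
        "mu": np.full(shape, mu),
        "theta": np.full(shape, theta),
        "sigma_I": np.full(shape, 0.3),
        "sigma_T": np.full(shape, sigma_T),
        "sigma_N": np.full(shape, sigma_N),
    }
    return PosteriorDraws(
        params=params, spec=None, settings=None, diagnostics={}, converged=True,
        raw_coefs=np.zeros((1, n, 2)), raw_variances=np.zeros((1, n, 3)),
    )


class TestPlanningEquations:
    def test_state_variance_hand_values(self):
        assert state_variance(0.0, 10) == 0.0
        assert state_variance(0.3, 45) == pytest.approx(0.004)

    def test_state_variance_halves_when_trials_double(self):
        assert state_variance(0.4, 80) == pytest.approx(state_variance(0.4, 40) / 2)

    def test_state_variance_validation(self):
        with pytest.raises(ValueError):
            state_variance(0.3, 0)

    def test_reliability_coefficient_values(self):
        assert reliability_coefficient(0.2, 0.2) == pytest.approx(0.5)
        assert reliability_coefficient(0.2, 0.0) == 1.0
        assert reliability_coefficient(0.03, 0.01) == pytest.approx(0.75)

    def test_reliability_coefficient_undefined_at_zero(self):
        with pytest.raises(ValueError):
            reliability_coefficient(0.0, 0.0)

    def test_trials_required_reproduces_planning_number(self):
        # eta = 0.13, r = 0.8 -> about 420 total trials
        total = trials_required(0.13, 0.8)
        assert total == pytest.approx(420.77, abs=0.05)
        assert round(total, -1) == 420

    def test_trials_required_hand_values(self):
        assert trials_required(1.0, 0.0) == 0.0
        assert trials_required(0.2, 0.9) == pytest.approx(426.3, abs=0.05)

    def test_trials_required_validation(self):
        with pytest.raises(ValueError):
            trials_required(0.13, 1.0)
        with pytest.raises(ValueError):
            trials_required(0.0, 0.8)

    def test_eta_required_friedman_miyake_reanalysis(self):
        # split-half reliability 0.59 from 40 trials per condition
        assert eta_required(0.59, 40) == pytest.approx(0.1634, abs=5e-4)
        assert round(eta_required(0.59, 40), 2) == 0.16

    def test_eta_required_validation_and_limit(self):
        with pytest.raises(ValueError):
            eta_required(1.0, 40)
        assert eta_required(1e-9, 40) < 1e-8

    def test_trait_state_ratio_correspondences(self):
        assert trait_state_ratio(0.8) == pytest.approx(4.0 / 3.0)
        assert abs(trait_state_ratio(0.8) - 1.35) < 0.02
        assert abs(trait_state_ratio(0.9) - 2.0) < 0.1
        assert trait_state_ratio(1 / np.sqrt(2)) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            trait_state_ratio(1.0)

    @given(
        sigma_N=st.floats(0.05, 2.0),
        eta=st.floats(0.05, 1.0),
        r=st.floats(0.3, 0.99),
    )
    @settings(max_examples=200, deadline=None)
    def test_equation_consistency_is_exact(self, sigma_N, eta, r):
        """reliability(sigma_T^2, state_variance(sigma_N, L)) == r^2 when
        L comes from the planning equation — the variance-ratio form of
        reliability is the square of the planning equation's r."""
        L = trials_required(eta, r) / 2
        if L < 1:
            return  # state_variance contract needs at least one trial
        sigma_T = eta * sigma_N
        got = reliability_coefficient(sigma_T**2, state_variance(sigma_N, L))
        assert got == pytest.approx(r**2, rel=1e-12)

    @given(
        r=st.floats(0.05, 0.95),
        L=st.integers(1, 1000),
    )
    @settings(max_examples=100, deadline=None)
    def test_eta_required_round_trip(self, r, L):
        assert trials_required(eta_required(r, L), r) == pytest.approx(2 * L, rel=1e-10)

    @given(
        eta=st.floats(0.02, 1.0),
        r=st.floats(0.1, 0.95),
        bump=st.floats(0.01, 0.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_trials_required_monotonicity(self, eta, r, bump):
        assert trials_required(eta + bump, r) < trials_required(eta, r)
        r_hi = r + (0.99 - r) * 0.5
        assert trials_required(eta, r_hi) > trials_required(eta, r)


class TestTraitPrecision:
    def test_point_mass_ratio_exact(self):
        est = trait_precision(point_mass_draws(sigma_T=0.05, sigma_N=0.25))
        assert est.median == pytest.approx(0.2)
        assert est.lower == est.upper == est.median

    def test_scale_invariance(self, standard_fit):
        scaled = point_mass_draws()
        base = trait_precision(standard_fit)
        doubled = PosteriorDraws(
            params={**standard_fit.params,
                    "sigma_T": 2 * standard_fit.params["sigma_T"],
                    "sigma_N": 2 * standard_fit.params["sigma_N"]},
            spec=standard_fit.spec, settings=standard_fit.settings,
            diagnostics={}, converged=True,
            raw_coefs=standard_fit.raw_coefs, raw_variances=standard_fit.raw_variances,
        )
        after = trait_precision(doubled)
        assert after.median == pytest.approx(base.median)
        assert after.lower == pytest.approx(base.lower)

    def test_zero_sigma_n_draws_excluded_with_warning(self):
        draws = point_mass_draws()
        draws.params["sigma_N"] = draws.params["sigma_N"].copy()
        draws.params["sigma_N"][0, :10] = 0.0
        with pytest.warns(RuntimeWarning, match="sigma_N = 0"):
            est = trait_precision(draws)
        assert est.median == pytest.approx(0.2, rel=1e-12)


class TestSecondsEquivalents:
    def test_zero_conflict_effect(self):
        out = seconds_equivalents(point_mass_draws(theta=0.0), n_aux=100)
        assert out["conflict_effect_seconds"].median == 0.0

    def test_hand_value(self):
        draws = point_mass_draws(mu=np.log(0.5), theta=np.log(1.2))
        out = seconds_equivalents(draws, n_aux=100)
        assert out["conflict_effect_seconds"].median == pytest.approx(0.1, rel=1e-10)

    def test_monotone_in_theta(self):
        lo = seconds_equivalents(point_mass_draws(theta=0.05), n_aux=100)
        hi = seconds_equivalents(point_mass_draws(theta=0.15), n_aux=100)
        assert hi["conflict_effect_seconds"].median > lo["conflict_effect_seconds"].median

    def test_trait_sd_scales_with_sigma_t(self):
        lo = seconds_equivalents(point_mass_draws(sigma_T=0.05), n_aux=5000, seed=1)
        hi = seconds_equivalents(point_mass_draws(sigma_T=0.10), n_aux=5000, seed=1)
        assert hi["trait_sd_seconds"].median > lo["trait_sd_seconds"].median


def summary_for(eta_value: float, level: int) -> ReliabilitySummary:
    e = Estimate(eta_value, eta_value, eta_value)
    z = Estimate(0.0, 0.0, 0.0)
    return ReliabilitySummary(
        aggregation_level=level, eta=e, conflict_effect_log=z, sigma_T=z, sigma_N=z,
        conflict_effect_seconds=z, trait_sd_seconds=z, noise_sd_seconds=z,
        eta_samples=np.full(200, eta_value),
    )


def eta_for_required(total: float, r: float) -> float:
    """Trait precision at which the planning equation returns ``total``."""
    return float(np.sqrt(4 * r**2 / (total * (1 - r**2))))


class TestReliabilityCurve:
    def test_constant_required_crosses_at_its_value(self):
        levels = range(48, 433, 48)
        eta = eta_for_required(100.0, 0.8)
        curve = reliability_curve([summary_for(eta, lvl) for lvl in levels], targets=(0.8,))
        assert curve.crossings[0.8] == pytest.approx(100.0)

    def test_two_level_interpolation_oracle(self):
        """required 200 at 96 available and 80 at 144: the identity line is
        met where available - required changes sign, at 96 + 48*104/168."""
        s1 = summary_for(eta_for_required(200.0, 0.8), 96)
        s2 = summary_for(eta_for_required(80.0, 0.8), 144)
        curve = reliability_curve([s1, s2], targets=(0.8,))
        assert curve.crossings[0.8] == pytest.approx(96 + 48 * 104 / 168, abs=0.01)

    def test_crossing_not_reached(self):
        eta = eta_for_required(2000.0, 0.8)
        curve = reliability_curve(
            [summary_for(eta, lvl) for lvl in (48, 96, 144)], targets=(0.8,)
        )
        assert curve.crossings[0.8] is None

    def test_requirement_met_from_the_start(self):
        eta = eta_for_required(10.0, 0.8)
        curve = reliability_curve([summary_for(eta, 48), summary_for(eta, 96)], targets=(0.8,))
        assert curve.crossings[0.8] == 48.0

    def test_interpolator_directly(self):
        assert _interpolate_crossing(np.array([96.0, 144.0]), np.array([200.0, 80.0])) == pytest.approx(125.714, abs=1e-3)
        assert _interpolate_crossing(np.array([48.0, 96.0]), np.array([300.0, 200.0])) is None

    def test_needs_two_levels(self):
        with pytest.raises(ValueError):
            reliability_curve([summary_for(0.2, 48)])

    def test_target_validation(self):
        with pytest.raises(ValueError):
            reliability_curve([summary_for(0.2, 48), summary_for(0.2, 96)], targets=(1.2,))

    def test_dataframe_export(self):
        curve = reliability_curve(
            [summary_for(0.3, 48), summary_for(0.25, 96)], targets=(0.8, 0.9)
        )
        df = curve.to_dataframe()
        assert list(df["trials_available"]) == [48, 96]
        assert "required_r0.8_median" in df.columns

    def test_summarize_reliability_from_fit(self, standard_fit):
        summary = summarize_reliability(standard_fit, trials_available=96, n_aux=500)
        assert summary.aggregation_level == 96
        assert summary.eta.lower <= summary.eta.median <= summary.eta.upper
        assert summary.eta_samples.size == standard_fit.n_total
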