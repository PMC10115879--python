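"""Reliability quantities for RT difference scores.

Reliability of a difference score is the ratio of trait variance to total
variance,

    r = sigma_T^2 / (sigma_T^2 + sigma_S^2),

where the state variance sigma_S^2 = 2 sigma_N^2 / L is the squared
standard error of a conflict effect measured with L trials per condition.
The trait precision eta = sigma_T / sigma_N therefore fixes the number of
trials needed for a target reliability:

    L = 2 r^2 / (eta^2 (1 - r^2)),

with the total trial count 2L covering both conditions.  Note the two
conventions at play: the planning equation treats r as the observed-true
*correlation*, whose square is the variance ratio above.  It is
implemented verbatim — only this form reproduces the conventional planning
numbers (420 total trials at eta = 0.13 for r = 0.8; trait SD about 1.35
and 2 standard errors at r = 0.8 and 0.9) — and the two-equation
consistency r_ratio = r_corr^2 is preserved exactly, not "corrected".

Seconds-scale equivalents back-transform the log-scale fit: the conflict
effect is exp(mu)(exp(theta) - 1); trait and noise SDs are obtained by
Monte-Carlo transformation of the log-scale random effect or residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import PosteriorDraws

DEFAULT_TARGETS = (0.8, 0.9)


@dataclass(frozen=True)
class Estimate:
    """Posterior median with central credible interval."""

    median: float
    lower: float
    upper: float

    @classmethod
    def from_draws(cls, draws: np.ndarray, level: float = 0.95) -> "Estimate":
        lo = (1 - level) / 2
        return cls(
            float(np.quantile(draws, 0.5)),
            float(np.quantile(draws, lo)),
            float(np.quantile(draws, 1 - lo)),
        )


# ---------------------------------------------------------------------------
# Closed-form planning quantities


def state_variance(sigma_N: float, L) -> float:
    """Squared standard error of a difference score: 2 sigma_N^2 / L
    for L trials per condition."""
    if sigma_N < 0:
        raise ValueError("sigma_N must be non-negative")
    L = np.asarray(L, dtype=float)
    if np.any(L < 1):
        raise ValueError("L must be at least 1")
    out = 2.0 * sigma_N**2 / L
    return float(out) if out.ndim == 0 else out


def reliability_coefficient(sigma_T_sq: float, sigma_S_sq: float) -> float:
    """Trait variance as a fraction of total variance."""
    if sigma_T_sq < 0 or sigma_S_sq < 0:
        raise ValueError("variances must be non-negative")
    if sigma_T_sq == 0 and sigma_S_sq == 0:
        raise ValueError("reliability undefined when both variances are zero")
    return sigma_T_sq / (sigma_T_sq + sigma_S_sq)


def trials_required(eta, r: float):
    """TOTAL trials 2L = 4 r^2 / (eta^2 (1 - r^2)) needed for target
    reliability ``r`` at trait precision ``eta``.

    ``eta`` may be an array of posterior draws.  L is doubled because both
    conditions contribute to the difference score.
    """
    if not 0.0 <= r < 1.0:
        raise ValueError("r must lie in [0, 1); the requirement diverges at r = 1")
    eta_arr = np.asarray(eta, dtype=float)
    if np.any(eta_arr <= 0):
        raise ValueError("eta must be positive")
    out = 4.0 * r**2 / (eta_arr**2 * (1.0 - r**2))
    return float(out) if out.ndim == 0 else out


def eta_required(r: float, L) -> float:
    """Trait precision needed for reliability ``r`` from L trials per
    condition: sqrt(2 r^2 / (L (1 - r^2)))."""
    if not 0.0 < r < 1.0:
        raise ValueError("r must lie in (0, 1)")
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("L must be positive")
    out = np.sqrt(2.0 * r**2 / (L * (1.0 - r**2)))
    return float(out) if out.ndim == 0 else out


def trait_state_ratio(r: float) -> float:
    """sigma_T / sigma_S implied by treating ``r`` as the observed-true
    correlation: r / sqrt(1 - r^2).  About 1.35 at r = 0.8 and 2 at 0.9."""
    if not 0.0 <= r < 1.0:
        raise ValueError("r must lie in [0, 1)")
    return r / np.sqrt(1.0 - r**2)


# ---------------------------------------------------------------------------
# Posterior transformations


def eta_draws(draws: PosteriorDraws) -> np.ndarray:
    """Per-draw trait precision sigma_T / sigma_N, chains flattened.

    Draws with sigma_N = 0 (impossible under the half-Cauchy prior, but
    guarded for externally supplied draws) are excluded with a warning.
    """
    st = draws.stacked("sigma_T")
    sn = draws.stacked("sigma_N")
    zero = sn == 0
    if zero.any():
        warnings.warn(f"excluded {int(zero.sum())} draws with sigma_N = 0", RuntimeWarning)
        st, sn = st[~zero], sn[~zero]
    return st / sn


def trait_precision(draws: PosteriorDraws, level: float = 0.95) -> Estimate:
    """Posterior median and credible interval of eta = sigma_T / sigma_N."""
    return Estimate.from_draws(eta_draws(draws), level)


def seconds_equivalents(
    draws: PosteriorDraws, n_aux: int = 10_000, seed: int = 0, level: float = 0.95
) -> dict[str, Estimate]:
    """Seconds-scale conflict effect and trait / noise SDs.

    Per posterior draw, the conflict effect in seconds is
    ``exp(mu + mean practice offset) * (exp(theta) - 1)`` with random
    effects at zero (the mean practice offset is zero under the
    sum-to-zero constraint).  The trait and noise SDs are transformed by
    Monte Carlo: ``n_aux`` standard-normal auxiliaries are scaled by each
    draw's sigma, exponentiated, and the SD of the implied seconds-scale
    quantity is taken.
    """
    mu = draws.stacked("mu")
    theta = draws.stacked("theta")
    sT = draws.stacked("sigma_T")
    sN = draws.stacked("sigma_N")
    if "practice" in draws.params:
        mu = mu + draws.stacked("practice").mean(axis=-1)

    ce_sec = np.exp(mu) * (np.exp(theta) - 1.0)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 424243]))
    z = rng.standard_normal(n_aux)
    n = mu.size
    trait_sd = np.empty(n)
    noise_sd = np.empty(n)
    chunk = max(1, int(5e6 // n_aux))
    for start in range(0, n, chunk):
        end = min(start + chunk, n)
        et = np.exp(sT[start:end, None] * z[None, :])
        trait_sd[start:end] = np.exp(mu[start:end] + theta[start:end]) * et.std(axis=1)
        en = np.exp(sN[start:end, None] * z[None, :])
        noise_sd[start:end] = np.exp(mu[start:end]) * en.std(axis=1)

    return {
        "conflict_effect_seconds": Estimate.from_draws(ce_sec, level),
        "trait_sd_seconds": Estimate.from_draws(trait_sd, level),
        "noise_sd_seconds": Estimate.from_draws(noise_sd, level),
    }


@dataclass
class ReliabilitySummary:
    """Reliability quantities for one cumulative aggregation level."""

    aggregation_level: int  # total scheduled trials (48, 96, ... 432)
    eta: Estimate
    conflict_effect_log: Estimate
    sigma_T: Estimate
    sigma_N: Estimate
    conflict_effect_seconds: Estimate
    trait_sd_seconds: Estimate
    noise_sd_seconds: Estimate
    eta_samples: np.ndarray = field(repr=False)

    def to_row(self) -> dict:
        row: dict = {"aggregation_level": self.aggregation_level}
        for name in (
            "eta",
            "conflict_effect_log",
            "sigma_T",
            "sigma_N",
            "conflict_effect_seconds",
            "trait_sd_seconds",
            "noise_sd_seconds",
        ):
            est: Estimate = getattr(self, name)
            row[f"{name}_median"] = est.median
            row[f"{name}_lower"] = est.lower
            row[f"{name}_upper"] = est.upper
        return row


def summarize_reliability(
    draws: PosteriorDraws,
    trials_available: int,
    n_aux: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> ReliabilitySummary:
    """Bundle one fit's reliability quantities for an aggregation level."""
    eta_s = eta_draws(draws)
    seconds = seconds_equivalents(draws, n_aux=n_aux, seed=seed, level=level)
    return ReliabilitySummary(
        aggregation_level=int(trials_available),
        eta=Estimate.from_draws(eta_s, level),
        conflict_effect_log=Estimate.from_draws(draws.stacked("theta"), level),
        sigma_T=Estimate.from_draws(draws.stacked("sigma_T"), level),
        sigma_N=Estimate.from_draws(draws.stacked("sigma_N"), level),
        eta_samples=eta_s,
        **seconds,
    )


# ---------------------------------------------------------------------------
# Trials-required curves and identity-line crossings


def _interpolate_crossing(available: np.ndarray, required: np.ndarray) -> float | None:
    """First point where the required curve meets the identity line,
    linearly interpolated between adjacent aggregation levels.

    Returns the first available level if the requirement is already met
    there, or None when required > available across the whole range.
    """
    d = available - required
    if d[0] >= 0:
        return float(available[0])
    for i in range(d.size - 1):
        if d[i] < 0 <= d[i + 1]:
            frac = -d[i] / (d[i + 1] - d[i])
            return float(available[i] + frac * (available[i + 1] - available[i]))
    return None


@dataclass
class ReliabilityCurve:
    """Trials available vs. trials required, per target reliability.

    ``crossings[r]`` is the interpolated trial count at which the trials
    required for reliability ``r`` equal the trials already collected, or
    None when the requirement is never met within the measured range.
    ``crossing_intervals[r]`` applies the same interpolation to the
    credible-band edges (lower band edge -> optimistic crossing).
    """

    levels: np.ndarray
    targets: tuple[float, ...]
    required_median: dict[float, np.ndarray]
    required_lower: dict[float, np.ndarray]
    required_upper: dict[float, np.ndarray]
    crossings: dict[float, float | None]
    crossing_intervals: dict[float, tuple[float | None, float | None]]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, lvl in enumerate(self.levels):
            row = {"trials_available": int(lvl)}
            for r in self.targets:
                row[f"required_r{r}_median"] = self.required_median[r][i]
                row[f"required_r{r}_lower"] = self.required_lower[r][i]
                row[f"required_r{r}_upper"] = self.required_upper[r][i]
            rows.append(row)
        return pd.DataFrame(rows)


def reliability_curve(
    summaries: list[ReliabilitySummary],
    targets: tuple[float, ...] = DEFAULT_TARGETS,
    level: float = 0.95,
) -> ReliabilityCurve:
    """Draw-wise trials-required curves across aggregation levels.

    For each level and target reliability, the planning equation is
    applied to every posterior eta draw; medians and credible bands are
    interpolated against the identity line to find where enough trials
    have been collected.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 aggregation levels for a curve")
    summaries = sorted(summaries, key=lambda s: s.aggregation_level)
    levels = np.array([s.aggregation_level for s in summaries], dtype=float)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2

    med: dict[float, np.ndarray] = {}
    lower: dict[float, np.ndarray] = {}
    upper: dict[float, np.ndarray] = {}
    crossings: dict[float, float | None] = {}
    intervals: dict[float, tuple[float | None, float | None]] = {}
    for r in targets:
        if not 0.0 < r < 1.0:
            raise ValueError("targets must lie in (0, 1)")
        m = np.empty(levels.size)
        lo = np.empty(levels.size)
        hi = np.empty(levels.size)
        for i, s in enumerate(summaries):
            req = trials_required(s.eta_samples, r)
            m[i] = np.quantile(req, 0.5)
            lo[i] = np.quantile(req, lo_q)
            hi[i] = np.quantile(req, hi_q)
        med[r], lower[r], upper[r] = m, lo, hi
        crossings[r] = _interpolate_crossing(levels, m)
        intervals[r] = (
            _interpolate_crossing(levels, lo),
            _interpolate_crossing(levels, hi),
        )
    return ReliabilityCurve(
        levels=levels.astype(int),
        targets=tuple(targets),
        required_median=med,
        required_lower=lower,
        required_upper=upper,
        crossings=crossings,
        crossing_intervals=intervals,
    )
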