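"""Hierarchical Bayesian linear mixed models for log-shifted conflict RTs.

The "standard" model for the transformed response y = log(rt - 0.2) is

    y_n = mu + b[superblock_n] + theta * x_n + u_i(n) + t_i(n) * x_n + eps_n

with x = 1 on incongruent trials and 0 on congruent, additive sum-to-zero
practice offsets b per 48-trial superblock, subject intercepts
u_i ~ N(0, sigma_I^2), subject conflict slopes t_i ~ N(0, sigma_T^2) and
residual noise eps ~ N(0, sigma_N^2).  Two comparison models bracket the
practice assumptions: ``no_practice`` drops b, ``interaction`` adds
sum-to-zero superblock-by-conflict offsets.

Priors: independent N(0, 0.5^2) on effect coefficients (conflict,
practice, interaction), a vague N(0, 10^2) on the intercept, and
half-Cauchy priors on the three standard deviations, implemented through
the inverse-gamma mixture of Huang & Wand so that every Gibbs block is
conjugate.  Sampling is blocked Gibbs: the fixed-effect vector jointly,
subject intercepts and slopes in vectorized per-subject updates, then the
variances and their auxiliaries.

Bayes factors comparing the standard model to the two alternatives are
computed either by bridge sampling on the random-effects-integrated
posterior (default) or by a Rao-Blackwellised Savage-Dickey density ratio
for the nested comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Callable

import arviz as az
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from sklearn.base import BaseEstimator

VARIANTS = ("standard", "no_practice", "interaction")

_log = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """Which model variant to fit, and its prior scales."""

    variant: str = "standard"
    include_practice: bool | None = None  # None = automatic (False for 1 superblock)
    fixed_effect_scale: float = 0.5
    random_effect_scale: float = 1.0
    residual_scale: float = 1.0
    intercept_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        for name in ("fixed_effect_scale", "random_effect_scale", "residual_scale", "intercept_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class McmcSettings:
    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 2500
    seed: int = 0
    rhat_threshold: float = 1.01
    min_ess: int = 400

    def __post_init__(self) -> None:
        for name in ("n_chains", "n_warmup", "n_draws"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PosteriorDraws:
    """MCMC draws, shaped (n_chains, n_draws[, k]) per parameter.

    ``params`` holds the interpretable parameters (mu, practice offsets,
    theta, interaction offsets, sigma_I, sigma_T, sigma_N); ``raw_coefs``
    and ``raw_variances`` keep the untransformed sampler state used for
    marginal-likelihood estimation.  ``logp_zero`` holds, per draw, the
    log conditional posterior density of the variant's tested coefficient
    block at zero (Rao-Blackwellised Savage-Dickey numerator).
    """

    params: dict[str, np.ndarray]
    spec: ModelSpec
    settings: McmcSettings
    diagnostics: dict
    converged: bool
    raw_coefs: np.ndarray  # (chains, draws, p)
    raw_variances: np.ndarray  # (chains, draws, 3): sigma_I^2, sigma_T^2, sigma_N^2
    logp_zero: np.ndarray | None = None
    log_prior_zero: float | None = None

    @property
    def n_total(self) -> int:
        c, d = self.params["sigma_N"].shape
        return c * d

    def stacked(self, name: str) -> np.ndarray:
        """Draws for one parameter, chains flattened."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {}
        c, d = self.params["sigma_N"].shape
        cols["chain"] = np.repeat(np.arange(c), d)
        cols["draw"] = np.tile(np.arange(d), c)
        for name, arr in self.params.items():
            flat = arr.reshape(c * d, -1)
            if flat.shape[1] == 1:
                cols[name] = flat[:, 0]
            else:
                for j in range(flat.shape[1]):
                    cols[f"{name}[{j + 1}]"] = flat[:, j]
        return pd.DataFrame(cols)

    def to_inference_data(self) -> az.InferenceData:
        return az.from_dict(posterior={k: v for k, v in self.params.items()})


@dataclass
class BayesFactorResult:
    """BF1 (standard vs no-practice) and BF2 (standard vs interaction)."""

    bf1: float
    bf2: float
    bf1_log_se: float
    bf2_log_se: float
    method: str
    flagged: bool = False


# ---------------------------------------------------------------------------
# Design matrices


def _sum_coding(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero (deviation) coding: n_levels - 1 columns."""
    C = np.zeros((levels.size, n_levels - 1))
    for j in range(n_levels - 1):
        C[:, j] = (levels == j).astype(float) - (levels == n_levels - 1).astype(float)
    return C


def _prepare(data: pd.DataFrame, spec: ModelSpec):
    """Validate the analysis table and build the fixed-effect design."""
    required = {"subject", "superblock", "condition", "y"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"analysis table missing columns: {sorted(missing)}")
    y = data["y"].to_numpy(dtype=float)
    x = (data["condition"].to_numpy() == "incongruent").astype(float)
    subjects, subj_idx = np.unique(data["subject"].to_numpy(), return_inverse=True)
    if subjects.size < 2:
        raise ValueError("at least 2 subjects are required")
    both = pd.crosstab(data["subject"], data["condition"])
    if both.shape[1] < 2 or (both == 0).any().any():
        raise ValueError("every subject needs trials in both conditions")

    sblocks = data["superblock"].to_numpy(dtype=int)
    levels = np.unique(sblocks)
    S = levels.size
    s_idx = np.searchsorted(levels, sblocks)

    include_practice = spec.include_practice
    if include_practice is None:
        include_practice = spec.variant != "no_practice" and S >= 2
    if spec.variant == "no_practice":
        include_practice = False
    if include_practice and S < 2:
        raise ValueError("include_practice requires at least 2 superblocks")
    if spec.variant == "interaction" and not include_practice:
        raise ValueError("the interaction variant requires practice effects")

    cols = [np.ones_like(y)]
    names = ["mu"]
    prior_sd = [spec.intercept_scale]
    practice_cols: list[int] = []
    inter_cols: list[int] = []
    if include_practice:
        C = _sum_coding(s_idx, S)
        for j in range(S - 1):
            practice_cols.append(len(cols))
            cols.append(C[:, j])
            names.append(f"practice_c{j + 1}")
            prior_sd.append(spec.fixed_effect_scale)
    theta_col = len(cols)
    cols.append(x)
    names.append("theta")
    prior_sd.append(spec.fixed_effect_scale)
    if spec.variant == "interaction":
        C = _sum_coding(s_idx, S)
        for j in range(S - 1):
            inter_cols.append(len(cols))
            cols.append(x * C[:, j])
            names.append(f"interaction_c{j + 1}")
            prior_sd.append(spec.fixed_effect_scale)

    X = np.column_stack(cols)
    return {
        "y": y,
        "x": x,
        "X": X,
        "names": names,
        "prior_sd": np.asarray(prior_sd),
        "subj_idx": subj_idx,
        "n_subjects": subjects.size,
        "subjects": subjects,
        "s_idx": s_idx,
        "n_superblocks": S,
        "theta_col": theta_col,
        "practice_cols": practice_cols,
        "inter_cols": inter_cols,
        "include_practice": include_practice,
    }


# ---------------------------------------------------------------------------
# Gibbs sampler


def _invgamma(rng: np.random.Generator, shape: float, scale, size=None):
    """Draw from InverseGamma(shape, scale) (scale = rate of 1/X)."""
    return scale / rng.gamma(shape, 1.0, size=size)


def _run_chain(design: dict, spec: ModelSpec, n_warmup: int, n_draws: int,
               rng: np.random.Generator, sd_cols: list[int]):
    y = design["y"]
    X = design["X"]
    x = design["x"]
    subj = design["subj_idx"]
    I = design["n_subjects"]
    n, p = X.shape

    XtX = X.T @ X
    counts = np.bincount(subj, minlength=I).astype(float)
    m_i = np.bincount(subj, weights=x, minlength=I)
    prior_prec = 1.0 / design["prior_sd"] ** 2
    A_I = A_T = spec.random_effect_scale
    A_N = spec.residual_scale

    vy = float(np.var(y))
    beta = np.zeros(p)
    u = np.zeros(I)
    t = np.zeros(I)
    sig2_N = max(0.5 * vy, 1e-4)
    sig2_I = max(0.25 * vy, 1e-4)
    sig2_T = max(0.01 * vy, 1e-6)
    a_I = a_T = a_N = 1.0

    coefs = np.empty((n_draws, p))
    variances = np.empty((n_draws, 3))
    u_draws = np.empty((n_draws, I))
    t_draws = np.empty((n_draws, I))
    logp0 = np.empty(n_draws) if sd_cols else None
    other_cols = [j for j in range(p) if j not in sd_cols]

    for it in range(n_warmup + n_draws):
        # -- fixed effects, jointly
        r = y - u[subj] - t[subj] * x
        prec = XtX / sig2_N + np.diag(prior_prec)
        cho = cho_factor(prec, lower=True)
        mean = cho_solve(cho, X.T @ r / sig2_N)
        z = rng.standard_normal(p)
        beta = mean + solve_triangular(cho[0].T, z, lower=False)
        fitted = X @ beta

        save = it >= n_warmup
        if save and sd_cols:
            # Rao-Blackwellised Savage-Dickey: conditional density of the
            # tested block at zero given the current state.
            P_AA = prec[np.ix_(sd_cols, sd_cols)]
            P_AB = prec[np.ix_(sd_cols, other_cols)]
            dB = beta[other_cols] - mean[other_cols]
            m_cond = mean[sd_cols] - np.linalg.solve(P_AA, P_AB @ dB)
            L = cholesky(P_AA, lower=True)
            k = len(sd_cols)
            quad = m_cond @ (P_AA @ m_cond)
            logp0[it - n_warmup] = (
                float(np.sum(np.log(np.diag(L)))) - 0.5 * k * np.log(2 * np.pi) - 0.5 * quad
            )

        # -- subject intercepts
        r_u = y - fitted - t[subj] * x
        s_u = np.bincount(subj, weights=r_u, minlength=I)
        prec_u = counts / sig2_N + 1.0 / sig2_I
        u = s_u / sig2_N / prec_u + rng.standard_normal(I) / np.sqrt(prec_u)

        # -- subject conflict slopes
        r_t = y - fitted - u[subj]
        s_t = np.bincount(subj, weights=r_t * x, minlength=I)
        prec_t = m_i / sig2_N + 1.0 / sig2_T
        t = s_t / sig2_N / prec_t + rng.standard_normal(I) / np.sqrt(prec_t)

        # -- translation moves along the non-identified directions
        # (mu + d, u - d) and (theta + d, t - d): the likelihood is
        # invariant, so d has an exact Gaussian conditional from the
        # priors alone; sampling it breaks the random-walk coupling
        # between fixed effects and random-effect means.
        pd_mu = 1.0 / design["prior_sd"][0] ** 2 + I / sig2_I
        md_mu = (-beta[0] / design["prior_sd"][0] ** 2 + u.sum() / sig2_I) / pd_mu
        d = md_mu + rng.standard_normal() / np.sqrt(pd_mu)
        beta[0] += d
        u -= d
        tc = design["theta_col"]
        pd_th = 1.0 / design["prior_sd"][tc] ** 2 + I / sig2_T
        md_th = (-beta[tc] / design["prior_sd"][tc] ** 2 + t.sum() / sig2_T) / pd_th
        d = md_th + rng.standard_normal() / np.sqrt(pd_th)
        beta[tc] += d
        t -= d
        fitted = X @ beta

        # -- variances (half-Cauchy via Huang-Wand auxiliaries)
        resid = y - fitted - u[subj] - t[subj] * x
        sse = float(resid @ resid)
        sig2_N = _invgamma(rng, 0.5 + 0.5 * n, 1.0 / a_N + 0.5 * sse)
        a_N = _invgamma(rng, 1.0, 1.0 / A_N**2 + 1.0 / sig2_N)
        sig2_I = _invgamma(rng, 0.5 + 0.5 * I, 1.0 / a_I + 0.5 * float(u @ u))
        a_I = _invgamma(rng, 1.0, 1.0 / A_I**2 + 1.0 / sig2_I)
        sig2_T = _invgamma(rng, 0.5 + 0.5 * I, 1.0 / a_T + 0.5 * float(t @ t))
        a_T = _invgamma(rng, 1.0, 1.0 / A_T**2 + 1.0 / sig2_T)

        if save:
            j = it - n_warmup
            coefs[j] = beta
            variances[j] = (sig2_I, sig2_T, sig2_N)
            u_draws[j] = u
            t_draws[j] = t

    return coefs, variances, u_draws, t_draws, logp0


def _offsets_from_coefs(coefs: np.ndarray) -> np.ndarray:
    """Map S-1 sum-coded coefficients to S sum-to-zero offsets."""
    last = -coefs.sum(axis=-1, keepdims=True)
    return np.concatenate([coefs, last], axis=-1)


def fit_model(
    data: pd.DataFrame, spec: ModelSpec | None = None, settings: McmcSettings | None = None
) -> PosteriorDraws:
    """Fit one model variant to an analysis table by blocked Gibbs MCMC.

    Returns posterior draws with convergence diagnostics attached; a
    failed R-hat / ESS gate raises a warning and marks the result, never
    fails silently.
    """
    spec = spec or ModelSpec()
    settings = settings or McmcSettings()
    design = _prepare(data, spec)
    p = design["X"].shape[1]
    S = design["n_superblocks"]

    if spec.variant == "standard" and design["include_practice"]:
        sd_cols = design["practice_cols"]
    elif spec.variant == "interaction":
        sd_cols = design["inter_cols"]
    else:
        sd_cols = []

    all_coefs = np.empty((settings.n_chains, settings.n_draws, p))
    all_vars = np.empty((settings.n_chains, settings.n_draws, 3))
    logp0 = np.empty((settings.n_chains, settings.n_draws)) if sd_cols else None
    for c in range(settings.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([settings.seed, c]))
        coefs, variances, _, _, lp0 = _run_chain(
            design, spec, settings.n_warmup, settings.n_draws, rng, sd_cols
        )
        all_coefs[c] = coefs
        all_vars[c] = variances
        if sd_cols:
            logp0[c] = lp0
        _log.info(
            "chain %d/%d done (%s, %d draws)",
            c + 1, settings.n_chains, spec.variant, settings.n_draws,
        )

    params: dict[str, np.ndarray] = {"mu": all_coefs[:, :, 0]}
    if design["practice_cols"]:
        params["practice"] = _offsets_from_coefs(all_coefs[:, :, design["practice_cols"]])
    params["theta"] = all_coefs[:, :, design["theta_col"]]
    if design["inter_cols"]:
        params["interaction"] = _offsets_from_coefs(all_coefs[:, :, design["inter_cols"]])
    params["sigma_I"] = np.sqrt(all_vars[:, :, 0])
    params["sigma_T"] = np.sqrt(all_vars[:, :, 1])
    params["sigma_N"] = np.sqrt(all_vars[:, :, 2])

    idata = az.from_dict(posterior=params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # arviz warns on few chains/draws
        rhat = az.rhat(idata)
        ess = az.ess(idata, method="bulk")
    max_rhat = float(max(np.nanmax(np.atleast_1d(rhat[v].values)) for v in rhat.data_vars))
    min_ess = float(min(np.nanmin(np.atleast_1d(ess[v].values)) for v in ess.data_vars))
    converged = bool(max_rhat <= settings.rhat_threshold and min_ess >= settings.min_ess)
    diagnostics = {
        "max_rhat": max_rhat,
        "min_ess": min_ess,
        "n_chains": settings.n_chains,
        "n_draws": settings.n_draws,
        "n_subjects": int(design["n_subjects"]),
        "n_trials": int(design["y"].size),
        "n_superblocks": S,
        "variant": spec.variant,
        "include_practice": design["include_practice"],
    }
    if not converged:
        warnings.warn(
            f"convergence gate failed: max R-hat {max_rhat:.3f} "
            f"(threshold {settings.rhat_threshold}), min ESS {min_ess:.0f} "
            f"(minimum {settings.min_ess})",
            RuntimeWarning,
            stacklevel=2,
        )

    log_prior_zero = None
    if sd_cols:
        k = len(sd_cols)
        log_prior_zero = -0.5 * k * np.log(2 * np.pi * spec.fixed_effect_scale**2)

    resolved = replace(spec, include_practice=design["include_practice"])
    return PosteriorDraws(
        params=params,
        spec=resolved,
        settings=settings,
        diagnostics=diagnostics,
        converged=converged,
        raw_coefs=all_coefs,
        raw_variances=all_vars,
        logp_zero=logp0,
        log_prior_zero=log_prior_zero,
    )


# ---------------------------------------------------------------------------
# Posterior summaries


def posterior_summary(draws: PosteriorDraws | dict[str, np.ndarray], level: float = 0.95) -> pd.DataFrame:
    """Median and central credible interval per parameter.

    Quantiles use linear interpolation; for level 0.95 the interval is the
    (2.5%, 97.5%) pair.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if isinstance(draws, PosteriorDraws):
        mapping = {k: draws.stacked(k) for k in draws.params}
    else:
        mapping = {k: np.asarray(v).reshape(-1, *np.asarray(v).shape[2:]) if np.asarray(v).ndim > 2 else np.asarray(v).ravel() for k, v in draws.items()}
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for name, arr in mapping.items():
        arr = np.asarray(arr, dtype=float)
        if arr.size == 0:
            raise ValueError(f"no draws for parameter {name}")
        if arr.ndim == 1:
            arr = arr[:, None]
            labels = [name]
        else:
            labels = [f"{name}[{j + 1}]" for j in range(arr.shape[1])]
        for j, label in enumerate(labels):
            col = arr[:, j]
            rows.append(
                {
                    "parameter": label,
                    "median": float(np.quantile(col, 0.5)),
                    "lower": float(np.quantile(col, lo_q)),
                    "upper": float(np.quantile(col, hi_q)),
                }
            )
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# Marginal likelihood: integrated likelihood + bridge sampling


def _subject_suffstats(design: dict):
    """Per-subject sufficient statistics for the random-effects-integrated
    likelihood (Woodbury form)."""
    y, X, x, subj = design["y"], design["X"], design["x"], design["subj_idx"]
    I = design["n_subjects"]
    p = X.shape[1]
    n_i = np.bincount(subj, minlength=I).astype(float)
    m_i = np.bincount(subj, weights=x, minlength=I)
    yty = np.bincount(subj, weights=y * y, minlength=I)
    Xty = np.zeros((I, p))
    Zty = np.zeros((I, 2))
    ZtX = np.zeros((I, 2, p))
    XtX = np.zeros((I, p, p))
    for i in range(I):
        sel = subj == i
        Xi = X[sel]
        yi = y[sel]
        xi = x[sel]
        Zi = np.column_stack([np.ones(sel.sum()), xi])
        Xty[i] = Xi.T @ yi
        Zty[i] = Zi.T @ yi
        ZtX[i] = Zi.T @ Xi
        XtX[i] = Xi.T @ Xi
    ZtZ = np.zeros((I, 2, 2))
    ZtZ[:, 0, 0] = n_i
    ZtZ[:, 0, 1] = ZtZ[:, 1, 0] = m_i
    ZtZ[:, 1, 1] = m_i
    return {"n_i": n_i, "yty": yty, "Xty": Xty, "Zty": Zty, "ZtX": ZtX, "XtX": XtX, "ZtZ": ZtZ}


def _integrated_loglik(ss: dict, beta: np.ndarray, sig2_I: float, sig2_T: float, sig2_N: float) -> float:
    """Log-likelihood with subject intercepts and slopes integrated out."""
    rtr = ss["yty"] - 2.0 * ss["Xty"] @ beta + np.einsum("ipq,p,q->i", ss["XtX"], beta, beta)
    Ztr = ss["Zty"] - ss["ZtX"] @ beta  # (I, 2)
    a = np.array([np.sqrt(sig2_I), np.sqrt(sig2_T)])
    # B = I_2 + A Z'Z A / sig2_N  (A diagonal)
    AZZA = ss["ZtZ"] * np.outer(a, a)[None, :, :]
    B = np.eye(2)[None, :, :] + AZZA / sig2_N
    det = B[:, 0, 0] * B[:, 1, 1] - B[:, 0, 1] * B[:, 1, 0]
    w = Ztr * a[None, :]
    # w' B^{-1} w via 2x2 inverse
    winv = (
        w[:, 0] ** 2 * B[:, 1, 1] - 2.0 * w[:, 0] * w[:, 1] * B[:, 0, 1] + w[:, 1] ** 2 * B[:, 0, 0]
    ) / det
    quad = rtr / sig2_N - winv / sig2_N**2
    logdet = ss["n_i"] * np.log(sig2_N) + np.log(det)
    return float(-0.5 * np.sum(ss["n_i"] * np.log(2 * np.pi) + logdet + quad))


def _log_half_cauchy(s: np.ndarray | float, scale: float):
    s = np.asarray(s, dtype=float)
    return np.log(2.0) - np.log(np.pi * scale * (1.0 + (s / scale) ** 2))


def _make_log_target(design: dict, spec: ModelSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Unnormalised log posterior over (beta, log sigma_I, log sigma_T,
    log sigma_N), random effects integrated out analytically."""
    ss = _subject_suffstats(design)
    prior_sd = design["prior_sd"]
    p = prior_sd.size

    def log_target(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        out = np.empty(theta.shape[0])
        for j, row in enumerate(theta):
            beta = row[:p]
            ls = row[p:]
            sig = np.exp(ls)
            ll = _integrated_loglik(ss, beta, sig[0] ** 2, sig[1] ** 2, sig[2] ** 2)
            lp = float(np.sum(-0.5 * (beta / prior_sd) ** 2 - 0.5 * np.log(2 * np.pi) - np.log(prior_sd)))
            lp += float(_log_half_cauchy(sig[0], spec.random_effect_scale) + ls[0])
            lp += float(_log_half_cauchy(sig[1], spec.random_effect_scale) + ls[1])
            lp += float(_log_half_cauchy(sig[2], spec.residual_scale) + ls[2])
            out[j] = ll + lp
        return out

    return log_target


def _bridge_once(l1: np.ndarray, l2: np.ndarray, tol: float = 1e-10, max_iter: int = 1000) -> float:
    """Meng-Wong optimal bridge given l = log target - log proposal at
    posterior draws (l1) and proposal draws (l2)."""
    n1, n2 = l1.size, l2.size
    s1 = n1 / (n1 + n2)
    s2 = n2 / (n1 + n2)
    lstar = np.median(l1)
    e1 = np.exp(l1 - lstar)
    e2 = np.exp(l2 - lstar)
    r = 1.0
    for _ in range(max_iter):
        num = np.mean(e2 / (s1 * e2 + s2 * r))
        den = np.mean(1.0 / (s1 * e1 + s2 * r))
        r_new = num / den
        if not np.isfinite(r_new) or r_new <= 0:
            break
        if abs(r_new - r) <= tol * abs(r):
            r = r_new
            break
        r = r_new
    return float(np.log(r) + lstar)


def marginal_likelihood(
    data: pd.DataFrame,
    spec: ModelSpec,
    settings: McmcSettings,
    draws: PosteriorDraws | None = None,
    n_batches: int = 4,
) -> tuple[float, float]:
    """Log marginal likelihood by bridge sampling, with a batch-based
    standard error.

    Posterior draws (fit on demand if not supplied) are mapped to
    (beta, log sigma) space; a moment-matched Gaussian serves as the
    proposal.  The estimate is recomputed on ``n_batches`` disjoint batches
    of draws; the reported SE is the batch standard error.
    """
    if draws is None:
        draws = fit_model(data, spec, settings)
    design = _prepare(data, draws.spec)
    log_target = _make_log_target(design, draws.spec)

    p = design["X"].shape[1]
    coefs = draws.raw_coefs.reshape(-1, p)
    sig = np.sqrt(draws.raw_variances.reshape(-1, 3))
    theta = np.column_stack([coefs, np.log(sig)])
    # thin to keep density evaluations affordable
    max_draws = 4000
    if theta.shape[0] > max_draws:
        idx = np.linspace(0, theta.shape[0] - 1, max_draws).astype(int)
        theta = theta[idx]
    n1 = theta.shape[0]

    mean = theta.mean(axis=0)
    cov = np.cov(theta.T) + 1e-10 * np.eye(theta.shape[1])
    L = cholesky(cov, lower=True)
    rng = np.random.default_rng(np.random.SeedSequence([draws.settings.seed, 777]))
    z = rng.standard_normal((n1, theta.shape[1]))
    prop = mean + z @ L.T

    def logq(pts: np.ndarray) -> np.ndarray:
        d = pts - mean
        sol = solve_triangular(L, d.T, lower=True)
        return (
            -0.5 * np.sum(sol**2, axis=0)
            - np.sum(np.log(np.diag(L)))
            - 0.5 * pts.shape[1] * np.log(2 * np.pi)
        )

    l1 = log_target(theta) - logq(theta)
    l2 = log_target(prop) - logq(prop)

    logml = _bridge_once(l1, l2)
    batch_vals = []
    for b in range(n_batches):
        sel1 = np.arange(b, n1, n_batches)
        batch_vals.append(_bridge_once(l1[sel1], l2[sel1 % l2.size]))
    se = float(np.std(batch_vals, ddof=1) / np.sqrt(n_batches))
    return logml, se


def savage_dickey_bf(draws: PosteriorDraws) -> tuple[float, float]:
    """Savage-Dickey Bayes factor for the variant's nested comparison.

    For a ``standard`` fit this is BF(standard / no_practice); for an
    ``interaction`` fit it is BF(standard / interaction), i.e. evidence for
    the nested zero-block in both cases is in the numerator position the
    ratio implies.  Returns (log BF, log-scale SE across chains).
    """
    if draws.logp_zero is None:
        raise ValueError("fit has no tested coefficient block for Savage-Dickey")
    lp = draws.logp_zero  # (chains, draws)
    per_chain = _logmeanexp(lp, axis=1)
    log_post_zero = _logmeanexp(lp.ravel())
    se = float(np.std(per_chain, ddof=1) / np.sqrt(lp.shape[0])) if lp.shape[0] > 1 else 0.3
    if draws.spec.variant == "standard":
        # BF(full/nested) = prior density at 0 / posterior density at 0
        log_bf = draws.log_prior_zero - log_post_zero
    else:  # interaction: BF(nested/full) favours the standard model
        log_bf = log_post_zero - draws.log_prior_zero
    return float(log_bf), se


def _logmeanexp(a: np.ndarray, axis=None):
    a = np.asarray(a)
    amax = np.max(a, axis=axis, keepdims=True)
    out = np.log(np.mean(np.exp(a - amax), axis=axis)) + np.squeeze(amax, axis=axis if axis is not None else None)
    return out


def bayes_factors(
    data: pd.DataFrame,
    settings: McmcSettings | None = None,
    spec: ModelSpec | None = None,
    method: str = "bridge",
    se_flag_threshold: float = 0.5,
) -> BayesFactorResult:
    """BF1 = p(y | standard) / p(y | no_practice) and
    BF2 = p(y | standard) / p(y | interaction).

    ``method="bridge"`` uses bridge-sampled marginal likelihoods of all
    three variants; ``method="savage_dickey"`` uses the Rao-Blackwellised
    density ratio at the nested zero blocks (practice block of the
    standard fit; interaction block of the interaction fit).  Results with
    a log-scale SE above ``se_flag_threshold`` are flagged, not hidden.
    """
    settings = settings or McmcSettings()
    base = spec or ModelSpec()
    if method not in ("bridge", "savage_dickey"):
        raise ValueError("method must be 'bridge' or 'savage_dickey'")

    specs = {v: replace(base, variant=v, include_practice=None) for v in VARIANTS}
    if method == "bridge":
        lml: dict[str, tuple[float, float]] = {}
        for v in VARIANTS:
            fit = fit_model(data, specs[v], settings)
            lml[v] = marginal_likelihood(data, specs[v], settings, draws=fit)
        log_bf1 = lml["standard"][0] - lml["no_practice"][0]
        log_bf2 = lml["standard"][0] - lml["interaction"][0]
        se1 = float(np.hypot(lml["standard"][1], lml["no_practice"][1]))
        se2 = float(np.hypot(lml["standard"][1], lml["interaction"][1]))
    else:
        fit_std = fit_model(data, specs["standard"], settings)
        fit_int = fit_model(data, specs["interaction"], settings)
        log_bf1, se1 = savage_dickey_bf(fit_std)
        log_bf2, se2 = savage_dickey_bf(fit_int)

    flagged = max(se1, se2) > se_flag_threshold
    return BayesFactorResult(
        bf1=float(np.exp(log_bf1)),
        bf2=float(np.exp(log_bf2)),
        bf1_log_se=se1,
        bf2_log_se=se2,
        method=method,
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# Estimator facade


class HierarchicalConflictModel(BaseEstimator):
    """sklearn-style estimator for the hierarchical conflict-RT model.

    ``fit`` takes an analysis table (long format with columns ``subject``,
    ``superblock``, ``condition`` and the log-shifted response ``y``) and
    draws from the posterior by blocked Gibbs sampling.

    Parameters mirror :class:`ModelSpec` and :class:`McmcSettings`.

    Attributes
    ----------
    draws_ : PosteriorDraws
    summary_ : pandas.DataFrame
        Median and 95% credible interval per parameter.
    diagnostics_ : dict
        Max R-hat, min bulk ESS, data shape.
    converged_ : bool
    """

    def __init__(
        self,
        variant: str = "standard",
        include_practice: bool | None = None,
        fixed_effect_scale: float = 0.5,
        random_effect_scale: float = 1.0,
        n_chains: int = 4,
        n_warmup: int = 1000,
        n_draws: int = 2500,
        seed: int = 0,
        rhat_threshold: float = 1.01,
        min_ess: int = 400,
    ):
        self.variant = variant
        self.include_practice = include_practice
        self.fixed_effect_scale = fixed_effect_scale
        self.random_effect_scale = random_effect_scale
        self.n_chains = n_chains
        self.n_warmup = n_warmup
        self.n_draws = n_draws
        self.seed = seed
        self.rhat_threshold = rhat_threshold
        self.min_ess = min_ess

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            variant=self.variant,
            include_practice=self.include_practice,
            fixed_effect_scale=self.fixed_effect_scale,
            random_effect_scale=self.random_effect_scale,
        )

    def _settings(self) -> McmcSettings:
        return McmcSettings(
            n_chains=self.n_chains,
            n_warmup=self.n_warmup,
            n_draws=self.n_draws,
            seed=self.seed,
            rhat_threshold=self.rhat_threshold,
            min_ess=self.min_ess,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "HierarchicalConflictModel":
        self.draws_ = fit_model(X, self._spec(), self._settings())
        self.summary_ = posterior_summary(self.draws_)
        self.diagnostics_ = self.draws_.diagnostics
        self.converged_ = self.draws_.converged
        return self

    def trait_precision(self):
        """Posterior trait precision eta = sigma_T / sigma_N."""
        from .reliability import trait_precision

        if not hasattr(self, "draws_"):
            raise ValueError("model is not fitted")
        return trait_precision(self.draws_)

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean integrated log-likelihood over posterior draws (up to the
        random-effects integration), a crude fit index for model selection
        smoke checks."""
        if not hasattr(self, "draws_"):
            raise ValueError("model is not fitted")
        design = _prepare(X, self.draws_.spec)
        ss = _subject_suffstats(design)
        coefs = self.draws_.raw_coefs.reshape(-1, self.draws_.raw_coefs.shape[-1])
        variances = self.draws_.raw_variances.reshape(-1, 3)
        idx = np.linspace(0, coefs.shape[0] - 1, min(200, coefs.shape[0])).astype(int)
        vals = [
            _integrated_loglik(ss, coefs[j], variances[j, 0], variances[j, 1], variances[j, 2])
            for j in idx
        ]
        return float(np.mean(vals))
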