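"""Bayesian random-regression (reaction-norm) model for hissing behaviour.

The model is the Gaussian mixed model

    y_ij = x_ij' beta + u0_i + u1_i * day_ij + e_ij

with per-female (u0, u1) drawn from a 2x2 covariance matrix G (among-
individual intercept/slope variances and their covariance) and iid
residuals e.  Posterior draws are obtained by a blocked Gibbs sampler with
conjugate updates: Gaussian for beta and the (u0, u1) blocks, inverse-
Wishart for G and inverse-gamma for the residual variance.

Responses are analysed on the mean-centred, unit-variance scale; fixed
effects follow the field-study specification: day in the nesting cycle
(centred on hatching), per-female mean Julian test date, within-female
mean test time and its per-trial deviation, and female age class
(first-year reference, adult and unknown levels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MCMCOptions",
    "ModelSpec",
    "BRNPosterior",
    "FemaleEffects",
    "standardize",
    "fit_random_regression",
    "extract_female_effects",
]

VARIANCE_PARAMS = ("var_intercept", "var_slope", "cov_int_slope", "var_resid")


class DegenerateInputError(ValueError):
    """Input with no usable variation."""


class SamplerConfigError(ValueError):
    """Invalid MCMC configuration."""


def standardize(values) -> tuple[np.ndarray, float, float]:
    """Mean-centre and scale to unit variance (denominator n - 1).

    Returns ``(standardized, mean, sd)`` so the transform can be inverted.
    Raises :class:`DegenerateInputError` for constant input.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("need at least two values to standardize")
    mu = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("cannot standardize a constant response")
    return (x - mu) / sd, mu, sd


@dataclass(frozen=True)
class MCMCOptions:
    """Chain length and prior settings for the Gibbs samplers.

    Defaults (13 000 iterations, 3 000 burn-in, thinning 10) retain 1 000
    draws and keep lag-1 autocorrelation of the retained chain below 0.05
    on the synthetic defaults.  The among-individual covariance matrix has
    an inverse-Wishart prior (identity scale, minimal proper degrees of
    freedom q + 1 unless overridden); the residual variance an
    inverse-gamma(1e-3, 1e-3) prior; fixed effects are essentially flat.
    """

    n_iter: int = 13_000
    burn_in: int = 3_000
    thin: int = 10
    prior_scale: np.ndarray | None = None
    prior_df: float | None = None
    resid_shape: float = 1e-3
    resid_rate: float = 1e-3
    beta_prec: float = 1e-8

    @property
    def n_retained(self) -> int:
        return -((self.n_iter - self.burn_in) // -self.thin)

    def validate(self) -> None:
        if self.burn_in >= self.n_iter or self.thin < 1:
            raise SamplerConfigError("burn-in/thinning inconsistent with n_iter")
        if self.n_retained < 1:
            raise SamplerConfigError("no draws retained after burn-in/thinning")


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect selection and random-slope switch."""

    fixed_effects: tuple[str, ...] = (
        "day",
        "julian_date",
        "time_mean",
        "time_dev",
        "age",
    )
    random_slope: bool = True
    response: str = "hiss_std"


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def build_fixed_design(
    trials: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for the fixed effects.

    Time-of-day within-female centring is recomputed from the data (raw
    trial time = time_mean + time_dev), and the Julian covariate is the
    per-female mean test date; continuous nuisance covariates are z-scored.
    The day covariate stays on its raw (days) scale.
    """
    cols: list[np.ndarray] = [np.ones(len(trials))]
    names = ["intercept"]
    by_fem = trials.groupby("female_id", sort=False)
    for term in spec.fixed_effects:
        if term == "day":
            cols.append(trials["day_centred"].to_numpy(dtype=float))
            names.append("day")
        elif term == "julian_date":
            jmean = by_fem["julian_date"].transform("mean").to_numpy(dtype=float)
            cols.append(_zscore(jmean))
            names.append("julian_date")
        elif term == "time_mean":
            raw = (trials["time_mean"] + trials["time_dev"]).to_numpy(dtype=float)
            tmean = (
                pd.Series(raw, index=trials.index)
                .groupby(trials["female_id"], sort=False)
                .transform("mean")
                .to_numpy()
            )
            cols.append(_zscore(tmean))
            names.append("time_mean")
        elif term == "time_dev":
            raw = (trials["time_mean"] + trials["time_dev"]).to_numpy(dtype=float)
            tmean = (
                pd.Series(raw, index=trials.index)
                .groupby(trials["female_id"], sort=False)
                .transform("mean")
                .to_numpy()
            )
            cols.append(_zscore(raw - tmean))
            names.append("time_dev")
        elif term == "age":
            age = trials["age_class"].astype(str)
            cols.append((age == "adult").to_numpy(dtype=float))
            names.append("age_adult")
            cols.append((age == "unknown").to_numpy(dtype=float))
            names.append("age_unknown")
        else:
            raise SamplerConfigError(f"unknown fixed effect {term!r}")
    return np.column_stack(cols), names


@dataclass(frozen=True)
class FemaleEffects:
    """Posterior-mean per-female intercept/slope deviations."""

    frame: pd.DataFrame  # female_id, intercept_dev, slope_dev

    def lookup(self, female_id: str) -> tuple[float, float]:
        row = self.frame[self.frame["female_id"] == female_id]
        if row.empty:
            raise KeyError(f"female {female_id!r} was not in the fitted data")
        return float(row["intercept_dev"].iloc[0]), float(row["slope_dev"].iloc[0])


@dataclass
class BRNPosterior:
    """Retained MCMC draws and diagnostics from the random regression."""

    draws: pd.DataFrame
    female_ids: list[str]
    u_mean: np.ndarray  # (n_females, 2) posterior-mean deviations
    random_slope: bool
    fixed_names: list[str] = field(default_factory=list)
    convergence: pd.DataFrame | None = None
    converged: bool = True

    def summary(self) -> pd.DataFrame:
        """Posterior mean, central 95% CrI and support flag per parameter.

        Fixed effects (and the intercept-slope covariance) are flagged
        "supported" when the CrI excludes zero; variances are bounded away
        from zero by construction, so the flag is left False for them.
        """
        rows = []
        for name in self.draws.columns:
            x = self.draws[name].to_numpy()
            lo, hi = np.percentile(x, [2.5, 97.5])
            sign_testable = name.startswith("beta_") or name == "cov_int_slope"
            rows.append(
                {
                    "parameter": name,
                    "mean": float(x.mean()),
                    "lower95": float(lo),
                    "upper95": float(hi),
                    "supported": bool(sign_testable and (lo > 0 or hi < 0)),
                }
            )
        return pd.DataFrame(rows)


def _sample_inv_wishart(rng: np.random.Generator, df: float, scale: np.ndarray):
    """Inverse-Wishart draw via the Bartlett decomposition."""
    p = scale.shape[0]
    l_inv = np.linalg.cholesky(np.linalg.inv(scale))
    a = np.zeros((p, p))
    for i in range(p):
        a[i, i] = np.sqrt(rng.chisquare(df - i))
    tril = np.tril_indices(p, -1)
    a[tril] = rng.standard_normal(len(tril[0]))
    x = l_inv @ a
    w = x @ x.T
    return np.linalg.inv(w)


def _split_rhat(x: np.ndarray) -> float:
    """Potential scale reduction factor on a single split chain."""
    n = len(x) // 2
    if n < 2:
        return np.nan
    chains = np.stack([x[:n], x[n : 2 * n]])
    within = chains.var(axis=1, ddof=1).mean()
    between = n * chains.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0
    var_hat = (n - 1) / n * within + between / n
    return float(np.sqrt(var_hat / within))


def _lag1_autocorr(x: np.ndarray) -> float:
    if len(x) < 3 or x.std() == 0:
        return 0.0
    return float(np.corrcoef(x[:-1], x[1:])[0, 1])


def fit_random_regression(
    trials: pd.DataFrame,
    model_spec: ModelSpec | None = None,
    mcmc: MCMCOptions | None = None,
    seed: int | None = None,
) -> BRNPosterior:
    """Fit the random-intercept(/slope) model by Gibbs sampling.

    Parameters
    ----------
    trials
        One row per behavioural trial with the standard columns
        (``female_id``, ``day_centred``, covariates, ``hiss_std``).
    model_spec
        Fixed-effect selection and random-slope switch; defaults to the
        full specification with random slopes.
    mcmc
        Chain and prior settings.
    seed
        Mandatory seed for the sampler.

    Returns
    -------
    BRNPosterior
        Retained draws of the fixed effects (``beta_*``), variance
        components and residual variance, posterior-mean female effects,
        and convergence diagnostics (split-chain scale reduction factors
        and lag-1 autocorrelations).  Non-convergence (any scale reduction
        factor >= 1.05) sets ``converged=False`` and emits a warning
        rather than raising.
    """
    if seed is None:
        raise SamplerConfigError("a seed is required")
    spec = model_spec or ModelSpec()
    opts = mcmc or MCMCOptions()
    opts.validate()
    rng = np.random.default_rng(seed)

    fem_codes, fem_ids = pd.factorize(trials["female_id"], sort=False)
    nf = len(fem_ids)
    if nf < 2:
        raise DegenerateInputError("need at least two females")
    y = trials[spec.response].to_numpy(dtype=float)
    day = trials["day_centred"].to_numpy(dtype=float)
    x, names = build_fixed_design(trials, spec)
    n, p = x.shape
    q = 2 if spec.random_slope else 1

    # sufficient statistics that never change
    xtx = x.T @ x
    xty = x.T @ y
    n_i = np.bincount(fem_codes, minlength=nf).astype(float)
    sd_i = np.bincount(fem_codes, weights=day, minlength=nf)
    sdd_i = np.bincount(fem_codes, weights=day * day, minlength=nf)
    s0y = np.bincount(fem_codes, weights=y, minlength=nf)
    s1y = np.bincount(fem_codes, weights=y * day, minlength=nf)
    # per-female cross-products of the fixed design with (1, day): (nf, p, 2)
    t0 = np.stack(
        [np.bincount(fem_codes, weights=x[:, j], minlength=nf) for j in range(p)],
        axis=1,
    )
    t1 = np.stack(
        [
            np.bincount(fem_codes, weights=x[:, j] * day, minlength=nf)
            for j in range(p)
        ],
        axis=1,
    )
    a_blk = np.stack([t0, t1], axis=2)  # (nf, p, 2)

    v0 = np.asarray(
        opts.prior_scale if opts.prior_scale is not None else np.eye(q),
        dtype=float,
    )
    if v0.shape != (q, q):
        raise SamplerConfigError(f"prior_scale must be {q}x{q}")
    nu0 = opts.prior_df if opts.prior_df is not None else q + 1.0

    beta = np.zeros(p)
    u0 = np.zeros(nf)
    u1 = np.zeros(nf)
    g = np.eye(q) * max(0.1, float(np.var(y)) / 2)
    sig2 = max(float(np.var(y)) / 2, 1e-6)

    n_keep = opts.n_retained
    beta_out = np.empty((n_keep, p))
    var_out = np.empty((n_keep, 4 if q == 2 else 2))
    u_sum = np.zeros((nf, 2))
    kept = 0

    prior_prec = opts.beta_prec * np.eye(p)
    for it in range(opts.n_iter):
        # conditional covariance M_i = (G^-1 + Z_i'Z_i / sig2)^-1 of each
        # female's effect block, given the current G and residual variance
        if q == 2:
            det_g = g[0, 0] * g[1, 1] - g[0, 1] ** 2
            gi00, gi01, gi11 = (
                g[1, 1] / det_g,
                -g[0, 1] / det_g,
                g[0, 0] / det_g,
            )
            p00 = n_i / sig2 + gi00
            p01 = sd_i / sig2 + gi01
            p11 = sdd_i / sig2 + gi11
            det_p = p00 * p11 - p01**2
            c00, c01, c11 = p11 / det_p, -p01 / det_p, p00 / det_p
            m_blk = np.empty((nf, 2, 2))
            m_blk[:, 0, 0] = c00
            m_blk[:, 0, 1] = m_blk[:, 1, 0] = c01
            m_blk[:, 1, 1] = c11
        else:
            c00 = 1.0 / (n_i / sig2 + 1.0 / g[0, 0])

        # --- fixed effects, female effects marginalized out (collapsed)
        # X'V^-1X = X'X/s2 - sum_i A_i M_i A_i' / s2^2 with A_i = X_i'Z_i
        if q == 2:
            corr = np.einsum("fpk,fkl,fql->pq", a_blk, m_blk, a_blk)
            sy = np.stack([s0y, s1y], axis=1)  # (nf, 2)
            corr_y = np.einsum("fpk,fkl,fl->p", a_blk, m_blk, sy)
        else:
            corr = (t0 * c00[:, None]).T @ t0
            corr_y = (t0 * c00[:, None]).T @ s0y
        a = xtx / sig2 - corr / sig2**2 + prior_prec
        b = xty / sig2 - corr_y / sig2**2
        la = np.linalg.cholesky(a)
        mean = np.linalg.solve(a, b)
        beta = mean + np.linalg.solve(la.T, rng.standard_normal(p))

        # --- female effects given the fixed effects
        r = y - x @ beta
        s0 = np.bincount(fem_codes, weights=r, minlength=nf)
        if q == 2:
            s1 = np.bincount(fem_codes, weights=r * day, minlength=nf)
            m0 = (c00 * s0 + c01 * s1) / sig2
            m1 = (c01 * s0 + c11 * s1) / sig2
            # analytic 2x2 cholesky of the covariance
            l00 = np.sqrt(c00)
            l10 = c01 / l00
            l11 = np.sqrt(np.maximum(c11 - l10**2, 1e-300))
            e0 = rng.standard_normal(nf)
            e1 = rng.standard_normal(nf)
            u0 = m0 + l00 * e0
            u1 = m1 + l10 * e0 + l11 * e1
        else:
            m0 = c00 * s0 / sig2
            u0 = m0 + np.sqrt(c00) * rng.standard_normal(nf)
            u1 = np.zeros(nf)

        # --- among-individual covariance matrix
        if q == 2:
            s_u = np.array(
                [
                    [u0 @ u0, u0 @ u1],
                    [u0 @ u1, u1 @ u1],
                ]
            )
        else:
            s_u = np.array([[u0 @ u0]])
        g = _sample_inv_wishart(rng, nu0 + nf, v0 + s_u)

        # --- residual variance
        resid = r - u0[fem_codes] - (u1[fem_codes] * day if q == 2 else 0.0)
        rss = resid @ resid
        sig2 = (opts.resid_rate + 0.5 * rss) / rng.gamma(
            opts.resid_shape + 0.5 * n
        )

        if it >= opts.burn_in and (it - opts.burn_in) % opts.thin == 0:
            beta_out[kept] = beta
            if q == 2:
                var_out[kept] = (g[0, 0], g[1, 1], g[0, 1], sig2)
            else:
                var_out[kept] = (g[0, 0], sig2)
            u_sum[:, 0] += u0
            u_sum[:, 1] += u1
            kept += 1

    cols = {f"beta_{nm}": beta_out[:, j] for j, nm in enumerate(names)}
    if q == 2:
        cols.update(
            var_intercept=var_out[:, 0],
            var_slope=var_out[:, 1],
            cov_int_slope=var_out[:, 2],
            var_resid=var_out[:, 3],
        )
    else:
        cols.update(var_intercept=var_out[:, 0], var_resid=var_out[:, 1])
    draws = pd.DataFrame(cols)

    diag_rows = []
    worst = 1.0
    for name in draws.columns:
        arr = draws[name].to_numpy()
        rhat = _split_rhat(arr)
        ac = _lag1_autocorr(arr)
        worst = max(worst, rhat if np.isfinite(rhat) else 1.0)
        diag_rows.append({"parameter": name, "rhat": rhat, "lag1_autocorr": ac})
    converged = worst < 1.05
    if not converged:
        warnings.warn(
            f"chain may not have converged (max scale reduction {worst:.3f})",
            RuntimeWarning,
            stacklevel=2,
        )

    return BRNPosterior(
        draws=draws,
        female_ids=list(fem_ids),
        u_mean=u_sum / max(kept, 1),
        random_slope=spec.random_slope,
        fixed_names=names,
        convergence=pd.DataFrame(diag_rows),
        converged=converged,
    )


def extract_female_effects(
    posterior: BRNPosterior, trials: pd.DataFrame | None = None
) -> FemaleEffects:
    """Posterior-mean intercept/slope deviation per female.

    If ``trials`` is given, every female in it must be present in the fit
    (KeyError otherwise).
    """
    frame = pd.DataFrame(
        {
            "female_id": posterior.female_ids,
            "intercept_dev": posterior.u_mean[:, 0],
            "slope_dev": posterior.u_mean[:, 1],
        }
    )
    if trials is not None:
        missing = set(trials["female_id"]) - set(posterior.female_ids)
        if missing:
            raise KeyError(
                f"females absent from the fitted model: {sorted(missing)[:5]}"
            )
    return FemaleEffects(frame=frame)
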