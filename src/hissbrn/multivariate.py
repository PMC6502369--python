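"""Multivariate partitioning of trait covariances into ID and R matrices.

A five-trait Gaussian mixed model with random female intercepts partitions
the phenotypic covariance of hissing behaviour, lay date, clutch size,
fledgling number and mean fledgling mass into an among-individual (ID)
matrix and a residual (R) matrix.  Hissing behaviour contributes repeated
records, so its within-individual variance is estimated in R; the four
reproductive traits have a single record per female, so their residual
variances are fixed to a tiny constant ("essentially zero") and all
residual covariances are fixed to zero - within-individual covariances
involving single-record traits are not identifiable.

Only successful nests enter the model (fledgling data exist for them);
all responses are mean-centred and scaled to unit variance beforehand.
The sampler mirrors the univariate one: Gaussian updates for trait means
and per-female effect vectors, inverse-Wishart for the 5x5 ID matrix and
inverse-gamma for the hissing residual variance.  Posterior draws of the
ID matrix are retained so that path analysis can propagate estimation
uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .brn import DegenerateInputError, MCMCOptions, _sample_inv_wishart, standardize
from .design import DesignError
from .traits import TRAIT_ORDER

__all__ = [
    "CovariancePartition",
    "fit_multivariate",
    "id_correlations",
    "MV_MCMC_DEFAULT",
]

#: Default tiny residual variance for single-record traits, on the
#: unit-variance response scale.
FIXED_RESID_DEFAULT = 1e-4

MV_MCMC_DEFAULT = MCMCOptions(n_iter=6_000, burn_in=1_000, thin=10)

_TRAIT_COLUMNS = {
    "lay_date": "lay_date",
    "clutch_size": "clutch_size",
    "fledgling_number": "n_fledged",
    "fledgling_mass": "mean_fledgling_mass",
}


@dataclass
class CovariancePartition:
    """Posterior samples of the among-individual (ID) trait matrix."""

    trait_order: tuple[str, ...]
    id_samples: np.ndarray  # (n_samples, 5, 5)
    resid_var_hissing: np.ndarray  # (n_samples,)
    fixed_resid: float
    female_ids: list[str]

    @property
    def n_females(self) -> int:
        return len(self.female_ids)

    @property
    def n_samples(self) -> int:
        return self.id_samples.shape[0]

    def posterior_mean(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.id_samples.mean(axis=0),
            index=self.trait_order,
            columns=self.trait_order,
        )

    def correlation_summary(self) -> pd.DataFrame:
        """Pairwise posterior mean ID correlations with 95% CrIs."""
        corr = id_correlations(self)
        rows = []
        k = len(self.trait_order)
        for i in range(k):
            for j in range(i + 1, k):
                vals = corr[:, i, j]
                lo, hi = np.percentile(vals, [2.5, 97.5])
                rows.append(
                    {
                        "trait_a": self.trait_order[i],
                        "trait_b": self.trait_order[j],
                        "mean": float(vals.mean()),
                        "lower95": float(lo),
                        "upper95": float(hi),
                    }
                )
        return pd.DataFrame(rows)


def fit_multivariate(
    trials: pd.DataFrame,
    females: pd.DataFrame,
    mcmc: MCMCOptions | None = None,
    seed: int | None = None,
    *,
    fixed_resid: float = FIXED_RESID_DEFAULT,
) -> CovariancePartition:
    """Fit the five-trait random-intercept model on successful nests.

    Parameters
    ----------
    trials
        Repeated hissing trials (``female_id``, ``hiss_std``, ...).
    females
        Per-female reproductive records (``female_id``, ``lay_date``,
        ``clutch_size``, ``nest_success``, ``n_fledged``,
        ``mean_fledgling_mass``).
    fixed_resid
        Residual variance assigned to the single-record traits; must be
        small relative to 1 (results are insensitive to its exact value).
    """
    if seed is None:
        raise ValueError("a seed is required")
    if not 0 < fixed_resid < 0.1:
        raise ValueError("fixed_resid must be a small positive number")
    opts = mcmc or MV_MCMC_DEFAULT
    opts.validate()
    rng = np.random.default_rng(seed)

    ok = females[females["nest_success"].astype(bool)].copy()
    cols = list(_TRAIT_COLUMNS.values())
    ok = ok.dropna(subset=cols)
    ok = ok[ok["female_id"].isin(trials["female_id"])]
    nf = len(ok)
    if nf < 5:
        raise DesignError(
            f"only {nf} females with complete records; need at least 5"
        )
    sub = trials[trials["female_id"].isin(ok["female_id"])]

    for trait, col in _TRAIT_COLUMNS.items():
        if ok[col].nunique() <= 1:
            raise DegenerateInputError(f"trait {trait!r} is constant")
    if sub["hiss_std"].nunique() <= 1:
        raise DegenerateInputError("hissing response is constant")

    # standardize every response within the analysed subset
    y_h, _, _ = standardize(sub["hiss_std"].to_numpy())
    fem_codes, fem_ids = pd.factorize(sub["female_id"], sort=False)
    ok = ok.set_index("female_id").loc[list(fem_ids)]
    y_traits = np.column_stack(
        [standardize(ok[col].to_numpy())[0] for col in _TRAIT_COLUMNS.values()]
    )  # (nf, 4)

    n_obs_h = len(y_h)
    n_i = np.bincount(fem_codes, minlength=nf).astype(float)
    s_h = np.bincount(fem_codes, weights=y_h, minlength=nf)

    k = len(TRAIT_ORDER)
    nu0 = k + 1.0
    v0 = np.eye(k)
    a0 = b0 = 1e-3

    mu = np.zeros(k)
    u = np.zeros((nf, k))
    g = np.eye(k) * 0.5
    sig2h = 0.5

    n_keep = opts.n_retained
    id_out = np.empty((n_keep, k, k))
    rvh_out = np.empty(n_keep)
    kept = 0

    d_base = np.zeros(k)
    d_base[1:] = 1.0 / fixed_resid

    for it in range(opts.n_iter):
        # --- per-female effect vectors
        ginv = np.linalg.inv(g)
        prec = np.broadcast_to(ginv + np.diag(d_base), (nf, k, k)).copy()
        prec[:, 0, 0] += n_i / sig2h
        b = np.empty((nf, k))
        b[:, 0] = (s_h - n_i * mu[0]) / sig2h
        b[:, 1:] = (y_traits - mu[1:]) / fixed_resid
        lo = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, b[..., None])[..., 0]
        z = rng.standard_normal((nf, k, 1))
        u = mean + np.linalg.solve(np.swapaxes(lo, 1, 2), z)[..., 0]

        # --- trait means
        resid_h = y_h - u[fem_codes, 0]
        mu = np.empty(k)
        mu[0] = resid_h.mean() + np.sqrt(sig2h / n_obs_h) * rng.standard_normal()
        rmeans = (y_traits - u[:, 1:]).mean(axis=0)
        mu[1:] = rmeans + np.sqrt(fixed_resid / nf) * rng.standard_normal(k - 1)

        # --- ID matrix
        g = _sample_inv_wishart(rng, nu0 + nf, v0 + u.T @ u)

        # --- hissing residual variance
        e = y_h - mu[0] - u[fem_codes, 0]
        sig2h = (b0 + 0.5 * (e @ e)) / rng.gamma(a0 + 0.5 * n_obs_h)

        if it >= opts.burn_in and (it - opts.burn_in) % opts.thin == 0:
            id_out[kept] = g
            rvh_out[kept] = sig2h
            kept += 1

    return CovariancePartition(
        trait_order=TRAIT_ORDER,
        id_samples=id_out,
        resid_var_hissing=rvh_out,
        fixed_resid=fixed_resid,
        female_ids=list(fem_ids),
    )


def id_correlations(
    partition: CovariancePartition | np.ndarray,
    cond_threshold: float = 1e10,
) -> np.ndarray:
    """Convert each ID covariance sample to a correlation matrix.

    Near-singular samples (condition number above ``cond_threshold``) are
    ridge-jittered before conversion, with a warning.
    """
    samples = (
        partition.id_samples
        if isinstance(partition, CovariancePartition)
        else np.asarray(partition, dtype=float)
    )
    if samples.ndim == 2:
        samples = samples[None]
    out = np.empty_like(samples)
    n_jittered = 0
    for s, cov in enumerate(samples):
        if np.linalg.cond(cov) > cond_threshold:
            cov = cov + np.eye(cov.shape[0]) * (np.trace(cov) * 1e-10)
            n_jittered += 1
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
        out[s] = corr
    if n_jittered:
        warnings.warn(
            f"{n_jittered} near-singular covariance samples were ridge-jittered",
            RuntimeWarning,
            stacklevel=2,
        )
    return out
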