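"""Repeatability estimates and permutation tests for variance components.

Adjusted repeatability is the among-individual variance divided by the sum
of the among-individual and residual variances, computed per posterior
draw and then summarized.  Stage-specific repeatabilities come from
random-intercept-only fits on the incubation or nestling subset.

Because variance components are bounded below by zero, their credible
intervals never overlap zero; significance is therefore assessed by a
permutation scheme: the response is reshuffled uniformly across all
observations (design and covariates fixed), the model refitted, and the
observed posterior mean compared with the null distribution of posterior
means.  The permutation p-value is the exceedance proportion
(number of null means >= observed) / n_perm; when no null mean reaches the
observed value it is reported as "< 1/n_perm".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .brn import (
    BRNPosterior,
    DegenerateInputError,
    MCMCOptions,
    ModelSpec,
    fit_random_regression,
)

__all__ = [
    "RepeatabilityEstimate",
    "PermutationResult",
    "adjusted_repeatability",
    "stage_repeatability",
    "permutation_test",
]

#: Shorter chains used for each permutation refit (only posterior means of
#: variance components are needed from them).
PERM_MCMC_DEFAULT = MCMCOptions(n_iter=3_000, burn_in=500, thin=5)

PERMUTABLE_COMPONENTS = ("var_intercept", "var_slope", "cov_int_slope")


@dataclass(frozen=True)
class RepeatabilityEstimate:
    """Posterior summary of an intraclass correlation."""

    r: float
    lower95: float
    upper95: float
    scope: str = "overall"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower95 <= self.upper95 <= 1.0:
            raise ValueError("repeatability CrI outside [0, 1]")


@dataclass(frozen=True)
class PermutationResult:
    component: str
    observed: float
    null_means: np.ndarray
    n_perm: int

    @property
    def n_effective(self) -> int:
        return len(self.null_means)

    @property
    def p(self) -> float:
        if self.n_effective == 0:
            return float("nan")
        return float(np.sum(self.null_means >= self.observed) / self.n_effective)

    @property
    def p_label(self) -> str:
        """Printable p; exceedance count zero is below the resolvable level."""
        if self.n_effective and self.p == 0.0:
            return f"< {1 / self.n_effective:g}"
        return f"{self.p:g}"


def _ratio_summary(vi: np.ndarray, vr: np.ndarray, scope: str) -> RepeatabilityEstimate:
    with np.errstate(invalid="ignore"):
        ratio = np.where(vi + vr > 0, vi / (vi + vr), 0.0)
    lo, hi = np.percentile(ratio, [2.5, 97.5])
    return RepeatabilityEstimate(
        r=float(ratio.mean()),
        lower95=float(max(lo, 0.0)),
        upper95=float(min(hi, 1.0)),
        scope=scope,
    )


def adjusted_repeatability(
    posterior: BRNPosterior, scope: str = "overall"
) -> RepeatabilityEstimate:
    """R_adj = var_intercept / (var_intercept + var_resid), per draw."""
    if len(posterior.draws) == 0:
        raise ValueError("empty posterior")
    return _ratio_summary(
        posterior.draws["var_intercept"].to_numpy(),
        posterior.draws["var_resid"].to_numpy(),
        scope,
    )


def stage_repeatability(
    trials: pd.DataFrame,
    stage: str,
    mcmc: MCMCOptions | None = None,
    seed: int | None = None,
    model_spec: ModelSpec | None = None,
) -> RepeatabilityEstimate:
    """Repeatability from a random-intercept fit on one breeding stage."""
    if stage not in ("incubation", "nestling"):
        raise ValueError(f"unknown stage {stage!r}")
    sub = trials[trials["stage"] == stage]
    if sub.empty:
        raise DegenerateInputError(f"no trials in stage {stage!r}")
    repeats = sub.groupby("female_id").size()
    if (repeats >= 2).sum() < 2:
        raise DegenerateInputError(
            f"stage {stage!r} has fewer than two females with repeated trials"
        )
    spec = model_spec or ModelSpec(random_slope=False)
    if spec.random_slope:
        spec = ModelSpec(
            fixed_effects=spec.fixed_effects,
            random_slope=False,
            response=spec.response,
        )
    post = fit_random_regression(sub, model_spec=spec, mcmc=mcmc, seed=seed)
    return adjusted_repeatability(post, scope=stage)


def permutation_test(
    trials: pd.DataFrame,
    component: str = "var_intercept",
    n_perm: int = 100,
    seed: int | None = None,
    *,
    model_spec: ModelSpec | None = None,
    mcmc: MCMCOptions | None = None,
    perm_mcmc: MCMCOptions | None = None,
    observed_posterior: BRNPosterior | None = None,
    max_retries: int = 3,
) -> PermutationResult:
    """Permutation significance test for a variance component.

    The observed posterior mean comes from a full fit (or a supplied
    ``observed_posterior``); each permutation reshuffles the response
    across all observations, breaking female identity entirely, and refits
    the same model with shorter chains.  Refit failures are retried with a
    new shuffle up to ``max_retries`` times, then dropped with a warning.
    """
    if component not in PERMUTABLE_COMPONENTS:
        raise ValueError(
            f"component must be one of {PERMUTABLE_COMPONENTS}, got {component!r}"
        )
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None:
        raise ValueError("a seed is required")
    spec = model_spec or ModelSpec()
    rng = np.random.default_rng(seed)

    if observed_posterior is None:
        observed_posterior = fit_random_regression(
            trials, model_spec=spec, mcmc=mcmc, seed=int(rng.integers(2**31))
        )
    observed = float(observed_posterior.draws[component].mean())

    popts = perm_mcmc or PERM_MCMC_DEFAULT
    null_means: list[float] = []
    n_failed = 0
    for _ in range(n_perm):
        for attempt in range(max_retries + 1):
            shuffled = trials.copy()
            shuffled[spec.response] = rng.permutation(
                shuffled[spec.response].to_numpy()
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    post = fit_random_regression(
                        shuffled,
                        model_spec=spec,
                        mcmc=popts,
                        seed=int(rng.integers(2**31)),
                    )
            except Exception:  # noqa: BLE001 - refit failures are retried
                continue
            null_means.append(float(post.draws[component].mean()))
            break
        else:
            n_failed += 1
    if n_failed:
        warnings.warn(
            f"{n_failed} permutation refits failed after retries and were "
            "excluded",
            RuntimeWarning,
            stacklevel=2,
        )

    return PermutationResult(
        component=component,
        observed=observed,
        null_means=np.asarray(null_means),
        n_perm=n_perm,
    )
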