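"""Synthetic data generators for the nest-defence analysis pipeline.

Two generators mirror the study design:

* :func:`simulate_brn` draws repeated hissing-behaviour trials under a
  behavioural-reaction-norm model: each female has a random intercept
  (average hissing level, her "nest defence personality") and a random
  slope (plasticity over the nesting cycle), drawn jointly from a 2x2
  covariance matrix, plus Gaussian residual noise.  The response is
  produced directly on the mean-centred, unit-variance scale used by the
  analysis; raw call counts are obtained by an affine calibration
  (:func:`counts_from_latent`).
* :func:`simulate_reproduction` draws the per-female reproductive traits
  (lay date, clutch size, fledgling number, mean fledgling mass) together
  with a latent nest-defence trait from a user-specified causal diagram
  (DAG), so that downstream covariance partitioning and path analysis can
  be validated against known generating structures.

Default generative parameters are the posterior means of the reference
field study (104 females, 448 trials): among-individual intercept variance
0.85, slope variance 0.0014, intercept-slope covariance 0.010, residual
variance 0.19 and a population slope of 0.02 standardized units per day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .design import TrialDesign, stage_of
from .traits import TRAIT_ORDER

AGE_CLASSES = ("first_year", "adult", "unknown")


class ParameterError(ValueError):
    """Invalid generator parameters."""


@dataclass(frozen=True)
class ReactionNormParams:
    """Fixed effects and variance components of the reaction-norm model.

    All values are on the standardized response scale.  ``beta_day`` is per
    day in the nesting cycle (centred on hatching); the remaining covariate
    coefficients are per standard deviation of their covariate.  Defaults
    are the reference study's posterior means.
    """

    beta0: float = 0.08
    beta_day: float = 0.02
    beta_julian: float = -0.05
    beta_time_mean: float = 0.07
    beta_time_dev: float = 0.01
    beta_age_adult: float = -0.14
    beta_age_unknown: float = 0.70
    var_intercept: float = 0.85
    var_slope: float = 0.0014
    cov_int_slope: float = 0.010
    var_resid: float = 0.19

    def __post_init__(self) -> None:
        if self.var_intercept < 0 or self.var_slope < 0:
            raise ParameterError("random-effect variances must be >= 0")
        if self.var_resid < 0:
            raise ParameterError("residual variance must be >= 0")
        det = self.var_intercept * self.var_slope - self.cov_int_slope**2
        if det < -1e-12:
            raise ParameterError(
                "intercept/slope covariance matrix is not positive "
                f"semidefinite (determinant {det:.3g})"
            )

    @property
    def g_matrix(self) -> np.ndarray:
        """2x2 among-individual (intercept, slope) covariance matrix."""
        return np.array(
            [
                [self.var_intercept, self.cov_int_slope],
                [self.cov_int_slope, self.var_slope],
            ]
        )


@dataclass(frozen=True)
class CovariateConfig:
    """Distributions of the nuisance covariates attached to each trial.

    Julian test date (days since 1 July of the previous year) is constant
    per female; test time (minutes after sunrise) varies per trial.  Both
    are uniform; female age class is categorical.  These only need to exist
    with realistic ranges - the analysis centres and standardizes them.
    """

    julian_range: tuple[float, float] = (281.0, 318.0)
    time_range: tuple[float, float] = (60.0, 660.0)
    age_probs: tuple[float, float, float] = (0.45, 0.45, 0.10)

    def julian_moments(self) -> tuple[float, float]:
        lo, hi = self.julian_range
        return (lo + hi) / 2.0, (hi - lo) / math.sqrt(12.0)

    def time_moments(self) -> tuple[float, float]:
        lo, hi = self.time_range
        return (lo + hi) / 2.0, (hi - lo) / math.sqrt(12.0)


@dataclass(frozen=True)
class CountCalibration:
    """Affine map from the standardized scale to raw hissing-call counts.

    Defaults reproduce the reference dataset's count moments
    (mean 12.83, s.d. 11.06) and observed range 0-43 calls per 60 s.
    """

    location: float = 12.83
    scale: float = 11.06
    lower: int = 0
    upper: int = 43

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ParameterError("count calibration scale must be > 0")
        if self.lower >= self.upper:
            raise ParameterError("count calibration bounds must be ordered")


def counts_from_latent(
    hiss_std: np.ndarray | float,
    calibration: CountCalibration | None = None,
) -> np.ndarray:
    """Map standardized hissing scores to integer call counts."""
    cal = calibration or CountCalibration()
    x = np.asarray(hiss_std, dtype=float)
    raw = cal.location + cal.scale * x
    return np.clip(np.round(raw), cal.lower, cal.upper).astype(int)


def simulate_brn(
    design: TrialDesign,
    params: ReactionNormParams,
    seed: int,
    *,
    intercept_dev: np.ndarray | None = None,
    covariates: CovariateConfig | None = None,
    calibration: CountCalibration | None = None,
) -> pd.DataFrame:
    """Simulate repeated hissing trials under the reaction-norm model.

    Per female, an (intercept, slope) deviation pair is drawn from the 2x2
    among-individual covariance matrix; per trial,

    ``hiss_std = linear predictor + intercept_dev + slope_dev * day + e``

    with residual variance ``var_resid``.  Covariates enter the linear
    predictor standardized by their configured theoretical moments.

    Parameters
    ----------
    intercept_dev
        Optional per-female intercept deviations (aligned with
        ``design.females``), e.g. to couple the behavioural intercept to a
        trait generated by :func:`simulate_reproduction`.  Slope deviations
        are then drawn from their conditional distribution given the
        intercept.
    """
    rng = np.random.default_rng(seed)
    cov = covariates or CovariateConfig()
    females = design.females
    nf = len(females)

    g = params.g_matrix
    if intercept_dev is not None:
        b0 = np.asarray(intercept_dev, dtype=float)
        if b0.shape != (nf,):
            raise ParameterError(
                f"intercept_dev has shape {b0.shape}, expected ({nf},)"
            )
        if params.var_intercept > 0:
            cond_mean = params.cov_int_slope / params.var_intercept * b0
            cond_var = max(
                params.var_slope
                - params.cov_int_slope**2 / params.var_intercept,
                0.0,
            )
        else:
            cond_mean = np.zeros(nf)
            cond_var = params.var_slope
        b1 = cond_mean + math.sqrt(cond_var) * rng.standard_normal(nf)
    else:
        # guard exact-zero matrices: multivariate_normal handles PSD
        dev = rng.multivariate_normal(np.zeros(2), g, size=nf, method="svd")
        b0, b1 = dev[:, 0], dev[:, 1]

    jl_mu, jl_sd = cov.julian_moments()
    tm_mu, tm_sd = cov.time_moments()
    julian = rng.uniform(*cov.julian_range, size=nf)
    age = rng.choice(len(AGE_CLASSES), size=nf, p=cov.age_probs)

    rows = []
    for i, fem in enumerate(females):
        days = np.asarray(design.schedule[fem], dtype=float)
        k = len(days)
        t_raw = rng.uniform(*cov.time_range, size=k)
        t_mean = t_raw.mean()
        lp = (
            params.beta0
            + params.beta_day * days
            + params.beta_julian * (julian[i] - jl_mu) / jl_sd
            + params.beta_time_mean * (t_mean - tm_mu) / tm_sd
            + params.beta_time_dev * (t_raw - t_mean) / tm_sd
            + params.beta_age_adult * (age[i] == 1)
            + params.beta_age_unknown * (age[i] == 2)
        )
        resid = math.sqrt(params.var_resid) * rng.standard_normal(k)
        hiss = lp + b0[i] + b1[i] * days + resid
        for j in range(k):
            rows.append(
                (
                    fem,
                    days[j],
                    stage_of(days[j]),
                    julian[i],
                    t_mean,
                    t_raw[j] - t_mean,
                    AGE_CLASSES[age[i]],
                    hiss[j],
                )
            )

    df = pd.DataFrame(
        rows,
        columns=[
            "female_id",
            "day_centred",
            "stage",
            "julian_date",
            "time_mean",
            "time_dev",
            "age_class",
            "hiss_std",
        ],
    )
    df["hiss_count"] = counts_from_latent(df["hiss_std"].to_numpy(), calibration)
    return df[
        [
            "female_id",
            "day_centred",
            "stage",
            "julian_date",
            "time_mean",
            "time_dev",
            "age_class",
            "hiss_count",
            "hiss_std",
        ]
    ]


# ---------------------------------------------------------------------------
# Reproductive traits from a causal diagram


@dataclass(frozen=True)
class CausalScenario:
    """A causal diagram over the five traits plus a nest-success process.

    Edges carry standardized path weights; every trait has unit marginal
    variance (endogenous residual variances are solved for accordingly).
    Nest success is Bernoulli(``success_prob``), independent of all traits,
    unless ``n_success`` fixes the exact number of successful nests.
    """

    edges: Mapping[tuple[str, str], float] = field(default_factory=dict)
    success_prob: float = 0.74
    n_success: int | None = None
    discretize_fledglings: bool = False
    traits: tuple[str, ...] = TRAIT_ORDER

    def __post_init__(self) -> None:
        for (a, b) in self.edges:
            if a not in self.traits or b not in self.traits:
                raise ParameterError(f"edge {(a, b)} references unknown trait")
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise ParameterError("causal diagram contains a cycle")
        if not (0.0 < self.success_prob <= 1.0):
            raise ParameterError("success_prob must be in (0, 1]")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.traits)
        g.add_edges_from(self.edges.keys())
        return g

    def parents(self, trait: str) -> list[str]:
        return [a for (a, b) in self.edges if b == trait]

    def implied_correlation(self) -> pd.DataFrame:
        """Trait correlation matrix implied by the diagram (path tracing).

        Built trait by trait in topological order; raises if the configured
        weights would require a negative residual variance (i.e. imply a
        marginal variance above 1).
        """
        order = list(nx.topological_sort(self.graph()))
        idx = {t: i for i, t in enumerate(self.traits)}
        sigma = np.zeros((len(self.traits), len(self.traits)))
        for t in order:
            i = idx[t]
            pa = self.parents(t)
            if not pa:
                sigma[i, i] = 1.0
                continue
            w = np.array([self.edges[(p, t)] for p in pa])
            pi = [idx[p] for p in pa]
            explained = float(w @ sigma[np.ix_(pi, pi)] @ w)
            psi = 1.0 - explained
            if psi <= 1e-9:
                raise ParameterError(
                    f"edge weights into {t!r} imply variance >= 1 "
                    f"(explained {explained:.3f})"
                )
            cross = sigma[:, pi] @ w
            sigma[i, :] = cross
            sigma[:, i] = cross
            sigma[i, i] = 1.0
        return pd.DataFrame(sigma, index=self.traits, columns=self.traits)


#: Ready-made generating scenarios.  ``model3_strong`` follows the
#: best-supported causal structure (lay date -> nest defence -> clutch size,
#: plus the reproductive cascade) with effect sizes large enough for model
#: recovery; ``independence`` has no cross-trait effects.
SCENARIOS: dict[str, CausalScenario] = {
    "independence": CausalScenario(),
    "model3_strong": CausalScenario(
        edges={
            ("lay_date", "nest_defence"): -0.25,
            ("nest_defence", "clutch_size"): -0.40,
            ("lay_date", "clutch_size"): -0.45,
            ("clutch_size", "fledgling_number"): 0.60,
            ("lay_date", "fledgling_number"): -0.10,
            ("clutch_size", "fledgling_mass"): -0.30,
            ("lay_date", "fledgling_mass"): -0.10,
        }
    ),
}

#: Affine maps from the standardized latent scale to field-realistic units
#: (purely cosmetic; all analyses re-standardize).
_RAW_SCALES = {
    "lay_date": (105.0, 6.0),  # April days since 1 Jan
    "clutch_size": (8.7, 1.6),  # eggs
    "fledgling_number": (6.5, 2.2),  # fledged young
    "fledgling_mass": (16.4, 1.3),  # g at day 15
}


def simulate_reproduction(
    scenario: CausalScenario,
    female_ids: Sequence[str],
    seed: int,
    *,
    nest_defence: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw per-female reproductive traits from a causal scenario.

    Traits are generated in topological order as weighted sums of their
    parents plus Gaussian noise, each with unit marginal variance, then
    mapped to field-realistic scales.  Unsuccessful nests carry no
    fledgling records (NaN).

    Parameters
    ----------
    nest_defence
        Optional standardized values for the nest-defence node (e.g. a
        female's latent behavioural intercept).  Only valid when the node
        has no parents in the diagram.
    """
    rng = np.random.default_rng(seed)
    females = list(female_ids)
    n = len(females)
    order = list(nx.topological_sort(scenario.graph()))

    z: dict[str, np.ndarray] = {}
    sigma = scenario.implied_correlation()  # validates weights
    for t in order:
        pa = scenario.parents(t)
        if t == "nest_defence" and nest_defence is not None:
            if pa:
                raise ParameterError(
                    "cannot fix nest_defence values: node has parents"
                )
            vals = np.asarray(nest_defence, dtype=float)
            if vals.shape != (n,):
                raise ParameterError(
                    f"nest_defence has shape {vals.shape}, expected ({n},)"
                )
            z[t] = vals
            continue
        if not pa:
            z[t] = rng.standard_normal(n)
            continue
        w = np.array([scenario.edges[(p, t)] for p in pa])
        explained = float(
            w @ sigma.loc[pa, pa].to_numpy() @ w
        )
        psi = max(1.0 - explained, 1e-12)
        mean = sum(scenario.edges[(p, t)] * z[p] for p in pa)
        z[t] = mean + math.sqrt(psi) * rng.standard_normal(n)

    if scenario.n_success is not None:
        if not 1 <= scenario.n_success <= n:
            raise ParameterError("n_success outside 1..n_females")
        success = np.zeros(n, dtype=bool)
        success[rng.choice(n, size=scenario.n_success, replace=False)] = True
    else:
        success = rng.random(n) < scenario.success_prob

    df = pd.DataFrame({"female_id": females, "nest_defence": z["nest_defence"]})
    for t, (loc, scale) in _RAW_SCALES.items():
        df[t] = loc + scale * z[t]
    if scenario.discretize_fledglings:
        df["clutch_size"] = np.clip(np.round(df["clutch_size"]), 1, None)
        df["fledgling_number"] = np.clip(np.round(df["fledgling_number"]), 0, None)
    df["nest_success"] = success.astype(int)
    df.loc[~success, ["fledgling_number", "fledgling_mass"]] = np.nan
    df = df.rename(
        columns={
            "fledgling_number": "n_fledged",
            "fledgling_mass": "mean_fledgling_mass",
        }
    )
    return df[
        [
            "female_id",
            "nest_defence",
            "lay_date",
            "clutch_size",
            "nest_success",
            "n_fledged",
            "mean_fledgling_mass",
        ]
    ]


def couple_intercepts(
    repro: pd.DataFrame, params: ReactionNormParams
) -> np.ndarray:
    """Per-female intercept deviations coupling behaviour to the DAG.

    Scales the standardized nest-defence trait by the among-individual
    intercept standard deviation, for use as ``intercept_dev`` in
    :func:`simulate_brn`.
    """
    return math.sqrt(params.var_intercept) * repro["nest_defence"].to_numpy()
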