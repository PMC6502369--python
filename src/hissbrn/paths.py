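"""Recursive path models over the among-individual trait matrix.

A path model is a DAG over the five traits; standardized path coefficients
are estimated by maximum likelihood from a correlation matrix S by
minimizing the SEM discrepancy function

    F_ML = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

where Sigma(theta) = (I - B)^-1 Psi (I - B)^-T is the structure implied by
the coefficient matrix B and the diagonal (residual/exogenous) variance
matrix Psi.  Model fit uses chi-square = (n_obs - 1) F_ML and
AIC = chi-square + 2 k, with k the number of free parameters; only AIC
differences (dAIC) between models fitted to the same matrix are
interpreted, so the additive constant of this classical SEM convention is
immaterial.  dAIC > 2 marks a model as less supported.

To propagate posterior uncertainty, each candidate model is fitted to
every posterior draw of the ID correlation matrix and coefficients/AIC are
summarized across draws.

The default candidate set encodes the competing causal scenarios linking
nest-defence personality to reproduction:

* model 0 - all traits independent (null);
* model 1 - the reproductive cascade only (lay date and clutch size drive
  fledgling number and mass), nest defence isolated;
* model 2 - model 1 plus lay date -> nest defence;
* model 3 - model 2 plus nest defence -> clutch size (a defence/clutch
  trade-off).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .traits import TRAIT_ORDER

__all__ = [
    "PathModel",
    "PathSampleFit",
    "PathFit",
    "default_models",
    "fit_path_model",
    "fit_over_posterior",
    "compare_models",
    "nest_success_stage",
]

_BASE_EDGES = (
    ("lay_date", "clutch_size"),
    ("clutch_size", "fledgling_number"),
    ("clutch_size", "fledgling_mass"),
    ("lay_date", "fledgling_number"),
    ("lay_date", "fledgling_mass"),
)


class MatrixError(ValueError):
    """Input matrix not usable (asymmetric or not positive definite)."""


@dataclass(frozen=True)
class PathModel:
    """A recursive (acyclic) path diagram over observed traits.

    Free parameters: one coefficient per edge, one residual variance per
    endogenous node, one variance per exogenous node, plus any declared
    covariances between exogenous nodes.
    """

    name: str
    edges: tuple[tuple[str, str], ...] = ()
    variables: tuple[str, ...] = TRAIT_ORDER
    exog_covariances: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a not in self.variables or b not in self.variables:
                raise ValueError(f"edge {(a, b)} references unknown variable")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError(f"model {self.name!r} is not acyclic")
        endo = self.endogenous
        for a, b in self.exog_covariances:
            if a in endo or b in endo:
                raise ValueError(
                    "exogenous covariances may only link exogenous nodes"
                )

    @property
    def endogenous(self) -> tuple[str, ...]:
        targets = {b for _, b in self.edges}
        return tuple(v for v in self.variables if v in targets)

    @property
    def exogenous(self) -> tuple[str, ...]:
        targets = {b for _, b in self.edges}
        return tuple(v for v in self.variables if v not in targets)

    @property
    def n_free(self) -> int:
        return len(self.edges) + len(self.variables) + len(self.exog_covariances)


def default_models(variables: tuple[str, ...] = TRAIT_ORDER) -> list[PathModel]:
    """The four competing causal scenarios (models 0-3)."""
    return [
        PathModel("model0", (), variables),
        PathModel("model1", _BASE_EDGES, variables),
        PathModel(
            "model2", _BASE_EDGES + (("lay_date", "nest_defence"),), variables
        ),
        PathModel(
            "model3",
            _BASE_EDGES
            + (("lay_date", "nest_defence"), ("nest_defence", "clutch_size")),
            variables,
        ),
    ]


@dataclass
class PathSampleFit:
    """ML fit of one path model to one correlation matrix."""

    model: str
    coefficients: dict[tuple[str, str], float]
    residual_variances: dict[str, float]
    f_ml: float
    chi2: float
    aic: float
    converged: bool


def _check_pd(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise MatrixError("input must be a square matrix")
    if not np.allclose(s, s.T, atol=1e-8):
        raise MatrixError("input matrix is not symmetric")
    try:
        np.linalg.cholesky(s)
    except np.linalg.LinAlgError as exc:
        raise MatrixError("input matrix is not positive definite") from exc
    return s


def fit_path_model(
    corr_matrix: np.ndarray, model: PathModel, n_obs: int
) -> PathSampleFit:
    """Maximum-likelihood fit of one path model to one correlation matrix.

    For recursive models with uncorrelated residuals the estimated path
    coefficients coincide with per-equation least-squares partial
    regression coefficients; the fit is nonetheless obtained by direct
    minimization of F_ML so that any declared exogenous covariances and
    non-standard structures are handled uniformly.
    """
    s = _check_pd(corr_matrix)
    p = len(model.variables)
    if s.shape[0] != p:
        raise MatrixError(
            f"matrix is {s.shape[0]}x{s.shape[0]} but model has {p} variables"
        )
    if n_obs < p + 1:
        raise ValueError("n_obs must exceed the number of variables")

    idx = {v: i for i, v in enumerate(model.variables)}
    ne = len(model.edges)
    nc = len(model.exog_covariances)
    sign_det, logdet_s = np.linalg.slogdet(s)
    if sign_det <= 0:
        raise MatrixError("input matrix is not positive definite")

    eye = np.eye(p)

    def build(theta: np.ndarray):
        bmat = np.zeros((p, p))
        for k, (a, b) in enumerate(model.edges):
            bmat[idx[b], idx[a]] = theta[k]
        psi = np.diag(np.exp(theta[ne : ne + p]))
        for k, (a, b) in enumerate(model.exog_covariances):
            psi[idx[a], idx[b]] = psi[idx[b], idx[a]] = theta[ne + p + k]
        amat = np.linalg.inv(eye - bmat)
        return amat, psi, amat @ psi @ amat.T

    def objective(theta: np.ndarray):
        amat, psi, sigma = build(theta)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e10, np.zeros_like(theta)
        sigma_inv = np.linalg.inv(sigma)
        f = logdet + float(np.sum(sigma_inv * s)) - logdet_s - p
        # dF = tr(W dSigma), W = Sigma^-1 - Sigma^-1 S Sigma^-1
        w = sigma_inv - sigma_inv @ s @ sigma_inv
        grad = np.empty_like(theta)
        swa = sigma @ w @ amat
        awa = amat.T @ w @ amat
        for k, (a, b) in enumerate(model.edges):
            grad[k] = 2.0 * swa[idx[a], idx[b]]
        psi_diag = np.exp(theta[ne : ne + p])
        grad[ne : ne + p] = psi_diag * np.diag(awa)
        for k, (a, b) in enumerate(model.exog_covariances):
            grad[ne + p + k] = 2.0 * awa[idx[a], idx[b]]
        return f, grad

    theta0 = np.zeros(ne + p + nc)
    res = minimize(
        objective,
        theta0,
        method="BFGS",
        jac=True,
        options={"gtol": 1e-10, "maxiter": 500},
    )
    f_ml = max(float(res.fun), 0.0)
    converged = bool(np.isfinite(res.fun) and res.fun < 1e9)
    if converged and not res.success:
        # accept flat-gradient stops; anything else is flagged
        gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        converged = gnorm < 1e-5

    coeffs = {
        edge: float(res.x[k]) for k, edge in enumerate(model.edges)
    }
    resid = {
        v: float(np.exp(res.x[ne + i])) for i, v in enumerate(model.variables)
    }
    chi2 = (n_obs - 1) * f_ml
    return PathSampleFit(
        model=model.name,
        coefficients=coeffs,
        residual_variances=resid,
        f_ml=f_ml,
        chi2=chi2,
        aic=chi2 + 2 * model.n_free,
        converged=converged,
    )


@dataclass
class PathFit:
    """A path model fitted across posterior draws of the ID matrix."""

    model: PathModel
    n_obs: int
    coefficients: pd.DataFrame  # edge, mean, lower95, upper95, supported
    aic_samples: np.ndarray
    f_ml_samples: np.ndarray
    aic_mean_matrix: float
    n_flagged: int

    @property
    def mean_aic(self) -> float:
        return float(self.aic_samples.mean())

    def aic(self, aggregate: str = "mean_matrix") -> float:
        """AIC under the chosen aggregation over posterior draws.

        ``"mean_matrix"`` fits the model to the across-draw mean
        correlation matrix; ``"samples"`` averages per-draw AICs.  The
        former is the default for model ranking: per-draw matrices carry
        the posterior's sampling noise, which edge-rich models can absorb
        while sparse ones cannot, so averaging per-draw AICs biases dAIC
        against sparse models (a Jensen-gap artifact).
        """
        if aggregate == "mean_matrix":
            return self.aic_mean_matrix
        if aggregate == "samples":
            return self.mean_aic
        raise ValueError(f"unknown aggregation {aggregate!r}")


def fit_over_posterior(
    corr_samples: np.ndarray,
    model: PathModel,
    n_obs: int,
    *,
    min_samples: int = 100,
    max_flagged_frac: float = 0.10,
) -> PathFit:
    """Fit one path model to every posterior correlation matrix.

    Coefficient summaries are across-sample means and central 95%
    intervals; an edge is "supported" when its interval excludes zero.
    Samples whose optimization fails (or whose matrix is unusable) are
    flagged and excluded; more than ``max_flagged_frac`` flagged samples
    aborts, since uncertainty propagation would be unreliable.
    """
    samples = np.asarray(corr_samples, dtype=float)
    if samples.ndim != 3:
        raise ValueError("corr_samples must be (n_samples, p, p)")
    if samples.shape[0] < min_samples:
        raise ValueError(
            f"need at least {min_samples} posterior matrices, "
            f"got {samples.shape[0]}"
        )

    coef_draws: list[dict] = []
    aics: list[float] = []
    fmls: list[float] = []
    n_flagged = 0
    for s in samples:
        try:
            fit = fit_path_model(s, model, n_obs)
        except MatrixError:
            n_flagged += 1
            continue
        if not fit.converged:
            n_flagged += 1
            continue
        coef_draws.append(fit.coefficients)
        aics.append(fit.aic)
        fmls.append(fit.f_ml)
    if n_flagged > max_flagged_frac * len(samples):
        raise RuntimeError(
            f"{n_flagged}/{len(samples)} path-model fits were flagged; "
            "posterior summaries would be unreliable"
        )

    rows = []
    for edge in model.edges:
        vals = np.array([d[edge] for d in coef_draws])
        lo, hi = np.percentile(vals, [2.5, 97.5])
        rows.append(
            {
                "edge": f"{edge[0]} -> {edge[1]}",
                "mean": float(vals.mean()),
                "lower95": float(lo),
                "upper95": float(hi),
                "supported": bool(lo > 0 or hi < 0),
            }
        )
    coefficients = pd.DataFrame(
        rows, columns=["edge", "mean", "lower95", "upper95", "supported"]
    )
    mean_fit = fit_path_model(samples.mean(axis=0), model, n_obs)
    return PathFit(
        model=model,
        n_obs=n_obs,
        coefficients=coefficients,
        aic_samples=np.asarray(aics),
        f_ml_samples=np.asarray(fmls),
        aic_mean_matrix=mean_fit.aic,
        n_flagged=n_flagged,
    )


@dataclass
class ModelComparison:
    table: pd.DataFrame
    fits: dict[str, PathFit]


def compare_models(
    models: list[PathModel],
    corr_samples: np.ndarray,
    n_obs: int,
    aggregate: str = "mean_matrix",
    **kwargs,
) -> ModelComparison:
    """Rank candidate models by AIC over the posterior ID matrices.

    By default each model's AIC is computed on the across-draw mean
    correlation matrix (see :meth:`PathFit.aic` for why); ``aggregate=
    "samples"`` averages per-draw AICs instead.  dAIC is relative to the
    lowest AIC; models with dAIC > 2 are flagged as less supported.
    """
    names = [m.name for m in models]
    if len(set(names)) != len(names):
        raise ValueError("duplicate model names")
    fits = {
        m.name: fit_over_posterior(corr_samples, m, n_obs, **kwargs)
        for m in models
    }
    table = pd.DataFrame(
        {
            "model": names,
            "mean_aic": [fits[n].aic(aggregate) for n in names],
            "n_free": [m.n_free for m in models],
        }
    )
    table["delta_aic"] = table["mean_aic"] - table["mean_aic"].min()
    table["less_supported"] = table["delta_aic"] > 2.0
    return ModelComparison(
        table=table.sort_values("mean_aic", ignore_index=True), fits=fits
    )


# ---------------------------------------------------------------------------
# Preliminary nest-success stage


def _firth_logit(
    x: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Penalized (Jeffreys-prior) logistic regression, robust to separation."""
    beta = np.zeros(x.shape[1])
    info = np.eye(x.shape[1])
    for _ in range(max_iter):
        pvec = expit(x @ beta)
        w = pvec * (1 - pvec)
        xw = x * w[:, None]
        info = x.T @ xw
        cinv = np.linalg.inv(info)
        hat = np.einsum("ij,jk,ik->i", xw, cinv, x)
        score = x.T @ (y - pvec + hat * (0.5 - pvec))
        step = cinv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta, np.linalg.inv(info)


def nest_success_stage(
    females: pd.DataFrame, female_effects
) -> pd.DataFrame:
    """Binary-response regression of nest success on behaviour and decisions.

    Regresses nest success (at least one fledged young) on the
    standardized among-individual hissing level (posterior-mean BRN
    intercept deviation), lay date and clutch size, via logistic
    regression.  Complete or quasi-complete separation triggers a
    penalized-likelihood (Firth) refit, recorded in the ``method`` column.
    """
    import statsmodels.api as sm

    eff = getattr(female_effects, "frame", female_effects)
    df = females.merge(
        eff[["female_id", "intercept_dev"]], on="female_id", how="inner"
    )
    y = df["nest_success"].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("nest_success has a single class; nothing to fit")

    def z(col):
        v = df[col].to_numpy(dtype=float)
        return (v - v.mean()) / v.std(ddof=1)

    terms = ["hissing_level", "lay_date", "clutch_size"]
    x = np.column_stack(
        [np.ones(len(df)), z("intercept_dev"), z("lay_date"), z("clutch_size")]
    )

    import warnings

    method = "logit"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
        params = np.asarray(fit.params)
        cov = np.asarray(fit.cov_params())
        bad = (
            not fit.mle_retvals.get("converged", True)
            or np.max(np.abs(params)) > 15
            or not np.all(np.isfinite(cov))
        )
    except Exception:  # perfect separation raises in statsmodels
        bad = True
    if bad:
        method = "firth"
        params, cov = _firth_logit(x, y.astype(float))

    se = np.sqrt(np.diag(cov))
    lo = params - 1.959964 * se
    hi = params + 1.959964 * se
    rows = []
    for i, term in enumerate(["intercept"] + terms):
        rows.append(
            {
                "term": term,
                "estimate": float(params[i]),
                "se": float(se[i]),
                "lower95": float(lo[i]),
                "upper95": float(hi[i]),
                "supported": bool(term != "intercept" and (lo[i] > 0 or hi[i] < 0)),
                "method": method,
            }
        )
    return pd.DataFrame(rows)
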