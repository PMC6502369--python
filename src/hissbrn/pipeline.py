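"""End-to-end orchestration of the nest-defence analysis pipeline.

Stages: simulate -> random regression -> repeatability + permutation test
-> multivariate covariance partition -> path-model comparison (including
the preliminary nest-success regression) -> report.  Each stage reads its
inputs from files and writes its outputs to files, so any stage can be
re-run in isolation; a manifest of SHA-256 content hashes makes
end-to-end determinism checkable (identical config and seeds give
identical hashes).

Configuration is a YAML document with one section per stage.  A master
``seed`` is required; per-stage seeds are derived from it deterministically
unless a stage declares its own.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .brn import MCMCOptions, ModelSpec, fit_random_regression, extract_female_effects
from .design import build_design
from .multivariate import FIXED_RESID_DEFAULT, fit_multivariate, id_correlations
from .paths import PathModel, compare_models, default_models, nest_success_stage
from .repeatability import (
    adjusted_repeatability,
    permutation_test,
    stage_repeatability,
)
from .simulate import (
    SCENARIOS,
    CausalScenario,
    CountCalibration,
    ReactionNormParams,
    couple_intercepts,
    simulate_brn,
    simulate_reproduction,
)

log = logging.getLogger("hissbrn")

STOCHASTIC_STAGES = ("simulate", "brn", "permutation", "multivariate")
ALL_STAGES = ("simulate", "brn", "permutation", "multivariate", "path", "report")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


DEFAULT_CONFIG: dict = {
    "seed": None,
    "simulate": {
        "n_females": 104,
        "pattern": "paper",
        "scenario": "model3_strong",
        "n_success": None,
        "couple_intercepts": True,
        "params": {},
    },
    "brn": {"n_iter": 13_000, "burn_in": 3_000, "thin": 10},
    "permutation": {
        "component": "var_intercept",
        "n_perm": 100,
        "n_iter": 3_000,
        "burn_in": 500,
        "thin": 5,
    },
    "multivariate": {
        "n_iter": 6_000,
        "burn_in": 1_000,
        "thin": 10,
        "fixed_resid": FIXED_RESID_DEFAULT,
    },
    "path": {"models": "default", "aggregate": "mean_matrix"},
    "report": {},
}


@dataclass
class PipelineConfig:
    """Validated configuration with materialized per-stage seeds."""

    data: dict

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = copy.deepcopy(DEFAULT_CONFIG)
        for key, val in (raw or {}).items():
            if key == "seed":
                cfg["seed"] = val
            elif key in cfg and isinstance(val, dict):
                cfg[key].update(val)
            else:
                raise ConfigError(f"unknown config section {key!r}")
        master = cfg.get("seed")
        missing = [
            s for s in STOCHASTIC_STAGES if cfg[s].get("seed") is None
        ]
        if master is None and missing:
            raise ConfigError(
                f"no master seed and stages {missing} lack explicit seeds"
            )
        if master is not None:
            children = np.random.SeedSequence(int(master)).spawn(
                len(STOCHASTIC_STAGES)
            )
            for stage, child in zip(STOCHASTIC_STAGES, children):
                if cfg[stage].get("seed") is None:
                    cfg[stage]["seed"] = int(child.generate_state(1)[0] % 2**31)
        return cls(data=cfg)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=True)

    def __getitem__(self, key: str) -> dict:
        return self.data[key]


def _mcmc_from(section: dict) -> MCMCOptions:
    return MCMCOptions(
        n_iter=int(section.get("n_iter", 13_000)),
        burn_in=int(section.get("burn_in", 3_000)),
        thin=int(section.get("thin", 10)),
    )


def _scenario_from(section: dict) -> CausalScenario:
    name = section.get("scenario", "independence")
    if isinstance(name, dict):
        edges = {
            tuple(k.split(" -> ")): float(v) for k, v in name.items()
        }
        base = CausalScenario(edges=edges)
    elif name in SCENARIOS:
        base = SCENARIOS[name]
    else:
        raise ConfigError(f"unknown scenario {name!r}")
    return CausalScenario(
        edges=base.edges,
        success_prob=float(section.get("success_prob", base.success_prob)),
        n_success=section.get("n_success"),
        discretize_fledglings=bool(section.get("discretize_fledglings", False)),
    )


def _models_from(section: dict) -> list[PathModel]:
    spec = section.get("models", "default")
    if spec == "default":
        return default_models()
    models = []
    for name, edge_strings in spec.items():
        edges = tuple(
            tuple(part.strip() for part in e.split("->")) for e in edge_strings
        )
        models.append(PathModel(name, edges))
    return models


# --------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    sec = cfg["simulate"]
    params = ReactionNormParams(**sec.get("params", {}))
    design = build_design(
        int(sec["n_females"]), sec.get("pattern", "paper"), seed=sec["seed"]
    )
    scenario = _scenario_from(sec)
    seeds = np.random.SeedSequence(sec["seed"]).spawn(2)
    repro = simulate_reproduction(
        scenario,
        design.females,
        seed=int(seeds[0].generate_state(1)[0] % 2**31),
    )
    dev = couple_intercepts(repro, params) if sec.get("couple_intercepts") else None
    trials = simulate_brn(
        design,
        params,
        seed=int(seeds[1].generate_state(1)[0] % 2**31),
        intercept_dev=dev,
    )
    hio.write_trials(trials, out / "trials.csv")
    hio.write_females(repro, out / "females.csv")


def stage_brn(cfg: PipelineConfig, out: Path) -> None:
    sec = cfg["brn"]
    trials = hio.read_trials(out / "trials.csv")
    post = fit_random_regression(
        trials, mcmc=_mcmc_from(sec), seed=int(sec["seed"])
    )
    post.draws.to_csv(out / "brn_posterior.csv", index=False)
    post.summary().to_csv(out / "brn_summary.csv", index=False)
    extract_female_effects(post).frame.to_csv(
        out / "female_effects.csv", index=False
    )

    rows = [adjusted_repeatability(post)]
    seeds = np.random.SeedSequence(int(sec["seed"])).spawn(2)
    for i, stage in enumerate(("incubation", "nestling")):
        rows.append(
            stage_repeatability(
                trials,
                stage,
                mcmc=_mcmc_from(sec),
                seed=int(seeds[i].generate_state(1)[0] % 2**31),
            )
        )
    pd.DataFrame(
        [
            {"scope": r.scope, "r": r.r, "lower95": r.lower95, "upper95": r.upper95}
            for r in rows
        ]
    ).to_csv(out / "repeatability.csv", index=False)


def stage_permutation(cfg: PipelineConfig, out: Path) -> None:
    sec = cfg["permutation"]
    trials = hio.read_trials(out / "trials.csv")
    result = permutation_test(
        trials,
        component=sec.get("component", "var_intercept"),
        n_perm=int(sec.get("n_perm", 100)),
        seed=int(sec["seed"]),
        perm_mcmc=_mcmc_from(sec),
        mcmc=_mcmc_from(cfg["brn"]),
    )
    pd.DataFrame(
        [
            {
                "component": result.component,
                "observed": result.observed,
                "p": result.p,
                "p_label": result.p_label,
                "n_perm": result.n_perm,
            }
        ]
    ).to_csv(out / "permutation.csv", index=False)
    pd.DataFrame(
        {
            "perm_index": np.arange(result.n_effective),
            "null_mean": result.null_means,
        }
    ).to_csv(out / "permutation_null.csv", index=False)


def stage_multivariate(cfg: PipelineConfig, out: Path) -> None:
    sec = cfg["multivariate"]
    trials = hio.read_trials(out / "trials.csv")
    females = hio.read_females(out / "females.csv")
    part = fit_multivariate(
        trials,
        females,
        mcmc=_mcmc_from(sec),
        seed=int(sec["seed"]),
        fixed_resid=float(sec.get("fixed_resid", FIXED_RESID_DEFAULT)),
    )
    hio.write_id_samples_long(
        part.id_samples, part.trait_order, out / "id_samples.csv"
    )
    part.correlation_summary().to_csv(out / "id_summary.csv", index=False)
    (out / "mv_meta.json").write_text(
        json.dumps({"n_females": part.n_females, "fixed_resid": part.fixed_resid})
    )


def stage_path(cfg: PipelineConfig, out: Path) -> None:
    from .traits import TRAIT_ORDER

    sec = cfg["path"]
    id_samples = hio.read_id_samples_long(out / "id_samples.csv", TRAIT_ORDER)
    meta = json.loads((out / "mv_meta.json").read_text())
    n_obs = int(sec.get("n_obs") or meta["n_females"])
    corr = id_correlations(id_samples)
    comparison = compare_models(
        _models_from(sec), corr, n_obs,
        aggregate=sec.get("aggregate", "mean_matrix"),
    )
    comparison.table.to_csv(out / "model_comparison.csv", index=False)
    coef_frames = []
    for name, fit in comparison.fits.items():
        if fit.coefficients.empty:
            continue
        frame = fit.coefficients.copy()
        frame.insert(0, "model", name)
        coef_frames.append(frame)
    columns = ["model", "edge", "mean", "lower95", "upper95", "supported"]
    coefs = (
        pd.concat(coef_frames, ignore_index=True)
        if coef_frames
        else pd.DataFrame(columns=columns)
    )
    coefs.to_csv(out / "path_coefficients.csv", index=False)

    # preliminary nest-success regression on all females
    females = hio.read_females(out / "females.csv")
    effects = pd.read_csv(out / "female_effects.csv")
    try:
        nest_success_stage(females, effects).to_csv(
            out / "nest_success.csv", index=False
        )
    except ValueError as exc:
        log.warning("nest-success stage skipped: %s", exc)


def stage_report(cfg: PipelineConfig, out: Path) -> None:
    render_report(out)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "brn": stage_brn,
    "permutation": stage_permutation,
    "multivariate": stage_multivariate,
    "path": stage_path,
    "report": stage_report,
}

_ARTIFACTS = [
    "trials.csv",
    "females.csv",
    "brn_posterior.csv",
    "brn_summary.csv",
    "female_effects.csv",
    "repeatability.csv",
    "permutation.csv",
    "permutation_null.csv",
    "id_samples.csv",
    "id_summary.csv",
    "mv_meta.json",
    "model_comparison.csv",
    "path_coefficients.csv",
    "nest_success.csv",
    "report.md",
    "reaction_norm_data.csv",
]


def run_stage(name: str, cfg: PipelineConfig, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if name not in _STAGE_FUNCS:
        raise ConfigError(f"unknown stage {name!r}")
    t0 = time.time()
    log.info("stage %s: starting", name)
    try:
        _STAGE_FUNCS[name](cfg, out)
    except Exception:
        log.error("stage %s: failed", name)
        raise
    log.info("stage %s: done in %.1f s", name, time.time() - t0)


def run_all(cfg: PipelineConfig, out_dir: str | Path) -> dict[str, str]:
    """Run every stage and return the artifact manifest (path -> SHA-256)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ALL_STAGES:
        run_stage(name, cfg, out)
    manifest = {}
    for rel in _ARTIFACTS:
        path = out / rel
        if path.exists():
            manifest[rel] = hashlib.sha256(path.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# --------------------------------------------------------------------------
# report


def _read_or_none(path: Path) -> pd.DataFrame | None:
    return pd.read_csv(path) if path.exists() else None


def _md_table(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
    for _, row in df.iterrows():
        cells = [
            f"{v:.4g}" if isinstance(v, float) else str(v) for v in row.tolist()
        ]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def render_report(out_dir: str | Path) -> Path:
    """Render the summary report and reaction-norm figure from artifacts.

    Missing artifacts are listed in the report rather than aborting.
    The figure's underlying line data are also written as CSV so the
    rendered content is byte-reproducible.
    """
    out = Path(out_dir)
    sections: list[str] = ["# Nest-defence reaction-norm pipeline report", ""]
    missing: list[str] = []

    brn = _read_or_none(out / "brn_summary.csv")
    perm = _read_or_none(out / "permutation.csv")
    if brn is not None:
        table = brn.copy()
        table["permutation_p"] = ""
        if perm is not None and len(perm):
            mask = table["parameter"] == perm["component"].iloc[0]
            table.loc[mask, "permutation_p"] = perm["p_label"].iloc[0]
        elif perm is None:
            missing.append("permutation.csv")
        sections += ["## Sources of variation in hissing behaviour", ""]
        sections += [_md_table(table), ""]
    else:
        missing.append("brn_summary.csv")

    rep = _read_or_none(out / "repeatability.csv")
    if rep is not None:
        sections += ["## Repeatability", "", _md_table(rep), ""]
    else:
        missing.append("repeatability.csv")

    comp = _read_or_none(out / "model_comparison.csv")
    if comp is not None:
        sections += ["## Path-model comparison", "", _md_table(comp), ""]
    else:
        missing.append("model_comparison.csv")

    coef = _read_or_none(out / "path_coefficients.csv")
    if coef is not None and comp is not None and len(comp):
        best = comp.sort_values("mean_aic")["model"].iloc[0]
        sections += [
            f"## Path coefficients (best model: {best})",
            "",
            _md_table(coef[coef["model"] == best].drop(columns=["model"])),
            "",
        ]

    ns = _read_or_none(out / "nest_success.csv")
    if ns is not None:
        sections += ["## Preliminary nest-success regression", "", _md_table(ns), ""]

    fig_path = _render_reaction_norms(out, brn)
    if fig_path is not None:
        sections += ["## Reaction norms", "", f"![reaction norms]({fig_path.name})", ""]
    else:
        missing.append("female_effects.csv")

    if missing:
        sections += ["## Missing artifacts", ""]
        sections += [f"- {m}" for m in missing]
        sections.append("")

    report = out / "report.md"
    report.write_text("\n".join(sections))
    return report


def _render_reaction_norms(out: Path, brn: pd.DataFrame | None) -> Path | None:
    effects = _read_or_none(out / "female_effects.csv")
    if effects is None or brn is None:
        return None
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    beta = dict(zip(brn["parameter"], brn["mean"]))
    b0 = beta.get("beta_intercept", 0.0)
    b_day = beta.get("beta_day", 0.0)
    grid = np.linspace(-10, 5, 16)

    data = {"day_centred": grid}
    fig, ax = plt.subplots(figsize=(6, 4))
    for _, row in effects.iterrows():
        line = (b0 + row["intercept_dev"]) + (b_day + row["slope_dev"]) * grid
        data[str(row["female_id"])] = line
        ax.plot(grid, line, color="0.7", lw=0.6)
    pop = b0 + b_day * grid
    data["population"] = pop
    ax.plot(grid, pop, color="black", lw=2.5)
    ax.set_xlabel("Day in nesting cycle (hatching = 0)")
    ax.set_ylabel("Hissing calls (standardized)")
    fig.tight_layout()
    fig.savefig(out / "reaction_norm.png", dpi=120)
    plt.close(fig)

    pd.DataFrame(data).to_csv(out / "reaction_norm_data.csv", index=False)
    return out / "reaction_norm.png"
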