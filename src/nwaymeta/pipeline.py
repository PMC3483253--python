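"""Config-driven end-to-end pipeline: design -> simulate -> fit -> report.

A :class:`RunConfig` (parsed from YAML or JSON) describes the design, the
dynamic system, the convergence controls and the metamodel settings.
:func:`run_pipeline` executes the requested stages in order and writes every
intermediate artifact (design CSV, convergence log, tensor container, R^2 and
sensitivity reports) plus a manifest recording the config hash and seeds, so
that a run is exactly reproducible from its output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as design_mod
from . import dynamics as dyn
from .hcplsr import HCConfig, fit_hcplsr_classical, fit_hcplsr_inverse, predict, r2_scores
from .sensitivity import benchmark_2way, npls_sensitivity, regional_sensitivities
from .tensorio import save_table, save_tensor

__all__ = ["RunConfig", "parse_config", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or malformed run configuration."""


@dataclass
class RunConfig:
    """Validated pipeline configuration with defaults filled in."""

    # design
    factors: list[design_mod.FactorSpec] = field(default_factory=design_mod.goodwin_demo_factors)
    run_exponent: int | None = None          # defaults to total replacement bits
    mc_runs: int = 0                          # optional Monte-Carlo test design
    # dynamics
    system: str = "goodwin"                   # built-in id; custom systems plug in via the API
    n_grid: int = 200
    period_tol: float = 0.001
    synchrony_tol: float = 0.0001
    max_time: float = 4000.0
    # metamodel
    directions: list[str] = field(default_factory=lambda: ["inverse", "classical"])
    n_clusters: int | str = 1                 # int or "auto"
    cluster_range: list[int] = field(default_factory=lambda: [1, 6])
    classifier: str = "qda"
    prediction_mode: str = "most_probable"
    fuzzifier: float = 2.0
    cv_folds: int = 10
    min_cv_variance: float = 0.01
    min_cluster_size: int = 10
    a_max: int = 10
    scheme: str = "columnwise"
    # bookkeeping
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: ["design", "simulate", "fit-inverse",
                                                       "fit-classical", "sensitivity"])
    output_dir: str = "nwaymeta_run"

    def hc_config(self, n_clusters: int) -> HCConfig:
        return HCConfig(
            n_clusters=n_clusters, classifier=self.classifier,
            fuzzifier=self.fuzzifier, min_cluster_size=self.min_cluster_size,
            cv_folds=self.cv_folds, min_cv_variance=self.min_cv_variance,
            a_max=self.a_max, prediction_mode=self.prediction_mode,
            scheme=self.scheme, seed=self.seed,
        )

    def canonical(self) -> dict:
        payload = dataclasses.asdict(self)
        payload["factors"] = [dataclasses.asdict(f) for f in self.factors]
        return payload

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.canonical(), sort_keys=True).encode()
        ).hexdigest()[:16]


_KNOWN_KEYS = {f.name for f in dataclasses.fields(RunConfig)}
_NUMERIC = {
    "run_exponent": int, "mc_runs": int, "n_grid": int, "cv_folds": int,
    "min_cluster_size": int, "a_max": int, "seed": int,
    "period_tol": float, "synchrony_tol": float, "max_time": float,
    "fuzzifier": float, "min_cv_variance": float,
}


def parse_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML (or JSON) run configuration.

    Unknown keys and malformed values raise :class:`ConfigError` naming the
    key; missing keys receive the standard defaults (fuzzifier 2,
    10-fold CV, 1% factor rule, min cluster size 10, 200-point grid,
    period tolerance 0.001, synchrony tolerance 0.0001).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key {sorted(unknown)[0]!r}")
    if "factors" in raw:
        try:
            raw["factors"] = [design_mod.FactorSpec(**f) for f in raw["factors"]]
        except (TypeError, ValueError) as e:
            raise ConfigError(f"invalid factors entry: {e}") from e
    for key, cast in _NUMERIC.items():
        if key in raw and raw[key] is not None:
            try:
                raw[key] = cast(raw[key])
            except (TypeError, ValueError) as e:
                raise ConfigError(f"malformed numeric value for key {key!r}") from e
    if "n_clusters" in raw and raw["n_clusters"] != "auto":
        try:
            raw["n_clusters"] = int(raw["n_clusters"])
        except (TypeError, ValueError) as e:
            raise ConfigError("malformed numeric value for key 'n_clusters'") from e
    try:
        return RunConfig(**raw)
    except TypeError as e:
        raise ConfigError(str(e)) from e


def _system_for(config: RunConfig) -> dyn.ODESystem:
    if config.system == "goodwin":
        return dyn.goodwin_demo_system()
    raise ConfigError(
        f"dynamics: adapter not found for system {config.system!r}; "
        "plug custom ODESystem objects in via the Python API"
    )


def run_pipeline(config: RunConfig, log=print) -> Path:
    """Execute the configured stages, writing artifacts and a manifest.

    Returns the output directory.  Any stage failure raises; artifacts
    written so far are retained together with a status entry in the manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash, "seed": config.seed,
                      "stages": {}, "artifacts": []}
    state: dict = {}

    def _record(stage: str, started: float, artifacts: list[str]) -> None:
        manifest["stages"][stage] = {"status": "ok", "wall_time_s": round(time.time() - started, 3)}
        manifest["artifacts"] += artifacts
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        log(f"[{stage}] done in {manifest['stages'][stage]['wall_time_s']}s")

    try:
        for stage in config.stages:
            started = time.time()
            if stage == "design":
                bits = sum(f.bits for f in config.factors)
                k = config.run_exponent or bits
                spec = design_mod.OMBRSpec(list(config.factors), k)
                table = design_mod.make_ombr_design(spec, optimizer_seed=config.seed)
                save_table(table, out / "design.csv")
                design_mod.save_ombr_spec(spec, out / "ombr_spec.json")
                state["design"] = table
                artifacts = ["design.csv", "ombr_spec.json"]
                if config.mc_runs:
                    mc = design_mod.make_mc_design(config.factors, config.mc_runs, config.seed)
                    save_table(mc, out / "mc_design.csv")
                    state["mc_design"] = mc
                    artifacts.append("mc_design.csv")
                _record(stage, started, artifacts)
            elif stage == "simulate":
                controls = dyn.ConvergenceControls(
                    period_tol=config.period_tol, synchrony_tol=config.synchrony_tol,
                    n_grid=config.n_grid, max_time=config.max_time,
                )
                tensor, kept, conv_log = dyn.build_tensor(state["design"], _system_for(config), controls)
                save_tensor(tensor, out / "tensor.nc")
                save_table(kept, out / "design_converged.csv")
                conv_log.to_csv(out / "convergence_log.csv", index=False)
                state["tensor"], state["design"] = tensor, kept
                _record(stage, started, ["tensor.nc", "design_converged.csv", "convergence_log.csv"])
            elif stage == "fit-inverse":
                n_clusters = config.n_clusters
                if n_clusters == "auto":
                    chosen, curve = fit_auto = _auto_clusters(config, state)
                    curve.to_csv(out / "cluster_sweep.csv", index=False)
                    n_clusters = chosen
                    manifest["chosen_clusters"] = chosen
                model = fit_hcplsr_inverse(state["tensor"], state["design"],
                                           config.hc_config(int(n_clusters)))
                state["inverse"] = model
                y_hat, report = predict(model, state["tensor"])
                r2 = r2_scores(state["design"], y_hat)
                pd.DataFrame({"parameter": state["design"].param_names, "r2": r2}).to_csv(
                    out / "inverse_r2.csv", index=False)
                report.to_csv(out / "inverse_prediction_report.csv", index=False)
                _record(stage, started, ["inverse_r2.csv", "inverse_prediction_report.csv"])
            elif stage == "fit-classical":
                model = fit_hcplsr_classical(state["design"], state["tensor"], state["inverse"])
                state["classical"] = model
                y_hat, report = predict(model, state["design"])
                r2 = r2_scores(state["tensor"], y_hat)
                pd.DataFrame({"variable": state["tensor"].var_names, "r2": r2}).to_csv(
                    out / "classical_r2.csv", index=False)
                _record(stage, started, ["classical_r2.csv"])
            elif stage == "sensitivity":
                mats = regional_sensitivities(state["classical"])
                artifacts = []
                for mat in mats:
                    fname = f"sensitivity_{mat.source.replace(' ', '_')}.csv"
                    mat.to_frame().to_csv(out / fname)
                    artifacts.append(fname)
                _record(stage, started, artifacts)
            elif stage == "benchmark":
                report = benchmark_2way(state["tensor"], state["design"],
                                        config.hc_config(int(config.n_clusters))
                                        if config.n_clusters != "auto"
                                        else config.hc_config(1))
                report.to_csv(out / "benchmark_2way.csv", index=False)
                _record(stage, started, ["benchmark_2way.csv"])
            else:
                raise ConfigError(f"unknown stage {stage!r}")
    except Exception as e:
        manifest["stages"][stage] = {"status": "failed", "error": str(e)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    return out


def _auto_clusters(config: RunConfig, state: dict):
    from .hcplsr import select_n_clusters
    lo, hi = config.cluster_range
    return select_n_clusters(state["tensor"], state["design"],
                             range(int(lo), int(hi) + 1), config.hc_config(1))
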