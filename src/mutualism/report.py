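"""Run configuration, reporting, and CSV/JSON export.

One config = one reproducible run: a model, a parameter set (explicit values
or a named fixture), the analyses to perform, and the numerical settings.
Reports embed the package version and every tolerance used.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import models as M
from . import fixtures as FX
from .dynamics import DynamicsSettings, find_equilibria, nullclines, default_box
from .phase import PhaseSettings, basin_map, separatrix
from .classify import ClassifySettings, classify_dynamics, critical_benefit_strength, sweep

__all__ = ["RunConfig", "ConfigError", "run", "load_config",
           "equilibria_frame", "nullcline_frame", "basin_frame", "report_json"]

ANALYSES = ("equilibria", "nullclines", "basins", "classify", "sweep",
            "critical", "portrait")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class RunConfig:
    model: str
    analyses: tuple[str, ...] = ("classify",)
    params: dict | None = None          # explicit symbol -> value map
    fixture: str | None = None          # or a named fixture regime
    box: tuple[float, float] | None = None
    grid_n: int = 64
    basin_grid_n: int = 61
    nullcline_resolution: int = 401
    t_max: float = 400.0
    seed: int = 0
    sweep_symbol: str | None = None
    sweep_values: tuple[float, ...] = ()
    critical_symbol: str | None = None
    critical_bracket: tuple[float, float] | None = None
    output_dir: str = "."
    strict: bool = False

    _KNOWN = None  # filled below

    def resolve_params(self) -> M.ParameterSet:
        spec = M.get_model(self.model)
        if self.fixture is not None and self.params is not None:
            raise ConfigError("give either explicit params or a fixture, not both")
        if self.fixture is not None:
            return FX.canonical_params(self.model, self.fixture)
        try:
            return M.make_params(spec, **(self.params or {}))
        except M.ParameterError as exc:
            raise ConfigError(str(exc)) from exc


RunConfig._KNOWN = {f.name for f in dataclasses.fields(RunConfig)
                    if not f.name.startswith("_")}


def load_config(source) -> RunConfig:
    """Build a RunConfig from a YAML/JSON file path or a mapping."""
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text())
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(data) - RunConfig._KNOWN
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "model" not in data:
        raise ConfigError("config requires a 'model' key")
    for tup_key in ("analyses", "sweep_values", "critical_bracket", "box"):
        if tup_key in data and data[tup_key] is not None:
            data[tup_key] = tuple(data[tup_key])
    cfg = RunConfig(**data)
    bad = set(cfg.analyses) - set(ANALYSES)
    if bad:
        raise ConfigError(f"unknown analyses: {sorted(bad)}; pick from {ANALYSES}")
    cfg.resolve_params()  # validate before any computation
    return cfg


# ---------------------------------------------------------------------------
# Tabular exports
# ---------------------------------------------------------------------------

def equilibria_frame(model_id, regime, eqs) -> pd.DataFrame:
    rows = [{
        "model": model_id, "regime": regime,
        "N1": e.location[0], "N2": e.location[1],
        "re1": e.eigenvalues[0].real, "im1": e.eigenvalues[0].imag,
        "re2": e.eigenvalues[1].real, "im2": e.eigenvalues[1].imag,
        "type": e.local_type, "class": e.position_class,
    } for e in eqs]
    return pd.DataFrame(rows, columns=["model", "regime", "N1", "N2", "re1",
                                       "im1", "re2", "im2", "type", "class"])


def nullcline_frame(ncs) -> pd.DataFrame:
    rows = []
    for ci, c in enumerate(ncs.curves):
        for vi, (x, y) in enumerate(c.points):
            rows.append({"curve": ci, "species": c.species, "kind": c.kind,
                         "vertex": vi, "N1": x, "N2": y})
    return pd.DataFrame(rows, columns=["curve", "species", "kind", "vertex", "N1", "N2"])


def basin_frame(bm) -> pd.DataFrame:
    xs, ys = bm.x0_grid
    rows = []
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            rows.append({"N1_0": x, "N2_0": y, "label": str(bm.labels[i, j])})
    return pd.DataFrame(rows, columns=["N1_0", "N2_0", "label"])


def report_json(payload: dict) -> str:
    """Stable-key-order JSON with a version field."""
    body = {"version": __version__, **payload}

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, complex):
            return [o.real, o.imag]
        raise TypeError(type(o))

    return json.dumps(body, indent=2, sort_keys=True, default=default)


# ---------------------------------------------------------------------------
# Run driver
# ---------------------------------------------------------------------------

def run(config: RunConfig, write: bool = True) -> dict:
    """Execute the configured analyses; returns the report bundle.

    Deterministic given (config, seed).  When ``write`` is true the report
    JSON, CSV tables and figures land in ``config.output_dir``.
    """
    spec = M.get_model(config.model)
    params = config.resolve_params()
    dyn = DynamicsSettings(grid_n=config.grid_n)
    cls = ClassifySettings(basin_grid_n=config.basin_grid_n, t_max=config.t_max,
                           dynamics=dyn)
    box = tuple(config.box) if config.box else default_box(spec, params)
    if box[1] <= box[0]:
        raise ConfigError("box must have positive extent")

    out: dict = {
        "model": spec.id,
        "params": dict(params.values),
        "provenance": params.provenance,
        "fixture": config.fixture,
        "seed": config.seed,
        "box": list(box),
        "tolerances": {
            "newton_tol": dyn.newton_tol, "dedupe_rel": dyn.dedupe_rel,
            "tol_hyp": dyn.tol_hyp, "grid_n": config.grid_n,
            "basin_grid_n": config.basin_grid_n, "t_max": config.t_max,
        },
    }
    outdir = Path(config.output_dir)
    frames: dict[str, pd.DataFrame] = {}
    figures: list[str] = []

    eqs = None
    if {"equilibria", "basins", "classify", "portrait"} & set(config.analyses):
        eqs = find_equilibria(spec, params, box=box, settings=dyn)
    if "equilibria" in config.analyses:
        out["equilibria"] = [
            {"N1": e.location[0], "N2": e.location[1], "type": e.local_type,
             "class": e.position_class, "residual": e.residual,
             "eigenvalues": [[v.real, v.imag] for v in e.eigenvalues]}
            for e in eqs]
        frames["equilibria"] = equilibria_frame(spec.id, config.fixture or "user", eqs)
    if "nullclines" in config.analyses:
        ncs = nullclines(spec, params, box=box,
                         resolution=config.nullcline_resolution)
        out["nullclines"] = [
            {"species": c.species, "kind": c.kind, "n_points": len(c.points),
             "geometry": list(c.geometry)} for c in ncs.curves]
        frames["nullclines"] = nullcline_frame(ncs)
    if "basins" in config.analyses:
        bm = basin_map(spec, params, box=box, grid_n=config.basin_grid_n,
                       t_max=config.t_max, equilibria=eqs)
        out["basins"] = {"counts": bm.counts, "grid_n": bm.grid_n,
                         "t_max": bm.t_max,
                         "attractors": [dict(a) for a in bm.attractors]}
        frames["basins"] = basin_frame(bm)
    if "classify" in config.analyses:
        rep = classify_dynamics(spec, params, box=box, settings=cls)
        out["classification"] = {
            "outcome_label": rep.outcome_label,
            "threshold_type": rep.threshold_type,
            "coexistence_character": rep.coexistence_character,
            "oscillation": rep.oscillation,
            "low_confidence": rep.low_confidence,
            "evidence": rep.evidence,
        }
    if "sweep" in config.analyses:
        if not config.sweep_symbol:
            raise ConfigError("sweep analysis needs sweep_symbol and sweep_values")
        sr = sweep(spec, params, config.sweep_symbol, config.sweep_values,
                   settings=cls)
        out["sweep"] = {
            "symbol": sr.symbol, "values": list(sr.values),
            "labels": [r.outcome_label for r in sr.reports],
            "change_brackets": [list(b) for b in sr.change_brackets],
        }
        frames["sweep"] = pd.DataFrame({
            "value": sr.values,
            "outcome_label": [r.outcome_label for r in sr.reports],
            "threshold_type": [r.threshold_type for r in sr.reports],
            "oscillation": [r.oscillation for r in sr.reports],
        })
    if "critical" in config.analyses:
        if not (config.critical_symbol and config.critical_bracket):
            raise ConfigError("critical analysis needs critical_symbol and critical_bracket")
        val = critical_benefit_strength(spec, params, config.critical_symbol,
                                        config.critical_bracket)
        out["critical"] = {"symbol": config.critical_symbol,
                           "bracket": list(config.critical_bracket),
                           "value": val}
    if "portrait" in config.analyses:
        from .plotting import render_portrait
        outdir.mkdir(parents=True, exist_ok=True)
        fig_path = outdir / f"portrait_{spec.id}.svg"
        render_portrait(spec, params, box=box, path=fig_path, equilibria=eqs)
        figures.append(str(fig_path))
        out["portrait"] = {"file": str(fig_path)}

    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / f"report_{spec.id}.json").write_text(report_json(out))
        for name, frame in frames.items():
            frame.to_csv(outdir / f"{name}_{spec.id}.csv", index=False)
    out["_figures"] = figures
    if config.strict and out.get("classification", {}).get("low_confidence"):
        raise RuntimeError("low-confidence classification in strict mode")
    return out
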