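"""Scenario files and tabular output writers.

Scenario files are YAML documents that name a built-in generator plus its
arguments and optional overrides; the loader rebuilds the scenario through
the same generator, so an exported file always round-trips losslessly.
Result tables are comma-separated UTF-8 with units in the column headers.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import yaml

from .boxmodel import Scenario, SimulationResult
from .photolysis import UVC_BINS

__all__ = [
    "scenario_spec",
    "spec_to_scenario",
    "write_scenario",
    "read_scenario",
    "write_timeseries",
    "write_flux_table",
    "write_jtable",
]


def scenario_spec(
    generator: str,
    args: dict | None = None,
    overrides: dict | None = None,
) -> dict:
    """Canonical scenario-file dictionary."""
    return {
        "generator": generator,
        "args": dict(sorted((args or {}).items())),
        "overrides": dict(sorted((overrides or {}).items())),
    }


def spec_to_scenario(spec: dict) -> Scenario:
    from . import scenarios as _scen

    gen = spec.get("generator")
    args = spec.get("args") or {}
    builders = {
        "office": _scen.office_validation_scenario,
        "kitchen": _scen.kitchen_bin_scenario,
        "classroom": _scen.classroom_scenario,
    }
    if gen not in builders:
        raise ValueError(f"unknown scenario generator {gen!r}; valid: {sorted(builders)}")
    scn = builders[gen](**args)
    for key, value in (spec.get("overrides") or {}).items():
        if key in ("rtol", "atol", "reporting_interval", "spinup_hours", "analysis_hours"):
            setattr(scn, key, float(value))
        elif key == "solver":
            scn.solver = str(value)
        elif key == "acr":
            scn.environment.acr = float(value)
        elif key == "relative_humidity":
            scn.environment.relative_humidity = float(value)
        else:
            raise KeyError(f"unknown scenario override {key!r}")
    return scn


def write_scenario(spec: dict, path: str | Path) -> None:
    text = yaml.safe_dump(spec, sort_keys=True, default_flow_style=False)
    Path(path).write_text(text, encoding="utf-8")


def read_scenario(path: str | Path) -> tuple[Scenario, dict]:
    spec = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return spec_to_scenario(spec), spec


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_timeseries(result: SimulationResult, path: str | Path) -> None:
    """Concentration time series, one ppb column per species."""
    m = result.scenario.environment.m
    buf = _io.StringIO()
    buf.write("time_s,clock_h," + ",".join(f"{s}_ppb" for s in result.species) + "\n")
    clock = result.clock_hours
    for j in range(result.time.size):
        row = [f"{result.time[j]:.0f}", f"{clock[j]:.4f}"]
        row += [_fmt(result.conc[i, j] / m * 1e9) for i in range(len(result.species))]
        buf.write(",".join(row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_flux_table(result: SimulationResult, path: str | Path) -> None:
    """Per-process O3 flux archive (cm^-3 s^-1) plus the lamp state."""
    keys = list(result.o3_flux)
    buf = _io.StringIO()
    buf.write("time_s," + ",".join(f"{k}_cm3_s" for k in keys) + "\n")
    for j in range(result.time.size):
        row = [f"{result.time[j]:.0f}"] + [_fmt(result.o3_flux[k][j]) for k in keys]
        buf.write(",".join(row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_flux_table(path: str | Path) -> dict[str, np.ndarray]:
    import pandas as pd

    df = pd.read_csv(path)
    out = {"time_s": df["time_s"].to_numpy()}
    for col in df.columns:
        if col.endswith("_cm3_s"):
            out[col[: -len("_cm3_s")]] = df[col].to_numpy()
    return out


def write_jtable(channels, lamp, path: str | Path) -> None:
    """Channel x bin photolysis-coefficient table (s^-1 contributions)."""
    from .photolysis import spectrum_to_bin_fluxes

    fluxes = spectrum_to_bin_fluxes(lamp)
    buf = _io.StringIO()
    labels = [b.label for b in UVC_BINS]
    buf.write("channel," + ",".join(f"{l}_s" for l in labels) + ",total_s\n")
    for ch in channels:
        h = ch.h_per_bin()
        contrib = [h[l] * fluxes[l] for l in labels]
        buf.write(
            ch.name + "," + ",".join(_fmt(v) for v in contrib) + f",{_fmt(sum(contrib))}\n"
        )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
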