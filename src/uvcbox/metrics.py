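"""Diagnostics computed from simulation archives.

The ozone budget diagnostics mirror the standard reporting conventions for
indoor UVC studies: a baseline-differenced total ozone production rate (PR,
mg h^-1, averaged over a stated clock window, counting in-room
photochemical production plus positive net infiltration from outdoors), a
total first-order loss rate (TLR, h^-1, evaluated at the peak ozone
concentration during lamp operation), the percentage partitioning of ozone
loss between surfaces, photolysis, NOx, VOCs and ventilation, and the
change in secondary-product creation potential (delta-SPCP, ppb, the
baseline-subtracted window-averaged sum of ozone and the listed secondary
oxidation products).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxmodel import SimulationResult
from .mechanism import rate_coefficient

__all__ = [
    "OzoneBudget",
    "SPCPReport",
    "ozone_production_rate",
    "ozone_total_loss_rate",
    "delta_spcp_mod",
    "oh_reactivity",
    "species_budget",
    "o3_closure_rms",
    "o3_rise_rate",
    "o3_decay_rate",
]

O3_MOLAR_MASS = 48.0  # g mol^-1

_LOSS_KEYS = ("loss_surface", "loss_photolysis", "loss_nox", "loss_voc")
_SHARE_NAMES = {
    "loss_surface": "surfaces",
    "loss_photolysis": "photolysis",
    "loss_nox": "nox",
    "loss_voc": "vocs",
    "vent_out": "ventilation",
}


@dataclass
class OzoneBudget:
    pr_mg_h: float
    tlr_per_h: float
    loss_shares_percent: dict[str, float] = field(default_factory=dict)


@dataclass
class SPCPReport:
    total_ppb: float
    contributions_ppb: dict[str, float] = field(default_factory=dict)


def _check_grids(result: SimulationResult, baseline: SimulationResult) -> None:
    if result.time.shape != baseline.time.shape or not np.allclose(
        result.time, baseline.time
    ):
        raise ValueError("result and baseline are on different time grids")


def _source_flux(result: SimulationResult) -> np.ndarray:
    """Total O3 source flux (cm^-3 s^-1): photochemistry + positive net inflow."""
    f = result.o3_flux
    net_in = np.clip(f["vent_in"] - f["vent_out"], 0.0, None)
    return f["production"] + net_in


def _flux_to_mg_per_h(flux_cm3_s: float, volume_m3: float) -> float:
    """Convert a volumetric molecule flux to a room-integrated mass rate."""
    from .constants import AVOGADRO

    molecules_per_h = flux_cm3_s * 3600.0 * volume_m3 * 1e6
    return molecules_per_h / AVOGADRO * O3_MOLAR_MASS * 1e3


def ozone_production_rate(
    result: SimulationResult,
    baseline: SimulationResult,
    window: tuple[float, float] = (9.0, 12.0),
    day: int = 1,
) -> float:
    """Baseline-differenced total O3 production rate (mg h^-1).

    Time-average over the clock window of the difference in total source
    flux (in-room photochemical production plus positive net ventilation
    inflow), converted to a mass rate with the room volume.
    """
    _check_grids(result, baseline)
    mask = result.window(*window, day=day)
    if not mask.any():
        raise ValueError("averaging window is outside the simulated range")
    delta = float(np.mean(_source_flux(result)[mask] - _source_flux(baseline)[mask]))
    return _flux_to_mg_per_h(delta, result.scenario.volume)


def ozone_total_loss_rate(result: SimulationResult) -> tuple[float, dict[str, float]]:
    """TLR (h^-1) at peak O3 and the percent partitioning of the loss routes.

    The peak is taken over lamp-on samples when the scenario has a lamp
    (TLR characterizes lamp operation), otherwise over the analysis window.
    Ventilation loss is the gross outflow lambda_r * [O3].
    """
    f = result.o3_flux
    o3 = result.conc[result.index("O3")]
    if np.all(o3 <= 0):
        raise ValueError("ozone is identically zero; TLR undefined")
    analysis = result.time >= result.scenario.spinup_hours * 3600.0
    sel = analysis & (f["lamp_on"] > 0) if np.any(f["lamp_on"] > 0) else analysis
    idx_candidates = np.flatnonzero(sel)
    i_peak = idx_candidates[np.argmax(o3[idx_candidates])]

    losses = {key: f[key][i_peak] for key in _LOSS_KEYS}
    losses["vent_out"] = f["vent_out"][i_peak]
    total = sum(losses.values())
    tlr = total / o3[i_peak] * 3600.0
    shares = {
        _SHARE_NAMES[k]: (v / total * 100.0 if total > 0 else 0.0)
        for k, v in losses.items()
    }
    return tlr, shares


def delta_spcp_mod(
    result: SimulationResult,
    baseline: SimulationResult,
    window: tuple[float, float] = (9.0, 15.0),
    day: int = 1,
) -> SPCPReport:
    """Baseline-subtracted secondary-product creation potential (ppb).

    Window-averaged sum over ozone, the lumped organic nitrate and PAN
    species, and the listed carbonyls of the concentration difference
    between the lamp simulation and its lamp-off baseline.
    """
    _check_grids(result, baseline)
    mask = result.window(*window, day=day)
    members = result.scenario.mechanism.spcp_names()
    missing = [s for s in members if s not in result.species]
    if missing:
        raise KeyError(f"SPCP species missing from the state vector: {missing}")
    contributions = {}
    for s in members:
        contributions[s] = float(np.mean(result.ppb(s)[mask] - baseline.ppb(s)[mask]))
    return SPCPReport(
        total_ppb=float(sum(contributions.values())), contributions_ppb=contributions
    )


def oh_reactivity(result: SimulationResult, sample_index: int) -> float:
    """OH reactivity (s^-1) at one archived sample: sum of k_OH+X * [X].

    Every mechanism reaction with OH as a reactant contributes, with the
    co-reactant concentration taken from the archive (fixed co-reactants
    from the environment); OH itself is excluded.
    """
    scn = result.scenario
    env = scn.environment
    fixed = env.fixed_concentrations()
    total = 0.0
    for rxn in scn.mechanism.reactions:
        if "OH" not in rxn.reactants or rxn.is_photolysis():
            continue
        partners = [r for r in rxn.reactants if r != "OH"]
        if len(partners) != len(rxn.reactants) - 1:
            continue  # OH + OH (not present, but guard)
        k = rate_coefficient(rxn, env)
        conc = 1.0
        for p in partners:
            conc *= fixed[p] if p in fixed else result.conc[result.index(p), sample_index]
        total += k * conc
    return total


@dataclass
class SpeciesBudget:
    """Per-reaction signed contributions to one species (ppb h^-1)."""

    species: str
    labels: list[str]
    series: np.ndarray  # reactions x time within window
    time: np.ndarray

    @property
    def net(self) -> np.ndarray:
        return self.series.sum(axis=0)

    def ranked(self) -> list[tuple[str, float]]:
        integral = np.abs(np.trapezoid(self.series, self.time / 3600.0, axis=1))
        order = np.argsort(integral)[::-1]
        means = self.series.mean(axis=1)
        return [(self.labels[i], float(means[i])) for i in order]


def species_budget(
    result: SimulationResult,
    species: str,
    window: tuple[float, float] = (0.0, 24.0),
    day: int = 1,
) -> SpeciesBudget:
    """Formation/loss budget of a species from the per-reaction archive."""
    i_sp = result.index(species)  # raises on unknown species
    mech = result.scenario.mechanism
    mask = result.window(*window, day=day)
    m_air = result.scenario.environment.m
    to_ppb_h = 3600.0 / m_air * 1e9

    labels, rows = [], []
    for r_idx, rxn in enumerate(mech.reactions):
        net = sum(y for s, y in rxn.products if s == species) - rxn.reactants.count(
            species
        )
        if net == 0:
            continue
        labels.append(rxn.label())
        rows.append(net * result.reaction_rates[r_idx, mask] * to_ppb_h)
    series = np.array(rows) if rows else np.zeros((0, int(mask.sum())))
    return SpeciesBudget(species=species, labels=labels, series=series, time=result.time[mask])


def o3_closure_rms(result: SimulationResult) -> float:
    """Relative RMS mismatch between d[O3]/dt and the process-flux archive.

    The conservation audit: the state-archive tendency should equal
    (sources - losses) from the process archive.  Returns the RMS of the
    difference normalized by the RMS of the gross flux magnitude.
    """
    f = result.o3_flux
    o3 = result.conc[result.index("O3")]
    dcdt = np.gradient(o3, result.time)
    net = (
        f["production"]
        + f["vent_in"]
        - f["vent_out"]
        - sum(f[k] for k in _LOSS_KEYS)
    )
    # exclude samples straddling schedule discontinuities (the finite
    # difference is invalid across them) and the initial mixing transient
    from .boxmodel import _segment_boundaries

    interior = np.ones_like(o3, dtype=bool)
    for tb in _segment_boundaries(result.scenario):
        near = np.abs(result.time - tb) <= 2.5 * result.scenario.reporting_interval
        interior[near] = False
    interior[:30] = interior[-2:] = False
    scale = np.sqrt(np.mean((np.abs(net[interior]) + f["vent_in"][interior] + 1.0) ** 2))
    return float(np.sqrt(np.mean((dcdt[interior] - net[interior]) ** 2)) / scale)


def o3_rise_rate(
    result: SimulationResult,
    start_clock: float = 21.0,
    end_clock: float = 22.0,
    day: int = 1,
) -> float:
    """Mean O3 rise rate (ppb h^-1) between two clock times of a day."""
    i0 = result.at_clock(start_clock, day=day)
    i1 = result.at_clock(end_clock, day=day)
    dt_h = (result.time[i1] - result.time[i0]) / 3600.0
    o3 = result.ppb("O3")
    return float((o3[i1] - o3[i0]) / dt_h)


def o3_decay_rate(
    result: SimulationResult,
    off_clock: float = 18.0,
    duration_h: float = 1.0,
    day: int = 1,
) -> float:
    """First-order O3 decay rate (h^-1) fitted after a lamp switch-off.

    Log-linear least squares on the raw concentration over the first
    ``duration_h`` hours of the off phase, the standard way decay constants
    are extracted from measured time series.
    """
    i0 = result.at_clock(off_clock, day=day)
    i1 = result.at_clock(off_clock + duration_h, day=day)
    t_h = result.time[i0 : i1 + 1] / 3600.0
    o3 = result.ppb("O3")[i0 : i1 + 1]
    if np.any(o3 <= 0):
        raise ValueError("ozone reached zero during the fit window")
    slope, _ = np.polyfit(t_h, np.log(o3), 1)
    return float(-slope)
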