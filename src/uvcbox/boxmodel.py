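"""Assembly and integration of the indoor mass-balance ODE system.

For each integrated species i,

    dC_i/dt = sum_j R_ij  +  lambda_r (C_i,out - C_i)  -  vd_i (A/V) C_i  +  k_t

i.e. gas-phase chemistry, ventilation exchange with the outdoor profile,
material-resolved surface deposition, and indoor emissions (breath, primary
material emissions, and at-surface ozonolysis products, which are coupled to
the instantaneous ozone concentration).

Time is kept as seconds from the start of a spin-up day; clock time is
(t/3600) mod 24 h.  The lamp is disabled during spin-up so the analysis
window starts from a chemically relaxed state.  Integration is piecewise
over the intervals on which every schedule (lamp, occupancy, emissions) is
constant, with a stiff-capable adaptive solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import constants as c
from .environment import Environment
from .mechanism import Mechanism, build_reduced_mechanism
from .photolysis import LampSpectrum, PhotolysisChannel, photolysis_coefficients
from .surfaces import Occupancy, SurfaceMaterial, breath_emission_terms, deposition_rate
from .xsections import default_channels

__all__ = [
    "Environment",
    "OutdoorProfile",
    "EmissionSchedule",
    "Scenario",
    "SimulationResult",
    "assemble_rhs",
    "integrate",
]


@dataclass
class OutdoorProfile:
    """Outdoor mixing ratios (ppb) as periodic functions of clock time (h)."""

    profiles: dict[str, Callable[[float], float]] = field(default_factory=dict)

    @classmethod
    def constant(cls, values_ppb: dict[str, float]) -> "OutdoorProfile":
        return cls({k: (lambda t, v=v: v) for k, v in values_ppb.items()})

    def species(self) -> list[str]:
        return list(self.profiles)

    def ppb(self, species: str, clock_hours: float) -> float:
        fn = self.profiles.get(species)
        return 0.0 if fn is None else max(0.0, fn(clock_hours % 24.0))


@dataclass
class EmissionSchedule:
    """Primary indoor volumetric sources (molecules cm^-3 s^-1).

    Each item is (species, rate, intervals); ``intervals`` is a list of daily
    clock windows or None for an always-on source.
    """

    items: list[tuple[str, float, list[tuple[float, float]] | None]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        if any(rate < 0 for _, rate, _ in self.items):
            raise ValueError("emission rates must be non-negative")

    def rates_at(self, clock_hours: float) -> dict[str, float]:
        h = clock_hours % 24.0
        out: dict[str, float] = {}
        for species, rate, intervals in self.items:
            if intervals is None or any(lo <= h < hi for lo, hi in intervals):
                out[species] = out.get(species, 0.0) + rate
        return out

    def switch_times(self) -> list[float]:
        times = set()
        for _, _, intervals in self.items:
            if intervals:
                for lo, hi in intervals:
                    times.add(lo % 24.0)
                    times.add(hi % 24.0)
        return sorted(times)


@dataclass
class Scenario:
    """Everything needed to integrate one room: chemistry, room, schedules."""

    name: str = "scenario"
    mechanism: Mechanism = field(default_factory=build_reduced_mechanism)
    environment: Environment = field(default_factory=Environment)
    volume: float = 30.0  # m^3
    materials: list[SurfaceMaterial] = field(default_factory=list)
    occupancy: Occupancy = field(default_factory=Occupancy)
    lamp: LampSpectrum | None = None
    channels: list[PhotolysisChannel] = field(default_factory=default_channels)
    outdoor: OutdoorProfile = field(default_factory=OutdoorProfile)
    emissions: EmissionSchedule = field(default_factory=EmissionSchedule)
    initial_ppb: dict[str, float] = field(default_factory=dict)
    spinup_hours: float = 24.0
    analysis_hours: float = 24.0
    reporting_interval: float = 60.0  # s
    rtol: float = 1e-6
    # 1e-3 cm^-3 resolves the microsecond-lifetime radicals (O3P, O1D, H),
    # whose quasi-steady abundances sit far below 1 cm^-3; a looser absolute
    # tolerance lets the stiff solver accept spurious excursions in them that
    # leak into the ozone budget.
    atol: float = 1e-3  # cm^-3
    solver: str = "BDF"

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("room volume must be positive")
        if self.spinup_hours < 24.0:
            raise ValueError("spin-up must be at least 24 h")
        names = set(self.mechanism.species)
        for source in (self.initial_ppb, dict.fromkeys(self.outdoor.species(), 0.0)):
            for s in source:
                if s not in names:
                    raise KeyError(f"scenario references unknown species {s!r}")

    @property
    def total_hours(self) -> float:
        return self.spinup_hours + self.analysis_hours

    def all_materials(self, occupants_present: bool) -> list[SurfaceMaterial]:
        mats = list(self.materials)
        if occupants_present:
            mats += self.occupancy.skin_materials()
        return mats


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------


class _RHS:
    """Precomputed tendency evaluator for one (lamp, occupancy) state."""

    def __init__(self, scn: Scenario):
        mech = scn.mechanism
        self.mech = mech
        self.comp = mech.compiled()
        self.names = mech.integrated_names
        self.n = len(self.names)
        self.env = scn.environment
        self.m_air = self.env.m
        self.lam = self.env.acr_per_second
        self.scn = scn

        # photolysis coefficients, lamp on vs off
        if scn.lamp is not None and scn.lamp.average_room_irradiance > 0:
            self.j_on = photolysis_coefficients(scn.channels, scn.lamp)
        else:
            self.j_on = {ch.name: 0.0 for ch in scn.channels}
        self.j_off = {ch.name: 0.0 for ch in scn.channels}
        self.k_on = self.comp.effective_k(self.env, self.j_on)
        self.k_off = self.comp.effective_k(self.env, self.j_off)

        # state-dependent loss/source vectors
        self.dep = {}
        self.surf_coef = {}
        for present in (False, True):
            mats = scn.all_materials(present)
            dep = np.zeros(self.n)
            for i, name in enumerate(self.names):
                cls = mech.species[name].deposition_class
                if cls != "none":
                    dep[i] = deposition_rate(cls, mats, scn.volume)
            self.dep[present] = dep
            coef = np.zeros(self.n)
            for mat in mats:
                k_dep = mat.vd_o3 * 0.01 * (mat.area / scn.volume)
                for prod, y in mat.yield_table.items():
                    coef[self.names.index(prod)] += y * k_dep
            self.surf_coef[present] = coef
        self.i_o3 = self.names.index("O3") if "O3" in self.names else None

        # outdoor profile: indices + callables
        self.outdoor_idx = []
        for s in scn.outdoor.species():
            if not mech.species[s].is_fixed:
                self.outdoor_idx.append((self.names.index(s), scn.outdoor.profiles[s]))

        self.molar_masses = {s.name: s.molar_mass for s in mech.species.values()}

    def outdoor_vector(self, clock: float) -> np.ndarray:
        out = np.zeros(self.n)
        for i, fn in self.outdoor_idx:
            out[i] = max(0.0, fn(clock % 24.0)) * 1e-9 * self.m_air
        return out

    def emission_vector(self, clock: float, present: bool) -> np.ndarray:
        src = np.zeros(self.n)
        for species, rate in self.scn.emissions.rates_at(clock).items():
            src[self.names.index(species)] += rate
        if present:
            breath = breath_emission_terms(
                self.scn.occupancy, self.scn.volume, clock, self.molar_masses
            )
            for species, rate in breath.items():
                src[self.names.index(species)] += rate
        return src

    def __call__(self, t: float, y: np.ndarray, lamp_on: bool, present: bool) -> np.ndarray:
        clock = (t / 3600.0) % 24.0
        conc = np.maximum(y, 0.0)
        k_eff = self.k_on if lamp_on else self.k_off
        dydt = self.comp.tendencies(conc, k_eff)
        dydt += self.lam * (self.outdoor_vector(clock) - conc)
        dydt -= self.dep[present] * conc
        if self.i_o3 is not None:
            dydt += self.surf_coef[present] * conc[self.i_o3]
        dydt += self.emission_vector(clock, present)
        return dydt

    def jacobian(self, y: np.ndarray, lamp_on: bool, present: bool) -> np.ndarray:
        """Dense analytic Jacobian of the tendency (outdoor term has no state dep)."""
        conc = np.maximum(y, 0.0)
        k_eff = self.k_on if lamp_on else self.k_off
        comp = self.comp
        ext = np.append(conc, 1.0)
        n_rxn = len(self.mech.reactions)
        dR = np.zeros((n_rxn, self.n))
        s0, s1, s2 = comp.slots[:, 0], comp.slots[:, 1], comp.slots[:, 2]
        c0, c1, c2 = ext[s0], ext[s1], ext[s2]
        for slot, others in ((s0, k_eff * c1 * c2), (s1, k_eff * c0 * c2), (s2, k_eff * c0 * c1)):
            valid = slot >= 0
            np.add.at(dR, (np.flatnonzero(valid), slot[valid]), others[valid])
        jac = comp.stoich @ dR
        jac[np.diag_indices(self.n)] -= self.lam + self.dep[present]
        if self.i_o3 is not None:
            jac[:, self.i_o3] += self.surf_coef[present]
        return jac


def assemble_rhs(scenario: Scenario) -> Callable[[float, np.ndarray], np.ndarray]:
    """The full tendency function f(t_seconds, state) for the scenario.

    Lamp and occupancy schedules are evaluated from t (spin-up keeps the
    lamp off).  Used directly in tests; :func:`integrate` uses the same
    evaluator piecewise for speed.
    """
    rhs = _RHS(scenario)

    def f(t: float, y: np.ndarray) -> np.ndarray:
        clock = (t / 3600.0) % 24.0
        lamp_on = (
            scenario.lamp is not None
            and t >= scenario.spinup_hours * 3600.0
            and scenario.lamp.is_on(clock)
        )
        present = scenario.occupancy.is_present(clock)
        return rhs(t, y, lamp_on, present)

    f.evaluator = rhs  # type: ignore[attr-defined]
    return f


# ---------------------------------------------------------------------------
# Result container
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    scenario: Scenario
    time: np.ndarray  # s from start of spin-up
    conc: np.ndarray  # species x time, cm^-3
    species: list[str]
    reaction_rates: np.ndarray  # reactions x time, cm^-3 s^-1
    o3_flux: dict[str, np.ndarray]  # process -> cm^-3 s^-1 archives
    floor_events: int = 0
    n_rhs_evaluations: int = 0

    @property
    def clock_hours(self) -> np.ndarray:
        return (self.time / 3600.0) % 24.0

    @property
    def hours(self) -> np.ndarray:
        return self.time / 3600.0

    def index(self, species: str) -> int:
        try:
            return self.species.index(species)
        except ValueError:
            raise KeyError(f"unknown species {species!r}") from None

    def ppb(self, species: str) -> np.ndarray:
        m = self.scenario.environment.m
        return self.conc[self.index(species)] / m * 1e9

    def ppb_sum(self, species_list: Sequence[str]) -> np.ndarray:
        return sum(self.ppb(s) for s in species_list)

    def at_clock(self, clock_hours: float, day: int = 1) -> int:
        """Index of the sample closest to a clock time on an analysis day."""
        target = (self.scenario.spinup_hours + 24.0 * (day - 1) + clock_hours) * 3600.0
        return int(np.argmin(np.abs(self.time - target)))

    def window(self, start_clock: float, end_clock: float, day: int = 1) -> np.ndarray:
        """Boolean mask over the time grid for a clock window on a day."""
        base = self.scenario.spinup_hours + 24.0 * (day - 1)
        lo, hi = (base + start_clock) * 3600.0, (base + end_clock) * 3600.0
        return (self.time >= lo) & (self.time <= hi)

    def to_dataframe(self):
        import pandas as pd

        data = {"time_s": self.time, "clock_h": self.clock_hours}
        m = self.scenario.environment.m
        for i, name in enumerate(self.species):
            data[f"{name}_ppb"] = self.conc[i] / m * 1e9
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def _segment_boundaries(scn: Scenario) -> list[float]:
    """All times (s) at which any schedule changes state, plus the endpoints."""
    daily = set()
    if scn.lamp is not None:
        daily.update(scn.lamp.switch_times())
    for lo, hi in scn.occupancy.schedule:
        daily.add(lo % 24.0)
        daily.add(hi % 24.0)
    daily.update(scn.emissions.switch_times())
    bounds = {0.0, scn.total_hours * 3600.0, scn.spinup_hours * 3600.0}
    n_days = int(math.ceil(scn.total_hours / 24.0))
    for day in range(n_days + 1):
        for h in daily:
            t = (24.0 * day + h) * 3600.0
            if 0.0 < t < scn.total_hours * 3600.0:
                bounds.add(t)
    return sorted(bounds)


def integrate(scenario: Scenario) -> SimulationResult:
    """Integrate the scenario over spin-up + analysis window.

    Returns concentrations on the fixed reporting grid together with the
    per-reaction rate archive and the per-process ozone flux archive
    (production, surface/photolysis/NOx/VOC losses, ventilation in/out),
    all evaluated on the reporting grid.
    """
    rhs_full = assemble_rhs(scenario)
    ev: _RHS = rhs_full.evaluator  # type: ignore[attr-defined]
    mech = scenario.mechanism
    names = ev.names
    m_air = ev.m_air

    y0 = np.zeros(ev.n)
    for i, name in enumerate(names):
        if name in scenario.initial_ppb:
            y0[i] = scenario.initial_ppb[name] * 1e-9 * m_air
        else:
            y0[i] = scenario.outdoor.ppb(name, 0.0) * 1e-9 * m_air

    report = np.arange(0.0, scenario.total_hours * 3600.0 + 1e-6, scenario.reporting_interval)
    conc = np.zeros((ev.n, report.size))
    conc[:, 0] = y0
    lamp_state = np.zeros(report.size, dtype=bool)
    present_state = np.zeros(report.size, dtype=bool)

    floor_events = 0
    n_rhs = 0
    bounds = _segment_boundaries(scenario)
    y = y0.copy()
    for t_lo, t_hi in zip(bounds[:-1], bounds[1:]):
        mid = 0.5 * (t_lo + t_hi)
        clock_mid = (mid / 3600.0) % 24.0
        lamp_on = (
            scenario.lamp is not None
            and mid >= scenario.spinup_hours * 3600.0
            and scenario.lamp.is_on(clock_mid)
        )
        present = scenario.occupancy.is_present(clock_mid)
        mask = (report > t_lo) & (report <= t_hi)
        t_eval = report[mask]
        # emissions and schedules are constant within a segment
        src = ev.emission_vector(clock_mid, present)
        k_eff = ev.k_on if lamp_on else ev.k_off
        dep = ev.dep[present]
        coef = ev.surf_coef[present]
        lam = ev.lam
        comp = ev.comp
        i_o3 = ev.i_o3

        # integrate in segment-local time so the post-switch radical
        # transients (ns-us) are not limited by floating-point spacing
        def f_seg(t, yy):
            conc = np.maximum(yy, 0.0)
            dydt = comp.tendencies(conc, k_eff)
            dydt += lam * (ev.outdoor_vector(((t_lo + t) / 3600.0) % 24.0) - conc)
            dydt -= dep * conc
            if i_o3 is not None:
                dydt += coef * conc[i_o3]
            return dydt + src

        sol = solve_ivp(
            f_seg,
            (0.0, t_hi - t_lo),
            y,
            method=scenario.solver,
            t_eval=(t_eval - t_lo) if t_eval.size else None,
            rtol=scenario.rtol,
            atol=scenario.atol,
            jac=lambda t, yy: ev.jacobian(yy, lamp_on, present),
        )
        if not sol.success:
            last_good = sol.t[-1] / 3600.0 if len(sol.t) else t_lo / 3600.0
            raise RuntimeError(
                f"solver failed in segment [{t_lo / 3600:.2f}, {t_hi / 3600:.2f}] h "
                f"(last good time {last_good:.3f} h): {sol.message}"
            )
        n_rhs += sol.nfev
        if t_eval.size:
            vals = sol.y
            neg = vals < 0
            floor_events += int(neg.sum())
            conc[:, mask] = np.where(neg, 0.0, vals)
            lamp_state[mask] = lamp_on
            present_state[mask] = present
        y = sol.y[:, -1] if sol.y.size else y
        negf = y < 0
        floor_events += int(negf.sum())
        y = np.where(negf, 0.0, y)

    # --- archives on the reporting grid ----------------------------------
    n_rxn = len(mech.reactions)
    rates = np.zeros((n_rxn, report.size))
    comp = ev.comp
    for j, on in enumerate(lamp_state):
        k_eff = ev.k_on if on else ev.k_off
        rates[:, j] = comp.rates(conc[:, j], k_eff)

    i_o3 = ev.i_o3
    o3_conc = conc[i_o3] if i_o3 is not None else np.zeros(report.size)
    prod = np.zeros(report.size)
    loss_phot = np.zeros(report.size)
    loss_nox = np.zeros(report.size)
    loss_voc = np.zeros(report.size)
    for r_idx, rxn in enumerate(mech.reactions):
        produced = sum(y_ for s, y_ in rxn.products if s == "O3")
        consumed = rxn.reactants.count("O3")
        if produced > 0:
            prod += produced * rates[r_idx]
        if consumed > 0:
            if rxn.category == "photolysis":
                loss_phot += consumed * rates[r_idx]
            elif rxn.category == "nox":
                loss_nox += consumed * rates[r_idx]
            else:
                loss_voc += consumed * rates[r_idx]

    if i_o3 is not None:
        dep_o3 = np.where(present_state, ev.dep[True][i_o3], ev.dep[False][i_o3])
    else:
        dep_o3 = np.zeros(report.size)
    loss_surf = dep_o3 * o3_conc
    lam = ev.lam
    out_o3 = np.array([scenario.outdoor.ppb("O3", h) for h in (report / 3600.0) % 24.0])
    vent_in = lam * out_o3 * 1e-9 * m_air
    vent_out = lam * o3_conc

    o3_flux = {
        "production": prod,
        "loss_surface": loss_surf,
        "loss_photolysis": loss_phot,
        "loss_nox": loss_nox,
        "loss_voc": loss_voc,
        "vent_in": vent_in,
        "vent_out": vent_out,
        "lamp_on": lamp_state.astype(float),
    }

    return SimulationResult(
        scenario=scenario,
        time=report,
        conc=conc,
        species=names,
        reaction_rates=rates,
        o3_flux=o3_flux,
        floor_events=floor_events,
        n_rhs_evaluations=n_rhs,
    )
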