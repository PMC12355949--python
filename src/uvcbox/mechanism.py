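"""Reduced gas-phase mechanism: species registry, reactions, rate laws.

The mechanism is a ~40-species / ~60-reaction reduction of tropospheric
chemistry centred on the processes that control indoor oxidants under UVC
lighting: O3/O(3P)/O(1D)/HOx inorganic chemistry, NOy, CO/CH4/HCHO
oxidation, one acyl-peroxy/PAN couple, a lumped organic nitrate, isoprene
(breath) and one monoterpene (limonene) with O3-initiated OH yields, and
the straight-chain carbonyls that enter the secondary-product-creation
metric.  Rate coefficients are hand-transcribed digests of JPL/IUPAC-style
evaluations; each reaction carries a source note, and falloff reactions use
documented 1-atm effective values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "ConstantRate",
    "ArrheniusRate",
    "TermolecularRate",
    "HO2RecombinationRate",
    "PhotolysisRate",
    "Mechanism",
    "MechanismOptions",
    "build_reduced_mechanism",
    "rate_coefficient",
    "chemistry_tendencies",
]

T_MIN, T_MAX = 250.0, 330.0

FIXED_SPECIES = ("M", "O2", "N2", "H2O")


@dataclass(frozen=True)
class Species:
    name: str
    molar_mass: float  # g mol^-1
    is_fixed: bool = False
    spcp_member: bool = False
    deposition_class: str = "none"
    is_ro2: bool = False  # counted in the lumped RO2 diagnostic

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar mass must be positive")


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------


class RateLaw:
    """Base: k(T, M, H2O).  Units follow reaction order (s^-1, cm^3 s^-1, cm^6 s^-1)."""

    def __call__(self, temperature: float, m: float, h2o: float) -> float:
        raise NotImplementedError

    def describe(self) -> str:
        raise NotImplementedError


@dataclass(frozen=True)
class ConstantRate(RateLaw):
    k: float

    def __call__(self, temperature, m, h2o):
        return self.k

    def describe(self):
        return f"const k={self.k:.3e}"


@dataclass(frozen=True)
class ArrheniusRate(RateLaw):
    """k = A * (T/300)^n * exp(-B/T) with B = E/R in K."""

    a: float
    b: float = 0.0
    n: float = 0.0

    def __call__(self, temperature, m, h2o):
        return self.a * (temperature / 300.0) ** self.n * math.exp(-self.b / temperature)

    def describe(self):
        return f"arrhenius A={self.a:.3e} B={self.b:g} n={self.n:g}"


@dataclass(frozen=True)
class TermolecularRate(RateLaw):
    """Low-pressure-limit termolecular coefficient, cm^6 s^-1.

    k = A * (T/300)^n; the [M] factor enters through the explicit M reactant.
    """

    a: float
    n: float = 0.0

    def __call__(self, temperature, m, h2o):
        return self.a * (temperature / 300.0) ** self.n

    def describe(self):
        return f"termolecular A={self.a:.3e} n={self.n:g}"


@dataclass(frozen=True)
class HO2RecombinationRate(RateLaw):
    """HO2 + HO2 effective bimolecular coefficient with M and H2O enhancement."""

    def __call__(self, temperature, m, h2o):
        k = 3.0e-13 * math.exp(460.0 / temperature) + 2.1e-33 * m * math.exp(
            920.0 / temperature
        )
        return k * (1.0 + 1.4e-21 * h2o * math.exp(2200.0 / temperature))

    def describe(self):
        return "ho2+ho2 effective (M and H2O enhanced)"


@dataclass(frozen=True)
class PhotolysisRate(RateLaw):
    """Defers to the externally supplied j-table, keyed by channel name."""

    channel: str

    def __call__(self, temperature, m, h2o):  # pragma: no cover - guarded upstream
        raise RuntimeError(f"photolysis channel {self.channel} requires a j-table")

    def describe(self):
        return f"photolysis channel={self.channel}"


@dataclass
class Reaction:
    reactants: list[str]
    products: list[tuple[str, float]]
    rate: RateLaw
    source_note: str = ""
    category: str = "gas"  # diagnostic tag used by the O3 loss partitioning

    def __post_init__(self) -> None:
        if not 1 <= len(self.reactants) <= 3:
            raise ValueError(f"reaction {self.label()}: 1-3 reactants required")
        if any(y < 0 for _, y in self.products):
            raise ValueError(f"reaction {self.label()}: negative product yield")
        if isinstance(self.rate, PhotolysisRate) and len(self.reactants) != 1:
            raise ValueError(f"reaction {self.label()}: photolysis needs exactly one reactant")

    def label(self) -> str:
        lhs = " + ".join(self.reactants)
        rhs = " + ".join(
            (f"{y:g} {s}" if y != 1.0 else s) for s, y in self.products
        ) or "(products not tracked)"
        return f"{lhs} -> {rhs}"

    def is_photolysis(self) -> bool:
        return isinstance(self.rate, PhotolysisRate)


def rate_coefficient(reaction: Reaction, env, j_table: dict[str, float] | None = None) -> float:
    """Rate coefficient at the environment's T/M/H2O (photolysis: current j)."""
    if not T_MIN <= env.temperature <= T_MAX:
        raise ValueError(
            f"temperature {env.temperature} K outside supported range [{T_MIN}, {T_MAX}] K"
        )
    if reaction.is_photolysis():
        if j_table is None:
            raise ValueError("photolysis reaction requires a j-table")
        return j_table.get(reaction.rate.channel, 0.0)
    k = reaction.rate(env.temperature, env.m, env.h2o)
    if not np.isfinite(k) or k < 0:
        raise ValueError(f"non-finite or negative rate for {reaction.label()}")
    return k


# ---------------------------------------------------------------------------
# Mechanism container
# ---------------------------------------------------------------------------


@dataclass
class Mechanism:
    species: dict[str, Species]
    reactions: list[Reaction]
    conserved_groups: dict[str, tuple[list[str], list[int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()
        self._compiled: _Compiled | None = None

    # -- registry views ---------------------------------------------------
    @property
    def integrated_names(self) -> list[str]:
        return [s.name for s in self.species.values() if not s.is_fixed]

    def index(self, name: str) -> int:
        try:
            return self.integrated_names.index(name)
        except ValueError:
            raise KeyError(f"{name} is not an integrated species") from None

    def ro2_names(self) -> list[str]:
        return [s.name for s in self.species.values() if s.is_ro2]

    def spcp_names(self) -> list[str]:
        return [s.name for s in self.species.values() if s.spcp_member]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        names = set(self.species)
        if len(names) != len(self.species):
            raise ValueError("duplicate species names")
        for rxn in self.reactions:
            for r in rxn.reactants:
                if r not in names:
                    raise ValueError(f"reaction '{rxn.label()}' references undeclared species {r}")
            for p, _ in rxn.products:
                if p not in names:
                    raise ValueError(f"reaction '{rxn.label()}' references undeclared species {p}")

    def orphan_species(self) -> list[str]:
        """Integrated species that appear in no reaction and have no deposition class."""
        seen: set[str] = set()
        for rxn in self.reactions:
            seen.update(rxn.reactants)
            seen.update(p for p, _ in rxn.products)
        return [
            s.name
            for s in self.species.values()
            if not s.is_fixed and s.name not in seen and s.deposition_class == "none"
        ]

    # -- compiled evaluator -------------------------------------------------
    def compiled(self) -> "_Compiled":
        if self._compiled is None:
            self._compiled = _Compiled(self)
        return self._compiled

    def rate_vector(self, env, j_table: dict[str, float]) -> np.ndarray:
        """Per-reaction rate coefficients (photolysis from the j-table)."""
        return np.array([rate_coefficient(r, env, j_table) for r in self.reactions])

    def document(self) -> str:
        """Human-readable reaction list with rate-law provenance."""
        lines = ["# reactants -> products ; rate law ; source"]
        for rxn in self.reactions:
            lines.append(f"{rxn.label()} ; {rxn.rate.describe()} ; {rxn.source_note}")
        return "\n".join(lines) + "\n"


class _Compiled:
    """Vectorized chemistry evaluator.

    Rates: r_i = k_i * prod over reactant slots of conc; fixed-species
    concentrations are folded into an environment-dependent factor so the
    inner loop touches only the integrated state vector.
    """

    def __init__(self, mech: Mechanism):
        self.mech = mech
        names = mech.integrated_names
        idx = {n: i for i, n in enumerate(names)}
        n_int, n_rxn = len(names), len(mech.reactions)
        self.n_int = n_int
        # reactant slots: integrated index or -1 (slot unused / fixed)
        self.slots = np.full((n_rxn, 3), -1, dtype=int)
        self.fixed_species = []  # per reaction: list of fixed reactant names
        self.stoich = np.zeros((n_int, n_rxn))
        for j, rxn in enumerate(mech.reactions):
            fixed = []
            slot = 0
            for r in rxn.reactants:
                if mech.species[r].is_fixed:
                    fixed.append(r)
                else:
                    self.slots[j, slot] = idx[r]
                    slot += 1
                    self.stoich[idx[r], j] -= 1.0
            self.fixed_species.append(fixed)
            for p, y in rxn.products:
                if not mech.species[p].is_fixed:
                    self.stoich[idx[p], j] += y
        self.stoich_pos = np.clip(self.stoich, 0.0, None)
        self.stoich_neg = np.clip(self.stoich, None, 0.0)

    def effective_k(self, env, j_table: dict[str, float]) -> np.ndarray:
        """k_i times the product of fixed-species concentrations."""
        k = self.mech.rate_vector(env, j_table)
        fixed_conc = env.fixed_concentrations()
        for j, fixed in enumerate(self.fixed_species):
            for name in fixed:
                k[j] *= fixed_conc[name]
        return k

    def rates(self, conc: np.ndarray, k_eff: np.ndarray) -> np.ndarray:
        ext = np.append(conc, 1.0)  # slot -1 -> factor 1
        return k_eff * ext[self.slots[:, 0]] * ext[self.slots[:, 1]] * ext[self.slots[:, 2]]

    def tendencies(self, conc: np.ndarray, k_eff: np.ndarray) -> np.ndarray:
        return self.stoich @ self.rates(conc, k_eff)


def chemistry_tendencies(
    mech: Mechanism, conc: np.ndarray, env, j_table: dict[str, float]
) -> np.ndarray:
    """Gas-phase chemistry tendency (cm^-3 s^-1) for the integrated state.

    Each reaction contributes -rate to every reactant and +yield*rate to
    every product; fixed species (O2, N2, M, H2O) have zero tendency by
    construction.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("negative concentration passed to chemistry_tendencies")
    comp = mech.compiled()
    return comp.tendencies(conc, comp.effective_k(env, j_table))


# ---------------------------------------------------------------------------
# The reduced mechanism
# ---------------------------------------------------------------------------


@dataclass
class MechanismOptions:
    terpene_chemistry: bool = True
    pan_chemistry: bool = True
    carbonyl_set: bool = True


def _species_table(opts: MechanismOptions) -> list[Species]:
    sp = [
        Species("M", 28.96, is_fixed=True),
        Species("O2", 32.0, is_fixed=True),
        Species("N2", 28.0, is_fixed=True),
        Species("H2O", 18.0, is_fixed=True),
        Species("O3", 48.0, spcp_member=True, deposition_class="ozone"),
        Species("O3P", 16.0),
        Species("O1D", 16.0),
        Species("H", 1.0),
        Species("OH", 17.0),
        Species("HO2", 33.0),
        Species("H2O2", 34.0, deposition_class="h2o2"),
        Species("NO", 30.0),
        Species("NO2", 46.0, deposition_class="no2"),
        Species("NO3", 62.0),
        Species("N2O5", 108.0, deposition_class="acid"),
        Species("HNO3", 63.0, deposition_class="acid"),
        Species("HONO", 47.0),
        Species("CO", 28.0),
        Species("CH4", 16.0),
        Species("CH3O2", 47.0, is_ro2=True),
        Species("HCHO", 30.0, spcp_member=True, deposition_class="carbonyl"),
        Species("CH3CHO", 44.0, spcp_member=True, deposition_class="carbonyl"),
        Species("ACETONE", 58.0, deposition_class="carbonyl"),
        Species("HCOOH", 46.0, deposition_class="acid"),
        Species("CH3COOH", 60.0, deposition_class="acid"),
        Species("C5H8", 68.0),
        Species("ISOPO2", 117.0, is_ro2=True),
        Species("RNO3", 105.0, spcp_member=True),
    ]
    if opts.pan_chemistry:
        sp += [
            Species("CH3CO3", 75.0, is_ro2=True),
            Species("PAN", 121.0, spcp_member=True),
        ]
    if opts.terpene_chemistry:
        sp += [
            Species("LIMONENE", 136.0),
            Species("LIMO2", 185.0, is_ro2=True),
            Species("MHO6", 126.0),  # 6-methyl-5-hepten-2-one, skin-lipid marker
            Species("OPA4", 100.0, deposition_class="carbonyl"),  # 4-oxopentanal
        ]
    if opts.carbonyl_set:
        sp += [
            Species("GLYOXAL", 58.0, spcp_member=True, deposition_class="carbonyl"),
            Species("ACROLEIN", 56.0, spcp_member=True, deposition_class="carbonyl"),
            Species("PROPANAL", 58.0, spcp_member=True, deposition_class="carbonyl"),
            Species("BUTANAL", 72.0, spcp_member=True, deposition_class="carbonyl"),
            Species("PENTANAL", 86.0, spcp_member=True, deposition_class="carbonyl"),
            Species("HEXANAL", 100.0, spcp_member=True, deposition_class="carbonyl"),
            Species("HEPTANAL", 114.0, spcp_member=True, deposition_class="carbonyl"),
            Species("OCTANAL", 128.0, spcp_member=True, deposition_class="carbonyl"),
            Species("NONANAL", 142.0, spcp_member=True, deposition_class="carbonyl"),
            Species("DECANAL", 156.0, spcp_member=True, deposition_class="carbonyl"),
        ]
    return sp


def build_reduced_mechanism(options: MechanismOptions | None = None) -> Mechanism:
    """Construct and validate the default reduced mechanism."""
    opts = options or MechanismOptions()
    species = {s.name: s for s in _species_table(opts)}
    A, C, T3, P = ArrheniusRate, ConstantRate, TermolecularRate, PhotolysisRate
    rx: list[Reaction] = []

    def add(reactants, products, rate, note, category="gas"):
        rx.append(Reaction(list(reactants), list(products), rate, note, category))

    # --- Ox / HOx core ---------------------------------------------------
    add(["O2"], [("O3P", 2.0)], P("jO2"), "Herzberg continuum photolysis", "photolysis")
    add(["O3P", "O2", "M"], [("O3", 1.0)], T3(6.1e-34, -2.4), "JPL digest: O+O2+M")
    add(["O3"], [("O1D", 1.0)], P("jO3_O1D"), "Hartley band, O(1D) channel", "photolysis")
    add(["O3"], [("O3P", 1.0)], P("jO3_O3P"), "Hartley band, O(3P) channel", "photolysis")
    add(["O1D", "N2"], [("O3P", 1.0)], A(2.15e-11, -110.0), "JPL digest: O1D quench by N2")
    add(["O1D", "O2"], [("O3P", 1.0)], A(3.3e-11, -55.0), "JPL digest: O1D quench by O2")
    add(["O1D", "H2O"], [("OH", 2.0)], A(1.63e-10, -60.0), "JPL digest: O1D+H2O")
    add(["H2O"], [("OH", 1.0), ("H", 1.0)], P("jH2O"), "far-UV water photolysis", "photolysis")
    add(["H", "O2", "M"], [("HO2", 1.0)], T3(4.4e-32, -1.3), "JPL digest: H+O2+M")
    add(["O3P", "O3"], [], A(8.0e-12, 2060.0), "JPL digest: O+O3", "ox_loss")
    add(["OH", "O3"], [("HO2", 1.0)], A(1.7e-12, 940.0), "JPL digest: OH+O3", "hox")
    add(["HO2", "O3"], [("OH", 1.0)], A(1.0e-14, 490.0), "JPL digest: HO2+O3", "hox")
    add(["OH", "HO2"], [], A(4.8e-11, -250.0), "JPL digest: OH+HO2")
    add(["HO2", "HO2"], [("H2O2", 1.0)], HO2RecombinationRate(), "JPL digest incl. M, H2O terms")
    add(["H2O2"], [("OH", 2.0)], P("jH2O2"), "H2O2 photolysis", "photolysis")
    add(["OH", "H2O2"], [("HO2", 1.0)], C(1.8e-12), "JPL digest: OH+H2O2")

    # --- CO / CH4 / HCHO --------------------------------------------------
    add(["OH", "CO"], [("HO2", 1.0)], C(2.4e-13), "1-atm effective OH+CO")
    add(["OH", "CH4"], [("CH3O2", 1.0)], A(2.45e-12, 1775.0), "JPL digest: OH+CH4")
    add(["CH3O2", "NO"], [("HCHO", 1.0), ("HO2", 1.0), ("NO2", 1.0)], A(2.8e-12, -300.0),
        "JPL digest; CH3O fate folded in")
    add(["CH3O2", "HO2"], [], A(3.8e-13, -780.0), "JPL digest; CH3OOH not tracked")
    add(["CH3O2", "CH3O2"], [("HCHO", 1.2), ("HO2", 0.8)], A(9.5e-14, -390.0),
        "self-reaction digest, branch-averaged")
    add(["OH", "HCHO"], [("HO2", 1.0), ("CO", 1.0)], A(5.5e-12, -125.0), "JPL digest: OH+HCHO")
    add(["HCHO"], [("HO2", 2.0), ("CO", 1.0)], P("jHCHO_rad"),
        "radical channel; H/HCO fates in air folded in", "photolysis")
    add(["HCHO"], [("CO", 1.0)], P("jHCHO_mol"), "molecular channel", "photolysis")

    # --- NOy ---------------------------------------------------------------
    add(["NO", "O3"], [("NO2", 1.0)], A(3.0e-12, 1500.0), "JPL digest: NO+O3", "nox")
    add(["NO2", "O3"], [("NO3", 1.0)], A(1.2e-13, 2450.0), "JPL digest: NO2+O3", "nox")
    add(["O3P", "NO2"], [("NO", 1.0)], A(5.1e-12, -210.0), "JPL digest: O+NO2")
    add(["HO2", "NO"], [("OH", 1.0), ("NO2", 1.0)], A(3.44e-12, -260.0), "JPL digest: HO2+NO")
    add(["OH", "NO2"], [("HNO3", 1.0)], C(1.1e-11), "1-atm effective falloff value")
    add(["OH", "NO"], [("HONO", 1.0)], C(7.4e-12), "1-atm effective falloff value")
    add(["HONO"], [("OH", 1.0), ("NO", 1.0)], P("jHONO"), "HONO photolysis", "photolysis")
    add(["OH", "HONO"], [("NO2", 1.0)], A(1.8e-11, 390.0), "digest: OH+HONO")
    add(["NO", "NO3"], [("NO2", 2.0)], A(1.5e-11, -170.0), "JPL digest: NO+NO3")
    add(["NO2", "NO3"], [("N2O5", 1.0)], C(1.2e-12), "1-atm effective falloff value")
    add(["N2O5"], [("NO2", 1.0), ("NO3", 1.0)], A(3.0e14, 10840.0),
        "thermal decomposition, 1-atm effective")
    add(["N2O5", "H2O"], [("HNO3", 2.0)], C(2.5e-22), "homogeneous hydrolysis digest")
    add(["NO3", "HCHO"], [("HNO3", 1.0), ("HO2", 1.0), ("CO", 1.0)], C(5.8e-16),
        "digest: NO3+HCHO")
    add(["NO3", "C5H8"], [("RNO3", 1.0)], A(3.3e-12, 450.0), "digest: NO3+isoprene")

    # --- isoprene ----------------------------------------------------------
    add(["C5H8", "OH"], [("ISOPO2", 1.0)], A(2.7e-11, -390.0), "IUPAC digest: OH+isoprene")
    add(["C5H8", "O3"],
        [("OH", 0.25), ("HO2", 0.25), ("HCHO", 0.6), ("ACROLEIN", 0.4), ("CO", 0.15)],
        A(1.03e-14, 1995.0),
        "IUPAC digest; MVK/MACR pool lumped into the acrolein surrogate", "voc")
    add(["ISOPO2", "NO"],
        [("NO2", 0.9), ("HO2", 0.9), ("HCHO", 0.6), ("ACROLEIN", 0.6), ("RNO3", 0.1)],
        A(2.7e-12, -360.0), "RO2+NO digest with 10% nitrate branch")
    add(["ISOPO2", "HO2"], [], A(2.05e-13, -1300.0), "RO2+HO2 digest; ROOH not tracked")

    if opts.terpene_chemistry:
        add(["LIMONENE", "OH"], [("LIMO2", 1.0)], A(4.28e-11, -401.0), "IUPAC digest: OH+limonene")
        add(["LIMONENE", "O3"],
            [("OH", 0.66), ("HO2", 0.16), ("HCHO", 0.2), ("LIMO2", 0.33)],
            A(2.95e-15, 783.0), "IUPAC digest; 66% OH yield", "voc")
        add(["LIMO2", "NO"],
            [("NO2", 0.78), ("HO2", 0.78), ("HCHO", 0.4), ("RNO3", 0.22)],
            A(2.7e-12, -360.0), "RO2+NO digest with 22% nitrate branch")
        add(["LIMO2", "HO2"], [], A(2.66e-13, -1300.0), "RO2+HO2 digest")
        add(["MHO6", "O3"],
            [("OPA4", 0.75), ("OH", 0.36), ("HO2", 0.2), ("ACETONE", 0.3)],
            C(3.9e-16), "6-MHO ozonolysis digest; 4-OPA main carbonyl", "voc")
        add(["MHO6", "OH"], [("CH3O2", 1.0), ("ACETONE", 0.3)], C(1.0e-10),
            "digest: OH+6-MHO, RO2 lumped into CH3O2")
        add(["OPA4", "OH"], [("CH3CO3" if opts.pan_chemistry else "CH3O2", 1.0)], C(1.5e-11),
            "digest: OH+4-OPA, acyl channel lumped")

    # --- acetaldehyde / PAN ------------------------------------------------
    acyl = "CH3CO3" if opts.pan_chemistry else "CH3O2"
    add(["CH3CHO", "OH"], [(acyl, 1.0)], A(4.7e-12, -345.0), "IUPAC digest: OH+CH3CHO")
    if opts.pan_chemistry:
        add(["CH3CO3", "NO2"], [("PAN", 1.0)], C(9.3e-12), "1-atm effective falloff value")
        add(["PAN"], [("CH3CO3", 1.0), ("NO2", 1.0)], A(2.52e16, 13573.0),
            "PAN thermal decomposition digest")
        add(["CH3CO3", "NO"], [("CH3O2", 1.0), ("NO2", 1.0)], A(8.1e-12, -270.0),
            "JPL digest: CH3CO3+NO")
        add(["CH3CO3", "HO2"], [], A(5.2e-13, -980.0), "digest; peracid not tracked")
    add(["ACETONE", "OH"], [(acyl, 1.0)], A(1.8e-12, 685.0), "digest: OH+acetone")
    add(["RNO3", "OH"], [("NO2", 1.0)], C(9.0e-13), "lumped organic nitrate OH loss")
    add(["HCOOH", "OH"], [("HO2", 1.0)], C(4.5e-13), "digest: OH+formic acid")
    add(["CH3COOH", "OH"], [("CH3O2", 1.0)], C(8.0e-13), "digest: OH+acetic acid")

    # --- SPCP carbonyl OH losses ------------------------------------------
    if opts.carbonyl_set:
        k_oh = {
            "GLYOXAL": 1.1e-11, "ACROLEIN": 2.0e-11, "PROPANAL": 2.0e-11,
            "BUTANAL": 2.4e-11, "PENTANAL": 2.8e-11, "HEXANAL": 3.0e-11,
            "HEPTANAL": 3.2e-11, "OCTANAL": 3.4e-11, "NONANAL": 3.6e-11,
            "DECANAL": 3.8e-11,
        }
        for name, k in k_oh.items():
            if name == "GLYOXAL":
                prods = [("HO2", 1.0), ("CO", 2.0)]
            else:
                prods = [(acyl, 1.0)]
            add([name, "OH"], prods, C(k), f"digest: OH+{name.lower()}, acyl channel lumped")

    mech = Mechanism(species=species, reactions=rx)
    # Ox is conserved within {O3P+O2+M; O3 photolysis; O1D quenching}.
    ox_idx = [i for i, r in enumerate(rx) if r.label() in (
        "O3P + O2 + M -> O3", "O3 -> O1D", "O3 -> O3P",
        "O1D + N2 -> O3P", "O1D + O2 -> O3P")]
    mech.conserved_groups["Ox"] = (["O3", "O3P", "O1D"], ox_idx)

    orphans = mech.orphan_species()
    if orphans:
        raise ValueError(f"orphan species in mechanism: {orphans}")
    return mech


# ---------------------------------------------------------------------------
# Text round-trip ("one reaction per line")
# ---------------------------------------------------------------------------


def mechanism_to_text(mech: Mechanism) -> str:
    lines = ["# reactants -> yield*product + ... ; rate ; source"]
    for rxn in mech.reactions:
        lhs = " + ".join(rxn.reactants)
        rhs = " + ".join(f"{y:g}*{s}" for s, y in rxn.products)
        lines.append(f"{lhs} -> {rhs} ; {_rate_to_text(rxn.rate)} ; {rxn.source_note}")
    return "\n".join(lines) + "\n"


def _rate_to_text(rate: RateLaw) -> str:
    if isinstance(rate, ConstantRate):
        return f"const {rate.k:.6e}"
    if isinstance(rate, ArrheniusRate):
        return f"arr {rate.a:.6e} {rate.b:g} {rate.n:g}"
    if isinstance(rate, TermolecularRate):
        return f"ter {rate.a:.6e} {rate.n:g}"
    if isinstance(rate, HO2RecombinationRate):
        return "ho2ho2"
    if isinstance(rate, PhotolysisRate):
        return f"phot {rate.channel}"
    raise TypeError(type(rate))


def _rate_from_text(text: str) -> RateLaw:
    parts = text.split()
    kind = parts[0]
    if kind == "const":
        return ConstantRate(float(parts[1]))
    if kind == "arr":
        return ArrheniusRate(float(parts[1]), float(parts[2]), float(parts[3]))
    if kind == "ter":
        return TermolecularRate(float(parts[1]), float(parts[2]))
    if kind == "ho2ho2":
        return HO2RecombinationRate()
    if kind == "phot":
        return PhotolysisRate(parts[1])
    raise ValueError(f"unknown rate law {text!r}")


def reactions_from_text(text: str) -> list[Reaction]:
    out = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        eqn, rate_txt, note = (p.strip() for p in line.split(";", 2))
        lhs, rhs = eqn.split("->")
        reactants = [t.strip() for t in lhs.split("+") if t.strip()]
        products = []
        for term in rhs.split("+"):
            term = term.strip()
            if not term:
                continue
            y, _, s = term.partition("*")
            products.append((s.strip(), float(y)))
        out.append(Reaction(reactants, products, _rate_from_text(rate_txt), note))
    return out
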