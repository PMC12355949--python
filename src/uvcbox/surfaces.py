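"""Material-resolved surface deposition and at-surface ozonolysis emissions.

Deposition is first order: loss = vd * (A/V) per material, with vd in
cm s^-1 and A/V in m^-1 (a factor 0.01 converts cm s^-1 to m s^-1).  Ozone
deposited on a material re-emits secondary carbonyls according to that
material's molar yield table (moles of product per mole of O3 taken up).

Default deposition velocities follow the all-surface values used for the
office evaluation (O3 0.0345 cm s^-1, H2O2 0.045 cm s^-1) for inanimate
materials; skin takes up ozone roughly an order of magnitude faster
(0.55 cm s^-1 here, in the measured range for people), which is what makes
occupants the dominant indoor ozone sink.

Yield tables are literature-informed defaults: skin-lipid ozonolysis feeds
6-MHO, 4-OPA, nonanal and decanal (plus acetone and the C1-C2 acids);
wood feeds formaldehyde, acetaldehyde and acrolein; paint and linoleum feed
C5-C10 aldehydes.  The decanal entries for paint/linoleum can be switched
off (they may reflect skin-oil contamination of the measured samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SurfaceMaterial",
    "Occupancy",
    "default_material",
    "deposition_rate",
    "surface_product_emissions",
    "breath_emission_terms",
    "DEFAULT_VD_O3",
    "DEFAULT_VD_H2O2",
    "SKIN_VD_O3",
]

DEFAULT_VD_O3 = 0.0345  # cm s^-1, inanimate surfaces
DEFAULT_VD_H2O2 = 0.045  # cm s^-1
SKIN_VD_O3 = 0.55  # cm s^-1
VD_ACID = 0.07  # cm s^-1 for sticky acids (HNO3, N2O5, organic acids)
VD_CARBONYL = 0.0005  # cm s^-1, weak irreversible VOC uptake
# effective NO2 uptake reproducing the low indoor/outdoor NO2 ratios
# observed in furnished rooms (surface hydrolysis is not modelled explicitly)
VD_NO2 = 0.05  # cm s^-1

KNOWN_MATERIALS = (
    "skin_adult", "skin_child", "paint", "wood", "linoleum", "metal",
    "concrete", "paper", "plastic", "glass", "soft_fabric",
)

# moles product per mole O3 deposited
_SKIN_YIELDS = {
    "MHO6": 0.10,
    "OPA4": 0.035,
    "NONANAL": 0.07,
    "DECANAL": 0.09,
    "ACETONE": 0.05,
    "HCOOH": 0.03,
    "CH3COOH": 0.03,
    "HEXANAL": 0.02,
}
_WOOD_YIELDS = {
    "HCHO": 0.10,
    "CH3CHO": 0.07,
    "ACROLEIN": 0.05,
    "PENTANAL": 0.02,
    "HEXANAL": 0.02,
}
_PAINT_YIELDS = {
    "PROPANAL": 0.010,
    "BUTANAL": 0.010,
    "PENTANAL": 0.012,
    "HEXANAL": 0.030,
    "HEPTANAL": 0.012,
    "OCTANAL": 0.012,
    "NONANAL": 0.020,
    "DECANAL": 0.030,
}
_LINOLEUM_YIELDS = dict(_PAINT_YIELDS)

_DEFAULT_YIELDS: dict[str, dict[str, float]] = {
    "skin_adult": _SKIN_YIELDS,
    "skin_child": _SKIN_YIELDS,
    "wood": _WOOD_YIELDS,
    "paint": _PAINT_YIELDS,
    "linoleum": _LINOLEUM_YIELDS,
}


@dataclass
class SurfaceMaterial:
    """One material class with its area and uptake/emission parameters."""

    name: str
    area: float  # m^2
    vd_o3: float = DEFAULT_VD_O3  # cm s^-1
    vd_h2o2: float = DEFAULT_VD_H2O2  # cm s^-1
    yield_table: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError(f"{self.name}: area must be non-negative")
        if self.vd_o3 < 0 or self.vd_h2o2 < 0:
            raise ValueError(f"{self.name}: deposition velocities must be non-negative")
        if any(y < 0 for y in self.yield_table.values()):
            raise ValueError(f"{self.name}: yields must be non-negative")


def default_material(
    name: str, area: float, include_inanimate_decanal: bool = True
) -> SurfaceMaterial:
    """A material with the bundled default velocities and yield table."""
    if name not in KNOWN_MATERIALS:
        raise KeyError(f"unknown material {name!r}; known: {', '.join(KNOWN_MATERIALS)}")
    vd_o3 = SKIN_VD_O3 if name.startswith("skin") else DEFAULT_VD_O3
    yields = dict(_DEFAULT_YIELDS.get(name, {}))
    if not include_inanimate_decanal and not name.startswith("skin"):
        yields.pop("DECANAL", None)
    return SurfaceMaterial(name=name, area=area, vd_o3=vd_o3, yield_table=yields)


def _vd(species_class: str, mat: SurfaceMaterial) -> float:
    if species_class == "ozone":
        return mat.vd_o3
    if species_class == "h2o2":
        return mat.vd_h2o2
    if species_class == "acid":
        return VD_ACID
    if species_class == "no2":
        return VD_NO2
    if species_class == "carbonyl":
        return VD_CARBONYL
    if species_class == "none":
        return 0.0
    raise KeyError(f"unknown deposition class {species_class!r}")


def deposition_rate(
    species_class: str, materials: list[SurfaceMaterial], volume: float
) -> float:
    """Total first-order surface loss (s^-1) for a deposition class.

    sum over materials of vd (cm s^-1) * 0.01 * A/V (m^-1).
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    return sum(_vd(species_class, m) * 0.01 * (m.area / volume) for m in materials)


def surface_product_emissions(
    o3_conc: float, materials: list[SurfaceMaterial], volume: float
) -> dict[str, float]:
    """Volumetric sources (cm^-3 s^-1) of ozonolysis products.

    For each material and product: yield * vd_O3 * (A/V) * [O3].
    """
    if o3_conc < 0:
        raise ValueError("ozone concentration must be non-negative")
    if volume <= 0:
        raise ValueError("volume must be positive")
    out: dict[str, float] = {}
    for mat in materials:
        dep = mat.vd_o3 * 0.01 * (mat.area / volume) * o3_conc
        for prod, y in mat.yield_table.items():
            out[prod] = out.get(prod, 0.0) + y * dep
    return out


# ---------------------------------------------------------------------------
# Occupants
# ---------------------------------------------------------------------------

ADULT_SKIN_AREA = 2.0  # m^2
CHILD_SKIN_AREA = 1.0  # m^2

# mg h^-1 per person, adult; children scaled by CHILD_BREATH_FACTOR
DEFAULT_BREATH_MG_H = {"ACETONE": 1.0, "C5H8": 0.35, "NO": 0.012}
CHILD_BREATH_FACTOR = 0.6


@dataclass
class Occupancy:
    """Headcount, skin surface and breath emissions with a presence schedule.

    ``schedule`` lists daily clock intervals (start_h, end_h) of presence.
    ``breath_mg_h`` maps species to per-adult emission rates in mg h^-1.
    """

    n_adults: int = 0
    n_children: int = 0
    schedule: list[tuple[float, float]] = field(default_factory=list)
    breath_mg_h: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BREATH_MG_H))

    def __post_init__(self) -> None:
        if self.n_adults < 0 or self.n_children < 0:
            raise ValueError("occupant counts must be non-negative")

    @property
    def skin_area(self) -> float:
        return ADULT_SKIN_AREA * self.n_adults + CHILD_SKIN_AREA * self.n_children

    def is_present(self, clock_hours: float) -> bool:
        h = clock_hours % 24.0
        return any(lo <= h < hi for lo, hi in self.schedule)

    def skin_materials(self) -> list[SurfaceMaterial]:
        mats = []
        if self.n_adults:
            mats.append(default_material("skin_adult", ADULT_SKIN_AREA * self.n_adults))
        if self.n_children:
            mats.append(default_material("skin_child", CHILD_SKIN_AREA * self.n_children))
        return mats


def breath_emission_terms(
    occupancy: Occupancy,
    volume: float,
    clock_hours: float,
    molar_masses: dict[str, float],
) -> dict[str, float]:
    """Breath sources (molecules cm^-3 s^-1) at a clock time; zero when absent."""
    if not occupancy.is_present(clock_hours):
        return {}
    from .constants import AVOGADRO

    heads = occupancy.n_adults + CHILD_BREATH_FACTOR * occupancy.n_children
    vol_cm3 = volume * 1e6
    out = {}
    for species, mg_h in occupancy.breath_mg_h.items():
        mm = molar_masses[species]
        molecules_per_s = mg_h * 1e-3 / mm * AVOGADRO / 3600.0
        out[species] = heads * molecules_per_s / vol_cm3
    return out
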