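"""Built-in room scenarios and synthetic outdoor diurnal profiles.

Three rooms are bundled:

* ``office_validation_scenario`` — an unoccupied 33 m^3 office with a KrCl
  222 nm lamp (room average 0.86 uW cm^-2) cycling 3 h on / 3 h off, used to
  check the lamp-driven ozone rise and decay against measured behaviour.
* ``kitchen_bin_scenario`` — a 25 m^3 kitchen (surface-to-volume 2.53 m^-1,
  one adult) illuminated 07:00-19:00 by a single 10 nm slice of the KrCl
  lamp's emission, the slices scaled so the 220-230 nm bin carries
  93.8 uW cm^-2 (the at-20-cm fluence of the source lamp, used without
  renormalization).
* ``classroom_scenario`` — an occupied 178 m^3 classroom; 21 lamp/ACR
  combinations plus three lamp-off baselines; lamp and occupants follow the
  school-day schedule (09:00-12:00 and 13:00-15:00).

Outdoor O3/NO/NO2 follow smooth 24 h-periodic curves emulating suburban
diurnal profiles; all parameters are explicit and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .boxmodel import EmissionSchedule, Environment, OutdoorProfile, Scenario
from .surfaces import Occupancy, SurfaceMaterial, default_material
from .xsections import hg_254_lamp, krcl_lamp

__all__ = [
    "DiurnalProfileSpec",
    "synthetic_outdoor_profiles",
    "office_validation_scenario",
    "kitchen_bin_scenario",
    "classroom_scenario",
    "CLASSROOM_TABLE",
]


@dataclass(frozen=True)
class DiurnalProfileSpec:
    """A 24 h-periodic outdoor profile: bounds, peak time and shape."""

    species: str
    min_ppb: float
    max_ppb: float
    peak_hour: float = 15.0
    shape: str = "sinusoid"  # or "double-peak"

    def __post_init__(self) -> None:
        if self.min_ppb > self.max_ppb:
            raise ValueError(f"{self.species}: min > max")
        if self.shape not in ("sinusoid", "double-peak"):
            raise ValueError(f"unknown profile shape {self.shape!r}")

    def __call__(self, clock_hours: float) -> float:
        h = clock_hours % 24.0
        amp = self.max_ppb - self.min_ppb
        if self.shape == "sinusoid":
            return self.min_ppb + amp * 0.5 * (
                1.0 + math.cos(2.0 * math.pi * (h - self.peak_hour) / 24.0)
            )
        # double-peak: morning and evening bumps (rush-hour shape), the
        # taller anchored at peak_hour; periodic von-Mises-style bumps.
        def bump(mu, kappa):
            return math.exp(kappa * (math.cos(2.0 * math.pi * (h - mu) / 24.0) - 1.0))

        second = (self.peak_hour + 11.0) % 24.0
        raw = bump(self.peak_hour, 18.0) + 0.7 * bump(second, 12.0)
        return self.min_ppb + amp * min(1.0, raw)


def synthetic_outdoor_profiles(specs: list[DiurnalProfileSpec]) -> OutdoorProfile:
    """Smooth periodic outdoor profiles hitting the stated min/max."""
    return OutdoorProfile({s.species: s for s in specs})


_SUBURBAN_SPECS = [
    DiurnalProfileSpec("O3", 15.0, 40.0, peak_hour=15.0),
    DiurnalProfileSpec("NO", 0.5, 8.0, peak_hour=8.0, shape="double-peak"),
    DiurnalProfileSpec("NO2", 4.0, 16.0, peak_hour=8.0, shape="double-peak"),
    DiurnalProfileSpec("CO", 180.0, 220.0, peak_hour=8.0, shape="double-peak"),
    DiurnalProfileSpec("CH4", 1900.0, 1900.0),
    DiurnalProfileSpec("HCHO", 1.0, 2.0, peak_hour=15.0),
    DiurnalProfileSpec("CH3CHO", 0.5, 1.0, peak_hour=15.0),
    DiurnalProfileSpec("C5H8", 0.1, 0.5, peak_hour=14.0),
    DiurnalProfileSpec("ACETONE", 0.5, 1.0, peak_hour=14.0),
]


def suburban_outdoor() -> OutdoorProfile:
    return synthetic_outdoor_profiles(list(_SUBURBAN_SPECS))


# ---------------------------------------------------------------------------
# Office (model evaluation)
# ---------------------------------------------------------------------------


def office_validation_scenario() -> Scenario:
    """Unoccupied 33 m^3 office, GUV222 0.86 uW cm^-2 cycling 3 h on/off.

    Surface-to-volume ratio 1.0 m^-1 with uniform deposition velocities
    (O3 0.0345, H2O2 0.045 cm s^-1); constant outdoor ozone of 3 ppb; ACR
    0.79 h^-1; 295.7 K and 50% RH.  The on-phase anchor places a switch-on
    at 21:00 so the first on-hour of the evening cycle is 21:00-22:00.
    """
    env = Environment(temperature=295.7, relative_humidity=50.0, acr=0.79)
    lamp = krcl_lamp(0.86, schedule=[(3.0, 6.0), (9.0, 12.0), (15.0, 18.0), (21.0, 24.0)])
    outdoor = synthetic_outdoor_profiles(
        [
            DiurnalProfileSpec("O3", 3.0, 3.0),
            DiurnalProfileSpec("NO", 0.1, 0.1),
            DiurnalProfileSpec("NO2", 1.0, 1.0),
            DiurnalProfileSpec("CO", 200.0, 200.0),
            DiurnalProfileSpec("CH4", 1900.0, 1900.0),
        ]
    )
    materials = [SurfaceMaterial(name="paint", area=33.0, yield_table={})]
    return Scenario(
        name="office_validation",
        environment=env,
        volume=33.0,
        materials=materials,
        occupancy=Occupancy(),
        lamp=lamp,
        outdoor=outdoor,
    )


# ---------------------------------------------------------------------------
# Kitchen (UVC bin experiment)
# ---------------------------------------------------------------------------

KITCHEN_AREAS = {
    "soft_fabric": 2.0,
    "paint": 25.0,
    "wood": 17.0,
    "metal": 8.0,
    "concrete": 1.0,
    "paper": 0.2,
    "plastic": 7.0,
    "glass": 1.0,
}

UV225_FLUENCE = 93.8  # uW cm^-2 carried by the 220-230 nm bin

_KITCHEN_EMISSIONS = [
    # species, molecules cm^-3 s^-1, schedule (None = always)
    ("LIMONENE", 6.0e6, None),
    ("HCHO", 1.1e7, None),  # primary paint+wood emission
    ("CH3CHO", 4.0e6, None),
    ("PENTANAL", 8.0e5, None),
    ("HEXANAL", 1.5e6, None),
]


def kitchen_bin_scenario(bin_label: str, lighting: str = "single-bin") -> Scenario:
    """Kitchen illuminated 07:00-19:00 by one UVC bin of the 222 nm lamp.

    ``bin_label`` is UV205 ... UV295 (ignored when lighting="dark").  Each
    bin carries its share of the synthesized KrCl spectrum, scaled so that
    UV225 carries 93.8 uW cm^-2.
    """
    if lighting not in ("single-bin", "dark"):
        raise ValueError("lighting must be 'single-bin' or 'dark'")
    env = Environment(temperature=273.15 + 19.9, relative_humidity=53.8, acr=0.5)
    schedule = [(7.0, 19.0)]
    if lighting == "dark":
        lamp = None
    else:
        base = krcl_lamp(1.0, schedule=schedule)
        share_225 = base.bin_irradiances()["UV225"]
        full = krcl_lamp(UV225_FLUENCE / share_225, schedule=schedule)
        lamp = full.restricted_to_bin(bin_label)  # KeyError on unknown bin
    materials = [default_material(name, area) for name, area in KITCHEN_AREAS.items()]
    occupancy = Occupancy(n_adults=1, schedule=[(0.0, 24.0)])
    return Scenario(
        name=f"kitchen_{'dark' if lighting == 'dark' else bin_label}",
        environment=env,
        volume=25.0,
        materials=materials,
        occupancy=occupancy,
        lamp=lamp,
        outdoor=suburban_outdoor(),
        emissions=EmissionSchedule(list(_KITCHEN_EMISSIONS)),
    )


# ---------------------------------------------------------------------------
# Classroom (occupied, 21 simulations + 3 baselines)
# ---------------------------------------------------------------------------

#: sim id -> (ACR h^-1, lamp nm or None, average room irradiance uW cm^-2, occupied)
CLASSROOM_TABLE: dict[str, tuple[float, int | None, float, bool]] = {
    "low-baseline": (0.125, None, 0.0, True),
    "1": (0.125, 222, 1.0, True),
    "2": (0.125, 222, 3.0, True),
    "3": (0.125, 222, 5.0, True),
    "4": (0.125, 254, 9.0, True),
    "5": (0.125, 254, 12.0, True),
    "6": (0.125, 254, 15.0, True),
    "mid-baseline": (0.5, None, 0.0, True),
    "7": (0.5, 222, 1.0, True),
    "8": (0.5, 222, 3.0, True),
    "9": (0.5, 222, 5.0, True),
    "10": (0.5, 254, 9.0, True),
    "11": (0.5, 254, 12.0, True),
    "12": (0.5, 254, 15.0, True),
    "high-baseline": (2.0, None, 0.0, True),
    "13": (2.0, 222, 1.0, True),
    "14": (2.0, 222, 3.0, True),
    "15": (2.0, 222, 5.0, True),
    "16": (2.0, 254, 9.0, True),
    "17": (2.0, 254, 12.0, True),
    "18": (2.0, 254, 15.0, True),
    "19": (0.125, 222, 5.0, False),
    "20": (0.5, 222, 5.0, False),
    "21": (2.0, 222, 5.0, False),
}

CLASSROOM_AREAS = {"paint": 144.0, "wood": 26.0, "linoleum": 60.0}

_SCHOOL_DAY = [(9.0, 12.0), (13.0, 15.0)]

_CLASSROOM_EMISSIONS = [
    ("LIMONENE", 4.0e6, None),
    ("HCHO", 3.0e7, None),
    ("CH3CHO", 1.0e7, None),
    ("PENTANAL", 2.0e6, None),
    ("HEXANAL", 4.0e6, None),
]


def classroom_scenario(
    sim_id: str | int,
    relative_humidity: float = 37.5,
    include_inanimate_decanal: bool = True,
) -> Scenario:
    """One row of the classroom simulation matrix (or a lamp-off baseline).

    ``sim_id`` is "1".."21" or "{low,mid,high}-baseline".  Simulations 1-18
    and the baselines have 20 children and one adult present during the
    school day; 19-21 are unoccupied.  ``relative_humidity`` supports the
    60% sensitivity variant of simulations 9 and 12.
    """
    key = str(sim_id)
    if key not in CLASSROOM_TABLE:
        raise KeyError(
            f"unknown classroom simulation {sim_id!r}; valid: {', '.join(CLASSROOM_TABLE)}"
        )
    acr, lamp_nm, irradiance, occupied = CLASSROOM_TABLE[key]
    env = Environment(temperature=295.0, relative_humidity=relative_humidity, acr=acr)
    if lamp_nm is None:
        lamp = None
    elif lamp_nm == 222:
        lamp = krcl_lamp(irradiance, schedule=list(_SCHOOL_DAY))
    else:
        lamp = hg_254_lamp(irradiance, schedule=list(_SCHOOL_DAY))
    materials = [
        default_material(name, area, include_inanimate_decanal=include_inanimate_decanal)
        for name, area in CLASSROOM_AREAS.items()
    ]
    occupancy = (
        Occupancy(n_adults=1, n_children=20, schedule=list(_SCHOOL_DAY))
        if occupied
        else Occupancy()
    )
    return Scenario(
        name=f"classroom_{key}",
        environment=env,
        volume=178.0,
        materials=materials,
        occupancy=occupancy,
        lamp=lamp,
        outdoor=suburban_outdoor(),
        emissions=EmissionSchedule(list(_CLASSROOM_EMISSIONS)),
    )
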