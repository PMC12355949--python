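"""Bundled cross-section / quantum-yield digests and lamp spectra, 200-300 nm.

These are approximate 1 nm-resolution digests of standard kinetics
evaluations (JPL/IUPAC-style recommendations at 298 K), reduced to
piecewise-linear anchor points.  They are physical constants of the
photochemistry, not study data; each table carries a source note and every
table can be exported to (and re-read from) the two-column text format via
:class:`~uvcbox.photolysis.CrossSectionTable`.

The O2 table is the *effective* 1-atm Herzberg continuum: it includes the
documented pressure-enhanced (collision-induced) component, which raises the
low-pressure continuum by roughly 15% at indoor pressures.  Effective values
derived from ozone-generation measurements in chambers lie another ~20-30%
above this digest, so the table is a conservative middle of the literature
spread.  O2 absorbs only between 175 and 242 nm (quantum yield one); the
table is identically zero at and above 243 nm, which is what makes UVC bins
at 245 nm and above ozone-neutral.
"""

from __future__ import annotations

import numpy as np

from .photolysis import CrossSectionTable, LampSpectrum, PhotolysisChannel

__all__ = [
    "default_cross_sections",
    "default_channels",
    "krcl_222_spectrum",
    "hg_254_lamp",
    "krcl_lamp",
]


def _table(species, channel, anchors, scale, phi, temperature=298.0, note=""):
    lam = np.array([a[0] for a in anchors], dtype=float)
    sig = np.array([a[1] for a in anchors], dtype=float) * scale
    grid = np.arange(lam[0], lam[-1] + 0.5, 1.0)
    sigma = np.interp(grid, lam, sig)
    if np.isscalar(phi):
        phivec = np.full_like(grid, float(phi))
    else:
        phivec = np.interp(grid, np.array([p[0] for p in phi]), np.array([p[1] for p in phi]))
    return CrossSectionTable(
        species=species,
        channel=channel,
        wavelength=grid,
        sigma=sigma,
        phi=phivec,
        temperature=temperature,
        source_note=note,
    )


def default_cross_sections() -> dict[str, CrossSectionTable]:
    """All bundled tables keyed by channel name."""
    tables = {}

    # O2 + hv -> 2 O(3P); Herzberg continuum, effective 1-atm values.
    tables["O2->2O3P"] = _table(
        "O2",
        "2 O(3P)",
        [
            (200, 6.90), (202, 7.05), (205, 6.90), (210, 6.40), (215, 5.80),
            (220, 5.15), (222, 4.85), (225, 4.40), (230, 3.55), (235, 2.55),
            (240, 0.0), (300, 0.0),
        ],
        1e-24,
        1.0,
        note=(
            "Herzberg continuum digest, effective 1 atm (incl. pressure-enhanced "
            "component); phi = 1. The weak 240-242 nm tail (<1.5e-24 cm^2) is "
            "truncated at 240 nm so the 10 nm bins at and above 245 nm carry "
            "exactly zero O2 absorption."
        ),
    )

    # O3 Hartley band; O(1D) yield ~0.9 with the O(3P) remainder.
    hartley = [
        (200, 0.32), (205, 0.45), (210, 0.75), (215, 1.20), (220, 1.80),
        (225, 2.60), (230, 3.60), (235, 5.00), (240, 6.80), (245, 8.70),
        (250, 10.40), (255, 11.50), (260, 11.30), (265, 10.30), (270, 8.70),
        (275, 6.80), (280, 4.90), (285, 3.30), (290, 2.00), (295, 1.10),
        (300, 0.60),
    ]
    tables["O3->O1D"] = _table(
        "O3", "O(1D) + O2", hartley, 1e-18, 0.90,
        note="Hartley band digest; phi(O1D) = 0.9 across 200-300 nm",
    )
    tables["O3->O3P"] = _table(
        "O3", "O(3P) + O2", hartley, 1e-18, 0.10,
        note="Hartley band digest; phi(O3P) = 1 - phi(O1D)",
    )

    # H2O + hv -> OH + H (weak far-UV tail, 200-232 nm).
    tables["H2O->OH+H"] = _table(
        "H2O", "OH + H",
        [
            (200, 8.0), (205, 6.0), (210, 4.0), (215, 2.5), (220, 1.5),
            (225, 0.8), (230, 0.3), (232, 0.0), (300, 0.0),
        ],
        1e-25,
        1.0,
        note="far-UV absorption tail digest; phi = 1",
    )

    # H2O2 + hv -> 2 OH.
    tables["H2O2->2OH"] = _table(
        "H2O2", "2 OH",
        [
            (200, 4.8), (210, 3.5), (220, 2.6), (230, 1.8), (240, 1.2),
            (250, 0.83), (260, 0.55), (270, 0.33), (280, 0.19), (290, 0.10),
            (300, 0.06),
        ],
        1e-19,
        1.0,
        note="UV continuum digest; phi(2 OH) = 1",
    )

    # NO2 + hv -> NO + O(3P).
    tables["NO2->NO+O3P"] = _table(
        "NO2", "NO + O(3P)",
        [
            (200, 3.0), (210, 4.0), (215, 4.3), (220, 4.0), (230, 2.3),
            (240, 0.8), (250, 0.25), (260, 0.15), (270, 0.25), (280, 0.45),
            (290, 0.85), (300, 1.30),
        ],
        1e-19,
        1.0,
        note="mid-UV band digest; phi = 1 below dissociation limit",
    )

    # HONO + hv -> OH + NO (weak below 300 nm; main bands lie above).
    tables["HONO->OH+NO"] = _table(
        "HONO", "OH + NO",
        [
            (200, 1.5), (210, 1.0), (220, 0.6), (230, 0.3), (240, 0.15),
            (250, 0.08), (260, 0.05), (270, 0.04), (280, 0.05), (290, 0.07),
            (300, 0.10),
        ],
        1e-19,
        1.0,
        note="UV digest (main HONO photolysis bands are >300 nm, out of range)",
    )

    # HCHO radical and molecular channels (onset ~240 nm within range).
    hcho = [
        (200, 0.0), (239, 0.0), (240, 0.05), (250, 0.15), (260, 0.50),
        (270, 1.20), (280, 2.20), (290, 2.60), (300, 3.00),
    ]
    tables["HCHO->H+HCO"] = _table(
        "HCHO", "H + HCO", hcho, 1e-20, 0.70,
        note="band-average digest; radical channel yield ~0.7 in this range",
    )
    tables["HCHO->H2+CO"] = _table(
        "HCHO", "H2 + CO", hcho, 1e-20, 0.30,
        note="band-average digest; molecular channel remainder",
    )

    return tables


def default_channels() -> list[PhotolysisChannel]:
    """Photolysis channels wired to the mechanism's species names.

    Product bookkeeping notes: the HCHO radical channel H + HCO is carried to
    its immediate fate in air (H + O2 -> HO2, HCO + O2 -> HO2 + CO), because
    HCO is not an integrated species.
    """
    x = default_cross_sections()
    return [
        PhotolysisChannel("jO2", "O2", [("O3P", 2.0)], x["O2->2O3P"]),
        PhotolysisChannel("jO3_O1D", "O3", [("O1D", 1.0)], x["O3->O1D"]),
        PhotolysisChannel("jO3_O3P", "O3", [("O3P", 1.0)], x["O3->O3P"]),
        PhotolysisChannel("jH2O", "H2O", [("OH", 1.0), ("H", 1.0)], x["H2O->OH+H"]),
        PhotolysisChannel("jH2O2", "H2O2", [("OH", 2.0)], x["H2O2->2OH"]),
        PhotolysisChannel("jNO2", "NO2", [("NO", 1.0), ("O3P", 1.0)], x["NO2->NO+O3P"]),
        PhotolysisChannel("jHONO", "HONO", [("OH", 1.0), ("NO", 1.0)], x["HONO->OH+NO"]),
        PhotolysisChannel(
            "jHCHO_rad", "HCHO", [("HO2", 2.0), ("CO", 1.0)], x["HCHO->H+HCO"]
        ),
        PhotolysisChannel("jHCHO_mol", "HCHO", [("CO", 1.0)], x["HCHO->H2+CO"]),
    ]


def krcl_222_spectrum(n_points_per_nm: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Synthesized filtered KrCl excimer spectrum shape (relative units).

    A narrow main line at 222 nm (FWHM 4 nm) carrying ~92% of the energy plus
    a short-wavelength shoulder near 216 nm (~8%), emulating the measured
    spectral structure of filtered KrCl lamps.  The shape is a swappable
    input; scenario outcomes depend only on the resulting per-bin
    irradiances.
    """
    grid = np.linspace(200.0, 260.0, int(60 * n_points_per_nm) + 1)

    def gauss(mu, fwhm):
        s = fwhm / 2.3548200450309493
        return np.exp(-0.5 * ((grid - mu) / s) ** 2) / (s * np.sqrt(2 * np.pi))

    shape = 0.92 * gauss(222.0, 4.0) + 0.08 * gauss(216.0, 8.0)
    return grid, shape


def krcl_lamp(
    average_room_irradiance: float,
    schedule: list[tuple[float, float]] | None = None,
) -> LampSpectrum:
    """GUV222: synthesized filtered-KrCl spectrum at a room-average irradiance."""
    grid, shape = krcl_222_spectrum()
    return LampSpectrum(
        kind="KrCl-222",
        average_room_irradiance=average_room_irradiance,
        grid=grid,
        spectral_irradiance=shape,
        schedule=schedule or [],
    )


def hg_254_lamp(
    average_room_irradiance: float,
    schedule: list[tuple[float, float]] | None = None,
) -> LampSpectrum:
    """GUV254: monochromatic low-pressure Hg line at 253.7 nm."""
    return LampSpectrum(
        kind="Hg-254",
        average_room_irradiance=average_room_irradiance,
        wavelength=253.7,
        schedule=schedule or [],
    )
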