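"""Binned UVC photolysis coefficients.

The 200-300 nm range is tiled by ten 10 nm bins named after their midpoint
wavelength (UV205 ... UV295).  For each photolysis channel the coefficient is

    j = sum over bins of  h(bin) * I(bin)

where h(bin) is the bin-width-normalized average of the absorption
cross-section times quantum yield (cm^2) and I(bin) the spherically
integrated photon flux in the bin (photons cm^-2 s^-1) delivered by the lamp.

Note on normalization: h is the (10 nm)^-1 average of sigma*phi over each
bin, so that for a monochromatic lamp j reduces to sigma(lambda)*phi(lambda)
times the total photon flux, as it must.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constants import HC

__all__ = [
    "WavelengthBin",
    "UVC_BINS",
    "CrossSectionTable",
    "LampSpectrum",
    "PhotolysisChannel",
    "photon_energy",
    "irradiance_to_photon_flux",
    "spectrum_to_bin_fluxes",
    "bin_average_h",
    "photolysis_coefficients",
]


@dataclass(frozen=True)
class WavelengthBin:
    """Half-open wavelength interval [lo, hi) labelled by its midpoint."""

    label: str
    lo: float  # nm, inclusive
    hi: float  # nm, exclusive

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def mid(self) -> float:
        return 0.5 * (self.lo + self.hi)


#: The ten UVC bins, UV205 = [200, 210) nm ... UV295 = [290, 300) nm.
UVC_BINS: tuple[WavelengthBin, ...] = tuple(
    WavelengthBin(f"UV{lo + 5}", float(lo), float(lo + 10)) for lo in range(200, 300, 10)
)

_BIN_BY_LABEL = {b.label: b for b in UVC_BINS}


def bin_by_label(label: str) -> WavelengthBin:
    try:
        return _BIN_BY_LABEL[label]
    except KeyError:
        raise KeyError(
            f"unknown UVC bin {label!r}; valid labels: {', '.join(_BIN_BY_LABEL)}"
        ) from None


def _bin_integral(grid: np.ndarray, values: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoid integral of sampled values over [lo, hi] with edge interpolation."""
    lo = max(lo, float(grid[0]))
    hi = min(hi, float(grid[-1]))
    if hi <= lo:
        return 0.0
    inner = (grid > lo) & (grid < hi)
    xs = np.concatenate(([lo], grid[inner], [hi]))
    ys = np.concatenate(
        ([np.interp(lo, grid, values)], values[inner], [np.interp(hi, grid, values)])
    )
    return float(np.trapezoid(ys, xs))


def photon_energy(wavelength_nm: float) -> float:
    """Photon energy E = hc/lambda in J; wavelength in nm (100 < lambda < 1000)."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    if not 100.0 < wavelength_nm < 1000.0:
        raise ValueError("wavelength outside supported range (100, 1000) nm")
    return HC / (wavelength_nm * 1e-9)


def irradiance_to_photon_flux(irradiance_uW_cm2: float, wavelength_nm: float) -> float:
    """Photon flux I = R/E (photons cm^-2 s^-1) for irradiance R in uW cm^-2."""
    if irradiance_uW_cm2 < 0:
        raise ValueError("irradiance must be non-negative")
    return irradiance_uW_cm2 * 1e-6 / photon_energy(wavelength_nm)


@dataclass
class CrossSectionTable:
    """Absorption cross-section and quantum-yield table for one channel.

    sigma in cm^2, phi dimensionless, on a strictly increasing wavelength
    grid (nm).  Values are assumed zero outside the tabulated support.
    """

    species: str
    channel: str
    wavelength: np.ndarray  # nm
    sigma: np.ndarray  # cm^2
    phi: np.ndarray
    temperature: float = 298.0
    source_note: str = ""

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError(f"{self.species}/{self.channel}: wavelength grid not increasing")
        if np.any(self.sigma < 0):
            raise ValueError(f"{self.species}/{self.channel}: negative cross-section")
        if np.any(self.phi < 0):
            raise ValueError(f"{self.species}/{self.channel}: negative quantum yield")

    def sigma_phi(self, wavelength_nm: np.ndarray) -> np.ndarray:
        """sigma*phi interpolated onto ``wavelength_nm``; zero outside support."""
        lam = np.asarray(wavelength_nm, dtype=float)
        out = np.interp(lam, self.wavelength, self.sigma * self.phi, left=0.0, right=0.0)
        return out

    def to_text(self) -> str:
        lines = [
            f"# species: {self.species}",
            f"# channel: {self.channel}",
            f"# temperature_K: {self.temperature}",
            f"# source: {self.source_note}",
            "# wavelength_nm\tsigma_cm2\tphi",
        ]
        for lam, s, p in zip(self.wavelength, self.sigma, self.phi):
            lines.append(f"{lam:.3f}\t{s:.6e}\t{p:.4f}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "CrossSectionTable":
        meta = {}
        lam, sig, phi = [], [], []
        for raw in text.splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split()
            lam.append(float(parts[0]))
            sig.append(float(parts[1]))
            phi.append(float(parts[2]))
        return cls(
            species=meta.get("species", "?"),
            channel=meta.get("channel", "?"),
            wavelength=np.array(lam),
            sigma=np.array(sig),
            phi=np.array(phi),
            temperature=float(meta.get("temperature_K", 298.0)),
            source_note=meta.get("source", ""),
        )


@dataclass
class LampSpectrum:
    """A UVC lamp: spectral shape, room-average irradiance and clock schedule.

    Either a sampled spectrum (wavelength grid + relative spectral irradiance)
    or a monochromatic line (``wavelength`` + no grid).  On construction the
    spectral irradiance is normalized so that its wavelength integral equals
    ``average_room_irradiance`` (uW cm^-2).

    ``schedule`` is a list of daily clock intervals (start_h, end_h) during
    which the lamp is on; empty means always off.
    """

    kind: str
    average_room_irradiance: float  # uW cm^-2
    wavelength: float | None = None  # nm, for a monochromatic lamp
    grid: np.ndarray | None = None  # nm
    spectral_irradiance: np.ndarray | None = None  # uW cm^-2 nm^-1 (relative on input)
    schedule: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.average_room_irradiance < 0:
            raise ValueError("irradiance must be non-negative")
        if self.grid is not None:
            self.grid = np.asarray(self.grid, dtype=float)
            self.spectral_irradiance = np.asarray(self.spectral_irradiance, dtype=float)
            if np.any(self.spectral_irradiance < 0):
                raise ValueError("spectral irradiance must be non-negative")
            total = np.trapezoid(self.spectral_irradiance, self.grid)
            if total > 0 and self.average_room_irradiance > 0:
                self.spectral_irradiance = (
                    self.spectral_irradiance / total * self.average_room_irradiance
                )
            elif self.average_room_irradiance > 0:
                raise ValueError("spectrum integrates to zero but irradiance > 0")
        elif self.wavelength is None and self.average_room_irradiance > 0:
            raise ValueError("need either a spectrum grid or a line wavelength")

    # -- schedule ---------------------------------------------------------
    def is_on(self, clock_hours: float) -> bool:
        h = clock_hours % 24.0
        return any(lo <= h < hi for lo, hi in self.schedule)

    def switch_times(self) -> list[float]:
        """Sorted daily clock hours at which the lamp state changes."""
        times = sorted({t % 24.0 for pair in self.schedule for t in pair})
        return times

    # -- spectral bookkeeping ---------------------------------------------
    def bin_irradiances(self) -> dict[str, float]:
        """Irradiance (uW cm^-2) carried by each UVC bin."""
        out = {}
        for b in UVC_BINS:
            if self.grid is None:
                r = (
                    self.average_room_irradiance
                    if (self.wavelength is not None and b.lo <= self.wavelength < b.hi)
                    else 0.0
                )
            else:
                r = _bin_integral(self.grid, self.spectral_irradiance, b.lo, b.hi)
            out[b.label] = r
        return out

    def bin_fluxes(self) -> dict[str, float]:
        """Photon flux (photons cm^-2 s^-1) in each UVC bin."""
        return spectrum_to_bin_fluxes(self)

    def scaled(self, factor: float) -> "LampSpectrum":
        lamp = LampSpectrum(
            kind=self.kind,
            average_room_irradiance=self.average_room_irradiance * factor,
            wavelength=self.wavelength,
            grid=None if self.grid is None else self.grid.copy(),
            spectral_irradiance=None
            if self.spectral_irradiance is None
            else self.spectral_irradiance.copy(),
            schedule=list(self.schedule),
        )
        return lamp

    def restricted_to_bin(self, label: str) -> "LampSpectrum":
        """The portion of this lamp's emission falling in one UVC bin.

        The restricted lamp keeps that bin's absolute irradiance share; other
        wavelengths are zeroed.
        """
        b = bin_by_label(label)
        if self.grid is None:
            keep = self.wavelength is not None and b.lo <= self.wavelength < b.hi
            return LampSpectrum(
                kind=f"{self.kind}[{label}]",
                average_room_irradiance=self.average_room_irradiance if keep else 0.0,
                wavelength=self.wavelength,
                schedule=list(self.schedule),
            )
        mask = (self.grid >= b.lo) & (self.grid < b.hi)
        spec = np.where(mask, self.spectral_irradiance, 0.0)
        # represent the spectral cut as a sharp step: insert near-duplicate
        # points just outside the bin edges so trapezoid integration over
        # neighbouring bins sees no sliver of this bin's energy
        eps = 1e-9
        edges_x = np.array([b.lo - eps, b.lo, b.hi - eps, b.hi])
        edges_y = np.array(
            [0.0, np.interp(b.lo, self.grid, self.spectral_irradiance),
             np.interp(b.hi - eps, self.grid, self.spectral_irradiance), 0.0]
        )
        grid = np.concatenate((self.grid, edges_x))
        spec = np.concatenate((spec, edges_y))
        order = np.argsort(grid, kind="stable")
        grid, spec = grid[order], spec[order]
        keep = np.concatenate(([True], np.diff(grid) > 0))
        grid, spec = grid[keep], spec[keep]
        share = _bin_integral(grid, spec, b.lo, b.hi)
        lamp = LampSpectrum(
            kind=f"{self.kind}[{label}]",
            average_room_irradiance=share,
            grid=grid,
            spectral_irradiance=spec,
            schedule=list(self.schedule),
        )
        return lamp


def spectrum_to_bin_fluxes(lamp: LampSpectrum) -> dict[str, float]:
    """Per-bin photon fluxes (photons cm^-2 s^-1) of a normalized lamp."""
    out = {b.label: 0.0 for b in UVC_BINS}
    if lamp.average_room_irradiance == 0.0:
        return out
    if lamp.grid is None:
        lam = lamp.wavelength
        for b in UVC_BINS:
            if b.lo <= lam < b.hi:
                out[b.label] = irradiance_to_photon_flux(lamp.average_room_irradiance, lam)
        if all(v == 0.0 for v in out.values()):
            import warnings

            warnings.warn("lamp emission lies entirely outside [200, 300) nm")
        return out
    energy = HC / (lamp.grid * 1e-9)  # J per photon at each grid wavelength
    flux_density = lamp.spectral_irradiance * 1e-6 / energy  # photons cm^-2 s^-1 nm^-1
    for b in UVC_BINS:
        out[b.label] = _bin_integral(lamp.grid, flux_density, b.lo, b.hi)
    if all(v == 0.0 for v in out.values()):
        import warnings

        warnings.warn("lamp emission lies entirely outside [200, 300) nm")
    return out


def bin_average_h(xsec: CrossSectionTable, wl_bin: WavelengthBin) -> float:
    """Bin-width-normalized average of sigma*phi over the bin (cm^2)."""
    lam = np.arange(wl_bin.lo, wl_bin.hi + 1e-9, 0.1)
    vals = xsec.sigma_phi(lam)
    return float(np.trapezoid(vals, lam) / wl_bin.width)


@dataclass
class PhotolysisChannel:
    """One photodissociation channel: reactant -> products at yield."""

    name: str
    reactant: str
    products: list[tuple[str, float]]
    xsec: CrossSectionTable

    def h_per_bin(self) -> dict[str, float]:
        return {b.label: bin_average_h(self.xsec, b) for b in UVC_BINS}


def photolysis_coefficients(
    channels: Iterable[PhotolysisChannel], lamp: LampSpectrum
) -> dict[str, float]:
    """j (s^-1) per channel for a lamp that is currently on.

    j = sum over bins of h(bin) * I(bin).  Schedule gating (j = 0 when the
    lamp is off) is applied by the box model, not here.
    """
    fluxes = spectrum_to_bin_fluxes(lamp)
    out = {}
    for ch in channels:
        h = ch.h_per_bin()
        out[ch.name] = float(sum(h[lbl] * fluxes[lbl] for lbl in fluxes))
    return out


def j_table(channels: Sequence[PhotolysisChannel], lamp: LampSpectrum) -> "pandas.DataFrame":
    """Channel x bin table of per-bin j contributions plus the total (s^-1)."""
    import pandas as pd

    fluxes = spectrum_to_bin_fluxes(lamp)
    rows = {}
    for ch in channels:
        h = ch.h_per_bin()
        contrib = {lbl: h[lbl] * fluxes[lbl] for lbl in fluxes}
        contrib["total"] = sum(contrib.values())
        rows[ch.name] = contrib
    return pd.DataFrame(rows).T
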