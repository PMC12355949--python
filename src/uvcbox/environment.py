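"""Indoor environment state: temperature, humidity, pressure, air exchange."""

from __future__ import annotations

from dataclasses import dataclass

from . import constants as c


@dataclass
class Environment:
    """Thermodynamic state of the (well-mixed) indoor air.

    acr is the air change rate in h^-1 (converted to s^-1 where used).
    M (total air number density) and the H2O number density are derived.
    """

    temperature: float = 295.0  # K
    relative_humidity: float = 50.0  # %
    pressure: float = c.ATM  # Pa
    acr: float = 0.5  # h^-1

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_humidity <= 100.0:
            raise ValueError("relative humidity must be within [0, 100] %")
        if self.temperature <= 0 or self.pressure <= 0:
            raise ValueError("temperature and pressure must be positive")
        if self.acr < 0:
            raise ValueError("air change rate must be non-negative")

    @property
    def m(self) -> float:
        """Air number density (cm^-3)."""
        return c.air_number_density(self.temperature, self.pressure)

    @property
    def h2o(self) -> float:
        """Water vapor number density (cm^-3)."""
        return c.water_vapor_concentration(self.temperature, self.relative_humidity)

    @property
    def acr_per_second(self) -> float:
        return self.acr / c.SECONDS_PER_HOUR

    def fixed_concentrations(self) -> dict[str, float]:
        m = self.m
        return {
            "M": m,
            "O2": c.X_O2 * m,
            "N2": c.X_N2 * m,
            "H2O": self.h2o,
        }
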