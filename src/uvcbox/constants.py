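"""Physical constants (CODATA 2018) and unit helpers.

Concentration convention: molecules cm^-3 internally; ppb at the I/O surface.
"""

from __future__ import annotations

PLANCK = 6.62607015e-34  # J s
SPEED_OF_LIGHT = 2.99792458e8  # m s^-1
BOLTZMANN = 1.380649e-23  # J K^-1
AVOGADRO = 6.02214076e23  # mol^-1

HC = PLANCK * SPEED_OF_LIGHT  # J m

ATM = 101325.0  # Pa

# Dry-air mole fractions
X_O2 = 0.2095
X_N2 = 0.7808

SECONDS_PER_HOUR = 3600.0


def air_number_density(temperature: float, pressure: float = ATM) -> float:
    """Air number density M (cm^-3) from the ideal gas law.

    295 K, 1 atm -> 2.49e19 cm^-3.
    """
    if temperature <= 0 or pressure <= 0:
        raise ValueError("temperature and pressure must be positive")
    return pressure / (BOLTZMANN * temperature) * 1e-6


def saturation_vapor_pressure(temperature: float) -> float:
    """Saturation vapor pressure of water (Pa), Arden Buck correlation.

    Accurate to ~0.1% over indoor temperatures (273-323 K).
    """
    t_c = temperature - 273.15
    return 611.21 * _exp(17.502 * t_c / (240.97 + t_c))


def water_vapor_concentration(temperature: float, relative_humidity: float) -> float:
    """Water vapor number density (cm^-3) at RH percent and temperature K."""
    if not 0.0 <= relative_humidity <= 100.0:
        raise ValueError("relative humidity must be within [0, 100] %")
    p_h2o = relative_humidity / 100.0 * saturation_vapor_pressure(temperature)
    return p_h2o / (BOLTZMANN * temperature) * 1e-6


def ppb_to_number_density(ppb: float, m_air: float) -> float:
    return ppb * 1e-9 * m_air


def number_density_to_ppb(conc: float, m_air: float) -> float:
    return conc / m_air * 1e9


def _exp(x):
    import math

    return math.exp(x)
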