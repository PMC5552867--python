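"""Gas and unit conversions shared by every analysis stage.

Conversions between % air saturation, gas fractions and oxygen partial
pressure, oxygen solubility in (sea)water, and oxygen-uptake unit
conversions.  Solubility follows the Garcia & Gordon (1992, Limnol.
Oceanogr. 37:1307) combined fit to the Benson & Krause data; saturated
water-vapor pressure follows Benson & Krause (1984).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "WaterConditions",
    "O2_FRACTION_AIR",
    "airsat_to_po2",
    "o2_solubility",
    "o2_saturation_concentration",
    "water_vapor_pressure_mmhg",
    "mo2_unit_convert",
    "MO2_UNITS",
]

#: Mole fraction of O2 in dry air.
O2_FRACTION_AIR = 0.2095

#: Real-gas molar volume of O2 at STP (L mol-1), Benson & Krause.
_O2_MOLAR_VOLUME_L = 22.3916

# Garcia & Gordon (1992) combined-fit coefficients, ml(O2) L-1.
_GG_A = (2.00907, 3.22014, 4.05010, 4.94457, -0.256847, 3.88767)
_GG_B = (-0.00624523, -0.00737614, -0.0103410, -0.00817083)
_GG_C0 = -4.88682e-7


@dataclass(frozen=True)
class WaterConditions:
    """Physical water conditions for gas calculations.

    Parameters
    ----------
    temperature : float
        Water temperature in degrees Celsius; must lie in [0, 40].
    salinity : float
        Practical salinity (psu), >= 0.
    barometric_pressure : float
        Barometric pressure in mmHg (default 760).
    """

    temperature: float
    salinity: float = 0.0
    barometric_pressure: float = 760.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.temperature <= 40.0:
            raise ValueError(
                f"temperature {self.temperature} degC outside supported range [0, 40]"
            )
        if self.salinity < 0.0:
            raise ValueError(f"salinity must be >= 0, got {self.salinity}")
        if self.salinity > 42.0:
            raise ValueError(
                f"salinity {self.salinity} psu outside solubility-fit validity (<= 42)"
            )
        if self.barometric_pressure <= 0.0:
            raise ValueError("barometric_pressure must be > 0")


def water_vapor_pressure_mmhg(temperature_c: float) -> float:
    """Saturated water-vapor pressure (mmHg) at ``temperature_c`` (degC).

    Benson & Krause (1984): ln p_w(atm) = 11.8571 - 3840.70/T - 216961/T^2
    with T in kelvin.
    """
    t_k = temperature_c + 273.15
    ln_p_atm = 11.8571 - 3840.70 / t_k - 216961.0 / t_k**2
    return math.exp(ln_p_atm) * 760.0


def airsat_to_po2(
    percent_airsat: float,
    conditions: WaterConditions,
    vapor_corrected: bool = False,
) -> float:
    """Convert % air saturation to oxygen partial pressure (mmHg).

    With ``vapor_corrected=False`` (the default) the dry-gas conversion
    ``percent/100 * 0.2095 * P_bar`` is used; with the flag set, saturated
    water-vapor pressure at the water temperature is subtracted from the
    barometric pressure first.  The conversion is linear in
    ``percent_airsat``.
    """
    if not 0.0 <= percent_airsat <= 100.0:
        raise ValueError(
            f"percent air saturation must lie in [0, 100], got {percent_airsat}"
        )
    p_total = conditions.barometric_pressure
    if vapor_corrected:
        p_total = p_total - water_vapor_pressure_mmhg(conditions.temperature)
    return percent_airsat / 100.0 * O2_FRACTION_AIR * p_total


def o2_saturation_concentration(conditions: WaterConditions) -> float:
    """Air-saturated dissolved O2 concentration (umol L-1).

    Garcia & Gordon (1992) combined fit (their Table 1, ml L-1 column)
    evaluated at the given temperature and salinity, converted to umol L-1
    via the real-gas molar volume 22.3916 L mol-1.  Valid for temperature
    in [0, 40] degC and salinity in [0, 42] psu.
    """
    t = conditions.temperature
    s = conditions.salinity
    ts = math.log((298.15 - t) / (273.15 + t))
    a0, a1, a2, a3, a4, a5 = _GG_A
    b0, b1, b2, b3 = _GG_B
    ln_c = (
        a0
        + a1 * ts
        + a2 * ts**2
        + a3 * ts**3
        + a4 * ts**4
        + a5 * ts**5
        + s * (b0 + b1 * ts + b2 * ts**2 + b3 * ts**3)
        + _GG_C0 * s**2
    )
    ml_per_l = math.exp(ln_c)
    return ml_per_l * 1000.0 / _O2_MOLAR_VOLUME_L


def o2_solubility(conditions: WaterConditions) -> float:
    """Oxygen solubility coefficient alpha (umol L-1 mmHg-1).

    The Garcia-Gordon saturation concentration corresponds to water in
    equilibrium with water-saturated air at 1 atm total pressure, so the
    solubility coefficient is the saturation concentration divided by the
    corresponding PO2 = 0.2095 * (P_bar - p_H2O(T)).
    """
    c_sat = o2_saturation_concentration(conditions)
    po2_sat = O2_FRACTION_AIR * (
        conditions.barometric_pressure - water_vapor_pressure_mmhg(conditions.temperature)
    )
    return c_sat / po2_sat


#: Recognised oxygen-uptake unit labels.
MO2_UNITS = ("umol/kg/min", "mgO2/kg/h")

# 1 umol O2 min-1 = 60 min/h * 32 g/mol / 1000 = 1.92 mg h-1.
_UMOL_MIN_TO_MG_H = 60.0 * 32.0 / 1000.0


def mo2_unit_convert(value: float, from_units: str, to_units: str) -> float:
    """Convert an oxygen-uptake rate between umol kg-1 min-1 and mgO2 kg-1 h-1.

    Uses the O2 molar mass of 32 g mol-1; the round trip is exact.
    """
    for u in (from_units, to_units):
        if u not in MO2_UNITS:
            raise ValueError(f"unknown MO2 unit {u!r}; expected one of {MO2_UNITS}")
    if from_units == to_units:
        return value
    if from_units == "umol/kg/min":
        return value * _UMOL_MIN_TO_MG_H
    return value / _UMOL_MIN_TO_MG_H
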