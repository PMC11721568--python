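"""Air-water gas exchange: solubility, Schmidt numbers, transfer velocities, fluxes.

All routines accept scalars or numpy arrays and broadcast. Temperature is
in degrees Celsius, salinity on the practical scale, wind speed in m s-1
at 10 m. The CO2 flux convention is positive = evasion (water to air).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "water_vapour_pressure",
    "co2_solubility_K0",
    "schmidt_number",
    "gas_transfer_velocity",
    "water_air_co2_flux",
    "radon_evasion",
    "radon_partition_coefficient",
    "sgd_co2_flux",
    "pco2_to_concentration",
    "concentration_to_pco2",
    "SgdCo2Flux",
    "CMH_TO_MDAY",
    "SEAWATER_DENSITY",
]

#: cm h-1 -> m day-1
CMH_TO_MDAY = 0.24
#: default seawater density used in the unit chain, kg m-3 (configurable per call)
SEAWATER_DENSITY = 1025.0

# Schmidt number polynomials Sc = A + B*t + C*t**2 + D*t**3 + E*t**4 (t in degC),
# freshwater (S=0) and seawater (S=35); valid -2..40 degC. Linear interpolation
# in salinity between the two endmember fits.
_SC_COEFFS = {
    ("CO2", "fresh"): (1923.6, -125.06, 4.3773, -0.085681, 0.00070284),
    ("CO2", "sea"): (2116.8, -136.25, 4.7353, -0.092307, 0.0007555),
    ("Rn", "fresh"): (3171.0, -224.28, 8.2809, -0.16699, 0.0014158),
    ("Rn", "sea"): (3489.6, -244.56, 8.9713, -0.18022, 0.0015264),
}


def water_vapour_pressure(temperature, salinity):
    """Saturation water-vapour pressure over seawater, in atm.

    ln p = 24.4543 - 67.4509*(100/T) - 4.8489*ln(T/100) - 0.000544*S, T in K.
    """
    tk = np.asarray(temperature, dtype=float) + 273.15
    s = np.asarray(salinity, dtype=float)
    lnp = 24.4543 - 67.4509 * (100.0 / tk) - 4.8489 * np.log(tk / 100.0) - 0.000544 * s
    return np.exp(lnp)


def co2_solubility_K0(temperature, salinity):
    """CO2 solubility K0 in mol kg-1 atm-1 as a function of T (degC) and S.

    Weiss-form fit; decreasing in both temperature and salinity. Values
    outside the fitted range (-2..40 degC, 0..45) are extrapolated with a
    warning.
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t < -2.0) or np.any(t > 40.0):
        warnings.warn("temperature outside K0 fit range; extrapolating", stacklevel=2)
    tk = t + 273.15
    s = np.asarray(salinity, dtype=float)
    t100 = tk / 100.0
    lnk = (
        -60.2409
        + 93.4517 / t100
        + 23.3585 * np.log(t100)
        + s * (0.023517 - 0.023656 * t100 + 0.0047036 * t100**2)
    )
    return np.exp(lnk)


def schmidt_number(temperature, salinity, gas="CO2"):
    """Schmidt number for CO2 or Rn, interpolated linearly in salinity
    between freshwater and seawater (S=35) polynomial fits."""
    if gas not in ("CO2", "Rn"):
        raise ValueError(f"unsupported gas {gas!r}; expected 'CO2' or 'Rn'")
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)

    def _poly(coeffs):
        a, b, c, d, e = coeffs
        return a + b * t + c * t**2 + d * t**3 + e * t**4

    sc_fresh = _poly(_SC_COEFFS[(gas, "fresh")])
    sc_sea = _poly(_SC_COEFFS[(gas, "sea")])
    return sc_fresh + (s / 35.0) * (sc_sea - sc_fresh)


def gas_transfer_velocity(wind, sc):
    """Wind-driven gas transfer velocity, m day-1.

    k = 0.31 u^2 (Sc/660)^-0.5 in cm h-1, converted with CMH_TO_MDAY.
    """
    u = np.asarray(wind, dtype=float)
    if np.any(u < 0):
        raise ValueError("wind speed must be >= 0")
    sc = np.asarray(sc, dtype=float)
    if np.any(sc <= 0):
        raise ValueError("Schmidt number must be > 0")
    k_cmh = 0.31 * u**2 * (sc / 660.0) ** -0.5
    return k_cmh * CMH_TO_MDAY


def water_air_co2_flux(k, k0, delta_pco2, density=SEAWATER_DENSITY):
    """Water-air CO2 flux F = k * K0 * dpCO2, in mmol m-2 day-1.

    Parameters: k in m day-1, K0 in mol kg-1 atm-1, delta_pco2 = water - air
    in uatm, density in kg m-3. Positive flux is evasion to the atmosphere.
    """
    k = np.asarray(k, dtype=float)
    k0 = np.asarray(k0, dtype=float)
    dp_atm = np.asarray(delta_pco2, dtype=float) * 1e-6
    # mol m-2 d-1 -> mmol m-2 d-1
    return k * k0 * dp_atm * density * 1e3


def radon_evasion(k_rn, c_w, c_air, alpha):
    """Atmospheric radon evasion J = k (Cw - alpha*Cair), dpm m-2 day-1.

    k_rn in m day-1 (Schmidt-corrected for radon), concentrations in dpm m-3,
    alpha the dimensionless air-water partition coefficient. Negative values
    indicate invasion.
    """
    return np.asarray(k_rn, dtype=float) * (
        np.asarray(c_w, dtype=float)
        - np.asarray(alpha, dtype=float) * np.asarray(c_air, dtype=float)
    )


def radon_partition_coefficient(temperature, salinity):
    """Radon air-water partition coefficient alpha = C_water/C_air (dimensionless).

    Weiss-form temperature/salinity fit: decreases with temperature
    (radon is less soluble in warm water) and with salinity (salting out).
    Values outside 0..40 degC are extrapolated with a warning.
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t < 0.0) or np.any(t > 40.0):
        warnings.warn(
            "temperature outside radon partition fit range; extrapolating",
            stacklevel=2,
        )
    tk = t + 273.15
    s = np.asarray(salinity, dtype=float)
    t100 = tk / 100.0
    ln_alpha = (
        -76.14
        + 120.36 / t100
        + 31.26 * np.log(t100)
        + s * (-0.2631 + 0.1673 * t100 - 0.0270 * t100**2)
    )
    return np.exp(ln_alpha)


def pco2_to_concentration(pco2_uatm, temperature, salinity, density=SEAWATER_DENSITY):
    """Dissolved CO2 concentration (mmol m-3) from pCO2 (uatm) via K0."""
    k0 = co2_solubility_K0(temperature, salinity)
    return k0 * np.asarray(pco2_uatm, dtype=float) * 1e-6 * density * 1e3


def concentration_to_pco2(conc_mmol_m3, temperature, salinity, density=SEAWATER_DENSITY):
    """Inverse of :func:`pco2_to_concentration`."""
    k0 = co2_solubility_K0(temperature, salinity)
    return np.asarray(conc_mmol_m3, dtype=float) / (k0 * density * 1e3) * 1e6


@dataclass
class SgdCo2Flux:
    """Groundwater-derived CO2 flux to surface water.

    flux = sgd_rate (m day-1) x dissolved CO2 concentration of the
    groundwater end-member (mmol m-3), in mmol m-2 day-1.
    """

    sgd_rate: float  # m day-1
    gw_co2_conc: float  # mmol m-3
    flux: float  # mmol m-2 day-1
    uncertainty: float = float("nan")  # mmol m-2 day-1, optional
    flags: list = field(default_factory=list)


def sgd_co2_flux(
    sgd_rate,
    gw_pco2,
    temperature,
    salinity,
    density=SEAWATER_DENSITY,
    uncertainty_pct=None,
):
    """SGD-derived CO2 flux from an SGD rate and groundwater end-member pCO2.

    Parameters
    ----------
    sgd_rate : float
        Groundwater discharge rate in m day-1 (areal Darcy velocity).
    gw_pco2 : float
        Groundwater end-member pCO2 in uatm (> 0).
    temperature, salinity : float
        Groundwater end-member conditions for the solubility conversion.
    uncertainty_pct : float, optional
        Relative uncertainty (%) to attach to the flux.
    """
    if not np.isfinite(sgd_rate):
        raise ValueError("sgd_rate must be finite")
    if gw_pco2 <= 0:
        raise ValueError("gw_pco2 must be > 0")
    flags = []
    if sgd_rate < 0:
        warnings.warn("negative SGD rate: possible recharge interval", stacklevel=2)
        flags.append("negative_sgd_rate")
    conc = float(pco2_to_concentration(gw_pco2, temperature, salinity, density))
    flux = float(sgd_rate) * conc
    unc = abs(flux) * uncertainty_pct / 100.0 if uncertainty_pct is not None else float("nan")
    return SgdCo2Flux(
        sgd_rate=float(sgd_rate),
        gw_co2_conc=conc,
        flux=flux,
        uncertainty=unc,
        flags=flags,
    )
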