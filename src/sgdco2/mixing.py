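"""Two-end-member mixing diagnostics for surface pCO2 against radon.

If groundwater were the only CO2 source, surface pCO2 would mix linearly
between low-Rn/low-pCO2 seawater and the groundwater end-member. The OLS
regression of pCO2 on Rn is projected to the mean end-member radon
concentration; the deviation from the measured end-member mean,

    D  = S * Rn_gw_mean + In - pCO2_gw_mean          (uatm)
    DQ = 100 * D / pCO2_gw_mean                      (%)

quantifies additional CO2 sources (D > 0) or sinks (D < 0). Sites with
-100% <= DQ <= 100% (closed band) are classified as SGD-dominated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MixingResult",
    "MixingModel",
    "mixing_regression",
    "deviation",
    "deviation_quotient",
    "classify_mixing",
]

DQ_BAND = (-100.0, 100.0)

SGD_PRIMARY = "sgd_primary_driver"
OTHER_SOURCES = "other_sources"
OTHER_SINKS = "other_sinks"


def mixing_regression(series):
    """OLS regression of pCO2 (uatm) on Rn (dpm L-1): (slope, intercept, r).

    Requires >= 3 paired observations and nonzero Rn variance.
    """
    df = series.data[["rn", "pco2"]].dropna() if hasattr(series, "data") else series
    if len(df) < 3:
        raise ValueError("need at least 3 paired observations")
    if df["rn"].std() == 0:
        raise ValueError("zero radon variance; regression undefined")
    res = stats.linregress(df["rn"], df["pco2"])
    return float(res.slope), float(res.intercept), float(res.rvalue)


def deviation(slope_S, intercept_In, rn_gw_mean, pco2_gw_mean):
    """D = S * Rn_gw_mean + In - pCO2_gw_mean (uatm)."""
    if pco2_gw_mean <= 0:
        raise ValueError("pco2_gw_mean must be > 0")
    return slope_S * rn_gw_mean + intercept_In - pco2_gw_mean


def deviation_quotient(D, pco2_gw_mean):
    """DQ (%) = 100 * D / pCO2_gw_mean."""
    if pco2_gw_mean <= 0:
        raise ValueError("pco2_gw_mean must be > 0")
    return 100.0 * D / pco2_gw_mean


def classify_mixing(dq):
    """Classify a deviation quotient against the closed +/-100% band."""
    if not np.isfinite(dq):
        raise ValueError("DQ must be finite")
    if dq > DQ_BAND[1]:
        return OTHER_SOURCES
    if dq < DQ_BAND[0]:
        return OTHER_SINKS
    return SGD_PRIMARY


@dataclass
class MixingResult:
    """End-member mixing diagnostic for one site (or pooled ecosystem)."""

    slope_S: float  # uatm per dpm L-1
    intercept_In: float  # uatm
    r: float
    rn_gw_mean: float  # dpm L-1
    pco2_gw_mean: float  # uatm
    projected_pco2: float  # uatm
    D: float  # uatm
    DQ: float  # %
    classification: str

    @property
    def within_band(self):
        return DQ_BAND[0] <= self.DQ <= DQ_BAND[1]

    def summary(self):
        return "\n".join(
            [
                "End-member mixing diagnostic",
                f"  slope S        {self.slope_S:12.4g} uatm/(dpm/L)",
                f"  intercept In   {self.intercept_In:12.4g} uatm",
                f"  r              {self.r:12.3f}",
                f"  projected pCO2 {self.projected_pco2:12.4g} uatm at Rn_gw={self.rn_gw_mean:.3g}",
                f"  D              {self.D:12.4g} uatm",
                f"  DQ             {self.DQ:12.2f} %",
                f"  class          {self.classification}",
            ]
        )

    def to_dict(self):
        d = {
            k: getattr(self, k)
            for k in (
                "slope_S",
                "intercept_In",
                "r",
                "rn_gw_mean",
                "pco2_gw_mean",
                "projected_pco2",
                "D",
                "DQ",
                "classification",
            )
        }
        d["within_band"] = self.within_band
        return d


class MixingModel:
    """Fit the mixing diagnostic for one or several sites.

    Parameters
    ----------
    series : SurfaceTimeSeries or sequence of SurfaceTimeSeries
        Multiple series are pooled before the regression (per-ecosystem
        pooling mode).
    endmember : GroundwaterEndMember
    """

    def __init__(self, series, endmember):
        if isinstance(series, (list, tuple)):
            frames = [s.data[["rn", "pco2"]] for s in series]
            self._df = pd.concat(frames).dropna()
        else:
            self._df = series.data[["rn", "pco2"]].dropna()
        self.endmember = endmember

    def fit(self):
        slope, intercept, r = mixing_regression(self._df)
        rn_gw = self.endmember.mean("rn")
        pco2_gw = self.endmember.mean("pco2")
        if pco2_gw <= 0 or rn_gw <= 0:
            raise ValueError("end-member means must be > 0 for mixing diagnostics")
        proj = slope * rn_gw + intercept
        d = deviation(slope, intercept, rn_gw, pco2_gw)
        dq = deviation_quotient(d, pco2_gw)
        return MixingResult(
            slope_S=slope,
            intercept_In=intercept,
            r=r,
            rn_gw_mean=rn_gw,
            pco2_gw_mean=pco2_gw,
            projected_pco2=proj,
            D=d,
            DQ=dq,
            classification=classify_mixing(dq),
        )
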