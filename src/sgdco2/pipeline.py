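"""Per-site orchestration and multi-site summaries.

:class:`SiteModel` wires the full per-site analysis - preprocessing, gas
fluxes, radon mass balance, driver attribution and end-member mixing - and
``fit()`` returns a :class:`SiteResult` carrying every stage's output plus
provenance. Stages degrade independently: a failed precondition (e.g. a
nontidal record, or a corrupt end-member file) nulls that stage and records
the reason; only schema errors on the surface series abort the fit.

``summarize_sites`` aggregates SiteResults into the per-ecosystem table of
mean, sd and median saturation, fluxes and SGD rates, plus grand means.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .drivers import (
    correlation_summary,
    cusum_changepoint,
    cusum_driver_response,
    detect_tidal_extremes,
    tidal_diel_indices,
)
from .gas import (
    co2_solubility_K0,
    gas_transfer_velocity,
    schmidt_number,
    sgd_co2_flux,
    water_air_co2_flux,
)
from .io import (
    GroundwaterEndMember,
    SiteMetadata,
    SurfaceTimeSeries,
    align_series,
    lag_correct,
    read_endmember_csv,
    read_surface_csv,
)
from .mixing import MixingModel
from .radon import RadonBudgetTerms, RadonMassBalance

logger = logging.getLogger(__name__)

__all__ = ["AnalysisOptions", "SiteModel", "SiteResult", "run_site", "summarize_sites"]


@dataclass
class AnalysisOptions:
    """Tunable pipeline defaults; CLI flags map onto these."""

    target_step_min: float = 30.0
    co2_lag_min: float = 0.0
    rn_lag_min: float = 0.0
    mass_balance_method: str = "auto"  # auto -> tidal_cycle if tides else nonsteady
    nonsteady_step_h: float = 1.0
    smooth_window: int = 3
    mc_draws: int = 500
    mc_rn_gw_cv: float = 0.15  # relative spread on the end-member
    mc_d_dif_sd: float = 0.0  # absolute spread on sediment diffusion
    seed: int = 0


@dataclass
class SiteResult:
    """All per-site outputs in one place."""

    site_id: str
    ecosystem: str
    means: dict = field(default_factory=dict)
    saturation_pct: float = float("nan")
    gas_flux: dict = field(default_factory=dict)
    sgd: object = None  # SgdEstimate or None
    sgd_co2: object = None  # SgdCo2Flux or None
    correlations: object = None
    cusum: dict = field(default_factory=dict)
    tei_dei: dict = field(default_factory=dict)
    mixing: object = None
    stage_errors: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def summary(self):
        lines = [
            f"Site {self.site_id} ({self.ecosystem})",
            f"  mean pCO2   {self.means.get('pco2', float('nan')):10.1f} uatm"
            f"   (saturation {self.saturation_pct:.0f} %)",
            f"  mean Rn     {self.means.get('rn', float('nan')):10.2f} dpm/L",
            f"  mean DO     {self.means.get('do_sat', float('nan')):10.1f} %",
        ]
        if self.gas_flux:
            lines.append(
                f"  water-air CO2 flux {self.gas_flux['mean']:.1f} "
                f"+/- {self.gas_flux['sd']:.1f} mmol/m2/d"
            )
        if self.sgd is not None:
            lines.append(
                f"  SGD rate    {self.sgd.sgd_rate:10.2f} cm/d ({self.sgd.method})"
            )
        if self.sgd_co2 is not None:
            lines.append(f"  SGD CO2 flux {self.sgd_co2.flux:9.1f} mmol/m2/d")
        if self.mixing is not None:
            lines.append(
                f"  mixing DQ   {self.mixing.DQ:10.1f} % -> {self.mixing.classification}"
            )
        for stage, err in self.stage_errors.items():
            lines.append(f"  [{stage} skipped: {err}]")
        return "\n".join(lines)

    def to_dict(self):
        out = {
            "site_id": self.site_id,
            "ecosystem": self.ecosystem,
            "means": self.means,
            "saturation_pct": self.saturation_pct,
            "gas_flux": self.gas_flux,
            "stage_errors": self.stage_errors,
            "provenance": self.provenance,
        }
        out["sgd"] = (
            None
            if self.sgd is None
            else {
                "f_gw_m3_d": self.sgd.f_gw,
                "sgd_rate_cm_d": self.sgd.sgd_rate,
                "method": self.sgd.method,
                "uncertainty_pct": self.sgd.uncertainty_pct,
                "n_negative_steps": self.sgd.n_negative,
            }
        )
        out["sgd_co2"] = (
            None
            if self.sgd_co2 is None
            else {
                "flux_mmol_m2_d": self.sgd_co2.flux,
                "gw_co2_conc_mmol_m3": self.sgd_co2.gw_co2_conc,
                "uncertainty_mmol_m2_d": self.sgd_co2.uncertainty,
            }
        )
        out["correlations"] = None if self.correlations is None else self.correlations.to_dict()
        out["cusum"] = {
            drv: {
                "changepoint": c.changepoint,
                "s": [float(v) for v in c.s],
                "driver_sorted": [float(v) for v in c.driver_sorted],
            }
            for drv, c in self.cusum.items()
        }
        out["tei_dei"] = {p: t.to_dict() for p, t in self.tei_dei.items()}
        out["mixing"] = None if self.mixing is None else self.mixing.to_dict()
        return out

    def to_json(self, path=None, **kwargs):
        def _default(o):
            if isinstance(o, (np.floating, np.integer)):
                return float(o)
            if isinstance(o, pd.Timestamp):
                return o.isoformat()
            raise TypeError(type(o))

        text = json.dumps(self.to_dict(), indent=1, sort_keys=True,
                          default=_default, allow_nan=True, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _config_hash(*parts):
    h = hashlib.sha256()
    for p in parts:
        h.update(repr(p).encode())
    return h.hexdigest()[:12]


class SiteModel:
    """End-to-end analysis model for one site.

    Parameters
    ----------
    surface : SurfaceTimeSeries
    meta : SiteMetadata
    endmember : GroundwaterEndMember, optional
        Without it the SGD-CO2 and mixing stages are skipped.
    options : AnalysisOptions, optional
    """

    def __init__(self, surface, meta, endmember=None, options=None):
        self.surface = surface
        self.meta = meta
        self.endmember = endmember
        self.options = options or AnalysisOptions()

    @classmethod
    def from_files(cls, surface_csv, meta_file, endmember_csv=None, options=None):
        meta = SiteMetadata.from_file(meta_file)
        surface = read_surface_csv(surface_csv, meta)
        gw = read_endmember_csv(endmember_csv) if endmember_csv else None
        return cls(surface, meta, gw, options)

    def _budget_terms(self):
        if not self.meta.radon_budget:
            raise ValueError("site metadata has no radon_budget section")
        return RadonBudgetTerms.from_mapping(self.meta.radon_budget)

    def fit(self):
        opts = self.options
        t0 = time.perf_counter()
        series = align_series(self.surface, opts.target_step_min)
        if opts.co2_lag_min or opts.rn_lag_min:
            series = lag_correct(series, opts.co2_lag_min, opts.rn_lag_min)
        df = series.data
        result = SiteResult(site_id=self.meta.site_id, ecosystem=self.meta.ecosystem)
        result.means = {
            c: float(df[c].mean()) for c in ("pco2", "rn", "do_sat", "salinity")
        }
        result.provenance = {
            "software": f"sgdco2 {__version__}",
            "config_hash": _config_hash(vars(opts), vars(self.meta)),
            "seed": opts.seed,
            "n_samples": len(df),
            "preprocess_flags": list(series.flags),
        }
        result.saturation_pct = 100.0 * result.means["pco2"] / self.meta.atm_pco2

        # gas fluxes
        try:
            sc = schmidt_number(df["temperature"], df["salinity"], "CO2")
            k = gas_transfer_velocity(df["wind"], sc)
            k0 = co2_solubility_K0(df["temperature"], df["salinity"])
            delta = df["pco2"] - self.meta.atm_pco2
            flux = water_air_co2_flux(k, k0, delta)
            result.gas_flux = {
                "mean": float(np.nanmean(flux)),
                "sd": float(np.nanstd(flux)),
                "mean_k_m_d": float(np.nanmean(k)),
                "mean_delta_pco2_uatm": float(np.nanmean(delta)),
            }
        except Exception as exc:  # noqa: BLE001 - stage isolation
            result.stage_errors["gas_flux"] = str(exc)

        # tidal structure (shared by mass balance and indices)
        events = detect_tidal_extremes(df["depth"]) if df["depth"].notna().any() else []
        tidal = bool(events)

        # radon mass balance
        try:
            terms = self._budget_terms()
            method = opts.mass_balance_method
            if method == "auto":
                method = "tidal_cycle" if tidal else "nonsteady"
            spreads = {"rn_gw": opts.mc_rn_gw_cv * terms.rn_gw}
            if opts.mc_d_dif_sd > 0:
                spreads["d_dif"] = opts.mc_d_dif_sd
            kwargs = {}
            if method == "nonsteady":
                kwargs = {"step": opts.nonsteady_step_h, "smooth_window": opts.smooth_window}
            result.sgd = RadonMassBalance(terms, series).fit(
                method=method,
                mc_spreads=spreads,
                mc_draws=opts.mc_draws,
                seed=opts.seed,
                **kwargs,
            )
        except Exception as exc:  # noqa: BLE001
            result.stage_errors["radon_mass_balance"] = str(exc)

        # SGD-derived CO2 flux (needs end-member and SGD rate)
        try:
            if self.endmember is None:
                raise ValueError("no groundwater end-member provided")
            if result.sgd is None:
                raise ValueError("no SGD estimate")
            gw = self.endmember
            pco2_gw = gw.mean("pco2")
            cv_gw = 100.0 * gw.sd("pco2") / pco2_gw if pco2_gw > 0 else 0.0
            unc = float(
                np.hypot(
                    cv_gw,
                    result.sgd.uncertainty_pct
                    if np.isfinite(result.sgd.uncertainty_pct)
                    else 0.0,
                )
            )
            result.sgd_co2 = sgd_co2_flux(
                result.sgd.sgd_rate / 100.0,
                pco2_gw,
                gw.mean("temperature"),
                gw.mean("salinity"),
                uncertainty_pct=unc,
            )
        except Exception as exc:  # noqa: BLE001
            result.stage_errors["sgd_co2_flux"] = str(exc)

        # driver attribution
        try:
            result.correlations = correlation_summary(series)
            for drv in ("rn", "do_sat"):
                pair = df[[drv, "pco2"]].dropna()
                curve = cusum_driver_response(pair[drv], pair["pco2"])
                try:
                    curve.changepoint = cusum_changepoint(curve)
                except ValueError:
                    curve.changepoint = None
                result.cusum[drv] = curve
        except Exception as exc:  # noqa: BLE001
            result.stage_errors["driver_analysis"] = str(exc)

        try:
            if not tidal:
                raise ValueError("nontidal record; tidal indices undefined")
            for param in ("pco2", "rn", "do_sat", "salinity"):
                result.tei_dei[param] = tidal_diel_indices(series, events, param)
        except Exception as exc:  # noqa: BLE001
            result.stage_errors["tidal_diel_indices"] = str(exc)

        # end-member mixing
        try:
            if self.endmember is None:
                raise ValueError("no groundwater end-member provided")
            result.mixing = MixingModel(series, self.endmember).fit()
        except Exception as exc:  # noqa: BLE001
            result.stage_errors["mixing"] = str(exc)

        result.provenance["elapsed_s"] = round(time.perf_counter() - t0, 3)
        logger.info("site %s analysed in %.2fs", self.meta.site_id, result.provenance["elapsed_s"])
        return result


def run_site(surface_csv, endmember_csv, meta_file, options=None):
    """File-level convenience wrapper: run the full pipeline for one site."""
    return SiteModel.from_files(surface_csv, meta_file, endmember_csv, options).fit()


_SUMMARY_FIELDS = {
    "saturation_pct": lambda r: r.saturation_pct,
    "water_air_flux_mmol_m2_d": lambda r: r.gas_flux.get("mean") if r.gas_flux else np.nan,
    "sgd_rate_cm_d": lambda r: r.sgd.sgd_rate if r.sgd is not None else np.nan,
    "sgd_co2_flux_mmol_m2_d": lambda r: r.sgd_co2.flux if r.sgd_co2 is not None else np.nan,
    "mean_pco2_uatm": lambda r: r.means.get("pco2", np.nan),
    "mean_rn_dpm_l": lambda r: r.means.get("rn", np.nan),
}


def summarize_sites(results):
    """Per-ecosystem mean/sd/median table plus a grand-mean row.

    Accepts a sequence of :class:`SiteResult`. Returns a DataFrame indexed
    by ecosystem (with a final ``ALL`` row) and columns
    ``<quantity>_<stat>``.
    """
    results = list(results)
    if not results:
        raise ValueError("no site results to summarize")
    rows = []
    for r in results:
        row = {"site_id": r.site_id, "ecosystem": r.ecosystem}
        row.update({name: fn(r) for name, fn in _SUMMARY_FIELDS.items()})
        rows.append(row)
    per_site = pd.DataFrame(rows)
    stats = per_site.groupby("ecosystem")[list(_SUMMARY_FIELDS)].agg(
        ["mean", "std", "median"]
    )
    stats.columns = [f"{q}_{s}" for q, s in stats.columns]
    grand = {}
    for q in _SUMMARY_FIELDS:
        grand[f"{q}_mean"] = per_site[q].mean()
        grand[f"{q}_std"] = per_site[q].std()
        grand[f"{q}_median"] = per_site[q].median()
    stats.loc["ALL"] = pd.Series(grand)
    stats.attrs["per_site"] = per_site
    return stats
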