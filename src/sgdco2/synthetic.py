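"""Synthetic coastal time series with known ground truth.

A well-mixed box of tidally varying depth receives groundwater enriched in
radon and CO2 (discharge peaking near low tide, when the hydraulic gradient
between aquifer and sea is steepest), exchanges gas with the atmosphere,
is flushed toward offshore end-member concentrations, hosts diel net
ecosystem production, and loses radon to decay. Tracers are integrated with
an explicit Euler scheme; multiplicative lognormal measurement noise is
applied to the emitted tracer channels. Every hidden parameter (the true
SGD rate series above all) is recorded so recovery tests can score the
estimators against truth.

The optional ``co2_step_above_rn`` feature emits a fixed extra pCO2
enrichment whenever surface radon exceeds a threshold, emulating plumes of
respiration-derived CO2 that co-occur with high-radon porewater; it gives
driver-threshold detectors a known changepoint to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .gas import (
    concentration_to_pco2,
    gas_transfer_velocity,
    pco2_to_concentration,
    radon_partition_coefficient,
    schmidt_number,
)
from .io import GroundwaterEndMember, SiteMetadata, SurfaceTimeSeries
from .radon import LAMBDA_222, RadonBudgetTerms

__all__ = [
    "SyntheticSiteConfig",
    "SyntheticTruth",
    "generate_forcings",
    "simulate_box_model",
    "sample_endmembers",
    "make_site_bundle",
    "budget_terms_for",
    "preset",
    "PRESETS",
]

# Oxygen Schmidt-number polynomials (same form as gas.py), for the DO channel
_SC_O2 = {
    "fresh": (1745.1, -124.34, 4.8055, -0.10115, 0.00086842),
    "sea": (1920.4, -135.6, 5.2122, -0.10939, 0.00093777),
}

START_TIME = pd.Timestamp("2024-03-01 00:00")


@dataclass
class SyntheticSiteConfig:
    """Generator parameters; defaults describe a moderately tidal estuary."""

    seed: int
    site_id: str = "synthetic"
    ecosystem: str = "estuary"
    duration_days: float = 6.0
    dt_min: float = 5.0  # integration step
    out_dt_min: float = 30.0  # emitted sampling interval
    mean_depth: float = 1.5  # m
    tidal_amplitude: float = 0.5  # m
    tidal_period_h: float = 12.42
    sgd_base: float = 5.0  # cm day-1
    sgd_tidal_gain: float = 20.0  # cm day-1 per m of hydraulic head
    sgd_lag_h: float = 0.0
    sgd_springneap_mod: float = 0.0  # relative amplitude of spring-neap modulation
    springneap_period_d: float = 14.77
    springneap_phase: float = 0.0  # radians at t=0
    gw_rn: float = 60.0  # dpm L-1
    gw_pco2: float = 10000.0  # uatm
    gw_do: float = 20.0  # % saturation
    nep_amplitude: float = 5.0  # mmol C m-3 day-1 (photosynthesis peak)
    respiration_base: float = 3.0  # mmol C m-3 day-1
    flushing_rate: float = 1.0  # day-1
    wind_mean: float = 3.0  # m s-1
    wind_ar1_sd: float = 0.0  # m s-1, AR(1) jitter innovation sd
    noise_cv: float = 0.05  # multiplicative lognormal noise on tracers
    atm_pco2: float = 420.0  # uatm
    atm_rn: float = 100.0  # dpm m-3
    temperature: float = 25.0  # degC, constant
    salinity: float = 30.0
    d_dif: float = 0.0  # sediment diffusive radon flux, dpm m-2 day-1
    rn_decay: bool = True
    co2_step_above_rn: tuple | None = None  # (threshold dpm L-1, amplitude uatm)
    area_A: float = 1.0e4  # m2
    o2_sat_conc: float = 250.0  # mmol m-3 at saturation

    def __post_init__(self):
        if self.dt_min > 10.0:
            raise ValueError("dt_min must be <= 10 min for stable integration")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("sgd_base", "sgd_tidal_gain", "flushing_rate", "noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated series."""

    mean_sgd: float  # cm day-1, time mean of the true rate
    sgd_rate_series: pd.Series  # cm day-1 on the emitted grid
    true_changepoint: float | None
    conservative_mixing_only: bool
    gw_co2_conc: float  # mmol m-3
    config: dict = field(default_factory=dict)

    def to_jsonable(self):
        return {
            "mean_sgd_cm_d": self.mean_sgd,
            "true_changepoint_dpm_l": self.true_changepoint,
            "conservative_mixing_only": self.conservative_mixing_only,
            "gw_co2_conc_mmol_m3": self.gw_co2_conc,
            "sgd_rate_series_cm_d": [float(v) for v in self.sgd_rate_series],
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.config.items()
            },
        }


def _time_days(cfg):
    n = int(round(cfg.duration_days * 1440.0 / cfg.dt_min)) + 1
    return np.arange(n) * (cfg.dt_min / 1440.0)


def generate_forcings(cfg):
    """Depth, wind, light and true SGD-rate series on the integration grid.

    depth = mean + A sin(2 pi t / T); the SGD rate rises with the lagged
    hydraulic head max(0, mean_depth - depth(t - lag)) so discharge peaks
    just after low tide; light is a truncated sine peaking at local noon;
    wind is constant plus optional seeded AR(1) jitter.
    """
    t = _time_days(cfg)
    period_d = cfg.tidal_period_h / 24.0
    depth = cfg.mean_depth + cfg.tidal_amplitude * np.sin(2 * np.pi * t / period_d)
    lag_d = cfg.sgd_lag_h / 24.0
    depth_lagged = cfg.mean_depth + cfg.tidal_amplitude * np.sin(
        2 * np.pi * (t - lag_d) / period_d
    )
    head = np.maximum(0.0, cfg.mean_depth - depth_lagged)
    sn = 1.0 + cfg.sgd_springneap_mod * np.sin(
        2 * np.pi * t / cfg.springneap_period_d + cfg.springneap_phase
    )
    sgd = np.maximum(0.0, (cfg.sgd_base + cfg.sgd_tidal_gain * head) * sn)  # cm day-1
    hours = t * 24.0
    light = np.maximum(0.0, np.sin(2 * np.pi * (hours - 6.0) / 24.0))
    rng = np.random.default_rng(cfg.seed)
    wind = np.full_like(t, cfg.wind_mean)
    if cfg.wind_ar1_sd > 0:
        jitter = np.zeros_like(t)
        phi = 0.95
        for i in range(1, len(t)):
            jitter[i] = phi * jitter[i - 1] + rng.normal(0.0, cfg.wind_ar1_sd)
        wind = np.maximum(0.0, wind + jitter)
    return depth, wind, light, sgd


def _sc_o2(temperature, salinity):
    t = float(temperature)
    vals = {}
    for key, (a, b, c, d, e) in _SC_O2.items():
        vals[key] = a + b * t + c * t**2 + d * t**3 + e * t**4
    return vals["fresh"] + (salinity / 35.0) * (vals["sea"] - vals["fresh"])


def simulate_box_model(cfg):
    """Integrate the box model; returns (SurfaceTimeSeries, SyntheticTruth).

    Tracer equations (concentrations per m3, depth h in m, rates per day):

    * radon:  dC/dt = q Rn_gw / h + D_dif / h - lambda C
              - k_Rn (C - alpha C_air) / h - f (C - C_off)
    * CO2:    dX/dt = q X_gw / h - k_CO2 (X - X_eq) / h - f (X - X_off)
              + R - P light(t)
    * DO:     dO/dt = q (O_gw - O) / h - k_O2 (O - O_sat) / h - f (O - O_sat)
              + P light(t) - R

    The groundwater term is a pure source for radon and CO2 (tidal volume
    change carries ambient water); the DO groundwater term is a replacement
    flux so that low-oxygen groundwater pulls the water column down,
    reproducing the observed Rn-DO anticorrelation under respiration.
    """
    depth, wind, light, sgd = generate_forcings(cfg)
    t = _time_days(cfg)
    dt = cfg.dt_min / 1440.0
    q = sgd / 100.0  # m day-1

    T, S = cfg.temperature, cfg.salinity
    alpha = float(radon_partition_coefficient(T, S))
    k_rn = gas_transfer_velocity(wind, schmidt_number(T, S, "Rn"))
    k_co2 = gas_transfer_velocity(wind, schmidt_number(T, S, "CO2"))
    k_o2 = gas_transfer_velocity(wind, _sc_o2(T, S))

    lam = LAMBDA_222 if cfg.rn_decay else 0.0
    f = cfg.flushing_rate
    rn_gw = cfg.gw_rn * 1e3  # dpm m-3
    x_gw = float(pco2_to_concentration(cfg.gw_pco2, T, S))
    x_eq = float(pco2_to_concentration(cfg.atm_pco2, T, S))
    rn_off = alpha * cfg.atm_rn  # offshore water at atmospheric equilibrium
    x_off = x_eq
    o_sat = cfg.o2_sat_conc
    o_gw = cfg.gw_do / 100.0 * o_sat
    P = cfg.nep_amplitude
    R = cfg.respiration_base

    # stability guard for the explicit scheme
    max_rate = lam + f + max(k_rn.max(), k_co2.max(), k_o2.max()) / depth.min() + q.max() / depth.min()
    if max_rate * dt > 0.5:
        raise ValueError(
            f"explicit Euler unstable (rate*dt={max_rate * dt:.2f}); reduce dt_min"
        )

    n = len(t)
    rn = np.empty(n)
    co2 = np.empty(n)
    do = np.empty(n)
    # start at the quasi-steady state of the initial forcing; with no
    # relaxation pathway, start at the ambient (offshore/saturation) value
    def _init(rate, source, ambient):
        return source / rate if rate > 1e-12 else ambient

    r0 = lam + k_rn[0] / depth[0] + f
    rn[0] = _init(
        r0,
        q[0] * rn_gw / depth[0]
        + cfg.d_dif / depth[0]
        + (k_rn[0] / depth[0]) * alpha * cfg.atm_rn
        + f * rn_off,
        rn_off,
    )
    rc0 = k_co2[0] / depth[0] + f
    co2[0] = _init(
        rc0,
        q[0] * x_gw / depth[0] + (k_co2[0] / depth[0]) * x_eq + f * x_off + R - P * light[0],
        x_off,
    )
    ro0 = q[0] / depth[0] + k_o2[0] / depth[0] + f
    do[0] = _init(
        ro0,
        q[0] * o_gw / depth[0] + (k_o2[0] / depth[0] + f) * o_sat + P * light[0] - R,
        o_sat,
    )

    for i in range(n - 1):
        h = depth[i]
        drn = (
            q[i] * rn_gw / h
            + cfg.d_dif / h
            - lam * rn[i]
            - k_rn[i] * (rn[i] - alpha * cfg.atm_rn) / h
            - f * (rn[i] - rn_off)
        )
        dx = (
            q[i] * x_gw / h
            - k_co2[i] * (co2[i] - x_eq) / h
            - f * (co2[i] - x_off)
            + R
            - P * light[i]
        )
        do_ = (
            q[i] * (o_gw - do[i]) / h
            - k_o2[i] * (do[i] - o_sat) / h
            - f * (do[i] - o_sat)
            + P * light[i]
            - R
        )
        rn[i + 1] = rn[i] + dt * drn
        co2[i + 1] = co2[i] + dt * dx
        do[i + 1] = do[i] + dt * do_

    every = max(1, int(round(cfg.out_dt_min / cfg.dt_min)))
    idx = np.arange(0, n, every)
    times = START_TIME + pd.to_timedelta(t[idx], unit="D")
    times = times.round("s")

    rn_dpml = rn[idx] / 1e3
    pco2 = concentration_to_pco2(co2[idx], T, S)
    if cfg.co2_step_above_rn is not None:
        thr, amp = cfg.co2_step_above_rn
        pco2 = pco2 + amp * (rn_dpml > thr)
    do_pct = do[idx] / o_sat * 100.0

    rng = np.random.default_rng(cfg.seed + 1)
    if cfg.noise_cv > 0:
        sig = np.sqrt(np.log1p(cfg.noise_cv**2))
        for arr in (rn_dpml, pco2, do_pct):
            arr *= np.exp(rng.normal(-0.5 * sig**2, sig, size=arr.size))
        rn_dpml = np.maximum(rn_dpml, 0.0)

    df = pd.DataFrame(
        {
            "pco2": pco2,
            "rn": rn_dpml,
            "do_sat": do_pct,
            "salinity": np.full(idx.size, float(S)),
            "temperature": np.full(idx.size, float(T)),
            "depth": depth[idx],
            "wind": wind[idx],
        },
        index=pd.DatetimeIndex(times, name="timestamp"),
    )
    series = SurfaceTimeSeries(df)
    truth = SyntheticTruth(
        mean_sgd=float(sgd.mean()),
        sgd_rate_series=pd.Series(sgd[idx], index=df.index, name="sgd_cm_d"),
        true_changepoint=(cfg.co2_step_above_rn[0] if cfg.co2_step_above_rn else None),
        conservative_mixing_only=(
            P == 0 and R == 0 and cfg.wind_mean == 0 and cfg.wind_ar1_sd == 0 and not cfg.rn_decay
        ),
        gw_co2_conc=x_gw,
        config=asdict(cfg),
    )
    return series, truth


def budget_terms_for(cfg):
    """Radon budget terms consistent with the generator's physics."""
    alpha = float(radon_partition_coefficient(cfg.temperature, cfg.salinity))
    return RadonBudgetTerms(
        rn_gw=cfg.gw_rn * 1e3,
        a=cfg.area_A,
        v=cfg.area_A * cfg.mean_depth,
        q_ex=cfg.flushing_rate,
        rn_offshore=alpha * cfg.atm_rn,
        atm_rn=cfg.atm_rn,
        d_dif=cfg.d_dif,
        lambda222=LAMBDA_222 if cfg.rn_decay else 0.0,
    )


def sample_endmembers(cfg, n=12, seed=None, cv=0.3):
    """Draw discrete groundwater end-member samples (lognormal around truth)."""
    if n < 3:
        raise ValueError("need n >= 3 end-member samples")
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    sig = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0

    def draw(mean):
        if sig == 0:
            return np.full(n, float(mean))
        return mean * np.exp(rng.normal(-0.5 * sig**2, sig, size=n))

    df = pd.DataFrame(
        {
            "pco2": draw(cfg.gw_pco2),
            "rn": draw(cfg.gw_rn),
            "do_sat": np.full(n, cfg.gw_do),
            "salinity": np.full(n, cfg.salinity),
            "temperature": np.full(n, cfg.temperature),
        }
    )
    return GroundwaterEndMember(df)


def _metadata_for(cfg):
    budget = budget_terms_for(cfg)
    return SiteMetadata(
        site_id=cfg.site_id,
        ecosystem=cfg.ecosystem,
        tidal_range=2.0 * cfg.tidal_amplitude,
        atm_pco2=cfg.atm_pco2,
        atm_rn=cfg.atm_rn,
        area_A=cfg.area_A,
        volume_V=cfg.area_A * cfg.mean_depth,
        radon_budget={
            "rn_gw": budget.rn_gw,
            "a": budget.a,
            "v": budget.v,
            "q_ex": budget.q_ex,
            "rn_offshore": budget.rn_offshore,
            "atm_rn": budget.atm_rn,
            "d_dif": budget.d_dif,
            "lambda222": budget.lambda222,
        },
    )


def make_site_bundle(cfg, outdir, n_endmembers=12, endmember_cv=0.3):
    """Write a complete analysable site bundle to ``outdir``.

    Produces surface.csv, endmember.csv, meta.yaml and truth.json; the
    truth file is for tests only and is never read by the analysis
    pipeline. Same config + seed give byte-identical bundles.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series, truth = simulate_box_model(cfg)
    _io.write_surface_csv(series, outdir / "surface.csv")
    sample_endmembers(cfg, n=n_endmembers, cv=endmember_cv).to_csv(
        outdir / "endmember.csv"
    )
    _metadata_for(cfg).to_file(outdir / "meta.yaml")
    _io.write_truth_json(truth.to_jsonable(), outdir / "truth.json")
    return outdir


def preset(name, seed=0, **overrides):
    """Named study configurations with qualitatively distinct dynamics."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    cfg = PRESETS[name](seed)
    return replace(cfg, **overrides) if overrides else cfg


def _tidal_dominated(seed):
    # shallow mangrove creek: fast tidal flushing, discharge peaks at low
    # tide, CO2-rich porewater plumes appear above ~5 dpm/L radon
    return SyntheticSiteConfig(
        seed=seed,
        site_id="tidal_dominated",
        ecosystem="mangrove",
        mean_depth=1.0,
        tidal_amplitude=0.4,
        sgd_base=3.0,
        sgd_tidal_gain=80.0,
        sgd_lag_h=0.0,
        flushing_rate=16.0,
        gw_rn=600.0,
        gw_pco2=3000.0,
        gw_do=30.0,
        nep_amplitude=2.0,
        respiration_base=1.0,
        wind_mean=3.0,
        noise_cv=0.05,
        co2_step_above_rn=(5.0, 250.0),
    )


def _diel_dominated(seed):
    # productive shallow reef flat: constant background SGD, strong diel
    # metabolism
    return SyntheticSiteConfig(
        seed=seed,
        site_id="diel_dominated",
        ecosystem="coral reef",
        mean_depth=1.2,
        tidal_amplitude=0.3,
        sgd_base=5.0,
        sgd_tidal_gain=0.0,
        flushing_rate=2.0,
        gw_rn=150.0,
        gw_pco2=10000.0,
        gw_do=40.0,
        nep_amplitude=30.0,
        respiration_base=15.0,
        wind_mean=2.0,
        noise_cv=0.05,
    )


def _conservative_mixing(seed):
    # diagnostic regime: biology, gas exchange and decay off; strong SGD
    # with spring-neap-scale variability so the mixing line is well sampled
    return SyntheticSiteConfig(
        seed=seed,
        site_id="conservative_mixing",
        ecosystem="estuary",
        duration_days=10.0,
        mean_depth=1.0,
        tidal_amplitude=0.3,
        sgd_base=20.0,
        sgd_tidal_gain=30.0,
        sgd_lag_h=0.0,
        sgd_springneap_mod=0.5,
        springneap_phase=-np.pi / 2,
        flushing_rate=0.4,
        gw_rn=30.0,
        gw_pco2=20000.0,
        gw_do=20.0,
        nep_amplitude=0.0,
        respiration_base=0.0,
        wind_mean=0.0,
        noise_cv=0.01,
        rn_decay=False,
    )


def _nontidal_lake(seed):
    # nontidal coastal lake: negligible depth variation, weak SGD, diel
    # metabolism dominates
    return SyntheticSiteConfig(
        seed=seed,
        site_id="nontidal_lake",
        ecosystem="coastal lake",
        mean_depth=2.0,
        tidal_amplitude=0.01,
        sgd_base=0.5,
        sgd_tidal_gain=0.0,
        flushing_rate=0.5,
        gw_rn=100.0,
        gw_pco2=8000.0,
        gw_do=20.0,
        nep_amplitude=20.0,
        respiration_base=10.0,
        wind_mean=2.0,
        noise_cv=0.05,
    )


PRESETS = {
    "tidal_dominated": _tidal_dominated,
    "diel_dominated": _diel_dominated,
    "conservative_mixing": _conservative_mixing,
    "nontidal_lake": _nontidal_lake,
}
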