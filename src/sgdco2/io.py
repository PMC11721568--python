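"""Reading, validation and preprocessing of coastal site data.

Three containers cover the inputs of a site analysis:

* :class:`SiteMetadata` - static site descriptors (ecosystem type, geometry,
  atmospheric boundary conditions, radon budget terms).
* :class:`SurfaceTimeSeries` - the multivariate surface-water record
  (pCO2, 222Rn, DO, salinity, temperature, depth, wind) on a shared clock.
* :class:`GroundwaterEndMember` - discrete groundwater samples and their
  summary statistics.

CSV column conventions (exact names): ``timestamp`` (ISO 8601, local clock
time), ``pco2_uatm``, ``rn_dpm_l``, ``do_sat_pct``, ``salinity``, ``temp_c``,
``depth_m``, ``wind_ms``. Missing values are empty fields. End-member CSV:
``sample_id, pco2_uatm, rn_dpm_l, do_sat_pct, salinity, temp_c``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gas import radon_partition_coefficient, water_vapour_pressure

logger = logging.getLogger(__name__)

__all__ = [
    "ECOSYSTEM_TYPES",
    "SURFACE_COLUMNS",
    "SchemaError",
    "OrderingError",
    "SiteMetadata",
    "SurfaceTimeSeries",
    "GroundwaterEndMember",
    "read_surface_csv",
    "write_surface_csv",
    "read_endmember_csv",
    "align_series",
    "lag_correct",
    "dry_xco2_to_pco2",
    "rn_loop_to_water",
]

ECOSYSTEM_TYPES = (
    "coral reef",
    "mangrove",
    "salt marsh",
    "canal",
    "tidal river",
    "estuary",
    "tidal flat",
    "coastal lake",
    "seagrass meadow",
)

# CSV name -> canonical in-memory name
SURFACE_COLUMNS = {
    "pco2_uatm": "pco2",
    "rn_dpm_l": "rn",
    "do_sat_pct": "do_sat",
    "salinity": "salinity",
    "temp_c": "temperature",
    "depth_m": "depth",
    "wind_ms": "wind",
}
_CANONICAL_TO_CSV = {v: k for k, v in SURFACE_COLUMNS.items()}


class SchemaError(ValueError):
    """Input file does not match the documented schema."""


class OrderingError(ValueError):
    """Timestamps are duplicated or not strictly increasing."""


@dataclass
class SiteMetadata:
    """Static descriptors of an observation site."""

    site_id: str
    ecosystem: str
    latitude: float = float("nan")
    longitude: float = float("nan")
    tidal_range: float = float("nan")  # m
    utc_offset: float = 0.0  # hours
    atm_pco2: float = 420.0  # uatm
    atm_rn: float = 0.0  # dpm m-3
    area_A: float = float("nan")  # m2
    volume_V: float = float("nan")  # m3
    atm_pressure: float = 1.0  # atm
    radon_budget: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ecosystem not in ECOSYSTEM_TYPES:
            raise ValueError(
                f"unknown ecosystem {self.ecosystem!r}; expected one of {ECOSYSTEM_TYPES}"
            )
        if not (300.0 <= self.atm_pco2 <= 500.0):
            warnings.warn(
                f"atm_pco2={self.atm_pco2} uatm outside the typical 300-500 range",
                stacklevel=2,
            )

    @classmethod
    def from_file(cls, path):
        """Load from a YAML or JSON metadata file (schema version key 'spec: 1')."""
        raw = Path(path).read_text()
        data = yaml.safe_load(raw)
        data.pop("spec", None)
        return cls(**data)

    def to_file(self, path):
        data = asdict(self)
        data["spec"] = 1
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class SurfaceTimeSeries:
    """Aligned multivariate surface-water record.

    ``data`` is a DataFrame indexed by naive local timestamps with canonical
    columns pco2 (uatm), rn (dpm L-1), do_sat (%), salinity, temperature
    (degC), depth (m) and wind (m s-1). ``flags`` accumulates preprocessing
    events (gaps, rejected rows, rounded lags).
    """

    data: pd.DataFrame
    flags: list = field(default_factory=list)

    def __post_init__(self):
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("SurfaceTimeSeries requires a DatetimeIndex")
        if len(idx) >= 2 and not idx.is_monotonic_increasing:
            raise OrderingError("timestamps must be increasing")

    def __len__(self):
        return len(self.data)

    @property
    def step(self):
        """Median sampling interval as a Timedelta (None for < 2 rows)."""
        if len(self.data) < 2:
            return None
        return pd.Series(self.data.index).diff().median()

    def copy(self):
        return SurfaceTimeSeries(self.data.copy(), list(self.flags))

    def column(self, name):
        return self.data[name]


def read_surface_csv(path, meta=None):
    """Read a surface-water CSV into a :class:`SurfaceTimeSeries`.

    Rows with unparseable timestamps are dropped (count logged and flagged).
    Missing mandatory columns raise :class:`SchemaError`; duplicated or
    non-increasing timestamps raise :class:`OrderingError` naming the row.
    """
    df = pd.read_csv(path)
    missing = [c for c in ["timestamp", *SURFACE_COLUMNS] if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    n_bad = int(ts.isna().sum())
    flags = []
    if n_bad:
        logger.warning("%s: rejected %d rows with unparseable timestamps", path, n_bad)
        flags.append(f"rejected_timestamps:{n_bad}")
        df = df[ts.notna()]
        ts = ts[ts.notna()]
    out = df[list(SURFACE_COLUMNS)].rename(columns=SURFACE_COLUMNS)
    out.index = pd.DatetimeIndex(ts.values, name="timestamp")
    diffs = np.diff(out.index.view("i8"))
    bad = np.nonzero(diffs <= 0)[0]
    if bad.size:
        raise OrderingError(
            f"non-increasing timestamp at row {bad[0] + 1} ({out.index[bad[0] + 1]})"
        )
    out = out.astype(float)
    if (out["rn"].dropna() < 0).any() or (out["salinity"].dropna() < 0).any():
        raise SchemaError("rn_dpm_l and salinity must be >= 0")
    if (out["depth"].dropna() <= 0).any():
        raise SchemaError("depth_m must be > 0")
    return SurfaceTimeSeries(out, flags)


def write_surface_csv(series, path):
    """Write a :class:`SurfaceTimeSeries` back to the documented CSV schema."""
    df = series.data.rename(columns=_CANONICAL_TO_CSV)
    df = df[list(SURFACE_COLUMNS)]
    df.insert(0, "timestamp", series.data.index.strftime("%Y-%m-%dT%H:%M:%S"))
    df.to_csv(path, index=False)


@dataclass
class GroundwaterEndMember:
    """Discrete groundwater end-member samples (pCO2 uatm, Rn dpm L-1, ...)."""

    samples: pd.DataFrame  # columns pco2, rn, do_sat, salinity, temperature

    def __post_init__(self):
        if len(self.samples) < 1:
            raise ValueError("at least one groundwater sample is required")

    @property
    def n(self):
        return len(self.samples)

    def mean(self, col):
        return float(self.samples[col].mean())

    def sd(self, col):
        return float(self.samples[col].std(ddof=1)) if self.n > 1 else 0.0

    @property
    def summary(self):
        return {
            col: {"mean": self.mean(col), "sd": self.sd(col)}
            for col in self.samples.columns
        }

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path)
        needed = ["pco2_uatm", "rn_dpm_l", "do_sat_pct", "salinity", "temp_c"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise SchemaError(f"missing end-member column(s): {', '.join(missing)}")
        renamed = df[needed].rename(
            columns={
                "pco2_uatm": "pco2",
                "rn_dpm_l": "rn",
                "do_sat_pct": "do_sat",
                "temp_c": "temperature",
            }
        )
        return cls(renamed.astype(float))

    def to_csv(self, path):
        df = self.samples.rename(
            columns={
                "pco2": "pco2_uatm",
                "rn": "rn_dpm_l",
                "do_sat": "do_sat_pct",
                "temperature": "temp_c",
            }
        )
        df.insert(0, "sample_id", [f"gw{i + 1:03d}" for i in range(len(df))])
        df.to_csv(path, index=False)


def read_endmember_csv(path):
    return GroundwaterEndMember.from_csv(path)


def align_series(series, target_step):
    """Align all channels onto one uniform grid of ``target_step`` minutes.

    The grid is anchored at the first timestamp with a valid radon value
    (radon sets the pace of the coupled detector system). Channels sampled
    finer than the target step are bin-averaged; channels sampled coarser
    are linearly interpolated onto the grid. Gaps shorter than twice the
    target step are filled by linear interpolation, longer gaps are left
    missing and flagged.
    """
    if target_step <= 0:
        raise ValueError("target_step must be > 0 minutes")
    step = pd.Timedelta(minutes=target_step)
    df = series.data
    rn_valid = df.index[df["rn"].notna()]
    origin = rn_valid[0] if len(rn_valid) else df.index[0]

    native = series.step
    if native == step and not df.isna().any().any():
        offset = (df.index - origin) % step
        if (offset == pd.Timedelta(0)).all():
            return series  # already on the grid and gap-free

    grid = pd.date_range(origin, df.index[-1], freq=step)
    out = {}
    flags = list(series.flags)
    for col in df.columns:
        ch = df[col].dropna()
        if len(ch) == 0:
            out[col] = pd.Series(np.nan, index=grid)
            flags.append(f"empty_channel:{col}")
            continue
        ch_step = pd.Series(ch.index).diff().median() if len(ch) > 1 else step
        if ch_step is not None and ch_step <= step:
            binned = ch.resample(step, origin=origin).mean()
            out[col] = binned.reindex(grid)
        else:
            out[col] = (
                ch.reindex(ch.index.union(grid))
                .interpolate(method="time", limit_area="inside")
                .reindex(grid)
            )
    aligned = pd.DataFrame(out, index=grid)
    aligned.index.name = "timestamp"
    # fill gaps strictly shorter than 2 * target_step (i.e. one missing sample)
    for col in aligned.columns:
        n_missing = int(aligned[col].isna().sum())
        aligned[col] = aligned[col].interpolate(limit=1, limit_area="inside")
        still = int(aligned[col].isna().sum())
        if still:
            flags.append(f"gap:{col}:{still}")
        elif n_missing:
            flags.append(f"filled:{col}:{n_missing}")
    return SurfaceTimeSeries(aligned, flags)


def lag_correct(series, co2_lag=10.0, rn_lag=30.0):
    """Correct equilibrator response lags on the gas channels.

    A gas reading at time t reflects water that entered the equilibrator
    ``lag`` minutes earlier, so the pCO2 and Rn channels are shifted earlier
    by their lag. Lags round to the nearest whole grid step (sub-step lags
    warn and round, keeping channels bit-aligned); rows shifted off either
    end are dropped so all channels stay aligned.
    """
    if co2_lag < 0 or rn_lag < 0:
        raise ValueError("lags must be >= 0")
    step = series.step
    if step is None:
        raise ValueError("series too short to lag-correct")
    step_min = step.total_seconds() / 60.0
    span_min = (series.data.index[-1] - series.data.index[0]).total_seconds() / 60.0
    if co2_lag > span_min or rn_lag > span_min:
        raise ValueError("lag exceeds series span")
    flags = list(series.flags)
    shifts = {}
    for col, lag in (("pco2", co2_lag), ("rn", rn_lag)):
        n = int(round(lag / step_min))
        if abs(n * step_min - lag) > 1e-9:
            warnings.warn(
                f"{col} lag {lag} min rounded to {n} grid step(s) of {step_min} min",
                stacklevel=2,
            )
            flags.append(f"lag_rounded:{col}:{n}")
        shifts[col] = n
    df = series.data.copy()
    for col, n in shifts.items():
        if n:
            df[col] = df[col].shift(-n)
    n_max = max(shifts.values())
    if n_max:
        df = df.iloc[:-n_max] if n_max < len(df) else df.iloc[0:0]
    return SurfaceTimeSeries(df, flags)


def dry_xco2_to_pco2(xco2_dry, temperature, salinity, atm_pressure=1.0, p_h2o=None):
    """Convert dry-air CO2 mole fraction (ppm) to pCO2 (uatm).

    pCO2 = xCO2_dry * (P_atm - p_H2O(T, S)), with p_H2O the saturation
    water-vapour pressure at equilibrator temperature and salinity.
    ``p_h2o`` overrides the computed vapour pressure (test hook).
    """
    x = np.asarray(xco2_dry, dtype=float)
    if np.any(x < 0):
        raise ValueError("xco2_dry must be >= 0")
    if p_h2o is None:
        p_h2o = water_vapour_pressure(temperature, salinity)
    p_h2o = np.asarray(p_h2o, dtype=float)
    if np.any(np.asarray(atm_pressure) <= p_h2o):
        raise ValueError("atm_pressure <= water vapour pressure (nonphysical)")
    return x * (atm_pressure - p_h2o)


def rn_loop_to_water(c_loop, temperature, salinity):
    """Convert closed-air-loop radon concentration to in-water concentration.

    C_water = C_loop * alpha(T, S), both in dpm m-3, with alpha the
    temperature/salinity-dependent air-water partition coefficient.
    """
    c = np.asarray(c_loop, dtype=float)
    if np.any(c < 0):
        raise ValueError("loop concentration must be >= 0")
    return c * radon_partition_coefficient(temperature, salinity)


def write_truth_json(truth, path):
    """Serialize a synthetic-truth mapping to JSON (helper for bundles)."""
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True, default=float))
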