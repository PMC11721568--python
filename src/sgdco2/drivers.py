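"""Driver attribution for surface-water pCO2 variability.

Four diagnostics separate groundwater (radon-traced) from biological
(oxygen-traced) control of CO2:

* pairwise Pearson correlations of pCO2 against Rn, DO, salinity and depth,
  with the field's conventional moderate (|r| >= 0.5) and significance
  (p < 0.05) flags;
* CUSUM driver-response curves: the response is standardized, pairs are
  sorted by ascending driver, and the cumulative sum of z-scores is
  inspected for a slope turning positive (a driver threshold);
* tidal extreme detection on the depth record;
* tidal and diurnal effect indices, TEI = (eta_H - eta_L) / (2 eta_bar) and
  DEI = (eta_D - eta_N) / (2 eta_bar), from +/-1 h brackets around each
  tide peak hour and around local noon (12:00) / midnight (00:00).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "CorrelationSummary",
    "CusumCurve",
    "TidalDielIndices",
    "correlation_summary",
    "cusum_driver_response",
    "cusum_changepoint",
    "detect_tidal_extremes",
    "day_night_anchors",
    "peak_hour_means",
    "tidal_diel_indices",
]

MODERATE_R = 0.5
SIGNIFICANT_P = 0.05
#: depth range below which a record is classified nontidal, m
NONTIDAL_DEPTH_RANGE = 0.05
#: minimum separation between same-kind tidal extremes, hours
MIN_EXTREME_SEPARATION_H = 8.0


@dataclass
class CorrelationSummary:
    """Pearson correlations of pCO2 against candidate drivers."""

    pairs: dict  # driver -> {"r", "p", "n", "moderate", "significant"}

    def __getitem__(self, driver):
        return self.pairs[driver]

    def to_dict(self):
        return self.pairs


def correlation_summary(series, drivers=("rn", "do_sat", "salinity", "depth")):
    """Pairwise-complete Pearson r and two-sided p of pCO2 vs each driver.

    Channels with zero variance (or < 3 paired samples) are flagged
    undefined rather than raising.
    """
    df = series.data
    pairs = {}
    for drv in drivers:
        sub = df[["pco2", drv]].dropna()
        entry = {"r": float("nan"), "p": float("nan"), "n": len(sub)}
        if len(sub) < 3:
            entry["flag"] = "insufficient_pairs"
        elif sub["pco2"].std() == 0 or sub[drv].std() == 0:
            entry["flag"] = "zero_variance"
        else:
            r, p = stats.pearsonr(sub["pco2"], sub[drv])
            entry.update(r=float(r), p=float(p))
        entry["moderate"] = bool(abs(entry["r"]) >= MODERATE_R) if np.isfinite(entry["r"]) else False
        entry["significant"] = bool(entry["p"] < SIGNIFICANT_P) if np.isfinite(entry["p"]) else False
        pairs[drv] = entry
    return CorrelationSummary(pairs)


@dataclass
class CusumCurve:
    """CUSUM of a standardized response ordered by ascending driver."""

    driver_sorted: np.ndarray
    z: np.ndarray
    s: np.ndarray
    changepoint: float | None = None
    flags: list = field(default_factory=list)

    def __len__(self):
        return len(self.s)


def cusum_driver_response(driver, response):
    """Build the CUSUM driver-response curve s_i = z_i + s_{i-1}.

    The response is standardized with the population standard deviation;
    pairs are sorted by driver ascending (stable sort: ties keep time
    order). The final cumulative sum is zero by construction. A constant
    response yields an all-zero curve, flagged ``zero_response_variance``.
    """
    d = np.asarray(driver, dtype=float)
    y = np.asarray(response, dtype=float)
    ok = np.isfinite(d) & np.isfinite(y)
    d, y = d[ok], y[ok]
    if len(d) < 3:
        raise ValueError("need at least 3 paired observations")
    sd = y.std()  # population sd
    flags = []
    if sd == 0:
        z = np.zeros_like(y)
        flags.append("zero_response_variance")
    else:
        z = (y - y.mean()) / sd
    order = np.argsort(d, kind="stable")
    return CusumCurve(driver_sorted=d[order], z=z[order], s=np.cumsum(z[order]), flags=flags)


def cusum_changepoint(curve):
    """Driver value where the CUSUM slope turns positive, or None.

    A continuous two-segment piecewise-linear least-squares fit of s against
    rank is scanned over all interior breakpoints; a changepoint is reported
    only when the first segment slopes down and the second up (a V shape).
    Monotone or flat curves return None.
    """
    s = curve.s
    n = len(s)
    if n < 10:
        raise ValueError("need at least 10 points for a changepoint fit")
    if "zero_response_variance" in curve.flags or np.allclose(s, 0.0):
        return None
    r = np.arange(n, dtype=float)
    best = None
    for b in range(2, n - 2):
        X = np.column_stack([np.ones(n), r, np.maximum(0.0, r - b)])
        coef, res, *_ = np.linalg.lstsq(X, s, rcond=None)
        sse = float(res[0]) if res.size else float(np.sum((X @ coef - s) ** 2))
        if best is None or sse < best[0]:
            best = (sse, b, coef)
    _, b, coef = best
    slope1, slope2 = coef[1], coef[1] + coef[2]
    if slope1 < 0 < slope2:
        return float(curve.driver_sorted[b])
    return None


def detect_tidal_extremes(depth, min_separation_h=MIN_EXTREME_SEPARATION_H):
    """Locate low/high tide times in a depth series.

    The depth record is smoothed with a centred rolling mean (~2 h wide)
    and local extrema are found with a minimum same-kind separation
    (default 8 h, suited to semidiurnal tides). Alternation is enforced by
    keeping the more extreme of adjacent same-kind events. Records whose
    smoothed depth range is below ``NONTIDAL_DEPTH_RANGE`` are classified
    nontidal and return an empty list.
    """
    depth = depth.dropna()
    if len(depth) < 4:
        return []
    step_h = pd.Series(depth.index).diff().median().total_seconds() / 3600.0
    win = max(3, int(round(2.0 / step_h)) | 1)
    smooth = depth.rolling(win, center=True, min_periods=1).mean()
    if smooth.max() - smooth.min() < NONTIDAL_DEPTH_RANGE:
        return []
    dist = max(1, int(round(min_separation_h / step_h)))
    vals = smooth.to_numpy()
    highs, _ = signal.find_peaks(vals, distance=dist)
    lows, _ = signal.find_peaks(-vals, distance=dist)
    events = sorted(
        [(depth.index[i], "high") for i in highs] + [(depth.index[i], "low") for i in lows]
    )
    # enforce alternation: among adjacent same-kind events keep the more extreme
    cleaned = []
    for t, kind in events:
        if cleaned and cleaned[-1][1] == kind:
            prev_t, _ = cleaned[-1]
            prev_v, cur_v = smooth.loc[prev_t], smooth.loc[t]
            better = (cur_v > prev_v) if kind == "high" else (cur_v < prev_v)
            if better:
                cleaned[-1] = (t, kind)
        else:
            cleaned.append((t, kind))
    return cleaned


def day_night_anchors(index):
    """Local-noon (day) and local-midnight (night) anchors within a record."""
    start, end = index[0], index[-1]
    days = pd.date_range(start.normalize(), end.normalize(), freq="D")
    anchors = []
    for d in days:
        for t, kind in ((d + pd.Timedelta(hours=12), "day"), (d, "night")):
            if start <= t <= end:
                anchors.append((t, kind))
    anchors.sort()
    return anchors


def peak_hour_means(series, events, window_h=1.0, columns=None):
    """Mean of each channel within +/-window_h of each event time.

    ``events`` is a list of (timestamp, kind). Events whose window holds no
    samples are skipped (flag recorded on the returned list's ``.flags``
    via the third tuple element being None is avoided; skipped events are
    simply omitted and counted in the returned ``skipped`` value).

    Returns ``(rows, n_skipped)`` where rows are dicts with time, kind and
    per-channel means.
    """
    df = series.data if hasattr(series, "data") else series
    if columns is None:
        columns = list(df.columns)
    w = pd.Timedelta(hours=window_h)
    rows = []
    skipped = 0
    for t, kind in events:
        win = df.loc[t - w : t + w, columns]
        if win.dropna(how="all").empty:
            skipped += 1
            continue
        row = {"time": t, "kind": kind}
        row.update({c: float(win[c].mean()) for c in columns})
        rows.append(row)
    return rows, skipped


@dataclass
class TidalDielIndices:
    """Tidal and diurnal effect indices for one parameter.

    TEI = (eta_H - eta_L) / (2 eta_bar), DEI = (eta_D - eta_N) / (2 eta_bar),
    where eta_bar is the whole-record mean. Indices are computed per
    successive low-high (day-night) cycle and averaged; ``dominance`` is
    |TEI| / |DEI| (tidal control when > 1).
    """

    parameter: str
    eta_h: float
    eta_l: float
    eta_d: float
    eta_n: float
    eta_bar: float
    tei: float
    dei: float
    tei_per_cycle: list = field(default_factory=list)
    dei_per_cycle: list = field(default_factory=list)

    @property
    def dominance(self):
        if self.dei == 0 or not np.isfinite(self.dei):
            return float("inf") if self.tei else float("nan")
        return abs(self.tei) / abs(self.dei)

    def to_dict(self):
        d = {
            k: getattr(self, k)
            for k in ("parameter", "eta_h", "eta_l", "eta_d", "eta_n", "eta_bar", "tei", "dei")
        }
        d["dominance"] = self.dominance
        d["tei_per_cycle"] = list(self.tei_per_cycle)
        d["dei_per_cycle"] = list(self.dei_per_cycle)
        return d


def _successive_pairs(rows, first_kind, second_kind):
    pairs = []
    prev = None
    for row in rows:
        if row["kind"] == first_kind:
            prev = row
        elif row["kind"] == second_kind and prev is not None:
            pairs.append((prev, row))
            prev = None
    return pairs


def tidal_diel_indices(series, events, parameter):
    """Compute :class:`TidalDielIndices` for one parameter.

    ``events`` are tidal extremes from :func:`detect_tidal_extremes`; day
    and night anchors are derived from the record's clock (12:00 / 00:00
    local). Requires at least one complete low-high pair and one day-night
    pair; a nontidal record (no events) yields NaN tidal terms.
    """
    df = series.data
    eta_bar = float(df[parameter].mean())
    if eta_bar == 0 or not np.isfinite(eta_bar):
        raise ValueError("record mean is zero or undefined; indices undefined")
    tide_rows, _ = peak_hour_means(series, events, columns=[parameter])
    anchors = day_night_anchors(df.index)
    dn_rows, _ = peak_hour_means(series, anchors, columns=[parameter])

    def per_cycle(pairs):
        return [(b[parameter] - a[parameter]) / (2.0 * eta_bar) for a, b in pairs]

    # TEI is (high - low); successive low-high cycles
    tei_cycles = per_cycle(_successive_pairs(tide_rows, "low", "high"))
    # DEI is (day - night); successive day-night cycles
    dei_cycles = per_cycle(_successive_pairs(dn_rows, "night", "day"))

    def kind_mean(rows, kind):
        vals = [r[parameter] for r in rows if r["kind"] == kind]
        return float(np.mean(vals)) if vals else float("nan")

    return TidalDielIndices(
        parameter=parameter,
        eta_h=kind_mean(tide_rows, "high"),
        eta_l=kind_mean(tide_rows, "low"),
        eta_d=kind_mean(dn_rows, "day"),
        eta_n=kind_mean(dn_rows, "night"),
        eta_bar=eta_bar,
        tei=float(np.mean(tei_cycles)) if tei_cycles else float("nan"),
        dei=float(np.mean(dei_cycles)) if dei_cycles else float("nan"),
        tei_per_cycle=tei_cycles,
        dei_per_cycle=dei_cycles,
    )
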