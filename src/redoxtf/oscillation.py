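"""Windowed autocorrelation analysis of p53 traces.

p53 pulses with a ~5.5 h period in mildly stressed, surviving cells; in
doomed cells the rise is sustained instead.  The analysis window follows
the FOXO1-conditioned rule: for cells that never accumulate FOXO1 in the
nucleus, the first 10 h of the movie; for cells with a completed nuclear
episode, the 10 h after FOXO1 exits; cells whose episode never closes are
excluded.  The sample autocorrelation of the (optionally detrended)
window is scanned for a peak in the 3-8 h lag band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import ActivationThresholds, FoxoEpisodes
from .alignment import compute_events
from .trace_io import CellTrace, iter_traces

__all__ = [
    "AcfResult",
    "select_acf_window",
    "acf",
    "windowed_acf",
    "classify_oscillation",
    "compare_fates",
]

WINDOW_HOURS = 10.0
DEFAULT_LAG_BAND = (3.0, 8.0)
MIN_VALID_FRAMES = 8


@dataclass
class AcfResult:
    """Sample autocorrelation of one cell's p53 window."""

    cell_id: str
    window: tuple[float, float] | None
    lags: np.ndarray          # hours
    r: np.ndarray             # r[0] = 1
    n_points: int
    truncated: bool = False
    zero_variance: bool = False
    oscillation_score: float | None = None
    is_oscillatory: bool | None = None


def select_acf_window(
    episodes: FoxoEpisodes, t_last: float
) -> tuple[float, float, bool] | None:
    """[start, end, truncated] of the p53 autocorrelation window.

    No FOXO1 episode: the first 10 h.  Completed episode with exit at T:
    [T, T + 10 h].  Windows running past the last observed frame are
    truncated (flagged); cells with an open episode return None.
    """
    if episodes.primary is None:
        start = 0.0
    else:
        exit_time = episodes.exit_time
        if exit_time is None:
            return None
        start = exit_time
    end = start + WINDOW_HOURS
    truncated = end > t_last + 1e-9
    if truncated:
        end = t_last
    return (start, end, truncated)


def acf(series: np.ndarray, max_lag_frames: int | None = None) -> np.ndarray:
    """Sample autocorrelation r(k) = sum (x_t - m)(x_{t+k} - m) / sum (x_t - m)^2.

    ``m`` is the window mean; r(0) = 1.  Raises on zero variance or fewer
    than 8 valid frames.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < MIN_VALID_FRAMES:
        raise ValueError(f"need >= {MIN_VALID_FRAMES} valid frames, got {len(x)}")
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom <= 0:
        raise ZeroDivisionError("zero-variance series has undefined autocorrelation")
    if max_lag_frames is None:
        max_lag_frames = len(x) - 1
    max_lag_frames = min(max_lag_frames, len(x) - 1)
    r = np.empty(max_lag_frames + 1)
    for k in range(max_lag_frames + 1):
        r[k] = float(np.dot(xc[: len(x) - k], xc[k:])) / denom
    return r


def windowed_acf(
    trace: CellTrace,
    episodes: FoxoEpisodes,
    detrend: bool = True,
    lag_band: tuple[float, float] = DEFAULT_LAG_BAND,
    r_min: float = 0.2,
) -> AcfResult | None:
    """Full per-cell pipeline: window rule, ACF, oscillation call.

    Returns None for cells excluded by the window rule (open episode) or
    with too few valid frames in-window (e.g. early death).  A linear
    detrend (default on) removes monotone post-exit rises that would
    otherwise masquerade as long-lag structure.
    """
    t_last = trace.last_observed_time
    if t_last is None:
        return None
    sel = select_acf_window(episodes, t_last)
    if sel is None:
        return None
    start, end, truncated = sel
    mask = (trace.t >= start - 1e-9) & (trace.t <= end + 1e-9)
    x = trace.p53_nuc[mask]
    x = x[np.isfinite(x)]
    if len(x) < MIN_VALID_FRAMES:
        return None
    scale = max(1.0, float(np.abs(np.mean(x))))
    if detrend:
        x = x - np.polyval(np.polyfit(np.arange(len(x)), x, 1), np.arange(len(x)))
    dt = trace.dt
    try:
        if np.std(x) <= 1e-9 * scale:
            raise ZeroDivisionError
        r = acf(x)
    except ZeroDivisionError:
        return AcfResult(
            cell_id=trace.cell_id, window=(start, end), lags=np.array([0.0]),
            r=np.array([1.0]), n_points=len(x), truncated=truncated,
            zero_variance=True,
        )
    lags = np.arange(len(r)) * dt
    result = AcfResult(
        cell_id=trace.cell_id, window=(start, end), lags=lags, r=r,
        n_points=len(x), truncated=truncated,
    )
    classify_oscillation(result, lag_band=lag_band, r_min=r_min)
    return result


def classify_oscillation(
    result: AcfResult,
    lag_band: tuple[float, float] = DEFAULT_LAG_BAND,
    r_min: float = 0.2,
) -> bool | None:
    """Oscillation call: peak ACF in the lag band above a noise floor.

    ``oscillation_score`` is the maximum r over lags in ``lag_band``
    (intersected with the available lags; short windows are flagged via
    ``truncated``); the call compares it against
    ``max(r_min, 2 / sqrt(n_points))``.  Mutates and returns the result.
    """
    if result.zero_variance:
        result.oscillation_score = None
        result.is_oscillatory = None
        return None
    band = (result.lags >= lag_band[0] - 1e-9) & (result.lags <= lag_band[1] + 1e-9)
    if not band.any():
        result.oscillation_score = None
        result.is_oscillatory = None
        return None
    score = float(np.max(result.r[band]))
    result.oscillation_score = score
    result.is_oscillatory = bool(score > max(r_min, 2.0 / np.sqrt(result.n_points)))
    return result.is_oscillatory


def compare_fates(
    traces: pd.DataFrame,
    events: dict[str, FoxoEpisodes] | None = None,
    thresholds: ActivationThresholds = ActivationThresholds(),
    detrend: bool = True,
    r_min: float = 0.2,
    n_min: int = 5,
) -> dict:
    """Median +/- MAD ACF curves and oscillation calls, dying vs surviving.

    Returns a dict with per-group ``{'lags', 'median', 'mad', 'n_cells',
    'scores', 'oscillatory_fraction'}`` under keys ``'dying'`` and
    ``'surviving'`` (a group with fewer than ``n_min`` usable cells is
    None), plus ``'n_excluded'``.
    """
    if events is None:
        events = compute_events(traces, thresholds)
    groups: dict[str, list[AcfResult]] = {"dying": [], "surviving": []}
    n_excluded = 0
    for tr in iter_traces(traces):
        res = windowed_acf(tr, events[tr.cell_id], detrend=detrend, r_min=r_min)
        if res is None or res.zero_variance:
            n_excluded += 1
            continue
        groups["dying" if tr.death_time is not None else "surviving"].append(res)

    out: dict = {"n_excluded": n_excluded}
    for name, results in groups.items():
        if len(results) < n_min:
            out[name] = None
            continue
        max_len = max(len(r.r) for r in results)
        mat = np.full((len(results), max_len), np.nan)
        for i, r in enumerate(results):
            mat[i, : len(r.r)] = r.r
        n = np.sum(np.isfinite(mat), axis=0)
        med = np.full(max_len, np.nan)
        mad = np.full(max_len, np.nan)
        for k in np.flatnonzero(n >= n_min):
            col = mat[:, k][np.isfinite(mat[:, k])]
            med[k] = np.median(col)
            mad[k] = np.median(np.abs(col - med[k]))
        dt = results[0].lags[1] - results[0].lags[0] if len(results[0].lags) > 1 else np.nan
        scores = np.array([
            r.oscillation_score for r in results if r.oscillation_score is not None
        ])
        calls = [r.is_oscillatory for r in results if r.is_oscillatory is not None]
        out[name] = {
            "lags": np.arange(max_len) * dt,
            "median": med,
            "mad": mad,
            "n_cells": len(results),
            "scores": scores,
            "oscillatory_fraction": float(np.mean(calls)) if calls else np.nan,
        }
    return out
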