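"""Activation-event detection on single-cell traces.

FOXO1 nuclear episodes are called with a hysteresis rule on the (smoothed)
nuclear fraction: a cell *enters* at the first of ``persistence``
consecutive frames at or above ``foxo_hi`` and *exits* at the first of
``persistence`` consecutive frames at or below ``foxo_lo``.  Episodes that
are still open at the end of the movie (or at death) have no exit and are
counted to the last observed frame.  p53 accumulation onset is the first
time the trace stays above ``baseline + p53_mad_mult * MAD`` for
``onset_run`` consecutive frames, with the baseline taken from the first
three frames.  Only pre-death samples participate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trace_io import CellTrace

__all__ = [
    "ActivationThresholds",
    "FoxoEpisodes",
    "P53Onset",
    "smooth_trace",
    "detect_foxo1_episodes",
    "detect_p53_onset",
    "p53_rate",
]


@dataclass(frozen=True)
class ActivationThresholds:
    """Thresholds for episode and onset calling.

    The enter/exit pair implements hysteresis (``foxo_lo <= foxo_hi``);
    ``persistence`` frames are required to change state, which at 20-min
    sampling suppresses single-frame noise excursions.
    """

    foxo_hi: float = 0.55
    foxo_lo: float = 0.45
    persistence: int = 2
    p53_mad_mult: float = 3.0
    onset_run: int = 3
    #: lower bound on the noise-scale estimate, as a fraction of baseline --
    #: a 3-frame MAD is a fragile estimator and can collapse to ~0 by chance
    p53_rel_floor: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.foxo_lo <= self.foxo_hi < 1:
            raise ValueError("need 0 < foxo_lo <= foxo_hi < 1")
        if self.persistence < 1 or self.onset_run < 1:
            raise ValueError("persistence and onset_run must be >= 1")


@dataclass
class FoxoEpisodes:
    """Detected nuclear episodes of a shuttling TF for one cell.

    ``episodes`` is a list of ``(entry_time, exit_time)`` with ``exit_time
    = None`` for episodes open at the last observed frame.
    ``nuclear_duration`` sums all episode lengths (open episodes counted to
    the last observed frame).  ``primary`` indexes the longest episode.
    """

    cell_id: str
    episodes: list[tuple[float, float | None]] = field(default_factory=list)
    nuclear_duration: float = 0.0
    primary: int | None = None
    all_missing: bool = False

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)

    @property
    def entry_time(self) -> float | None:
        """Entry of the primary (longest) episode."""
        return self.episodes[self.primary][0] if self.primary is not None else None

    @property
    def exit_time(self) -> float | None:
        """Exit of the primary episode (None if open)."""
        return self.episodes[self.primary][1] if self.primary is not None else None


@dataclass
class P53Onset:
    cell_id: str
    onset_time: float | None
    baseline: float
    baseline_mad: float


def smooth_trace(series: np.ndarray, width: int = 3) -> np.ndarray:
    """Centered running median; shrunken windows at the edges.

    Missing (NaN) samples stay missing and do not contaminate neighbours.
    """
    if width % 2 == 0:
        raise ValueError("width must be odd")
    x = np.asarray(series, dtype=float)
    half = width // 2
    out = np.full_like(x, np.nan)
    for i in range(len(x)):
        if not np.isfinite(x[i]):
            continue
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        window = x[lo:hi]
        out[i] = np.nanmedian(window)
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of maximal True runs."""
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def detect_foxo1_episodes(
    trace: CellTrace,
    thresholds: ActivationThresholds = ActivationThresholds(),
    smooth_width: int = 3,
) -> FoxoEpisodes:
    """Hysteresis episode calling on the smoothed FOXO1 nuclear fraction."""
    obs = np.isfinite(trace.foxo1_nuc_frac)
    if not obs.any():
        return FoxoEpisodes(cell_id=trace.cell_id, all_missing=True)
    f = smooth_trace(trace.foxo1_nuc_frac, smooth_width)
    idx = np.flatnonzero(np.isfinite(f))
    t = trace.t[idx]
    fv = f[idx]
    k = thresholds.persistence

    # sustained-crossing start indices, computed on observed frames
    hi_ok = _sustained(fv >= thresholds.foxo_hi, k)
    lo_ok = _sustained(fv <= thresholds.foxo_lo, k)

    episodes: list[tuple[float, float | None]] = []
    state = "out"
    entry_t: float | None = None
    for i in range(len(fv)):
        if state == "out" and hi_ok[i]:
            state = "in"
            entry_t = float(t[i])
        elif state == "in" and lo_ok[i]:
            episodes.append((entry_t, float(t[i])))
            state = "out"
            entry_t = None
    if state == "in":
        episodes.append((entry_t, None))

    last_t = float(t[-1])
    lengths = [((last_t if ex is None else ex) - en) for en, ex in episodes]
    duration = float(sum(lengths))
    primary = int(np.argmax(lengths)) if episodes else None
    return FoxoEpisodes(
        cell_id=trace.cell_id,
        episodes=episodes,
        nuclear_duration=duration,
        primary=primary,
    )


def _sustained(cond: np.ndarray, k: int) -> np.ndarray:
    """True where ``cond`` holds here and for the next k-1 frames."""
    out = np.zeros(len(cond), dtype=bool)
    run = 0
    for i in range(len(cond) - 1, -1, -1):
        run = run + 1 if cond[i] else 0
        out[i] = run >= k
    return out


def detect_p53_onset(
    trace: CellTrace,
    thresholds: ActivationThresholds = ActivationThresholds(),
    after: float = 0.0,
) -> P53Onset:
    """First sustained rise of p53 above its early baseline.

    Baseline and its MAD come from the first three frames (which must be
    observed); onset is the first time ``>= after`` at which p53 exceeds
    ``baseline + p53_mad_mult * MAD`` for ``onset_run`` consecutive
    observed frames.
    """
    p = np.asarray(trace.p53_nuc, dtype=float)
    if len(p) < 3 or not np.all(np.isfinite(p[:3])):
        raise ValueError(f"cell {trace.cell_id}: baseline window (first 3 frames) missing")
    baseline = float(np.median(p[:3]))
    # 1.4826 makes the MAD a consistent sigma estimate for Gaussian noise;
    # the relative floor guards against the 3-point MAD collapsing to ~0
    mad = 1.4826 * float(np.median(np.abs(p[:3] - baseline)))
    scale = max(mad, thresholds.p53_rel_floor * abs(baseline))
    thr = baseline + thresholds.p53_mad_mult * scale

    idx = np.flatnonzero(np.isfinite(p))
    t = trace.t[idx]
    keep = t >= after
    idx, t = idx[keep], t[keep]
    above = p[idx] > thr
    ok = _sustained(above, thresholds.onset_run)
    hits = np.flatnonzero(ok)
    onset = float(t[hits[0]]) if hits.size else None
    return P53Onset(cell_id=trace.cell_id, onset_time=onset, baseline=baseline, baseline_mad=mad)


def p53_rate(trace: CellTrace) -> np.ndarray:
    """Time derivative of the p53 channel in AU per hour.

    Central differences in the interior, one-sided at the first and last
    valid frames; NaN propagates.  Fewer than 3 valid points gives an
    all-missing series.
    """
    p = np.asarray(trace.p53_nuc, dtype=float)
    dt = trace.dt
    out = np.full_like(p, np.nan)
    if np.sum(np.isfinite(p)) < 3:
        return out
    n = len(p)
    for i in range(n):
        if not np.isfinite(p[i]):
            continue
        prev_ok = i > 0 and np.isfinite(p[i - 1])
        next_ok = i < n - 1 and np.isfinite(p[i + 1])
        if prev_ok and next_ok:
            out[i] = (p[i + 1] - p[i - 1]) / (2 * dt)
        elif next_ok:
            out[i] = (p[i + 1] - p[i]) / dt
        elif prev_ok:
            out[i] = (p[i] - p[i - 1]) / dt
    return out
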