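"""Event-aligned trace aggregation and heat-map sort orders.

Heat maps of single-cell traces are sorted either by FOXO1 nuclear
residence duration (acute-exposure figures, longest on top) or by FOXO1
nuclear entry time (continuous-exposure figures, earliest on top).
Event-aligned ensembles re-index each cell's trace to lag = t - t_anchor
(anchor = FOXO1 exit or entry of the primary episode) and summarize each
lag by the median and the median absolute deviation (MAD) over the
contributing cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import ActivationThresholds, FoxoEpisodes, detect_foxo1_episodes, detect_p53_onset
from .trace_io import CellTrace, iter_traces

__all__ = [
    "AlignedEnsemble",
    "compute_events",
    "sort_order",
    "align_traces",
    "lag_statistic",
]


@dataclass
class AlignedEnsemble:
    """Event-aligned trace matrix with per-lag robust summaries.

    ``matrix`` is (n_cells, n_lags) with NaN outside each cell's
    observation window; ``median``/``mad`` are NaN where fewer than
    ``n_min`` cells contribute (``n`` carries the count regardless).
    """

    lags: np.ndarray
    cell_ids: list[str]
    matrix: np.ndarray
    median: np.ndarray
    mad: np.ndarray
    n: np.ndarray
    n_min: int
    n_excluded: int

    @property
    def is_empty(self) -> bool:
        return self.matrix.shape[0] == 0


def compute_events(
    traces: pd.DataFrame, thresholds: ActivationThresholds = ActivationThresholds()
) -> dict[str, FoxoEpisodes]:
    """FOXO1 episodes for every cell in a tidy trace table, keyed by cell id."""
    return {
        tr.cell_id: detect_foxo1_episodes(tr, thresholds) for tr in iter_traces(traces)
    }


def sort_order(events: dict[str, FoxoEpisodes], key: str = "duration") -> list[str]:
    """Heat-map row order.

    ``key='duration'`` sorts by nuclear residence duration, longest first;
    ``key='entry_time'`` sorts by primary-episode entry, earliest first.
    Cells without an episode go last; ties break by cell_id (stable).
    """
    ids = sorted(events)
    if key == "duration":
        def keyfun(cid):
            ep = events[cid]
            has = ep.primary is not None
            return (0 if has else 1, -ep.nuclear_duration if has else 0.0, cid)
    elif key == "entry_time":
        def keyfun(cid):
            ep = events[cid]
            has = ep.primary is not None
            return (0 if has else 1, ep.entry_time if has else 0.0, cid)
    else:
        raise ValueError("key must be 'duration' or 'entry_time'")
    return sorted(ids, key=keyfun)


def align_traces(
    traces: pd.DataFrame,
    events: dict[str, FoxoEpisodes],
    anchor: str = "foxo_exit",
    channel: str = "p53_nuc",
    window: float = 10.0,
    n_min: int = 5,
) -> AlignedEnsemble:
    """Align each cell's ``channel`` to its primary-episode event time.

    ``anchor`` is ``'foxo_exit'`` or ``'foxo_entry'``.  Cells lacking the
    anchor event are excluded and counted in ``n_excluded``.
    """
    if anchor not in ("foxo_exit", "foxo_entry"):
        raise ValueError("anchor must be 'foxo_exit' or 'foxo_entry'")
    cell_list = list(iter_traces(traces))
    if not cell_list:
        return _empty_ensemble(window, 1.0 / 3.0, n_min, 0)
    dt = cell_list[0].dt
    n_lag_half = int(round(window / dt))
    lags = np.arange(-n_lag_half, n_lag_half + 1) * dt

    rows, ids = [], []
    n_excluded = 0
    for tr in cell_list:
        ep = events.get(tr.cell_id)
        t_anchor = None
        if ep is not None and ep.primary is not None:
            t_anchor = ep.exit_time if anchor == "foxo_exit" else ep.entry_time
        if t_anchor is None:
            n_excluded += 1
            continue
        values = getattr(tr, _channel_attr(channel))
        i_anchor = int(round(t_anchor / dt))
        row = np.full(len(lags), np.nan)
        for k in range(len(lags)):
            i = i_anchor + k - n_lag_half
            if 0 <= i < len(values):
                row[k] = values[i]
        rows.append(row)
        ids.append(tr.cell_id)

    if not rows:
        return _empty_ensemble(window, dt, n_min, n_excluded)
    matrix = np.vstack(rows)
    n = np.sum(np.isfinite(matrix), axis=0)
    med = np.full(len(lags), np.nan)
    mad = np.full(len(lags), np.nan)
    enough = n >= n_min
    for k in np.flatnonzero(enough):
        col = matrix[:, k]
        col = col[np.isfinite(col)]
        med[k] = np.median(col)
        mad[k] = np.median(np.abs(col - med[k]))
    return AlignedEnsemble(
        lags=lags, cell_ids=ids, matrix=matrix, median=med, mad=mad,
        n=n, n_min=n_min, n_excluded=n_excluded,
    )


def _channel_attr(channel: str) -> str:
    mapping = {"p53_nuc": "p53_nuc", "foxo1_nuc_frac": "foxo1_nuc_frac"}
    if channel not in mapping:
        raise ValueError(f"unknown channel {channel!r}")
    return mapping[channel]


def _empty_ensemble(window, dt, n_min, n_excluded) -> AlignedEnsemble:
    n_half = int(round(window / dt))
    lags = np.arange(-n_half, n_half + 1) * dt
    empty = np.empty((0, len(lags)))
    nanrow = np.full(len(lags), np.nan)
    return AlignedEnsemble(
        lags=lags, cell_ids=[], matrix=empty, median=nanrow.copy(),
        mad=nanrow.copy(), n=np.zeros(len(lags), dtype=int),
        n_min=n_min, n_excluded=n_excluded,
    )


def lag_statistic(
    traces: pd.DataFrame,
    events: dict[str, FoxoEpisodes] | None = None,
    thresholds: ActivationThresholds = ActivationThresholds(),
) -> dict:
    """Per-cell (p53 onset - FOXO1 exit) lag, with cohort median and MAD.

    Only cells with both a detected exit and a detected p53 onset
    contribute; negative lags (onset before exit) are kept and reported.
    Returns ``{'per_cell': DataFrame, 'median': float|None, 'mad':
    float|None, 'n': int}``.
    """
    if events is None:
        events = compute_events(traces, thresholds)
    records = []
    for tr in iter_traces(traces):
        ep = events.get(tr.cell_id)
        if ep is None or ep.primary is None or ep.exit_time is None:
            continue
        try:
            onset = detect_p53_onset(tr, thresholds)
        except ValueError:
            continue
        if onset.onset_time is None:
            continue
        records.append(
            {
                "cell_id": tr.cell_id,
                "foxo_exit": ep.exit_time,
                "p53_onset": onset.onset_time,
                "lag_h": onset.onset_time - ep.exit_time,
            }
        )
    per_cell = pd.DataFrame.from_records(
        records, columns=["cell_id", "foxo_exit", "p53_onset", "lag_h"]
    )
    if per_cell.empty:
        return {"per_cell": per_cell, "median": None, "mad": None, "n": 0}
    lags = per_cell["lag_h"].to_numpy()
    med = float(np.median(lags))
    return {
        "per_cell": per_cell,
        "median": med,
        "mad": float(np.median(np.abs(lags - med))),
        "n": len(lags),
    }
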