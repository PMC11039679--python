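"""Fixed-timepoint quadrant classification and dose-response summaries.

A snapshot assigns each cell two activation readouts: a level channel
(log nuclear p53 by default) and a shuttling channel (FOXO1 nuclear
fraction by default).  Activation cuts are estimated as a high quantile
(default 95th percentile) of the untreated control distribution of each
channel; each cell then falls in one of four quadrants -- both active,
shuttling-TF only, level-TF only, or neither.  The same operation serves
any level/shuttling TF pair (e.g. p53 against RELA or NFAT1) by renaming
the channels.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "QuadrantThresholds",
    "estimate_thresholds",
    "quadrant_classify",
    "dose_response_table",
    "LABELS",
]

LABELS = ("both", "foxo1_only", "p53_only", "neither")
MIN_CONTROL_CELLS = 50


@dataclass(frozen=True)
class QuadrantThresholds:
    """Activation cuts for the two snapshot channels."""

    log_p53_cut: float
    foxo_frac_cut: float
    source: str = "control_quantile"
    quantile: float = 0.95

    def __post_init__(self) -> None:
        if not (np.isfinite(self.log_p53_cut) and np.isfinite(self.foxo_frac_cut)):
            raise ValueError("thresholds must be finite")
        if self.source == "control_quantile" and not 0.5 < self.quantile < 1:
            raise ValueError("quantile must lie in (0.5, 1)")


def estimate_thresholds(
    control_snapshot: pd.DataFrame,
    quantile: float = 0.95,
    level_channel: str = "log_p53",
    shuttle_channel: str = "foxo1_nuc_frac",
) -> QuadrantThresholds:
    """Control-quantile activation cuts from an untreated snapshot."""
    n = len(control_snapshot)
    if n < MIN_CONTROL_CELLS:
        raise ValueError(
            f"need >= {MIN_CONTROL_CELLS} control cells to set thresholds, got {n}"
        )
    return QuadrantThresholds(
        log_p53_cut=float(np.quantile(control_snapshot[level_channel], quantile)),
        foxo_frac_cut=float(np.quantile(control_snapshot[shuttle_channel], quantile)),
        quantile=quantile,
    )


def quadrant_classify(
    snapshot: pd.DataFrame,
    thresholds: QuadrantThresholds,
    level_channel: str = "log_p53",
    shuttle_channel: str = "foxo1_nuc_frac",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label each cell and summarize fractions per dose.

    A cell is active on a channel when strictly above the cut.  Returns
    ``(labelled_snapshot, summary)``; the summary has one row per dose
    with columns ``n`` and the four label fractions (summing to 1).
    """
    level_on = snapshot[level_channel].to_numpy() > thresholds.log_p53_cut
    shuttle_on = snapshot[shuttle_channel].to_numpy() > thresholds.foxo_frac_cut
    label = np.where(
        level_on & shuttle_on, "both",
        np.where(shuttle_on, "foxo1_only", np.where(level_on, "p53_only", "neither")),
    )
    labelled = snapshot.assign(label=label)
    rows = []
    for dose, sub in labelled.groupby("dose", sort=True):
        counts = sub["label"].value_counts()
        n = len(sub)
        rows.append(
            {"dose": dose, "n": n, **{lb: counts.get(lb, 0) / n for lb in LABELS}}
        )
    summary = pd.DataFrame(rows, columns=["dose", "n", *LABELS])
    return labelled, summary


def dose_response_table(summary: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Tidy (dose x label) fractions plus the mutual-exclusivity statistic.

    The statistic is the maximum both-active fraction across doses, the
    quantity bounded by ~5% when the two TF programs are mutually
    exclusive.  Empty dose groups are dropped with a warning.
    """
    keep = summary["n"] > 0
    if (~keep).any():
        warnings.warn(
            f"dropping {int((~keep).sum())} empty dose group(s)", stacklevel=2
        )
    summary = summary.loc[keep]
    tidy = summary.melt(
        id_vars=["dose", "n"], value_vars=list(LABELS),
        var_name="label", value_name="fraction",
    ).sort_values(["dose", "label"], ignore_index=True)
    max_both = float(summary["both"].max()) if len(summary) else float("nan")
    return tidy, max_both
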