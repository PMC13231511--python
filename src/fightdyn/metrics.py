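"""Per-fish summary fight statistics.

The metrics follow the activity vector sum (ActVSum) channel: overall effort
(mean, CV, cumulative sum), burstiness (run-length encoded exceedances of a
1.25 g s^-1 threshold), phase structure (mean intensity of the first and last
third of the fight) and a fatigue index (non-negative rate of decline in
ActVSum after peak effort).  Fight duration is carried alongside but is
excluded from the PCA input because of its strong correlation with the other
metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DegenerateColumnError, DomainError, SizeError
from .io import CaptureDataset, JerkTrace
from .preprocess import zscore

#: Default burst threshold (g s^-1): a conservative exceedance level for
#: discrete burst events, configurable per run.
BURST_THRESHOLD = 1.25

METRIC_COLUMNS = [
    "mean_actvsum",
    "cv_actvsum",
    "total_effort",
    "n_bursts",
    "early_intensity",
    "late_intensity",
    "fatigue_index",
]


@dataclass
class FightMetrics:
    """Summary statistics of one fish's fight."""

    fish_id: str
    fight_duration: float
    mean_actvsum: float
    cv_actvsum: float
    total_effort: float
    n_bursts: int
    early_intensity: float
    late_intensity: float
    early_late_ratio: float
    fatigue_index: float


def count_bursts(actvsum, threshold: float = BURST_THRESHOLD, min_run: int = 1) -> int:
    """Number of maximal runs of consecutive samples strictly above threshold.

    ``min_run`` sets the minimum run length that counts as a burst (default 1:
    a single exceedance is a burst).
    """
    x = np.asarray(actvsum, dtype=float)
    if x.size == 0:
        raise SizeError("count_bursts needs a non-empty sequence")
    above = x > threshold
    # run-length encoding: a burst starts at each False->True transition
    starts = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    if min_run <= 1:
        return int(starts.size)
    ends = np.flatnonzero(above & ~np.concatenate([above[1:], [False]]))
    return int(np.sum(ends - starts + 1 >= min_run))


def basic_metrics(trace: JerkTrace, duration: Optional[float] = None) -> dict:
    """Mean ActVSum, its CV (sample SD / mean) and total effort (cumulative sum)."""
    if len(trace) < 3:
        raise SizeError("basic_metrics needs a trace of length >= 3")
    x = trace.actvsum
    mean = float(x.mean())
    if mean == 0:
        raise DomainError("mean ActVSum is zero; CV undefined")
    return {
        "mean_actvsum": mean,
        "cv_actvsum": float(x.std(ddof=1) / mean),
        "total_effort": float(x.sum()),
        "fight_duration": float(duration if duration is not None else trace.duration),
    }


def phase_intensities(actvsum) -> tuple[float, float, float]:
    """Mean ActVSum over the first and last third of the fight, and their ratio.

    Thirds are floor(n/3) samples (minimum 1) so short fights still get a
    defined early and late phase.
    """
    x = np.asarray(actvsum, dtype=float)
    n = len(x)
    if n < 3:
        raise SizeError("phase_intensities needs >= 3 samples")
    m = max(n // 3, 1)
    early = float(x[:m].mean())
    late = float(x[-m:].mean())
    if late == 0:
        raise DomainError("late intensity is zero; early/late ratio undefined")
    return early, late, early / late


def fatigue_index(actvsum) -> float:
    """Non-negative rate of decline in ActVSum after initial peak effort.

    Takes the first global maximum as the peak, fits an ordinary least-squares
    line to ActVSum versus sample index from the peak to the end (peak
    included) and reports max(0, -slope) in g s^-1 per sample step.  Returns 0
    when fewer than 3 samples follow the peak.
    """
    x = np.asarray(actvsum, dtype=float)
    if x.size == 0:
        raise SizeError("fatigue_index needs a non-empty sequence")
    p = int(np.argmax(x))  # first global maximum
    if x.size - 1 - p < 3:
        return 0.0
    seg = x[p:]
    idx = np.arange(len(seg), dtype=float)
    slope = float(np.polyfit(idx, seg, 1)[0])
    return max(0.0, -slope)


def inter_axis_correlations(trace: JerkTrace) -> tuple[float, float, float, float]:
    """Pairwise Pearson correlations between the X, Y and Z axes, plus their mean."""
    if len(trace) < 3:
        raise SizeError("inter_axis_correlations needs >= 3 samples")
    axes = trace.axes()
    if np.any(axes.std(axis=0) == 0):
        raise DegenerateColumnError(f"trace {trace.fish_id!r}: constant axis")
    r = np.corrcoef(axes, rowvar=False)
    r_xy, r_yz, r_xz = float(r[0, 1]), float(r[1, 2]), float(r[0, 2])
    return r_xy, r_yz, r_xz, float(np.mean([r_xy, r_yz, r_xz]))


def compute_metrics(
    trace: JerkTrace,
    duration: Optional[float] = None,
    burst_threshold: float = BURST_THRESHOLD,
    min_run: int = 1,
) -> FightMetrics:
    """All summary fight metrics for one fish."""
    basics = basic_metrics(trace, duration)
    early, late, ratio = phase_intensities(trace.actvsum)
    return FightMetrics(
        fish_id=trace.fish_id,
        fight_duration=basics["fight_duration"],
        mean_actvsum=basics["mean_actvsum"],
        cv_actvsum=basics["cv_actvsum"],
        total_effort=basics["total_effort"],
        n_bursts=count_bursts(trace.actvsum, burst_threshold, min_run),
        early_intensity=early,
        late_intensity=late,
        early_late_ratio=ratio,
        fatigue_index=fatigue_index(trace.actvsum),
    )


def metrics_table(
    dataset: CaptureDataset, burst_threshold: float = BURST_THRESHOLD, min_run: int = 1
) -> pd.DataFrame:
    """Raw (un-standardized) fish x metric table including fight_duration."""
    rows = []
    for fid in dataset.fish_ids:
        rec = dataset.records.get(fid)
        duration = rec.fight_duration if rec is not None else None
        m = compute_metrics(dataset.traces[fid], duration, burst_threshold, min_run)
        rows.append(
            {
                "fish_id": m.fish_id,
                **{c: getattr(m, c) for c in METRIC_COLUMNS},
                "early_late_ratio": m.early_late_ratio,
                "fight_duration": m.fight_duration,
            }
        )
    return pd.DataFrame(rows).set_index("fish_id")


def metrics_matrix(
    dataset: CaptureDataset, burst_threshold: float = BURST_THRESHOLD, min_run: int = 1
) -> pd.DataFrame:
    """Z-scored fish x metric matrix for ordination.

    Columns are the seven summary metrics; fight_duration is retained as a
    side column named ``fight_duration`` but must not enter the PCA input.
    """
    raw = metrics_table(dataset, burst_threshold, min_run)
    out = {}
    for col in METRIC_COLUMNS:
        try:
            out[col] = zscore(raw[col].to_numpy())
        except DegenerateColumnError as exc:
            raise DegenerateColumnError(f"metric column {col!r} is degenerate") from exc
    z = pd.DataFrame(out, index=raw.index)
    z["fight_duration"] = raw["fight_duration"]
    return z
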