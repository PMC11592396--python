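"""Per-second regressor construction aligned to band-power bins.

Both the behavioural pleasure trace and the per-event surprisal series are
reduced to one value per 1-s bin on the same piece-start-anchored grid the
band power uses, so fitting pairs values with identical bin edges. Bins
with no information (no note events) carry an invalid mask rather than a
fabricated value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .surprisal import SurpriseSeries
from .synthetic import RatingSeries

__all__ = ["RegressorSeries", "ratings_to_regressor", "ic_to_regressor",
           "rating_series_to_regressor"]


@dataclass
class RegressorSeries:
    """Float value + validity mask per 1-s bin.

    ``kind`` is ``pleasure``, ``ic_melody`` or ``ic_harmony``. Masked-out
    bins are excluded from any fit that uses this series.
    """

    kind: str
    values: np.ndarray
    valid: np.ndarray
    piece_id: str = ""
    subject_id: str = ""
    flagged_constant: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid mask must have equal length")

    def __len__(self) -> int:
        return self.values.size


def ratings_to_regressor(
    trace: Sequence[Tuple[float, int]],
    piece_duration_s: float,
    kind: str = "pleasure",
    lag_s: float = 0.0,
) -> RegressorSeries:
    """Bin a raw key-press trace into per-second mean pleasure.

    ``trace`` is (time_s, value) pairs; the held key is a step function and
    each 1-s bin takes its time-weighted mean, so fractional values occur in
    bins containing a key change. Bins before the first press are neutral
    (1). ``lag_s`` shifts the trace earlier for sensitivity analyses
    (default 0: no lag correction).
    """
    n_bins = int(piece_duration_s)
    if not trace:
        return RegressorSeries(kind, np.ones(n_bins), np.ones(n_bins, dtype=bool),
                               flagged_constant=True)
    events = sorted(trace)
    for t, v in events:
        if not (1 <= v <= 4):
            raise ValueError(f"press value {v} outside 1..4")
        if not (0 <= t <= piece_duration_s):
            raise ValueError(f"press time {t} outside [0, {piece_duration_s}]")
    # step function: value 1 before the first press
    times = np.array([0.0] + [t - lag_s for t, _ in events] + [piece_duration_s])
    values = np.array([1.0] + [float(v) for _, v in events])
    out = np.empty(n_bins)
    for b in range(n_bins):
        lo, hi = float(b), float(b + 1)
        acc = 0.0
        for i in range(len(values)):
            seg_lo, seg_hi = times[i], times[i + 1]
            overlap = max(0.0, min(hi, seg_hi) - max(lo, seg_lo))
            acc += overlap * values[i]
        out[b] = acc
    return RegressorSeries(kind, out, np.ones(n_bins, dtype=bool),
                           flagged_constant=bool(np.all(out == out[0])))


def rating_series_to_regressor(rating: RatingSeries) -> RegressorSeries:
    """Adapt an already-binned integer rating series to a regressor."""
    vals = rating.values.astype(float)
    return RegressorSeries(
        "pleasure", vals, np.ones(vals.size, dtype=bool),
        piece_id=rating.piece_id, subject_id=rating.subject_id,
        flagged_constant=bool(vals.size and np.all(vals == vals[0])),
    )


def ic_to_regressor(
    series: SurpriseSeries,
    piece_duration_s: float,
    kind: str | None = None,
) -> RegressorSeries:
    """Per-bin mean information content; note-free bins are masked invalid.

    Masking (rather than zero-filling) avoids fabricating "no surprise"
    evidence in seconds with no events.
    """
    n_bins = int(piece_duration_s)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for t, x in zip(series.timestamps_s, series.ic_bits):
        if not (0 <= t <= piece_duration_s):
            raise ValueError(f"event time {t} outside [0, {piece_duration_s}]")
        b = int(t)
        if b < n_bins:
            sums[b] += x
            counts[b] += 1
    valid = counts > 0
    values = np.zeros(n_bins)
    values[valid] = sums[valid] / counts[valid]
    return RegressorSeries(
        kind or f"ic_{series.stream}", values, valid,
        piece_id=series.piece_id,
    )
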