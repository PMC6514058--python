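"""Dynamical readouts: threshold-rule duration, early/late AUC, phases.

Response duration is the total time an activity curve spends above the
threshold ``basal + 5% of the basal-corrected peak``; crossings are located
by linear interpolation between samples.  Early and late signalling are
quantified as basal-corrected trapezoid areas over the 0-2 h and 6-8 h
windows.  Biphasic curves are segmented into above-threshold intervals: the
first contiguous interval is the early peak, the start of the next one is
the second-phase onset.  The threshold uses the global peak of the curve
(not the first-peak value) in biphasic cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import SpecificationError
from .ikk import THRESHOLD_FRACTION

#: excursions shorter than this are treated as grazing contacts and dropped
MIN_EXCURSION = 0.01


@dataclass(frozen=True)
class ActivityCurve:
    """A sampled activity time course with its pre-stimulus basal value."""

    times: np.ndarray
    values: np.ndarray
    basal: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @classmethod
    def from_trajectory(cls, traj, which: str = "nfkbn") -> "ActivityCurve":
        getters = {"nfkbn": (traj.nfkbn, traj.basal_nfkbn),
                   "nrela": (traj.nrela, traj.basal_nrela),
                   "nrelb": (traj.nrelb, traj.basal_nrelb)}
        if which in getters:
            values, basal_fn = getters[which]
            return cls(traj.times, values, basal_fn())
        return cls(traj.times, traj.concentration(which),
                   traj.basal_concentration(which))

    @property
    def peak(self) -> float:
        return float(np.max(self.values))


@dataclass(frozen=True)
class DurationResult:
    threshold: float
    duration: float
    crossing_intervals: tuple[tuple[float, float], ...]

    @property
    def open_at_end(self) -> bool:
        """True when the last above-threshold interval reaches the last sample."""
        return bool(self.crossing_intervals) and \
            self.crossing_intervals[-1][1] >= self._t_end

    # populated by duration(); kept out of the comparison fields
    _t_end: float = float("nan")


def threshold_value(curve: ActivityCurve) -> float:
    """basal + 5% of the basal-corrected peak (equals basal when the curve
    never exceeds it)."""
    excess = max(curve.peak - curve.basal, 0.0)
    return curve.basal + THRESHOLD_FRACTION * excess


def above_threshold_intervals(curve: ActivityCurve, threshold: float,
                              min_excursion: float = MIN_EXCURSION
                              ) -> tuple[tuple[float, float], ...]:
    """Above-threshold intervals with linearly interpolated crossing times."""
    t, v = curve.times, curve.values - threshold
    above = v > 0
    if not np.any(above):
        return ()
    intervals: list[list[float]] = []
    if above[0]:
        intervals.append([float(t[0]), float(t[0])])
    sign_change = np.flatnonzero(above[:-1] != above[1:])
    for i in sign_change:
        # linear interpolation of the crossing between samples i and i+1
        frac = v[i] / (v[i] - v[i + 1])
        tc = float(t[i] + frac * (t[i + 1] - t[i]))
        if above[i + 1]:           # upward crossing
            intervals.append([tc, tc])
        else:                      # downward crossing closes the interval
            intervals[-1][1] = tc
    if above[-1]:
        intervals[-1][1] = float(t[-1])
    merged = [(a, b) for a, b in intervals if b - a > min_excursion]
    return tuple(merged)


def duration(curve: ActivityCurve) -> DurationResult:
    """Total time above the 5%-threshold (zero when the peak <= basal)."""
    if curve.times.size < 2:
        raise SpecificationError("curve needs at least 2 samples")
    thr = threshold_value(curve)
    if curve.peak <= curve.basal:
        return DurationResult(thr, 0.0, (), _t_end=float(curve.times[-1]))
    intervals = above_threshold_intervals(curve, thr)
    total = float(sum(b - a for a, b in intervals))
    return DurationResult(thr, total, intervals, _t_end=float(curve.times[-1]))


def persistence_time(curve: ActivityCurve) -> float:
    """Latest time the curve is above the duration threshold (0 if never)."""
    res = duration(curve)
    return res.crossing_intervals[-1][1] if res.crossing_intervals else 0.0


def _window_auc(curve: ActivityCurve, lo: float, hi: float) -> float:
    """Basal-corrected trapezoid AUC over [lo, hi], negative segments
    clipped at zero; window endpoints are interpolated into the grid."""
    t = curve.times
    y = np.clip(curve.values - curve.basal, 0.0, None)
    inside = (t > lo) & (t < hi)
    tt = np.concatenate(([lo], t[inside], [hi]))
    yy = np.interp(tt, t, y)
    return float(np.trapezoid(yy, tt))


@dataclass(frozen=True)
class PhaseMetrics:
    early_auc: float                      # nM*h, 0-2 h, basal-corrected
    late_auc: float                       # nM*h, 6-8 h, basal-corrected
    first_peak_duration: float            # h
    second_phase_onset: float | None      # h, None if monophasic
    second_phase_open: bool               # still above threshold at curve end
    threshold: float
    intervals: tuple[tuple[float, float], ...]


EARLY_WINDOW = (0.0, 2.0)
LATE_WINDOW = (6.0, 8.0)


def phase_metrics(curve: ActivityCurve) -> PhaseMetrics:
    """Early/late AUC plus segmentation of the above-threshold intervals."""
    if curve.times[-1] < LATE_WINDOW[1]:
        raise SpecificationError(
            f"curve must span at least {LATE_WINDOW[1]} h for the late "
            f"window; it ends at {curve.times[-1]:.2f} h")
    res = duration(curve)
    intervals = res.crossing_intervals
    first = intervals[0][1] - intervals[0][0] if intervals else 0.0
    onset = intervals[1][0] if len(intervals) > 1 else None
    open_late = bool(intervals) and intervals[-1][1] >= float(curve.times[-1])
    return PhaseMetrics(
        early_auc=_window_auc(curve, *EARLY_WINDOW),
        late_auc=_window_auc(curve, *LATE_WINDOW),
        first_peak_duration=float(first),
        second_phase_onset=None if onset is None else float(onset),
        second_phase_open=open_late and len(intervals) > 1,
        threshold=res.threshold,
        intervals=intervals)
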