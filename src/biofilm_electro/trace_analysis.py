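"""Peak and latency analysis of ThT fluorescence traces.

Normalization, hyperpolarization-event (peak) counting with a
terminal-plateau rule, time-to-first-peak, and ensemble latency statistics
(mean, sample SD, SE) as reported for sparse cells, microclusters, and
biofilms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .traces import ThTTrace

__all__ = [
    "PeakSet",
    "LatencyStats",
    "normalize_trace",
    "detect_peaks",
    "time_to_first_peak",
    "latency_statistics",
    "count_hyperpolarization_events",
]

#: below this raw peak-to-peak range a trace is considered flat (no dynamics)
FLAT_RANGE = 1e-9


@dataclass(frozen=True)
class PeakSet:
    """Detected hyperpolarization events of a normalized trace."""

    peak_times: np.ndarray  # min, increasing
    peak_heights: np.ndarray  # normalized intensity in [0, 1]
    prominence: float  # prominence threshold used (fraction of range)

    def __post_init__(self) -> None:
        pt = np.asarray(self.peak_times, dtype=float)
        ph = np.asarray(self.peak_heights, dtype=float)
        object.__setattr__(self, "peak_times", pt)
        object.__setattr__(self, "peak_heights", ph)
        if pt.size != ph.size:
            raise ValueError("peak_times and peak_heights must match in length")
        if pt.size > 1 and not np.all(np.diff(pt) > 0):
            raise ValueError("peak_times must be increasing")

    @property
    def n_peaks(self) -> int:
        return int(self.peak_times.size)


@dataclass(frozen=True)
class LatencyStats:
    """Ensemble latency summary: mean +/- SD +/- SE (minutes)."""

    n: int
    mean: float
    sd: float
    se: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        expected_se = self.sd / math.sqrt(self.n)
        if not math.isclose(self.se, expected_se, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("se must equal sd / sqrt(n)")


def normalize_trace(trace: ThTTrace) -> ThTTrace:
    """Min-max normalize a trace to [0, 1]; idempotent.

    Raises
    ------
    ValueError
        For a constant trace ("zero dynamic range").
    """
    lo = float(trace.intensity.min())
    hi = float(trace.intensity.max())
    if hi - lo <= FLAT_RANGE * max(abs(hi), 1.0):
        raise ValueError("zero dynamic range: trace is constant")
    if trace.normalized and math.isclose(lo, 0.0, abs_tol=1e-12) and math.isclose(hi, 1.0, rel_tol=1e-12):
        return trace
    scaled = (trace.intensity - lo) / (hi - lo)
    return trace.with_intensity(scaled, normalized=True)


def _terminal_plateau_onset(
    trace: ThTTrace, level: float = 0.8, min_duration: float = 10.0
) -> float | None:
    """Onset time of a sustained terminal plateau, or None.

    A terminal plateau is a run of samples at the end of the trace that
    stays at or above ``level`` (normalized units) for at least
    ``min_duration`` minutes.
    """
    above = trace.intensity >= level
    if not above[-1]:
        return None
    below_idx = np.where(~above)[0]
    start_idx = 0 if below_idx.size == 0 else int(below_idx[-1]) + 1
    onset = float(trace.times[start_idx])
    if float(trace.times[-1]) - onset < min_duration:
        return None
    return onset


def detect_peaks(
    trace: ThTTrace,
    min_prominence: float = 0.15,
    min_separation: float = 5.0,
    plateau_level: float = 0.8,
    plateau_min_duration: float = 10.0,
) -> PeakSet:
    """Detect hyperpolarization events in a normalized trace.

    Local maxima with prominence at least ``min_prominence`` (fraction of
    the normalized range) and pairwise separation at least
    ``min_separation`` minutes. A sustained terminal plateau (intensity >=
    ``plateau_level`` for the final >= ``plateau_min_duration`` minutes)
    counts as the final peak, because the habituated second
    hyperpolarization is a plateau rather than a transient; its "time" is
    the plateau onset. Detection is invariant under affine rescaling of
    the raw intensity because normalization precedes it.

    An empty PeakSet is a valid result (e.g. for the mechanosensitive
    knockouts, which show no spike dynamics).
    """
    if not trace.normalized:
        trace = normalize_trace(trace)
    dt = trace.dt_median
    distance = max(1, int(round(min_separation / dt))) if dt > 0 else 1
    idx, props = find_peaks(
        trace.intensity, prominence=min_prominence, distance=distance
    )
    peak_times = list(trace.times[idx])
    peak_heights = list(trace.intensity[idx])

    onset = _terminal_plateau_onset(trace, plateau_level, plateau_min_duration)
    if onset is not None:
        inside = [t for t in peak_times if t >= onset]
        if not inside:
            tail = trace.times >= onset
            peak_times.append(onset)
            peak_heights.append(float(trace.intensity[tail].max()))
    order = np.argsort(peak_times)
    return PeakSet(
        peak_times=np.asarray(peak_times)[order],
        peak_heights=np.asarray(peak_heights)[order],
        prominence=min_prominence,
    )


def count_hyperpolarization_events(
    trace: ThTTrace, min_dynamic_range: float = 0.2, **kwargs
) -> int:
    """Number of hyperpolarization events, robust to flat traces.

    Convenience wrapper over :func:`detect_peaks` that reports zero events
    for a trace whose raw peak-to-peak range is below
    ``min_dynamic_range`` (arbitrary fluorescence units): a flat or
    near-flat trace is exactly the no-response phenotype of the
    mechanosensitive knockouts, and min-max normalization would otherwise
    amplify numerical or measurement noise into spurious events.
    """
    span = float(trace.intensity.max() - trace.intensity.min())
    if not trace.normalized and span < min_dynamic_range:
        return 0
    try:
        if not trace.normalized:
            trace = normalize_trace(trace)
    except ValueError:
        return 0
    return detect_peaks(trace, **kwargs).n_peaks


def time_to_first_peak(trace: ThTTrace, stimulus_onset: float = 0.0, **kwargs) -> float:
    """Time of the first detected hyperpolarization event (min).

    Measured relative to ``stimulus_onset`` (light onset; assumed to
    coincide with recording onset). For a plateau-only trace this is the
    plateau onset time.

    Raises
    ------
    ValueError
        If no event is detected; the message distinguishes a flat trace
        ("no response") from a structured trace without qualifying peaks.
    """
    try:
        if not trace.normalized:
            trace = normalize_trace(trace)
    except ValueError:
        raise ValueError("no response: trace is flat (zero dynamic range)")
    peaks = detect_peaks(trace, **kwargs)
    if peaks.n_peaks == 0:
        raise ValueError(
            "no peaks detected: trace has dynamics but no event passes the "
            "prominence/separation criteria"
        )
    return float(peaks.peak_times[0]) - stimulus_onset


def latency_statistics(latencies) -> LatencyStats:
    """Sample mean, SD (n-1 denominator) and SE = SD/sqrt(n) of latencies.

    A single observation has undefined sample SD; it is reported as 0 with
    a warning.

    Raises
    ------
    ValueError
        For an empty input.
    """
    arr = np.asarray(list(latencies), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty latency list")
    n = int(arr.size)
    mean = float(arr.mean())
    if n == 1:
        warnings.warn(
            "sample SD undefined for n = 1; reporting 0", stacklevel=2
        )
        sd = 0.0
    else:
        sd = float(arr.std(ddof=1))
    return LatencyStats(n=n, mean=mean, sd=sd, se=sd / math.sqrt(n))
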