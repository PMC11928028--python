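"""ThT-fluorescence proxy time series.

Thioflavin T (ThT) is a cationic Nernstian voltage indicator: it accumulates
in cells with more negative membrane potential, so fluorescence reports
hyperpolarization. A :class:`ThTTrace` is the common currency between the
membrane-potential simulator, the fire-diffuse-fire biofilm simulator, the
peak/latency analysis, and the synthetic-data generator. Times are minutes
(all figure axes in this problem domain use minutes); intensity is in
arbitrary fluorescence units, non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ThTTrace"]


@dataclass(frozen=True)
class ThTTrace:
    """A time-stamped fluorescence-proxy series (global or per cell).

    Parameters
    ----------
    times
        Sample times in minutes, strictly increasing.
    intensity
        Fluorescence intensity (arbitrary units, >= 0), same length as
        ``times``.
    label
        Free-text provenance tag (variant, seed, generator, ...).
    normalized
        Whether the trace has been min-max normalized to [0, 1].
    """

    times: np.ndarray
    intensity: np.ndarray
    label: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensity", intensity)
        if times.ndim != 1 or intensity.ndim != 1:
            raise ValueError("times and intensity must be 1-D")
        if times.size != intensity.size:
            raise ValueError(
                f"times ({times.size}) and intensity ({intensity.size}) "
                "must have the same length"
            )
        if times.size == 0:
            raise ValueError("trace must contain at least one sample")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(intensity)):
            raise ValueError("trace contains non-finite values")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(intensity < 0):
            raise ValueError("intensity must be non-negative")
        if self.normalized and not np.isclose(intensity.max(), 1.0):
            raise ValueError("normalized trace must have max intensity 1")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        """Span of the trace in minutes."""
        return float(self.times[-1] - self.times[0])

    @property
    def dt_median(self) -> float:
        """Median sampling interval (minutes)."""
        if len(self) < 2:
            return 0.0
        return float(np.median(np.diff(self.times)))

    def with_intensity(self, intensity: np.ndarray, *, normalized: bool | None = None,
                       label: str | None = None) -> "ThTTrace":
        """Return a copy with a new intensity vector on the same time base."""
        return ThTTrace(
            times=self.times.copy(),
            intensity=np.asarray(intensity, dtype=float),
            label=self.label if label is None else label,
            normalized=self.normalized if normalized is None else normalized,
        )
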