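"""Quantification of glutamate-uncaging responses and spine grouping.

Uncaging-evoked EPSP/EPSC amplitudes are quantified per trial as the mean
of a 2-ms window centred on the response extremum after the uncaging
pulse, baseline-subtracted, then averaged over the 5-10 test pulses of a
recording.  Spines are grouped into long- and short-neck populations by
their length-to-head-width ratio, with a 0.2-um minimum length applied to
spines without a discernible neck.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "UncagingTraceSet",
    "SpineGeometryLM",
    "response_amplitude",
    "lw_ratio",
    "split_neck_groups",
    "normalized_intensity",
    "MIN_SPINE_LENGTH_UM",
]

MIN_SPINE_LENGTH_UM = 0.2  # floor for spines with no discernible neck


@dataclass(frozen=True)
class UncagingTraceSet:
    """Repeated traces around an uncaging pulse.

    ``traces`` is trials x samples on the uniform ``time_ms`` axis;
    ``units`` is "mV" for voltage (uEPSP, positive deflection) or "pA"
    for current (uEPSC, negative deflection).
    """

    time_ms: np.ndarray
    traces: np.ndarray
    pulse_time_ms: float
    units: str = "mV"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ms, dtype=float)
        tr = np.atleast_2d(np.asarray(self.traces, dtype=float))
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "traces", tr)
        if tr.shape[1] != t.size:
            raise ValueError("traces and time axis disagree in sample count")
        dt = np.diff(t)
        if t.size >= 2 and not np.allclose(dt, dt[0]):
            raise ValueError("time axis must be uniformly sampled")
        if not (t[0] <= self.pulse_time_ms <= t[-1]):
            raise ValueError("pulse_time_ms must lie within the record")

    @property
    def n_trials(self) -> int:
        return self.traces.shape[0]

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0]) if self.time_ms.size > 1 else 0.0


@dataclass(frozen=True)
class SpineGeometryLM:
    """Light-microscopy spine geometry: length (head tip to neck base, um),
    head width at the widest transect (um), shaft-normalised intensity."""

    spine_length: float
    head_width: float
    normalized_intensity: float = float("nan")

    def __post_init__(self) -> None:
        if self.head_width <= 0:
            raise ValueError(f"head_width must be > 0, got {self.head_width}")
        if self.spine_length < 0:
            raise ValueError(f"spine_length must be >= 0, got {self.spine_length}")


def response_amplitude(
    traces: UncagingTraceSet,
    search_ms: float = 50.0,
    baseline_ms: float = 20.0,
    window_ms: float = 2.0,
    negative: bool | None = None,
) -> float:
    """Mean uncaging-response amplitude across trials.

    Per trial: subtract the mean of the ``baseline_ms`` window before the
    pulse, locate the extremum within ``search_ms`` after the pulse, and
    average a ``window_ms`` window centred on it.  ``negative`` selects the
    deflection polarity; by default it is inferred from the units (uEPSCs
    in pA are inward/negative and reported as magnitude, uEPSPs positive).
    """
    t = traces.time_ms
    dt = traces.dt_ms
    if dt <= 0:
        raise ValueError("need at least two samples")
    if traces.pulse_time_ms + search_ms > t[-1]:
        raise ValueError("uncaging pulse is too close to the end of the record")
    if negative is None:
        negative = traces.units.lower() == "pa"

    base_mask = (t >= traces.pulse_time_ms - baseline_ms) & (t < traces.pulse_time_ms)
    if not base_mask.any():
        raise ValueError("baseline window is empty")
    search_mask = (t > traces.pulse_time_ms) & (t <= traces.pulse_time_ms + search_ms)
    search_idx = np.flatnonzero(search_mask)

    half = max(int(round(window_ms / 2.0 / dt)), 0)
    amps = np.empty(traces.n_trials)
    for k in range(traces.n_trials):
        y = traces.traces[k] - traces.traces[k, base_mask].mean()
        seg = y[search_idx]
        j = search_idx[np.argmin(seg) if negative else np.argmax(seg)]
        lo, hi = max(j - half, 0), min(j + half + 1, y.size)
        amps[k] = y[lo:hi].mean()
    mean_amp = float(amps.mean())
    return -mean_amp if negative else mean_amp


def lw_ratio(spine_length: float, head_width: float) -> float:
    """Spine length to head-width ratio with the minimum-length rule:
    lengths below 0.2 um (no discernible neck) are floored at 0.2 um."""
    if head_width <= 0:
        raise ValueError(f"head_width must be > 0, got {head_width}")
    return max(spine_length, MIN_SPINE_LENGTH_UM) / head_width


def split_neck_groups(
    spines: Sequence[SpineGeometryLM],
    threshold: float | None = None,
) -> tuple[list[int], list[int]]:
    """Partition spines into (long-neck, short-neck) index groups by their
    length/width ratio.

    By default the split is at the sample median (spines at the median go
    to the short group), giving balanced groups for distinct ratios; an
    explicit ``threshold`` overrides it.  Raises on an all-identical set,
    where no split is defined.
    """
    if len(spines) < 2:
        raise ValueError("need at least two spines to split")
    ratios = np.array([lw_ratio(s.spine_length, s.head_width) for s in spines])
    if np.all(ratios == ratios[0]):
        raise ValueError("all length/width ratios identical: split is degenerate")
    if threshold is None:
        threshold = float(np.median(ratios))
    long_idx = [i for i, r in enumerate(ratios) if r > threshold]
    short_idx = [i for i, r in enumerate(ratios) if r <= threshold]
    if not long_idx or not short_idx:
        raise ValueError("threshold leaves one group empty")
    return long_idx, short_idx


def normalized_intensity(
    spine_intensity: float, shaft_roi_intensities: Sequence[float]
) -> float:
    """Spine fluorescence normalised to the mean of four dendritic-shaft
    ROI intensities (all background-subtracted, hence positive)."""
    shaft = np.asarray(shaft_roi_intensities, dtype=float)
    if shaft.size != 4:
        raise ValueError(f"expected 4 shaft ROI intensities, got {shaft.size}")
    m = shaft.mean()
    if m <= 0:
        raise ValueError("mean shaft intensity must be > 0 after background subtraction")
    return float(spine_intensity / m)
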