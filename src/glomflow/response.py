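"""Baseline estimation, dF/F normalisation and stimulus-locked summaries.

Responses are expressed as the percent change of fluorescence F relative
to a pre-stimulus baseline F0:

    dF/F0 [%] = 100 * (F - F0) / F0

with F0 the arithmetic mean fluorescence over a baseline window preceding
the first stimulus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_roi import TraceSet, window_slice
from .synthetic import StimulusProtocol

__all__ = ["DffTraceSet", "compute_f0", "dff", "stimulus_locked_summary", "linear_detrend"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DffTraceSet:
    """Per-ROI dF/F traces in percent, with the baseline that produced them."""

    values: np.ndarray  # (T, n_rois), percent
    names: list[str]
    frame_interval: float
    baseline_f0: np.ndarray  # counts per ROI, all > 0
    baseline_window: tuple[float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        f0 = np.asarray(self.baseline_f0, dtype=float)
        if values.shape[1] != len(self.names) or f0.shape != (len(self.names),):
            raise ValueError("values, names and baseline_f0 sizes disagree")
        if not (f0 > 0).all():
            raise ValueError("baseline_f0 must be positive for every ROI")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "baseline_f0", f0)
        object.__setattr__(self, "names", list(self.names))

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.n_frames) + 0.5) * self.frame_interval

    def trace(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "time_s", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_f0(
    traces: TraceSet,
    window: tuple[float, float],
    protocol: StimulusProtocol | None = None,
) -> np.ndarray:
    """Per-ROI mean fluorescence over frames whose midpoint lies in the
    half-open baseline window.

    Logs a warning (and proceeds) if the window overlaps a stimulus in the
    given protocol; raises if the window selects fewer than 2 frames or if
    any resulting baseline is non-positive.
    """
    idx = window_slice(traces.n_frames, traces.frame_interval, window)
    if idx.size < 2:
        raise ValueError(f"baseline window {window} contains {idx.size} frames; need >= 2")
    if protocol is not None:
        for event in protocol.events:
            if event.onset_time < window[1] and event.onset_time + event.duration > window[0]:
                log.warning(
                    "baseline window %s overlaps stimulus at t=%.3f s", window, event.onset_time
                )
    f0 = traces.values[idx].mean(axis=0)
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        names = [traces.names[i] for i in bad]
        raise ValueError(f"non-positive baseline for ROI(s) {names}; cannot normalise")
    return f0


def default_baseline_window(
    traces: TraceSet, protocol: StimulusProtocol
) -> tuple[float, float]:
    """All frames before the first stimulus onset."""
    if not protocol.events:
        return (0.0, traces.n_frames * traces.frame_interval)
    return (0.0, protocol.events[0].onset_time)


def dff(
    traces: TraceSet,
    f0: np.ndarray | None = None,
    window: tuple[float, float] | None = None,
    protocol: StimulusProtocol | None = None,
    detrend: bool = False,
) -> DffTraceSet:
    """Normalise traces to percent dF/F.

    Either an explicit per-ROI baseline ``f0`` or a baseline ``window`` must
    be given (if both are absent and a protocol is supplied, the window
    defaults to everything before the first stimulus).  Optional linear
    detrending (``detrend=True``) removes a least-squares linear trend fit
    over the baseline window from each trace before normalisation.
    """
    values = traces.values
    if window is None and f0 is None:
        if protocol is None:
            raise ValueError("give either f0, a baseline window, or a protocol")
        window = default_baseline_window(traces, protocol)
    if window is None:
        window = (0.0, 0.0)  # placeholder; only recorded when used
    if detrend:
        values = linear_detrend(traces, window)
        traces = TraceSet(values=values, names=traces.names, frame_interval=traces.frame_interval)
    if f0 is None:
        f0 = compute_f0(traces, window, protocol)
    f0 = np.asarray(f0, dtype=float)
    if not (f0 > 0).all():
        raise ValueError("baseline f0 must be positive")
    out = 100.0 * (values - f0) / f0
    return DffTraceSet(
        values=out,
        names=traces.names,
        frame_interval=traces.frame_interval,
        baseline_f0=f0,
        baseline_window=tuple(window),
    )


def linear_detrend(traces: TraceSet, window: tuple[float, float]) -> np.ndarray:
    """Remove a linear trend fit over the baseline window, preserving the
    window mean (so F0 is unchanged to first order)."""
    idx = window_slice(traces.n_frames, traces.frame_interval, window)
    if idx.size < 2:
        raise ValueError("detrending needs >= 2 baseline frames")
    t = traces.times
    out = traces.values.copy()
    for j in range(out.shape[1]):
        slope, intercept = np.polyfit(t[idx], out[idx, j], 1)
        out[:, j] -= slope * t + intercept - out[idx, j].mean()
    return out


def stimulus_locked_summary(
    dff_traces: DffTraceSet,
    protocol: StimulusProtocol,
    response_window: float = 5.0,
) -> pd.DataFrame:
    """Per-event, per-ROI peak and mean dF/F in [onset, onset + window).

    Returns a tidy frame with one row per (event, ROI) carrying the event
    onset, power, peak and mean percent dF/F, and a flag marking the ROI
    with the largest peak for that event.  Overlapping response windows are
    tolerated with a logged warning.
    """
    t_end = dff_traces.n_frames * dff_traces.frame_interval
    rows = []
    prev_end = -np.inf
    for ei, event in enumerate(protocol.events):
        w = (event.onset_time, event.onset_time + response_window)
        if w[1] > t_end + dff_traces.frame_interval / 2:
            raise ValueError(f"response window for event {ei} extends past the recording")
        if w[0] < prev_end:
            log.warning("response windows overlap at event %d (t=%.2f s)", ei, w[0])
        prev_end = w[1]
        idx = window_slice(dff_traces.n_frames, dff_traces.frame_interval, w)
        seg = dff_traces.values[idx]
        peaks = seg.max(axis=0)
        argmax_roi = dff_traces.names[int(np.argmax(peaks))]
        for j, name in enumerate(dff_traces.names):
            rows.append(
                {
                    "event": ei,
                    "onset_s": event.onset_time,
                    "power_mw": event.power,
                    "roi": name,
                    "peak_dff_pct": float(peaks[j]),
                    "mean_dff_pct": float(seg[:, j].mean()),
                    "is_argmax": name == argmax_roi,
                }
            )
    return pd.DataFrame(rows)
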