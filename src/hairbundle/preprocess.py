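"""Trace preparation: detrending to stationarity and stimulus segmentation.

Hair-bundle position records drift slowly as the preparation relaxes, so
traces are detrended (polynomial fit and/or moving average, applied in
series) before any oscillation statistics are computed. Records spanning an
efferent-stimulation protocol are then split into pre / during / post
windows aligned with stimulus onset and offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "StimulusProtocol",
    "MotionTrace",
    "SegmentedTrace",
    "detrend",
    "segment",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing of an efferent-stimulation protocol, in seconds.

    The default 10/10/10 s layout leaves unstimulated flanks of the same
    duration as the stimulus window.
    """

    pre_s: float = 10.0
    during_s: float = 10.0
    post_s: float = 10.0

    @property
    def total_s(self) -> float:
        return self.pre_s + self.during_s + self.post_s


@dataclass
class MotionTrace:
    """A uniformly sampled 1-D bundle displacement series.

    samples are in nm (positive displacement = towards the kinocilium,
    i.e. the channel-opening direction), fs in frames per second.
    """

    samples: np.ndarray
    fs: float
    cell_id: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("MotionTrace samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"non-finite samples in trace {self.cell_id!r}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class SegmentedTrace:
    """Pre / during / post windows of one record; they tile the timeline."""

    pre: MotionTrace
    during: MotionTrace
    post: MotionTrace

    def __iter__(self):
        yield "pre", self.pre
        yield "during", self.during
        yield "post", self.post


def _as_trace(trace, fs: Optional[float]) -> MotionTrace:
    if isinstance(trace, MotionTrace):
        return trace
    if fs is None:
        raise ValueError("fs is required when passing a bare array")
    return MotionTrace(np.asarray(trace, dtype=float), fs)


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with a shrinking (truncated) window at the
    edges, so no samples near the stimulus transitions are discarded."""
    if window < 3:
        raise ValueError(f"moving-average window of {window} samples is too "
                         "short (need >= 3)")
    n = x.size
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def detrend(trace, fs: Optional[float] = None, method: str = "both",
            order: int = 2, window_s: float = 1.0) -> MotionTrace:
    """Remove slow drift from a position trace.

    method 'polynomial' subtracts a least-squares polynomial of the given
    order; 'moving_average' subtracts a centered running mean of width
    window_s; 'both' applies them in series (polynomial first). The running
    mean passes oscillations well above 1/window_s essentially unchanged
    (amplitude response 1 - sinc(f * window_s)).
    """
    t = _as_trace(trace, fs)
    if order > 5:
        raise ValueError("polynomial order > 5 is not supported")
    if method not in ("polynomial", "moving_average", "both"):
        raise ValueError(f"unknown detrend method {method!r}")
    y = t.samples.astype(float)
    if method in ("polynomial", "both"):
        u = np.linspace(-1.0, 1.0, y.size)
        coef = np.polynomial.polynomial.polyfit(u, y, order)
        y = y - np.polynomial.polynomial.polyval(u, coef)
    if method in ("moving_average", "both"):
        window = int(round(window_s * t.fs))
        y = y - moving_average(y, window)
    return replace(t, samples=y)


def segment(trace, protocol: StimulusProtocol,
            fs: Optional[float] = None) -> SegmentedTrace:
    """Split a record into pre / during / post stimulus windows.

    The stimulus-onset sample belongs to the 'during' window; the offset
    sample belongs to 'post'. The three windows partition the samples they
    cover exactly (concatenating them reproduces the record).
    """
    t = _as_trace(trace, fs)
    n = t.samples.size
    i_on = int(round(protocol.pre_s * t.fs))
    i_off = i_on + int(round(protocol.during_s * t.fs))
    i_end = i_off + int(round(protocol.post_s * t.fs))
    if n < i_end:
        missing = (i_end - n) / t.fs
        raise ValueError(
            f"trace {t.cell_id!r} covers {n / t.fs:.3f} s but the protocol "
            f"requires {protocol.total_s:.3f} s ({missing:.3f} s missing at "
            "the end)")
    mk = lambda s, lo: MotionTrace(s, t.fs, t.cell_id, t.t0 + lo / t.fs)
    return SegmentedTrace(
        pre=mk(t.samples[:i_on], 0),
        during=mk(t.samples[i_on:i_off], i_on),
        post=mk(t.samples[i_off:i_end], i_off),
    )
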