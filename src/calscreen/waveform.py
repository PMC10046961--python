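"""Whole-well fluorescence waveform analysis.

A recording is reduced to discrete oscillation pulses and five summary
parameters per well and window:

* peak number (pulses / 10 min) — the primary endpoint,
* mean pulse width (ms, time from the top peak to 90 % recovery toward
  the pulse's bottom level; the bottom-to-top rise width is also kept),
* mean pulse amplitude (RLU, background-subtracted),
* mean area under the pulse (RLU·s),
* mean peak-to-peak time (ms, between successive top peaks).

Detection works on the derivative of the smoothed trace: contiguous
samples whose derivative exceeds ``k`` robust scales mark upstrokes,
and each upstroke is expanded to a (bottom peak, top peak, return
point) triple on the smoothed trace.  Background fluorescence is the
smoothed trace with every pulse span bridged by linear interpolation;
amplitudes and areas are measured on the background-subtracted signal.

Small pulses are too variable to count reliably, so the per-well
feature summary only uses "large" pulses: amplitude at least a fixed
fraction of the well's reference amplitude (95th percentile of baseline
pulse amplitudes), with an absolute floor of five noise scales.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = [
    "Trace",
    "DetectorConfig",
    "PulseEvent",
    "WellFeatures",
    "smooth",
    "differentiate",
    "detect_pulses",
    "estimate_background",
    "compute_features",
]

_MAD_TO_SD = 1.4826  # consistency factor for Gaussian noise
_ABS_FLOOR_SCALES = 5.0  # absolute large-pulse floor, in residual noise scales
VALID_RATES = (2.0, 10.0)


@dataclass(frozen=True)
class Trace:
    """One well's uniformly sampled fluorescence time series."""

    well_id: str
    times: np.ndarray  # seconds, uniform from 0
    values: np.ndarray  # RLU
    rate_hz: float
    window: str = "baseline"  # baseline | post

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.shape != times.shape:
            raise ValueError(f"{self.well_id}: times/values must be 1-D and equal length")
        if times.size < 2:
            raise ValueError(f"{self.well_id}: trace needs at least 2 samples")
        if float(self.rate_hz) not in VALID_RATES:
            raise ValueError(f"{self.well_id}: rate_hz must be one of {VALID_RATES}")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValueError(f"{self.well_id}: times not strictly increasing")
        dt = 1.0 / self.rate_hz
        if np.max(np.abs(steps - dt)) > 1e-9:
            raise ValueError(f"{self.well_id}: non-uniform sampling (expected {dt} s steps)")
        if self.window not in ("baseline", "post"):
            raise ValueError(f"{self.well_id}: bad window {self.window!r}")

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def duration(self) -> float:
        """Recording length in seconds (sample count x sampling interval)."""
        return self.times.size * self.dt


@dataclass(frozen=True)
class DetectorConfig:
    """Pulse-detector tuning knobs (all time quantities in seconds)."""

    smooth_window: float = 2.5
    derivative_threshold_k: float = 5.0
    refractory: float = 2.0
    large_peak_fraction: float = 0.25
    return_fraction: float = 0.90
    width_mode: str = "return"  # return -> width_return; rise -> width_rise

    def __post_init__(self) -> None:
        if self.smooth_window <= 0 or self.derivative_threshold_k <= 0 or self.refractory <= 0:
            raise ValueError("detector config values must be positive")
        if not 0 < self.large_peak_fraction <= 1:
            raise ValueError("large_peak_fraction must be in (0, 1]")
        if not 0 < self.return_fraction <= 1:
            raise ValueError("return_fraction must be in (0, 1]")
        if self.width_mode not in ("return", "rise"):
            raise ValueError(f"bad width_mode {self.width_mode!r}")


@dataclass(frozen=True)
class PulseEvent:
    """One detected oscillation pulse."""

    bottom_time: float
    top_time: float
    end_time: float  # return point
    amplitude: float  # RLU, background-subtracted
    width_rise: float  # ms, bottom -> top
    width_return: float  # ms, top -> return point
    auc: float  # RLU*s
    is_large: bool

    def __post_init__(self) -> None:
        if not self.bottom_time < self.top_time <= self.end_time:
            raise ValueError("pulse times must satisfy bottom < top <= end")
        if self.amplitude <= 0 or self.auc <= 0:
            raise ValueError("pulse amplitude and AUC must be positive")


@dataclass(frozen=True)
class WellFeatures:
    """Per-well, per-window waveform parameter summary (large pulses only)."""

    peak_number: float  # pulses / 10 min
    mean_width: float | None  # ms
    mean_amplitude: float | None  # RLU
    mean_auc: float | None  # RLU*s
    mean_peak_to_peak: float | None  # ms
    n_events_raw: int
    n_events_large: int


# ---------------------------------------------------------------------------
# signal primitives
# ---------------------------------------------------------------------------

def _window_samples(window: float, rate_hz: float) -> int:
    size = int(round(window * rate_hz))
    if size < 2:
        raise ValueError(f"smoothing window {window} s is shorter than 2 samples at {rate_hz} Hz")
    if size % 2 == 0:
        size += 1
    return size


def smooth(trace: Trace, window: float | None = None) -> Trace:
    """Centered moving average (reflected ends; mean-preserving)."""
    size = _window_samples(window if window is not None else 2.5, trace.rate_hz)
    smoothed = uniform_filter1d(trace.values, size=size, mode="reflect")
    return replace(trace, values=smoothed)


def differentiate(trace: Trace) -> np.ndarray:
    """Time derivative (RLU/s): central differences, one-sided at the ends."""
    if trace.values.size < 3:
        raise ValueError(f"{trace.well_id}: need at least 3 samples to differentiate")
    return np.gradient(trace.values, trace.dt)


def _robust_scale(x: np.ndarray) -> float:
    med = np.median(x)
    return _MAD_TO_SD * float(np.median(np.abs(x - med)))


def _threshold_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open [start, stop) index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], above, [False])).astype(int)))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


def _merge_runs(runs: list[tuple[int, int]], min_start_gap: int) -> list[tuple[int, int]]:
    """Merge runs whose onsets are closer than ``min_start_gap`` samples."""
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][0] < min_start_gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], run[1]))
        else:
            merged.append(run)
    return merged


def _last_local_min(values: np.ndarray, before: int) -> int:
    """Index of the last local minimum at or before ``before``."""
    for j in range(min(before, values.size - 2), 0, -1):
        if values[j] <= values[j - 1] and values[j] <= values[j + 1]:
            return j
    return int(np.argmin(values[: before + 1]))


def _first_local_max(values: np.ndarray, after: int) -> int:
    """Index of the first local maximum at or after ``after``."""
    for j in range(max(after, 1), values.size - 1):
        if values[j] >= values[j - 1] and values[j] >= values[j + 1]:
            return j
    return after + int(np.argmax(values[after:]))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

@dataclass
class _Span:
    bottom: int
    top: int
    end: int


def _find_spans(smoothed: np.ndarray, deriv: np.ndarray, cfg: DetectorConfig,
                rate_hz: float) -> list[_Span]:
    sigma = _robust_scale(deriv)
    threshold = cfg.derivative_threshold_k * sigma
    runs = _threshold_runs(deriv > threshold)
    runs = _merge_runs(runs, max(1, int(round(cfg.refractory * rate_hz))))

    spans: list[_Span] = []
    n = smoothed.size
    for start, stop in runs:
        bottom = _last_local_min(smoothed, start)
        # the peak may be the last above-threshold sample, so scan from the
        # upstroke onset rather than from the run's end
        top = _first_local_max(smoothed, min(start + 1, n - 1))
        if top <= bottom:
            continue
        rise = smoothed[top] - smoothed[bottom]
        if rise <= 0:
            continue
        return_level = smoothed[bottom] + (1.0 - cfg.return_fraction) * rise
        below = np.flatnonzero(smoothed[top + 1:] <= return_level)
        end = top + 1 + int(below[0]) if below.size else n - 1
        spans.append(_Span(bottom, top, end))

    # keep spans ordered and non-overlapping: drop duplicates on the same top,
    # then clip each end to the next pulse's bottom
    spans.sort(key=lambda s: s.top)
    deduped: list[_Span] = []
    for span in spans:
        if deduped and span.top <= deduped[-1].top:
            continue
        if deduped and span.bottom < deduped[-1].end:
            span.bottom = max(span.bottom, deduped[-1].top + 1)
            if span.bottom >= span.top:
                continue
        deduped.append(span)
    for prev, nxt in zip(deduped, deduped[1:]):
        prev.end = min(prev.end, nxt.bottom)
        prev.end = max(prev.end, prev.top)
    return deduped


def _interpolate_spans(smoothed: np.ndarray, spans: Sequence[tuple[int, int]]) -> np.ndarray:
    """Bridge each [start, end] index span of ``smoothed`` linearly."""
    n = smoothed.size
    keep = np.ones(n, dtype=bool)
    for start, end in spans:
        keep[max(start, 0): min(end, n - 1) + 1] = False
    if not keep.any():
        raise ValueError("pulse spans cover the entire trace; no background support")
    background = smoothed.copy()
    idx = np.arange(n)
    background[~keep] = np.interp(idx[~keep], idx[keep], smoothed[keep])
    return background


def estimate_background(trace: Trace, events: Sequence[PulseEvent],
                        cfg: DetectorConfig | None = None) -> np.ndarray:
    """Background fluorescence: smoothed trace with pulse spans bridged.

    Equals the smoothed trace outside the detected pulse regions; across
    each [bottom_time, end_time] interval the smoothed trace is replaced
    by linear interpolation between the flanking non-pulse samples.
    """
    cfg = cfg or DetectorConfig()
    smoothed = smooth(trace, cfg.smooth_window).values
    rate = trace.rate_hz
    spans = [
        (int(round(ev.bottom_time * rate)), int(round(ev.end_time * rate))) for ev in events
    ]
    for (start, end), ev in zip(spans, events):
        if start < 0 or end >= trace.values.size:
            raise ValueError(f"event at t={ev.top_time} s lies outside the trace window")
    return _interpolate_spans(smoothed, spans)


def detect_pulses(
    trace: Trace,
    cfg: DetectorConfig | None = None,
    reference_amplitudes: Sequence[float] | None = None,
) -> list[PulseEvent]:
    """Detect oscillation pulses on one trace.

    ``reference_amplitudes`` supplies the same well's baseline-window
    pulse amplitudes for the large-pulse rule; when omitted the trace's
    own pulse amplitudes are used.  An empty list is a valid result.
    """
    cfg = cfg or DetectorConfig()
    smoothed = smooth(trace, cfg.smooth_window).values
    deriv = np.gradient(smoothed, trace.dt)
    spans = _find_spans(smoothed, deriv, cfg, trace.rate_hz)
    if not spans:
        return []

    # background comes from the smoothed trace, but amplitude/AUC are read
    # off the original wave so sharp peaks are not attenuated
    background = _interpolate_spans(smoothed, [(s.bottom, s.end) for s in spans])
    residual = trace.values - background

    dt = trace.dt
    raw: list[tuple[_Span, float, float]] = []
    for span in spans:
        seg = residual[span.bottom: span.end + 1]
        amplitude = float(seg.max())
        if amplitude <= 0:
            continue
        auc = float(np.trapezoid(np.clip(seg, 0.0, None), dx=dt))
        if auc <= 0:
            continue
        raw.append((span, amplitude, auc))
    if not raw:
        return []

    outside = np.ones(trace.values.size, dtype=bool)
    for span, _, _ in raw:
        outside[span.bottom: span.end + 1] = False
    noise_scale = _robust_scale(residual[outside]) if outside.any() else 0.0
    amplitudes = [amp for _, amp, _ in raw]
    ref = np.asarray(reference_amplitudes if reference_amplitudes else amplitudes, dtype=float)
    large_threshold = max(
        cfg.large_peak_fraction * float(np.percentile(ref, 95)),
        _ABS_FLOOR_SCALES * noise_scale,
    )

    events = [
        PulseEvent(
            bottom_time=span.bottom * dt,
            top_time=span.top * dt,
            end_time=span.end * dt,
            amplitude=amplitude,
            width_rise=(span.top - span.bottom) * dt * 1e3,
            width_return=(span.end - span.top) * dt * 1e3,
            auc=auc,
            is_large=bool(amplitude >= large_threshold),
        )
        for span, amplitude, auc in raw
    ]
    return events


def compute_features(trace: Trace, events: Sequence[PulseEvent],
                     cfg: DetectorConfig | None = None) -> WellFeatures:
    """Summarize detected pulses into the five waveform parameters.

    The peak number counts large pulses per 10 min; the remaining four
    parameters average over large pulses only and are reported absent
    (``None``) when the window has no large pulse.
    """
    cfg = cfg or DetectorConfig()
    duration = trace.duration
    if duration <= 0:
        raise ValueError(f"{trace.well_id}: zero-duration window")
    large = [ev for ev in events if ev.is_large]
    n_large = len(large)
    peak_number = n_large / duration * 600.0

    if n_large == 0:
        return WellFeatures(peak_number, None, None, None, None, len(events), 0)

    widths = [ev.width_return if cfg.width_mode == "return" else ev.width_rise for ev in large]
    tops = sorted(ev.top_time for ev in large)
    p2p = (
        float(np.mean(np.diff(tops))) * 1e3 if n_large >= 2 else None
    )
    return WellFeatures(
        peak_number=peak_number,
        mean_width=float(np.mean(widths)),
        mean_amplitude=float(np.mean([ev.amplitude for ev in large])),
        mean_auc=float(np.mean([ev.auc for ev in large])),
        mean_peak_to_peak=p2p,
        n_events_raw=len(events),
        n_events_large=n_large,
    )
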