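"""Synthetic plate-reader recordings with known ground truth.

Wells fire synchronized oscillation pulses as a renewal process with
Gamma-distributed inter-pulse intervals (CV = ``rate_jitter_cv``;
baseline wells keep a relatively stable within-well rate, so a pure
Poisson process would be too irregular).  Each pulse is rendered as a
linear rise followed by an exponential decay, on top of a baseline with
optional linear drift (photobleaching) and additive Gaussian noise.
Inter-pulse intervals are floored at a 2 s refractory period so pulses
stay resolvable at 2 Hz sampling.

A drug effect multiplies the firing rate and pulse amplitude from
``onset_delay`` seconds into the post-treatment window onward;
``rate_multiplier`` 0 silences the well, i.e. a -100 % change in peak
number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .reference_data import DoseSummary
from .waveform import Trace

__all__ = [
    "PulseShapeParams",
    "WellModel",
    "DrugEffectModel",
    "GroundTruth",
    "PlateSimulation",
    "REFRACTORY_S",
    "simulate_well",
    "simulate_plate",
    "effect_from_dose_summary",
    "well_labels",
    "is_edge_well",
]

REFRACTORY_S = 2.0  # minimum separation between pulse onsets
EDGE_JITTER_INFLATION = 3.0  # edge wells oscillate less regularly

_ROWS = "ABCDEFGHIJKLMNOP"  # 384-well plate: rows A-P, columns 1-24
_N_COLS = 24
_WELL_RE = re.compile(r"^([A-P])(\d{1,2})$")


@dataclass(frozen=True)
class PulseShapeParams:
    """Rendered pulse morphology: linear rise, exponential decay."""

    rise_time: float = 2.0  # s
    decay_time_constant: float = 8.0  # s
    amplitude_mean: float = 100.0  # RLU
    amplitude_cv: float = 0.2

    def __post_init__(self) -> None:
        if min(self.rise_time, self.decay_time_constant, self.amplitude_mean) <= 0:
            raise ValueError("pulse shape parameters must be strictly positive")
        if not 0 <= self.amplitude_cv < 1:
            raise ValueError("amplitude_cv must be in [0, 1)")


@dataclass(frozen=True)
class WellModel:
    """Per-well firing statistics and recording artifacts."""

    base_rate: float = 12.0  # pulses / 10 min
    rate_jitter_cv: float = 0.2
    baseline_level: float = 1000.0  # RLU
    drift_slope: float = 0.0  # RLU/s
    noise_sd: float = 5.0  # RLU
    is_edge: bool = False

    def __post_init__(self) -> None:
        if self.base_rate < 0 or self.noise_sd < 0 or self.rate_jitter_cv < 0:
            raise ValueError("base_rate, noise_sd and rate_jitter_cv must be non-negative")
        if not self.is_edge and self.base_rate > 25:
            raise ValueError("non-edge wells fire < 25 pulses/10 min at baseline")


@dataclass(frozen=True)
class DrugEffectModel:
    """Multiplicative treatment effect applied to the post window."""

    rate_multiplier: float = 1.0
    amplitude_multiplier: float = 1.0
    onset_delay: float = 0.0  # s after window start

    def __post_init__(self) -> None:
        if self.rate_multiplier < 0 or self.amplitude_multiplier < 0:
            raise ValueError("effect multipliers must be >= 0")
        if self.onset_delay < 0:
            raise ValueError("onset_delay must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Injected events for one well and one window."""

    onset_times: np.ndarray  # s
    peak_times: np.ndarray  # s (onset + rise_time)
    amplitudes: np.ndarray  # RLU
    effect: DrugEffectModel | None = None

    @property
    def n_events(self) -> int:
        return int(self.onset_times.size)


@dataclass(frozen=True)
class PlateSimulation:
    """All traces of a simulated plate, keyed by (well, window)."""

    traces: dict[tuple[str, str], Trace]
    truth: dict[tuple[str, str], GroundTruth]
    treatments: dict[str, tuple[str, float]]  # well -> (treatment, concentration)


# ---------------------------------------------------------------------------
# well-label helpers
# ---------------------------------------------------------------------------

def is_edge_well(well: str) -> bool:
    """True for the 144 outer-ring wells (the two outermost rows/columns)."""
    match = _WELL_RE.match(well)
    if not match or not 1 <= int(match.group(2)) <= _N_COLS:
        raise ValueError(f"bad 384-well label: {well!r}")
    row, col = match.group(1), int(match.group(2))
    return row in ("A", "B", "O", "P") or col in (1, 2, _N_COLS - 1, _N_COLS)


def well_labels(include_edge: bool = True) -> list[str]:
    """All 384 well labels in row-major order (optionally interior only)."""
    labels = [f"{row}{col}" for row in _ROWS for col in range(1, _N_COLS + 1)]
    if include_edge:
        return labels
    return [w for w in labels if not is_edge_well(w)]


# ---------------------------------------------------------------------------
# event process
# ---------------------------------------------------------------------------

def _draw_interval(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv <= 1e-12:
        interval = mean
    else:
        shape = 1.0 / cv**2
        interval = float(rng.gamma(shape, mean / shape))
    return max(interval, REFRACTORY_S)


def draw_event_times(
    rng: np.random.Generator,
    rate_per_10min: float,
    jitter_cv: float,
    duration: float,
    t_margin: float = 0.0,
) -> np.ndarray:
    """Onset times of a stationary Gamma-renewal process on [0, duration].

    The process is warmed up before t = 0 so the count in the window is
    unbiased; onsets are restricted to [0, duration - t_margin] so every
    rendered pulse peaks inside the recording.
    """
    if rate_per_10min <= 0 or duration <= t_margin:
        return np.empty(0)
    mean = 600.0 / rate_per_10min
    t = -10.0 * mean
    t += _draw_interval(rng, mean, jitter_cv) * float(rng.uniform())
    onsets: list[float] = []
    limit = duration - t_margin
    while t <= limit:
        if t >= 0.0:
            onsets.append(t)
        t += _draw_interval(rng, mean, jitter_cv)
    return np.asarray(onsets)


def _render(times: np.ndarray, onsets: np.ndarray, amplitudes: np.ndarray,
            shape: PulseShapeParams) -> np.ndarray:
    signal = np.zeros_like(times)
    rise, tau = shape.rise_time, shape.decay_time_constant
    for onset, amp in zip(onsets, amplitudes):
        rel = times - onset
        rising = (rel >= 0) & (rel < rise)
        decaying = rel >= rise
        signal[rising] += amp * rel[rising] / rise
        signal[decaying] += amp * np.exp(-(rel[decaying] - rise) / tau)
    return signal


_IDENTITY_EFFECT = DrugEffectModel()


def simulate_well(
    model: WellModel,
    shape: PulseShapeParams | None = None,
    duration: float = 1200.0,
    rate_hz: float = 2.0,
    seed: int | np.random.Generator = 0,
    window: str = "baseline",
    well_id: str = "B2",
    effect: DrugEffectModel | None = None,
) -> tuple[Trace, GroundTruth]:
    """Simulate one recording window of one well.

    Deterministic for a fixed seed; the returned ground truth lists
    every injected pulse (onset, peak time, amplitude).  When an
    ``effect`` is given, firing rate and pulse amplitude are multiplied
    from ``effect.onset_delay`` seconds onward.
    """
    shape = shape or PulseShapeParams()
    eff = effect or _IDENTITY_EFFECT
    if duration <= 0:
        raise ValueError("duration must be positive")
    if float(rate_hz) not in (2.0, 10.0):
        raise ValueError("rate_hz must be 2 or 10")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    jitter = model.rate_jitter_cv * (EDGE_JITTER_INFLATION if model.is_edge else 1.0)
    margin = shape.rise_time + 1.0  # every peak stays inside the window
    delay = min(eff.onset_delay, duration)
    if delay > 0:
        pre = draw_event_times(rng, model.base_rate, jitter, delay)
        post = draw_event_times(
            rng, model.base_rate * eff.rate_multiplier, jitter, duration - delay, margin
        ) + delay
        onsets = np.concatenate([pre, post])
    else:
        onsets = draw_event_times(
            rng, model.base_rate * eff.rate_multiplier, jitter, duration, margin
        )
    treated = onsets >= delay if delay > 0 else np.ones(onsets.size, dtype=bool)

    sd = shape.amplitude_cv * shape.amplitude_mean
    amplitudes = np.maximum(
        rng.normal(shape.amplitude_mean, sd, size=onsets.size), 0.1 * shape.amplitude_mean
    )
    amplitudes = np.where(treated, amplitudes * eff.amplitude_multiplier, amplitudes)

    n = int(round(duration * rate_hz))
    times = np.arange(n) / rate_hz
    values = (
        model.baseline_level
        + model.drift_slope * times
        + _render(times, onsets, amplitudes, shape)
    )
    if model.noise_sd > 0:
        values = values + rng.normal(0.0, model.noise_sd, size=n)

    truth = GroundTruth(
        onset_times=onsets,
        peak_times=onsets + shape.rise_time,
        amplitudes=amplitudes,
        effect=effect,
    )
    return Trace(well_id, times, values, rate_hz, window), truth


def simulate_plate(
    treatments: Mapping[str, tuple[str, float]],
    well_models: Mapping[str, WellModel],
    effects: Mapping[str, DrugEffectModel],
    shape: PulseShapeParams | None = None,
    duration: float = 1200.0,
    rate_hz: float = 2.0,
    seed: int = 0,
) -> PlateSimulation:
    """Simulate baseline and post-treatment windows for a set of wells.

    ``treatments`` maps interior well labels to (treatment name,
    concentration); assigning a treatment to an edge well is rejected.
    Every treatment must have an entry in ``effects``.  Edge wells in
    ``well_models`` are simulated with inflated rate jitter but get no
    treatment.
    """
    shape = shape or PulseShapeParams()
    for well, (treatment, _) in treatments.items():
        if is_edge_well(well):
            raise ValueError(f"treatment {treatment!r} assigned to edge well {well}")
        if treatment not in effects:
            raise ValueError(f"no effect model for treatment {treatment!r} (well {well})")
        if well not in well_models:
            raise ValueError(f"no well model for treated well {well}")

    traces: dict[tuple[str, str], Trace] = {}
    truth: dict[tuple[str, str], GroundTruth] = {}
    root = np.random.SeedSequence(seed)
    wells = sorted(well_models)
    for well, child in zip(wells, root.spawn(len(wells))):
        rng = np.random.default_rng(child)
        model = well_models[well]
        if is_edge_well(well) and not model.is_edge:
            model = replace(model, is_edge=True)

        trace, gt = simulate_well(model, shape, duration, rate_hz, rng, "baseline", well)
        traces[well, "baseline"] = trace
        truth[well, "baseline"] = gt

        effect = effects[treatments[well][0]] if well in treatments else _IDENTITY_EFFECT
        trace, gt = simulate_well(
            model, shape, duration, rate_hz, rng, "post", well, effect=effect
        )
        traces[well, "post"] = trace
        truth[well, "post"] = gt

    return PlateSimulation(traces=traces, truth=truth, treatments=dict(treatments))


def effect_from_dose_summary(summary: DoseSummary) -> DrugEffectModel:
    """Calibrate a rate effect from a published mean percent change."""
    if summary.mean_delta_pct < -100.0:
        raise ValueError("mean percent change below the -100% cessation floor")
    return DrugEffectModel(rate_multiplier=1.0 + summary.mean_delta_pct / 100.0)
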