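"""End-to-end orchestration: simulate -> detect -> stats -> classify.

Two entry modes:

* **full-signal mode** (:func:`analyze_plate`, :func:`dose_results_from_observations`)
  starts from per-well baseline/post traces, detects pulses, computes
  per-well percent changes of the peak number and summarizes them per
  drug and concentration against same-plate vehicle wells;
* **replay mode** (:func:`run_replay`) skips the waveform stages and
  scores the packaged per-drug call table against the clinical labels,
  so the panel-level metrics are reproducible without raw fluorescence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import classify, reference_data, stats
from .io import PlateMap, RunConfig, WellAssignment
from .synthetic import (
    DrugEffectModel,
    PlateSimulation,
    PulseShapeParams,
    WellModel,
    effect_from_dose_summary,
    simulate_plate,
    well_labels,
)
from .waveform import Trace, WellFeatures, compute_features, detect_pulses

__all__ = [
    "PipelineResult",
    "analyze_plate",
    "dose_results_from_observations",
    "run_replay",
    "simulate_demo_plate",
    "DEMO_DRUGS",
]

log = logging.getLogger("calscreen")

#: demo panel: two stimulators, one silencer, one inactive drug (dose chosen
#: from the packaged per-dose table, identified by its dose index)
DEMO_DRUGS: dict[str, int] = {
    "4-Aminopyridine": 4,
    "Theophylline": 4,
    "Maprotiline": 3,
    "Enoxacin": 4,
}


@dataclass(frozen=True)
class PipelineResult:
    features: pd.DataFrame  # one row per well and window
    observations: tuple[stats.DeltaObservation, ...]
    dose_results: tuple[stats.DoseResult, ...]


def _features_row(well: str, window: str, feats: WellFeatures) -> dict[str, object]:
    return {
        "well": well,
        "window": window,
        "peak_number": feats.peak_number,
        "mean_width_ms": feats.mean_width,
        "mean_amplitude": feats.mean_amplitude,
        "mean_auc": feats.mean_auc,
        "mean_peak_to_peak_ms": feats.mean_peak_to_peak,
        "n_events_raw": feats.n_events_raw,
        "n_events_large": feats.n_events_large,
    }


def analyze_plate(
    traces: Mapping[tuple[str, str], Trace],
    plate_map: PlateMap,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Detect pulses and build per-well percent-change observations.

    ``traces`` is keyed by (well, window) with windows ``baseline`` and
    ``post``.  Edge wells and unmapped wells are logged and excluded.
    The baseline window's pulse amplitudes serve as the large-pulse
    reference for the same well's post window.
    """
    config = config or RunConfig()
    cfg = config.detector
    rows: list[dict[str, object]] = []
    observations: list[stats.DeltaObservation] = []
    treated = plate_map.treated_wells()
    wells = sorted({well for well, _ in traces})
    for well in wells:
        if well not in treated:
            log.info("well %s excluded: no treatment assigned (edge or empty)", well)
            continue
        try:
            baseline = traces[well, "baseline"]
            post = traces[well, "post"]
        except KeyError as exc:
            raise ValueError(f"well {well}: missing window {exc} in trace set") from exc
        base_events = detect_pulses(baseline, cfg)
        base_ref = [ev.amplitude for ev in base_events if ev.is_large]
        post_events = detect_pulses(post, cfg, reference_amplitudes=base_ref or None)
        base_feats = compute_features(baseline, base_events, cfg)
        post_feats = compute_features(post, post_events, cfg)
        rows.append(_features_row(well, "baseline", base_feats))
        rows.append(_features_row(well, "post", post_feats))
        assignment = treated[well]
        obs = stats.delta_observation(
            well,
            plate_map.plate_id,
            assignment.treatment,
            assignment.concentration,
            base_feats.peak_number,
            post_feats.peak_number,
        )
        if obs.excluded:
            log.info("well %s excluded: %s", well, obs.reason)
        observations.append(obs)
    features = pd.DataFrame(rows)
    results = dose_results_from_observations(observations, config)
    return PipelineResult(features, tuple(observations), tuple(results))


def dose_results_from_observations(
    observations: Sequence[stats.DeltaObservation],
    config: RunConfig | None = None,
    vehicle: str = reference_data.VEHICLE_NAME,
) -> list[stats.DoseResult]:
    """Group observations by drug x concentration and test versus vehicle."""
    config = config or RunConfig()
    dmso = [o for o in observations if o.treatment == vehicle]
    if not any(not o.excluded for o in dmso):
        raise ValueError("no usable vehicle wells on the plate")
    groups: dict[tuple[str, float], list[stats.DeltaObservation]] = {}
    for obs in observations:
        if obs.treatment == vehicle:
            continue
        groups.setdefault((obs.treatment, obs.concentration), []).append(obs)
    results = []
    for (drug, conc), group in sorted(groups.items()):
        results.append(
            stats.summarize_dose(group, dmso, alpha=config.alpha, culture=config.culture)
        )
    return results


def control_tolerance_intervals(
    observations: Sequence[stats.DeltaObservation],
    config: RunConfig | None = None,
    treatments: Sequence[str] = (reference_data.VEHICLE_NAME,),
) -> dict[str, stats.ToleranceInterval | str]:
    """Tolerance intervals for control groups' percent changes.

    Groups whose sample size cannot reach the configured confidence are
    reported with the failure message instead of an interval.
    """
    config = config or RunConfig()
    out: dict[str, stats.ToleranceInterval | str] = {}
    for treatment in treatments:
        deltas = [
            o.delta_pct for o in observations
            if o.treatment == treatment and not o.excluded
        ]
        try:
            out[treatment] = stats.tolerance_interval(
                deltas, config.tolerance_coverage, config.tolerance_confidence
            )
        except ValueError as exc:
            out[treatment] = str(exc)
    return out


# ---------------------------------------------------------------------------
# replay mode
# ---------------------------------------------------------------------------

def run_replay(culture: str = "2D") -> classify.PredictivityReport:
    """Score the packaged per-drug call table against the clinical labels."""
    panel = reference_data.load_drug_panel()
    sig_calls = reference_data.load_significance_calls()
    calls = classify.calls_from_significance(sig_calls, panel, culture)
    cm = classify.build_confusion(calls, panel)
    return classify.predictivity_metrics(cm, per_drug_calls=calls)


# ---------------------------------------------------------------------------
# demo simulation
# ---------------------------------------------------------------------------

def simulate_demo_plate(
    seed: int = 0,
    n_wells_per_drug: int = 6,
    n_vehicle_wells: int = 12,
    base_rate: float = 12.0,
    drugs: Mapping[str, int] | None = None,
) -> tuple[PlateSimulation, PlateMap]:
    """Simulate a small plate of published-effect-calibrated treatments.

    Each demo drug is dosed at one concentration whose rate effect is
    calibrated from the packaged per-dose summary table; vehicle wells
    get the identity effect.
    """
    drugs = dict(drugs) if drugs is not None else dict(DEMO_DRUGS)
    summaries = {
        (s.drug, s.dose_index): s for s in reference_data.load_dose_summaries()
        if s.culture == "2D"
    }
    effects: dict[str, DrugEffectModel] = {reference_data.VEHICLE_NAME: DrugEffectModel()}
    doses: dict[str, float] = {}
    for drug, dose_index in drugs.items():
        summary = summaries[drug, dose_index]
        effects[drug] = effect_from_dose_summary(summary)
        doses[drug] = summary.concentration

    interior = well_labels(include_edge=False)
    treatments: dict[str, tuple[str, float]] = {}
    cursor = 0
    for drug in drugs:
        for _ in range(n_wells_per_drug):
            treatments[interior[cursor]] = (drug, doses[drug])
            cursor += 1
    for _ in range(n_vehicle_wells):
        treatments[interior[cursor]] = (reference_data.VEHICLE_NAME, 0.1)
        cursor += 1

    # realistic well-to-well spread: interval jitter at this level reproduces
    # per-dose percent-change SDs of roughly 15-25 %
    models = {
        well: WellModel(base_rate=base_rate, rate_jitter_cv=0.6, noise_sd=5.0)
        for well in treatments
    }
    sim = simulate_plate(treatments, models, effects, PulseShapeParams(), seed=seed)
    assignments = {
        well: WellAssignment(
            treatment=treatment,
            concentration=conc,
            role="vehicle" if treatment == reference_data.VEHICLE_NAME else "test",
        )
        for well, (treatment, conc) in treatments.items()
    }
    plate_map = PlateMap.from_assignments(f"demo-{seed}", assignments)
    return sim, plate_map
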