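"""Drug-level activity calls and panel predictivity metrics.

A drug is called *neuronally active* when any tested concentration
changed the peak number significantly versus same-plate vehicle; the
reported direction and concentration come from the lowest significant
dose.  A significant increase is additionally flagged as a potential
seizure signal.  Calls are scored against the panel's clinical labels:

* TP — clinically active drug with a significant call (either direction)
* FN — clinically active drug with no significant call
* TN — clinical negative with no significant call
* FP — clinical negative with a significant call

Sensitivity, specificity, PPV and NPV follow the usual ratios.  The
headline *predictivity* statistic divides (TP + TN) by the number of
clinically active drugs on the panel — a reverse-engineered convention
(see below) rather than the textbook accuracy over all drugs.

Concentrations are contextualized as fold-multiples of the drug's free
therapeutic plasma concentration (fCmax, upper bound of the published
range); drugs with no published fCmax propagate an absent fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .reference_data import DrugRecord, SignificanceCall
from .stats import DoseResult

__all__ = [
    "DrugCall",
    "ConfusionMatrix",
    "PredictivityReport",
    "call_drug",
    "calls_from_significance",
    "fold_cmax",
    "fold_bin",
    "build_confusion",
    "predictivity_metrics",
]

FOLD_BINS = ("<=1x", "<=10x", "<=30x", ">30x")


@dataclass(frozen=True)
class DrugCall:
    """Drug-level outcome for one culture format."""

    drug: str
    culture: str
    direction: str  # up | down | none
    lowest_significant_concentration: float | None
    fold_over_cmax: float | None
    activity: str  # neuronally_active | non_active
    seizure_flag: bool

    def __post_init__(self) -> None:
        if (self.direction != "none") != (self.activity == "neuronally_active"):
            raise ValueError(f"{self.drug}: activity inconsistent with direction")
        if self.seizure_flag and self.direction != "up":
            raise ValueError(f"{self.drug}: seizure flag requires an increase")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int
    n_active_expected: int
    n_negative_expected: int

    def __post_init__(self) -> None:
        if self.tp + self.fn != self.n_active_expected:
            raise ValueError("TP + FN must equal the expected-active count")
        if self.tn + self.fp != self.n_negative_expected:
            raise ValueError("TN + FP must equal the expected-negative count")


@dataclass(frozen=True)
class PredictivityReport:
    """Panel-level metrics, in percent; undefined ratios are ``None``."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    predictivity: float | None
    confusion: ConfusionMatrix
    per_drug_calls: tuple[DrugCall, ...] = ()


# ---------------------------------------------------------------------------
# drug-level calls
# ---------------------------------------------------------------------------

def fold_cmax(concentration: float, record: DrugRecord) -> float | None:
    """Concentration as a fold-multiple of the drug's (upper) free Cmax."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if record.free_cmax_high is None:
        return None
    return concentration / record.free_cmax_high


def fold_bin(fold: float | None) -> str | None:
    """Bin a fold-over-Cmax value; absent folds skip binning."""
    if fold is None:
        return None
    if fold <= 1:
        return FOLD_BINS[0]
    if fold <= 10:
        return FOLD_BINS[1]
    if fold <= 30:
        return FOLD_BINS[2]
    return FOLD_BINS[3]


def _make_call(drug: str, culture: str, direction: str,
               concentration: float | None, record: DrugRecord) -> DrugCall:
    fold = (
        fold_cmax(concentration, record)
        if (direction != "none" and concentration is not None)
        else None
    )
    return DrugCall(
        drug=drug,
        culture=culture,
        direction=direction,
        lowest_significant_concentration=concentration if direction != "none" else None,
        fold_over_cmax=fold,
        activity="neuronally_active" if direction != "none" else "non_active",
        seizure_flag=direction == "up",
    )


def call_drug(dose_results: Sequence[DoseResult], record: DrugRecord) -> DrugCall:
    """Collapse the four dose results of one drug/culture into one call."""
    if len(dose_results) != 4:
        raise ValueError(f"{record.name}: expected 4 dose results, got {len(dose_results)}")
    if any(r.drug != record.name for r in dose_results):
        raise ValueError(f"{record.name}: dose results from a different drug")
    cultures = {r.culture for r in dose_results}
    if len(cultures) != 1:
        raise ValueError(f"{record.name}: dose results mix cultures")
    ordered = sorted(dose_results, key=lambda r: r.concentration)
    significant = [r for r in ordered if r.significant]
    if not significant:
        return _make_call(record.name, next(iter(cultures)), "none", None, record)
    lowest = significant[0]
    return _make_call(record.name, lowest.culture, lowest.direction,
                      lowest.concentration, record)


def calls_from_significance(
    calls: Sequence[SignificanceCall],
    panel: Sequence[DrugRecord],
    culture: str,
) -> list[DrugCall]:
    """Replay mode: drug calls straight from the packaged call table."""
    records = {r.name: r for r in panel if not r.is_vehicle}
    out: list[DrugCall] = []
    for call in calls:
        if call.culture != culture:
            continue
        if call.drug not in records:
            raise ValueError(f"call for unknown drug {call.drug!r}")
        conc = call.call_concentration if call.direction != "none" else None
        out.append(_make_call(call.drug, culture, call.direction, conc, records[call.drug]))
    if len(out) != len(records):
        raise ValueError(f"expected one {culture} call per drug, got {len(out)}")
    return out


# ---------------------------------------------------------------------------
# panel metrics
# ---------------------------------------------------------------------------

def build_confusion(calls: Sequence[DrugCall], panel: Sequence[DrugRecord]) -> ConfusionMatrix:
    """Score drug-level calls against the panel's clinical labels."""
    records = {r.name: r for r in panel if not r.is_vehicle}
    by_drug = {c.drug: c for c in calls}
    if set(by_drug) != set(records) or len(calls) != len(records):
        missing = set(records) ^ set(by_drug)
        raise ValueError(f"calls do not match panel; mismatched drugs: {sorted(missing)}")
    tp = tn = fp = fn = 0
    for name, record in records.items():
        significant = by_drug[name].direction != "none"
        if record.clinical_class == "neuronally_active":
            tp += significant
            fn += not significant
        else:
            fp += significant
            tn += not significant
    return ConfusionMatrix(
        tp=tp, tn=tn, fp=fp, fn=fn,
        n_active_expected=tp + fn,
        n_negative_expected=tn + fp,
    )


def _ratio(num: int, den: int) -> float | None:
    return 100.0 * num / den if den else None


def predictivity_metrics(
    cm: ConfusionMatrix,
    per_drug_calls: Sequence[DrugCall] = (),
) -> PredictivityReport:
    """Sensitivity, specificity, PPV, NPV and the predictivity statistic.

    Predictivity = 100 x (TP + TN) / expected-active count.  The usual
    accuracy over the whole panel does not reproduce the published
    headline percentages; this denominator convention reproduces both
    culture formats' values and was confirmed by a brute-force search
    over candidate formulas (see the package tests).
    """
    return PredictivityReport(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        predictivity=_ratio(cm.tp + cm.tn, cm.n_active_expected),
        confusion=cm,
        per_drug_calls=tuple(per_drug_calls),
    )
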