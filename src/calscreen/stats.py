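"""Treatment-effect statistics on per-well percent changes.

Each well contributes one observation: the percent change of its peak
number between the baseline window and the post-treatment window.
Observations are grouped by drug and concentration on each plate and
compared against the same plate's vehicle (DMSO) wells with a two-sided
two-sample Wilcoxon rank-sum test (the samples are different wells, not
pairs).  A dose is called significant at p < 0.05; no multiple-testing
adjustment is applied, matching the per-concentration decision rule.

Nonparametric tolerance intervals (population coverage P with stated
confidence) summarize the spread of control wells using symmetric order
statistics: the coverage of (X(r), X(s)), s = n - r + 1, follows a
Beta(s - r, n - s + r + 1) law, independent of the sampled
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "DeltaObservation",
    "DoseResult",
    "ToleranceInterval",
    "percent_change",
    "delta_observation",
    "wilcoxon_vs_dmso",
    "tolerance_interval",
    "min_feasible_n",
    "summarize_dose",
]

ALPHA = 0.05
EXACT_MAX_N = 20  # combined sample size up to which the exact null is enumerated


@dataclass(frozen=True)
class DeltaObservation:
    """One well's percent change of peak number, or its exclusion."""

    well_id: str
    plate_id: str
    treatment: str
    concentration: float
    delta_pct: float | None
    excluded: bool = False
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.excluded:
            if self.delta_pct is not None or not self.reason:
                raise ValueError(f"{self.well_id}: excluded wells carry a reason and no delta")
        else:
            if self.delta_pct is None:
                raise ValueError(f"{self.well_id}: included well without a delta")
            if self.delta_pct < -100.0:
                raise ValueError(f"{self.well_id}: delta below the -100% cessation floor")


@dataclass(frozen=True)
class DoseResult:
    """Summary of one drug x concentration versus same-plate vehicle."""

    drug: str
    concentration: float
    n_wells: int
    mean_delta_pct: float
    sd_delta_pct: float
    p_value: float
    significant: bool
    direction: str  # up | down | none
    culture: str = "2D"
    plate_id: str = ""

    def __post_init__(self) -> None:
        if self.significant != (self.p_value < ALPHA):
            raise ValueError("significant flag inconsistent with p-value")
        expected = (
            "none" if not self.significant else ("up" if self.mean_delta_pct > 0 else "down")
        )
        if self.direction != expected:
            raise ValueError(f"direction {self.direction!r} inconsistent (expected {expected!r})")


@dataclass(frozen=True)
class ToleranceInterval:
    lower: float
    upper: float
    coverage_P: float
    confidence: float  # achieved
    order_indices: tuple[int, int]  # (r, s), 1-based

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("tolerance interval bounds inverted")


# ---------------------------------------------------------------------------
# percent change
# ---------------------------------------------------------------------------

def percent_change(baseline: float, post: float) -> float | None:
    """100 x (post - baseline) / baseline; ``None`` when baseline is 0."""
    if baseline < 0 or post < 0:
        raise ValueError("peak numbers must be non-negative")
    if baseline == 0:
        return None
    return 100.0 * (post - baseline) / baseline


def delta_observation(
    well_id: str,
    plate_id: str,
    treatment: str,
    concentration: float,
    baseline_peak_number: float,
    post_peak_number: float,
) -> DeltaObservation:
    """Build a per-well observation, excluding zero-baseline wells."""
    delta = percent_change(baseline_peak_number, post_peak_number)
    if delta is None:
        return DeltaObservation(
            well_id, plate_id, treatment, concentration, None,
            excluded=True, reason="zero baseline",
        )
    return DeltaObservation(well_id, plate_id, treatment, concentration, delta)


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def wilcoxon_vs_dmso(drug_deltas: Sequence[float], dmso_deltas: Sequence[float]) -> float:
    """Two-sided two-sample rank-sum p-value (drug vs same-plate vehicle).

    Exact enumeration when the combined sample size is at most 20 and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(drug_deltas, dtype=float)
    y = np.asarray(dmso_deltas, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0  # no rank separation at all
    if x.size + y.size <= EXACT_MAX_N and not _has_ties(pooled):
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# tolerance intervals
# ---------------------------------------------------------------------------

def _achieved_confidence(n: int, r: int, coverage: float) -> float:
    # coverage of (X(r), X(n-r+1)) ~ Beta(n - 2r + 1, 2r)
    return float(sps.beta.sf(coverage, n - 2 * r + 1, 2 * r))


def min_feasible_n(coverage: float, confidence: float) -> int:
    """Smallest n whose extreme order statistics reach the confidence."""
    n = 2
    while _achieved_confidence(n, 1, coverage) < confidence:
        n += 1
        if n > 100_000:  # pragma: no cover - unreachable for sane inputs
            raise RuntimeError("tolerance-interval search did not converge")
    return n


def tolerance_interval(
    samples: Sequence[float],
    coverage_P: float = 0.80,
    confidence: float = 0.95,
) -> ToleranceInterval:
    """Two-sided distribution-free tolerance interval from order statistics.

    Picks the most interior symmetric pair (largest r with s = n - r + 1)
    whose coverage probability still meets the confidence target; raises
    when even the sample extremes fall short, reporting the minimal
    feasible sample size.
    """
    if not 0 < coverage_P < 1 or not 0 < confidence < 1:
        raise ValueError("coverage and confidence must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2 or _achieved_confidence(n, 1, coverage_P) < confidence:
        raise ValueError(
            f"n={n} infeasible for P={coverage_P}, confidence={confidence}; "
            f"need n >= {min_feasible_n(coverage_P, confidence)}"
        )
    r = 1
    while 2 * (r + 1) <= n and _achieved_confidence(n, r + 1, coverage_P) >= confidence:
        r += 1
    s = n - r + 1
    return ToleranceInterval(
        lower=float(x[r - 1]),
        upper=float(x[s - 1]),
        coverage_P=coverage_P,
        confidence=_achieved_confidence(n, r, coverage_P),
        order_indices=(r, s),
    )


# ---------------------------------------------------------------------------
# per-dose summary
# ---------------------------------------------------------------------------

def summarize_dose(
    observations: Sequence[DeltaObservation],
    dmso: Sequence[DeltaObservation],
    alpha: float = ALPHA,
    culture: str = "2D",
) -> DoseResult:
    """Mean/SD and vehicle-comparison p-value for one drug x dose group."""
    included = [o for o in observations if not o.excluded]
    if not included:
        raise ValueError("all wells of the dose group are excluded")
    drugs = {o.treatment for o in included}
    concs = {o.concentration for o in included}
    plates = {o.plate_id for o in included}
    if len(drugs) != 1 or len(concs) != 1 or len(plates) != 1:
        raise ValueError("dose group must share drug, concentration and plate")
    dmso_deltas = [o.delta_pct for o in dmso if not o.excluded and o.plate_id in plates]
    deltas = [o.delta_pct for o in included]
    p = wilcoxon_vs_dmso(deltas, dmso_deltas)
    mean = float(np.mean(deltas))
    sd = float(np.std(deltas, ddof=1)) if len(deltas) > 1 else 0.0
    significant = bool(p < alpha)
    direction = "none" if not significant else ("up" if mean > 0 else "down")
    return DoseResult(
        drug=next(iter(drugs)),
        concentration=next(iter(concs)),
        n_wells=len(included),
        mean_delta_pct=mean,
        sd_delta_pct=sd,
        p_value=p,
        significant=significant,
        direction=direction,
        culture=culture,
        plate_id=next(iter(plates)),
    )
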