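"""Packaged reference tables for the 25-drug screening panel.

Three delimiter-separated fixtures ship with the package:

``drug_panel.tsv``
    Drug identity, free therapeutic plasma concentration (fCmax, µM),
    the four tested concentrations (µM) and the clinical activity label
    (3 negative controls, 22 neuronally active drugs, plus the DMSO
    vehicle entry).
``significance_calls.tsv``
    The per-drug, per-culture (2D/3D) peak-number call: direction of the
    significant change and the concentration at which it was called.
``dose_summaries.tsv``
    Per-drug, per-dose mean/SD of the percent change in peak number with
    the rank-test significance level versus same-plate vehicle.

Loaders validate row counts and field invariants and fail loudly naming
the offending file/row.  ``cross_table_report`` compares the call table
against the per-dose table and returns discrepancies as text, because
the two printed sources do not agree everywhere.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "DrugRecord",
    "SignificanceCall",
    "DoseSummary",
    "load_drug_panel",
    "load_significance_calls",
    "load_dose_summaries",
    "write_drug_panel",
    "write_significance_calls",
    "write_dose_summaries",
    "cross_table_report",
    "NEGATIVE_CONTROLS",
    "VEHICLE_NAME",
]

VEHICLE_NAME = "DMSO"
#: the three clinically non-neuronally-active drugs of the panel
NEGATIVE_CONTROLS = ("Aspirin", "Amoxicillin", "Acetaminophen")

CULTURES = ("2D", "3D")
DIRECTIONS = ("up", "down", "none")
SIGNIFICANCE_LEVELS = ("ns", "p<0.05", "p<0.01")


@dataclass(frozen=True)
class DrugRecord:
    """One panel entry: identity, fCmax range, tested doses, clinical label."""

    name: str
    cas: str
    source: str
    free_cmax_low: float | None
    free_cmax_high: float | None
    tested_concentrations: tuple[float, ...]
    clinical_class: str  # vehicle | negative_control | neuronally_active
    class_note: str

    def __post_init__(self) -> None:
        if self.clinical_class not in ("vehicle", "negative_control", "neuronally_active"):
            raise ValueError(f"{self.name}: bad clinical_class {self.clinical_class!r}")
        if self.clinical_class != "vehicle" and len(self.tested_concentrations) != 4:
            raise ValueError(f"{self.name}: expected 4 tested concentrations")
        concs = self.tested_concentrations
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError(f"{self.name}: tested concentrations not strictly increasing")
        if (self.free_cmax_low is None) != (self.free_cmax_high is None):
            raise ValueError(f"{self.name}: fCmax bounds must both be present or both absent")
        if self.free_cmax_low is not None and self.free_cmax_low > self.free_cmax_high:
            raise ValueError(f"{self.name}: fCmax low > high")

    @property
    def is_vehicle(self) -> bool:
        return self.clinical_class == "vehicle"


@dataclass(frozen=True)
class SignificanceCall:
    """Per-drug, per-culture peak-number direction call."""

    drug: str
    culture: str
    direction: str  # up | down | none
    call_concentration: float

    def __post_init__(self) -> None:
        if self.culture not in CULTURES:
            raise ValueError(f"{self.drug}: bad culture {self.culture!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"{self.drug}/{self.culture}: bad direction {self.direction!r}")
        if not self.call_concentration > 0:
            raise ValueError(f"{self.drug}/{self.culture}: non-positive concentration")


@dataclass(frozen=True)
class DoseSummary:
    """Mean/SD percent change of peak number for one drug at one dose."""

    drug: str
    culture: str
    dose_index: int
    concentration: float
    mean_delta_pct: float
    sd_delta_pct: float
    significance: str  # ns | p<0.05 | p<0.01

    def __post_init__(self) -> None:
        if self.culture not in CULTURES:
            raise ValueError(f"{self.drug}: bad culture {self.culture!r}")
        if self.dose_index not in (1, 2, 3, 4):
            raise ValueError(f"{self.drug}/{self.culture}: dose_index out of range")
        if self.mean_delta_pct < -100.0:
            raise ValueError(f"{self.drug}/{self.culture}: mean below -100% cessation floor")
        if self.sd_delta_pct < 0.0:
            raise ValueError(f"{self.drug}/{self.culture}: negative SD")
        if self.significance not in SIGNIFICANCE_LEVELS:
            raise ValueError(f"{self.drug}/{self.culture}: bad significance {self.significance!r}")

    @property
    def significant(self) -> bool:
        return self.significance != "ns"


# ---------------------------------------------------------------------------
# fixture IO
# ---------------------------------------------------------------------------

def _fixture_path(name: str) -> Path:
    path = Path(str(resources.files("calscreen").joinpath("data", name)))
    if not path.is_file():
        raise FileNotFoundError(f"packaged fixture missing: {name}")
    return path


def _read_rows(path: Path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    rows = list(reader)
    if not rows:
        raise ValueError(f"fixture {path.name} is empty or corrupt")
    return rows


def _maybe_float(text: str) -> float | None:
    text = text.strip()
    if text in ("na", "", "-"):
        return None
    return float(text)


def load_drug_panel(path: str | Path | None = None) -> list[DrugRecord]:
    """Load the drug panel fixture: 25 drug records plus one vehicle entry."""
    path = Path(path) if path is not None else _fixture_path("drug_panel.tsv")
    records: list[DrugRecord] = []
    for row in _read_rows(path):
        try:
            concs = tuple(
                c for c in (_maybe_float(row[f"conc_{i}"]) for i in (1, 2, 3, 4)) if c is not None
            )
            records.append(
                DrugRecord(
                    name=row["name"],
                    cas=row["cas"],
                    source=row["source"],
                    free_cmax_low=_maybe_float(row["free_cmax_low"]),
                    free_cmax_high=_maybe_float(row["free_cmax_high"]),
                    tested_concentrations=concs,
                    clinical_class=row["clinical_class"],
                    class_note=row["class_note"],
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path.name}: bad row for {row.get('name', '?')!r}: {exc}") from exc
    n_drugs = sum(1 for r in records if not r.is_vehicle)
    n_vehicle = sum(1 for r in records if r.is_vehicle)
    if n_drugs != 25 or n_vehicle != 1:
        raise ValueError(
            f"{path.name}: expected 25 drugs + 1 vehicle, found {n_drugs} + {n_vehicle}"
        )
    negatives = {r.name for r in records if r.clinical_class == "negative_control"}
    if negatives != set(NEGATIVE_CONTROLS):
        raise ValueError(f"{path.name}: negative controls are {sorted(negatives)}")
    return records


def load_significance_calls(path: str | Path | None = None) -> list[SignificanceCall]:
    """Load the per-drug call fixture: 25 drugs x 2 cultures = 50 calls."""
    path = Path(path) if path is not None else _fixture_path("significance_calls.tsv")
    calls: list[SignificanceCall] = []
    for row in _read_rows(path):
        try:
            calls.append(
                SignificanceCall(
                    drug=row["drug"],
                    culture=row["culture"],
                    direction=row["direction"],
                    call_concentration=float(row["concentration_uM"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(
                f"{path.name}: unparseable call for drug={row.get('drug', '?')!r} "
                f"culture={row.get('culture', '?')!r}: {exc}"
            ) from exc
    if len(calls) != 50:
        raise ValueError(f"{path.name}: expected 50 calls, found {len(calls)}")
    for culture in CULTURES:
        drugs = [c.drug for c in calls if c.culture == culture]
        if len(set(drugs)) != 25 or len(drugs) != 25:
            raise ValueError(f"{path.name}: {culture} calls not exactly one per drug")
    return calls


def load_dose_summaries(path: str | Path | None = None) -> list[DoseSummary]:
    """Load the per-dose summary fixture: 25 drugs x 2 cultures x 4 doses."""
    path = Path(path) if path is not None else _fixture_path("dose_summaries.tsv")
    rows = _read_rows(path)
    summaries: list[DoseSummary] = []
    for row in rows:
        try:
            summaries.append(
                DoseSummary(
                    drug=row["drug"],
                    culture=row["culture"],
                    dose_index=int(row["dose_index"]),
                    concentration=float(row["concentration_uM"]),
                    mean_delta_pct=float(row["mean_delta_pct"]),
                    sd_delta_pct=float(row["sd_delta_pct"]),
                    significance=row["significance"],
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(
                f"{path.name}: bad row for drug={row.get('drug', '?')!r}: {exc}"
            ) from exc
    if len(summaries) != 200:
        raise ValueError(f"{path.name}: expected 200 rows, found {len(summaries)}")
    return summaries


# ---------------------------------------------------------------------------
# writers (round-trip support)
# ---------------------------------------------------------------------------

def _fmt(value: float | None) -> str:
    if value is None:
        return "na"
    return format(value, "g")


def write_drug_panel(records: Iterable[DrugRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["name", "cas", "source", "free_cmax_low", "free_cmax_high",
             "conc_1", "conc_2", "conc_3", "conc_4", "clinical_class", "class_note"]
        )
        for r in records:
            concs = list(r.tested_concentrations) + [None] * (4 - len(r.tested_concentrations))
            writer.writerow(
                [r.name, r.cas, r.source, _fmt(r.free_cmax_low), _fmt(r.free_cmax_high)]
                + [_fmt(c) for c in concs]
                + [r.clinical_class, r.class_note]
            )


def write_significance_calls(calls: Iterable[SignificanceCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["drug", "culture", "direction", "concentration_uM"])
        for c in calls:
            writer.writerow([c.drug, c.culture, c.direction, _fmt(c.call_concentration)])


def write_dose_summaries(summaries: Iterable[DoseSummary], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["drug", "culture", "dose_index", "concentration_uM",
             "mean_delta_pct", "sd_delta_pct", "significance"]
        )
        for s in summaries:
            writer.writerow(
                [s.drug, s.culture, s.dose_index, _fmt(s.concentration),
                 _fmt(s.mean_delta_pct), _fmt(s.sd_delta_pct), s.significance]
            )


# ---------------------------------------------------------------------------
# consistency report
# ---------------------------------------------------------------------------

def cross_table_report(
    calls: Sequence[SignificanceCall] | None = None,
    summaries: Sequence[DoseSummary] | None = None,
) -> list[str]:
    """Compare the call table against the per-dose table.

    Returns one line per discrepancy.  This is a report, not an
    assertion: the two printed sources disagree for a handful of cells
    (e.g. doses flagged significant whose drug-level call is "none"),
    and the fixtures preserve each table verbatim.
    """
    calls = list(calls) if calls is not None else load_significance_calls()
    summaries = list(summaries) if summaries is not None else load_dose_summaries()
    by_key: dict[tuple[str, str], list[DoseSummary]] = {}
    for s in summaries:
        by_key.setdefault((s.drug, s.culture), []).append(s)
    lines: list[str] = []
    for call in calls:
        doses = sorted(by_key.get((call.drug, call.culture), []), key=lambda s: s.dose_index)
        if not doses:
            lines.append(f"{call.drug}/{call.culture}: no per-dose rows")
            continue
        sig = [d for d in doses if d.significant]
        if call.direction == "none":
            if sig:
                lines.append(
                    f"{call.drug}/{call.culture}: call is 'none' but doses "
                    f"{[d.concentration for d in sig]} are flagged significant"
                )
            continue
        if not sig:
            lines.append(
                f"{call.drug}/{call.culture}: call is '{call.direction}' but no dose "
                "is flagged significant"
            )
            continue
        lowest = sig[0]
        implied = "up" if lowest.mean_delta_pct > 0 else "down"
        if implied != call.direction:
            lines.append(
                f"{call.drug}/{call.culture}: call '{call.direction}' vs sign of lowest "
                f"significant dose mean ({lowest.mean_delta_pct:+.1f}% at "
                f"{lowest.concentration} µM)"
            )
    return lines
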