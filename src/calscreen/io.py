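"""File formats: wide trace tables, plate maps, and run configuration.

Trace files are wide delimiter-separated text: a ``time_s`` column
followed by one fluorescence column per well label.  Plate maps assign
each of the 384 wells a treatment, concentration and role; the 144
outer wells always carry the ``edge_unused`` role because their
oscillations are unstable.  Run configuration is a flat ``key = value``
text document whose defaults mirror the assay protocol (2 Hz / 10 Hz
sampling, 1200 s windows, alpha 0.05, tolerance P 0.80 at 95 %
confidence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .synthetic import is_edge_well, well_labels
from .waveform import DetectorConfig, Trace

__all__ = [
    "WellAssignment",
    "PlateMap",
    "RunConfig",
    "read_traces",
    "write_traces",
    "read_plate_map",
    "write_plate_map",
]

ROLES = ("vehicle", "negative_control", "positive_control", "test", "edge_unused")
_TIME_TOLERANCE_S = 1e-9


@dataclass(frozen=True)
class WellAssignment:
    treatment: str
    concentration: float
    role: str  # vehicle | negative_control | positive_control | test | edge_unused

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"bad role {self.role!r}")


@dataclass(frozen=True)
class PlateMap:
    """Assignment of all 384 wells of one plate."""

    plate_id: str
    wells: dict[str, WellAssignment]

    def __post_init__(self) -> None:
        expected = set(well_labels())
        if set(self.wells) != expected:
            missing = sorted(expected - set(self.wells))[:5]
            extra = sorted(set(self.wells) - expected)[:5]
            raise ValueError(
                f"plate {self.plate_id}: map must cover all 384 wells "
                f"(missing {missing}, extra {extra})"
            )
        for well, assignment in self.wells.items():
            if is_edge_well(well) != (assignment.role == "edge_unused"):
                raise ValueError(
                    f"plate {self.plate_id}: well {well} role {assignment.role!r} "
                    "conflicts with its edge status"
                )

    @classmethod
    def from_assignments(
        cls, plate_id: str, assignments: Mapping[str, WellAssignment]
    ) -> "PlateMap":
        """Build a full map from interior assignments; unassigned interior
        wells become untreated ``test`` wells, edges become ``edge_unused``."""
        wells: dict[str, WellAssignment] = {}
        for well in well_labels():
            if is_edge_well(well):
                wells[well] = WellAssignment("", 0.0, "edge_unused")
            elif well in assignments:
                wells[well] = assignments[well]
            else:
                wells[well] = WellAssignment("", 0.0, "test")
        return cls(plate_id, wells)

    def treated_wells(self) -> dict[str, WellAssignment]:
        """Interior wells with a treatment assigned."""
        return {
            w: a for w, a in self.wells.items() if a.role != "edge_unused" and a.treatment
        }


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run parameters with protocol defaults."""

    detector: DetectorConfig = field(default_factory=DetectorConfig)
    rate_hz: float = 2.0  # 2 Hz for 2D, 10 Hz for 3D recordings
    window_s: float = 1200.0  # 20-min recording windows
    alpha: float = 0.05
    tolerance_coverage: float = 0.80
    tolerance_confidence: float = 0.95
    seed: int = 0
    culture: str = "2D"

    def __post_init__(self) -> None:
        if self.culture not in ("2D", "3D"):
            raise ValueError(f"bad culture {self.culture!r}")
        if float(self.rate_hz) not in (2.0, 10.0):
            raise ValueError("rate_hz must be 2 or 10")
        if self.window_s <= 0 or not 0 < self.alpha < 1:
            raise ValueError("bad window length or alpha")

    def to_file(self, path: str | Path) -> None:
        lines = [
            "# flat key = value run configuration",
            f"rate_hz = {self.rate_hz:g}",
            f"window_s = {self.window_s:g}",
            f"alpha = {self.alpha:g}",
            f"tolerance_coverage = {self.tolerance_coverage:g}",
            f"tolerance_confidence = {self.tolerance_confidence:g}",
            f"seed = {self.seed}",
            f"culture = {self.culture}",
            f"detector.smooth_window = {self.detector.smooth_window:g}",
            f"detector.derivative_threshold_k = {self.detector.derivative_threshold_k:g}",
            f"detector.refractory = {self.detector.refractory:g}",
            f"detector.large_peak_fraction = {self.detector.large_peak_fraction:g}",
            f"detector.return_fraction = {self.detector.return_fraction:g}",
            f"detector.width_mode = {self.detector.width_mode}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        values: dict[str, str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: bad config line {raw!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            values[key] = val
        detector_kwargs = {}
        for f in fields(DetectorConfig):
            key = f"detector.{f.name}"
            if key in values:
                detector_kwargs[f.name] = (
                    values[key] if f.name == "width_mode" else float(values[key])
                )
        kwargs: dict[str, object] = {"detector": DetectorConfig(**detector_kwargs)}
        for name, cast in (
            ("rate_hz", float), ("window_s", float), ("alpha", float),
            ("tolerance_coverage", float), ("tolerance_confidence", float),
            ("seed", int), ("culture", str),
        ):
            if name in values:
                kwargs[name] = cast(values[name])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# trace tables
# ---------------------------------------------------------------------------

def write_traces(traces: Mapping[str, Trace], path: str | Path) -> None:
    """Write a wide trace table (time_s column + one column per well)."""
    traces = dict(traces)
    if not traces:
        raise ValueError("no traces to write")
    first = next(iter(traces.values()))
    for well, trace in traces.items():
        if trace.times.size != first.times.size or trace.rate_hz != first.rate_hz:
            raise ValueError(f"well {well}: traces must share the time axis")
    frame = pd.DataFrame({"time_s": first.times})
    for well, trace in traces.items():
        frame[well] = trace.values
    # %.17g guarantees doubles survive the text round trip bit-exactly
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_traces(
    path: str | Path,
    plate_map: PlateMap | None = None,
    rate_hz: float | None = None,
    window: str = "baseline",
) -> dict[str, Trace]:
    """Read a wide trace table into per-well traces.

    Validates a uniform time axis and the absence of NaNs, naming the
    offending row or well.  When a plate map is given, every mapped
    (treated or vehicle) well must be present in the file; edge wells
    are loaded like any other column and excluded downstream.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if "time_s" not in frame.columns:
        raise ValueError(f"{path}: first column must be 'time_s'")
    times = frame["time_s"].to_numpy(dtype=float)
    if times.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    steps = np.diff(times)
    dt = times[1] - times[0]
    bad = np.flatnonzero(np.abs(steps - dt) > _TIME_TOLERANCE_S)
    if bad.size:
        raise ValueError(f"{path}: non-uniform time step at row {int(bad[0]) + 1}")
    inferred_rate = rate_hz if rate_hz is not None else 1.0 / dt
    well_columns = [c for c in frame.columns if c != "time_s"]
    if plate_map is not None:
        required = {
            w for w, a in plate_map.wells.items()
            if a.role != "edge_unused" and a.treatment
        }
        missing = sorted(required - set(well_columns))
        if missing:
            raise ValueError(f"{path}: mapped wells missing from file: {missing}")
    traces: dict[str, Trace] = {}
    for well in well_columns:
        values = frame[well].to_numpy(dtype=float)
        if np.isnan(values).any():
            row = int(np.flatnonzero(np.isnan(values))[0])
            raise ValueError(f"{path}: NaN in well {well} at row {row}")
        traces[well] = Trace(well, times - times[0], values, inferred_rate, window)
    return traces


# ---------------------------------------------------------------------------
# plate maps
# ---------------------------------------------------------------------------

def write_plate_map(plate_map: PlateMap, path: str | Path) -> None:
    rows = [
        {
            "plate_id": plate_map.plate_id,
            "well": well,
            "treatment": assignment.treatment,
            "concentration_uM": assignment.concentration,
            "role": assignment.role,
        }
        for well, assignment in sorted(plate_map.wells.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_plate_map(path: str | Path) -> PlateMap:
    frame = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    plate_ids = frame["plate_id"].unique()
    if len(plate_ids) != 1:
        raise ValueError(f"{path}: expected exactly one plate, found {list(plate_ids)}")
    wells = {
        str(row.well): WellAssignment(
            treatment=str(row.treatment),
            concentration=float(row.concentration_uM) if row.concentration_uM != "" else 0.0,
            role=str(row.role),
        )
        for row in frame.itertuples()
    }
    return PlateMap(str(plate_ids[0]), wells)
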