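"""Ground-truth cells and calibration samples.

A ground-truth cell is one 30 m x 30 m raster pixel (900 m^2) whose
defoliated canopy area was delineated on high-resolution aerial imagery.
The interpreted defoliated fraction is expressed on a 5% grid, then binned
into four severity classes:

    nil 0-5% | low 10-30% | medium 35-65% | high 70-100%

Pairing each cell's observed defoliation fraction Y with the change-raster
value X at its pixel yields the calibration samples for the logistic model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, DataError
from .rasters import DviRaster
from .util import round_to_multiple

SEVERITY_CLASSES = ("nil", "low", "medium", "high")

#: upper percent bound of each class on the 5% interpretation grid
SEVERITY_UPPER_PCT = {"nil": 5, "low": 30, "medium": 65, "high": 100}

DEFAULT_CELL_AREA = 900.0  # m^2, one 30 m pixel


def defoliation_percent(defoliated_area: float, cell_area: float = DEFAULT_CELL_AREA) -> float:
    """Defoliated percent of a cell, rounded to the nearest 5% (ties away from zero)."""
    if cell_area <= 0:
        raise ConfigurationError("cell_area must be positive")
    if not 0 <= defoliated_area <= cell_area:
        raise DataError(
            f"defoliated_area {defoliated_area} outside [0, {cell_area}]"
        )
    return float(round_to_multiple(100.0 * defoliated_area / cell_area, 5))


def bin_severity(defoliation_pct: float) -> str:
    """Map a 5%-grid defoliation percent to its severity class."""
    pct = float(defoliation_pct)
    if not 0 <= pct <= 100:
        raise DataError(f"defoliation percent {pct} outside [0, 100]")
    if abs(pct / 5 - round(pct / 5)) > 1e-9:
        raise DataError(f"defoliation percent {pct} is not a multiple of 5")
    for cls in SEVERITY_CLASSES:
        if pct <= SEVERITY_UPPER_PCT[cls]:
            return cls
    raise AssertionError("unreachable")


@dataclass
class GroundTruthCell:
    """One interpreted 30 m cell, addressed by its (row, col) raster pixel."""

    cell_id: str
    row: int
    col: int
    defoliated_area: float
    cell_area: float = DEFAULT_CELL_AREA
    defoliation_pct: float | None = None
    severity: str | None = None

    def __post_init__(self):
        if self.defoliation_pct is None:
            self.defoliation_pct = defoliation_percent(self.defoliated_area, self.cell_area)
        else:
            if not 0 <= self.defoliation_pct <= 100:
                raise DataError(
                    f"cell {self.cell_id}: defoliation_pct {self.defoliation_pct} outside [0, 100]"
                )
        if self.severity is None:
            self.severity = bin_severity(self.defoliation_pct)
        elif self.severity != bin_severity(self.defoliation_pct):
            raise DataError(
                f"cell {self.cell_id}: severity {self.severity!r} inconsistent with "
                f"{self.defoliation_pct}% (expected {bin_severity(self.defoliation_pct)!r})"
            )


@dataclass
class CalibrationSample:
    """One (X, Y) calibration pair: change-raster value and defoliation fraction."""

    cell_id: str
    x: float
    y: float
    severity: str

    def __post_init__(self):
        if not 0.0 <= self.y <= 1.0:
            raise DataError(f"sample {self.cell_id}: y={self.y} outside [0, 1]")
        if not math.isfinite(self.x):
            raise DataError(f"sample {self.cell_id}: non-finite x")
        if self.severity not in SEVERITY_CLASSES:
            raise DataError(f"sample {self.cell_id}: unknown severity {self.severity!r}")


def extract_samples(dvi: DviRaster, cells: list[GroundTruthCell]) -> list[CalibrationSample]:
    """Pair each cell with the dVI value at its pixel, preserving input order.

    A cell out of bounds or sitting on a nodata pixel raises a
    :class:`DataError` naming the cell.
    """
    rows, cols = dvi.shape
    samples = []
    for cell in cells:
        if not (0 <= cell.row < rows and 0 <= cell.col < cols):
            raise DataError(
                f"cell {cell.cell_id}: pixel ({cell.row}, {cell.col}) outside raster {dvi.shape}"
            )
        value = int(dvi.grid[cell.row, cell.col])
        if value == dvi.nodata:
            raise DataError(f"cell {cell.cell_id}: pixel ({cell.row}, {cell.col}) is nodata")
        samples.append(
            CalibrationSample(
                cell_id=cell.cell_id,
                x=float(value),
                y=cell.defoliation_pct / 100.0,
                severity=cell.severity,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# CSV interchange

CELL_COLUMNS = ["cell_id", "row", "col", "defoliated_area_m2", "cell_area_m2", "defoliation_pct", "severity"]
SAMPLE_COLUMNS = ["cell_id", "x", "y", "severity"]


def write_cells_csv(path, cells: list[GroundTruthCell]) -> None:
    df = pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "row": c.row,
                "col": c.col,
                "defoliated_area_m2": c.defoliated_area,
                "cell_area_m2": c.cell_area,
                "defoliation_pct": c.defoliation_pct,
                "severity": c.severity,
            }
            for c in cells
        ],
        columns=CELL_COLUMNS,
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_cells_csv(path) -> list[GroundTruthCell]:
    df = pd.read_csv(path)
    missing = {"cell_id", "row", "col", "defoliated_area_m2"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    cells = []
    for rec in df.to_dict("records"):
        cells.append(
            GroundTruthCell(
                cell_id=str(rec["cell_id"]),
                row=int(rec["row"]),
                col=int(rec["col"]),
                defoliated_area=float(rec["defoliated_area_m2"]),
                cell_area=float(rec.get("cell_area_m2", DEFAULT_CELL_AREA)),
                defoliation_pct=(
                    float(rec["defoliation_pct"]) if "defoliation_pct" in rec and pd.notna(rec["defoliation_pct"]) else None
                ),
                severity=(rec["severity"] if "severity" in rec and pd.notna(rec["severity"]) else None),
            )
        )
    return cells


def write_samples_csv(path, samples: list[CalibrationSample]) -> None:
    df = pd.DataFrame(
        [{"cell_id": s.cell_id, "x": s.x, "y": s.y, "severity": s.severity} for s in samples],
        columns=SAMPLE_COLUMNS,
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_samples_csv(path) -> list[CalibrationSample]:
    df = pd.read_csv(path)
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    return [
        CalibrationSample(cell_id=str(r["cell_id"]), x=float(r["x"]), y=float(r["y"]), severity=str(r["severity"]))
        for r in df.to_dict("records")
    ]


def class_histogram(items) -> dict[str, int]:
    """Severity-class counts of cells or samples, keyed nil..high."""
    counts = {cls: 0 for cls in SEVERITY_CLASSES}
    for it in items:
        counts[it.severity] += 1
    return counts
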