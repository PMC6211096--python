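"""Threshold classification of change rasters and accuracy assessment.

The fitted logistic is strictly monotone, so cutting the predicted fraction
at the class boundaries {0.10, 0.35, 0.70} is equivalent to cutting the
predictor X at the inverted threshold limits.  A value exactly on a limit is
assigned to the more severe class.  Agreement between a classified map and
observed cells is summarized by a confusion matrix with producer's (row-wise,
omission), user's (column-wise, commission) and overall accuracy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calibration import ThresholdSet, thresholds_to_dict
from .errors import ConfigurationError, DataError
from .ground_truth import SEVERITY_CLASSES
from .rasters import Affine, DviRaster, DEFAULT_TRANSFORM, _read, _write

#: raster codes for severity classes
CLASS_CODES = {"nodata": 0, "nil": 1, "low": 2, "medium": 3, "high": 4}
CODE_CLASSES = {v: k for k, v in CLASS_CODES.items()}


def _classify_codes(values: np.ndarray, thresholds: ThresholdSet) -> np.ndarray:
    """Vectorized class codes (1..4) for finite values; no nodata handling."""
    t10, t35, t70 = thresholds.limits_x
    x = np.asarray(values, dtype=float)
    out = np.empty(x.shape, dtype=np.uint8)
    if thresholds.orientation == "decreasing":
        out[...] = CLASS_CODES["high"]
        out[x > t70] = CLASS_CODES["medium"]
        out[x > t35] = CLASS_CODES["low"]
        out[x > t10] = CLASS_CODES["nil"]
    else:
        out[...] = CLASS_CODES["nil"]
        out[x >= t10] = CLASS_CODES["low"]
        out[x >= t35] = CLASS_CODES["medium"]
        out[x >= t70] = CLASS_CODES["high"]
    return out


def classify_value(x: float, thresholds: ThresholdSet) -> str:
    """Severity class of a single predictor value (boundary -> more severe)."""
    return CODE_CLASSES[int(_classify_codes(np.asarray([x]), thresholds)[0])]


@dataclass
class SeverityMap:
    """Classified severity raster: codes 0=nodata, 1=nil, 2=low, 3=medium, 4=high."""

    grid: np.ndarray
    transform: Affine = DEFAULT_TRANSFORM
    index_name: str = ""
    thresholds: ThresholdSet | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.uint8)

    @property
    def shape(self):
        return self.grid.shape

    def class_counts(self) -> dict[str, int]:
        counts = np.bincount(self.grid.ravel(), minlength=5)
        return {name: int(counts[code]) for name, code in CLASS_CODES.items()}

    def class_at(self, row: int, col: int) -> str:
        return CODE_CLASSES[int(self.grid[row, col])]


def classify_dvi(dvi: DviRaster, thresholds: ThresholdSet) -> SeverityMap:
    """Apply threshold classification to every valid pixel of a change raster."""
    def _base(name):
        return (name[1:] if name.startswith("d") else name).upper()

    if thresholds.index_name and dvi.index_name and _base(thresholds.index_name) != _base(dvi.index_name):
        raise ConfigurationError(
            f"index mismatch: thresholds for {thresholds.index_name!r}, raster is {dvi.index_name!r}"
        )
    valid = dvi.valid_mask()
    grid = np.zeros(dvi.shape, dtype=np.uint8)  # 0 = nodata
    grid[valid] = _classify_codes(dvi.grid[valid], thresholds)
    sm = SeverityMap(grid=grid, transform=dvi.transform, index_name=dvi.index_name, thresholds=thresholds)
    sm.meta["class_counts"] = sm.class_counts()
    return sm


@dataclass
class ConfusionMatrix:
    """4x4 agreement counts; rows = observed class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple = SEVERITY_CLASSES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise DataError(f"counts shape {self.counts.shape} != ({k}, {k})")
        if (self.counts < 0).any():
            raise DataError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def confusion_matrix(observed, predicted, classes=SEVERITY_CLASSES) -> ConfusionMatrix:
    """Cross-tabulate observed vs predicted class labels."""
    observed, predicted = list(observed), list(predicted)
    if len(observed) != len(predicted):
        raise DataError(f"length mismatch: {len(observed)} observed vs {len(predicted)} predicted")
    idx = {cls: i for i, cls in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for o, p in zip(observed, predicted):
        if o not in idx or p not in idx:
            raise DataError(f"unknown class label in pair ({o!r}, {p!r})")
        counts[idx[o], idx[p]] += 1
    return ConfusionMatrix(counts=counts, classes=tuple(classes))


@dataclass
class AccuracyReport:
    """Producer's/user's accuracy per class and overall accuracy.

    A class absent from the observed (or predicted) margin has undefined
    producer's (or user's) accuracy, reported as NaN and excluded from any
    summary a caller builds.
    """

    matrix: ConfusionMatrix
    producer: dict[str, float] = field(default_factory=dict)
    user: dict[str, float] = field(default_factory=dict)
    overall: float = float("nan")


def accuracy_metrics(cm: ConfusionMatrix) -> AccuracyReport:
    """Producer's, user's and overall accuracy of a confusion matrix."""
    if cm.total == 0:
        raise DataError("empty confusion matrix")
    diag = np.diag(cm.counts)
    producer = {}
    user = {}
    for i, cls in enumerate(cm.classes):
        rt, ct = int(cm.row_totals[i]), int(cm.col_totals[i])
        producer[cls] = diag[i] / rt if rt else math.nan
        user[cls] = diag[i] / ct if ct else math.nan
    overall = float(diag.sum() / cm.total)
    return AccuracyReport(matrix=cm, producer=producer, user=user, overall=overall)


# ---------------------------------------------------------------------------
# I/O


def write_severity_map(path, sm: SeverityMap) -> None:
    """Single-band coded TIFF plus a JSON sidecar with threshold provenance."""
    meta = {
        "kind": "severity_map",
        "index_name": sm.index_name,
        "transform": list(sm.transform),
        "class_codes": CLASS_CODES,
        "class_counts": sm.class_counts(),
    }
    if sm.thresholds is not None:
        meta["thresholds"] = thresholds_to_dict(sm.thresholds)
    _write(path, sm.grid, meta)


def read_severity_map(path) -> SeverityMap:
    grid, meta = _read(path)
    ts = None
    if "thresholds" in meta:
        t = meta["thresholds"]
        ts = ThresholdSet(
            index_name=t.get("index_name", ""),
            boundaries_y=tuple(t["boundaries_y"]),
            limits_x=tuple(t["limits_x_raw"]),
            orientation=t["orientation"],
        )
    return SeverityMap(
        grid=grid,
        transform=Affine(*meta.get("transform", DEFAULT_TRANSFORM)),
        index_name=meta.get("index_name", ""),
        thresholds=ts,
    )


def report_to_dict(report: AccuracyReport) -> dict:
    def clean(d):
        return {k: (None if math.isnan(v) else round(v, 6)) for k, v in d.items()}

    return {
        "classes": list(report.matrix.classes),
        "counts": report.matrix.counts.tolist(),
        "row_totals": report.matrix.row_totals.tolist(),
        "col_totals": report.matrix.col_totals.tolist(),
        "producer_accuracy": clean(report.producer),
        "user_accuracy": clean(report.user),
        "overall_accuracy": round(report.overall, 6),
        "total": report.matrix.total,
    }


def write_report_json(path, report: AccuracyReport) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(report_to_dict(report), indent=1, sort_keys=True) + "\n")
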