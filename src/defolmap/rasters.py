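"""Raster containers and TIFF input/output.

Grids are row-major 2D numpy arrays, 0-based, pixel-is-area, georeferenced by
a six-coefficient affine transform (30 m square pixels by default).  Rasters
are written as plain integer TIFFs via :mod:`tifffile`, with a JSON sidecar
(``<name>.tif.json``) carrying the transform, nodata sentinel, date tag and
band layout, so every output stays a self-describing text-plus-TIFF pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import tifffile

from .errors import ConfigurationError, DataError

#: surface reflectance is distributed as integers scaled by 10^4
REFLECTANCE_MAX = 10_000

DEFAULT_BAND_NODATA = -9999
DEFAULT_INDEX_NODATA = -32768


class Affine(NamedTuple):
    """Affine georeference mapping (col, row) -> (x, y).

    ``x = a*col + b*row + c`` ; ``y = d*col + e*row + f`` with (col, row)
    measured from the upper-left raster corner.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def from_origin(cls, west: float, north: float, xsize: float = 30.0, ysize: float = 30.0) -> "Affine":
        return cls(xsize, 0.0, west, 0.0, -ysize, north)

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        """World coordinates of the center of pixel (row, col)."""
        cx, cy = col + 0.5, row + 0.5
        return (self.a * cx + self.b * cy + self.c, self.d * cx + self.e * cy + self.f)

    def world_to_pixel(self, x: float, y: float) -> tuple[int, int]:
        """Nearest pixel (row, col) whose center is closest to world (x, y)."""
        det = self.a * self.e - self.b * self.d
        if det == 0:
            raise ConfigurationError("degenerate affine transform")
        dx, dy = x - self.c, y - self.f
        col = (self.e * dx - self.b * dy) / det
        row = (-self.d * dx + self.a * dy) / det
        return (int(np.floor(row)), int(np.floor(col)))


#: default georeference: UTM-like origin, 30 m pixels
DEFAULT_TRANSFORM = Affine.from_origin(500_000.0, 4_650_000.0, 30.0, 30.0)


@dataclass
class BandStack:
    """Multi-band surface-reflectance raster for one acquisition date.

    Reflectance is integer-scaled (true reflectance x 10^4); valid values lie
    in [0, 10000].  All band grids share one shape and georeference.
    """

    bands: dict[int, np.ndarray]
    transform: Affine = DEFAULT_TRANSFORM
    nodata: int = DEFAULT_BAND_NODATA
    date_tag: str = ""

    def __post_init__(self):
        if not self.bands:
            raise ConfigurationError("BandStack requires at least one band")
        self.bands = {int(b): np.asarray(g, dtype=np.int32) for b, g in self.bands.items()}
        shapes = {g.shape for g in self.bands.values()}
        if len(shapes) != 1:
            raise DataError(f"band grids have differing shapes: {sorted(shapes)}")
        for b, g in self.bands.items():
            valid = g != self.nodata
            bad = valid & ((g < 0) | (g > REFLECTANCE_MAX))
            if bad.any():
                raise DataError(
                    f"band {b}: {int(bad.sum())} reflectance values outside [0, {REFLECTANCE_MAX}]"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    def valid_mask(self) -> np.ndarray:
        """Boolean grid, True where every band is non-nodata."""
        out = np.ones(self.shape, dtype=bool)
        for g in self.bands.values():
            out &= g != self.nodata
        return out


@dataclass
class PixelMask:
    """Boolean usability mask (True = usable pixel)."""

    grid: np.ndarray
    kind: str = "qa_clear"  # or "forest_pine"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.kind not in ("qa_clear", "forest_pine"):
            raise ConfigurationError(f"unknown mask kind {self.kind!r}")

    @classmethod
    def from_codes(cls, code_grid, clear_codes, kind: str = "qa_clear") -> "PixelMask":
        """Build a mask from a coded QA raster and the list of 'clear' codes."""
        code_grid = np.asarray(code_grid)
        return cls(np.isin(code_grid, list(clear_codes)), kind=kind)


@dataclass
class ViRaster:
    """Single-date vegetation index raster (integer-scaled values)."""

    index_name: str
    grid: np.ndarray
    transform: Affine = DEFAULT_TRANSFORM
    nodata: int = DEFAULT_INDEX_NODATA
    date_tag: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.int32)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def valid_mask(self) -> np.ndarray:
        return self.grid != self.nodata


@dataclass
class DviRaster:
    """Per-pixel pre-minus-post index difference (the predictor X)."""

    index_name: str
    grid: np.ndarray
    transform: Affine = DEFAULT_TRANSFORM
    nodata: int = DEFAULT_INDEX_NODATA
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.int32)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def valid_mask(self) -> np.ndarray:
        return self.grid != self.nodata


# ---------------------------------------------------------------------------
# TIFF + JSON-sidecar I/O


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def _write(path, array: np.ndarray, meta: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(array), photometric="minisblack")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def _read(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"raster not found: {path}")
    array = tifffile.imread(path)
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return array, meta


def write_band_stack(path, stack: BandStack) -> None:
    band_ids = sorted(stack.bands)
    cube = np.stack([stack.bands[b] for b in band_ids])
    _write(path, cube, {
        "kind": "band_stack",
        "bands": band_ids,
        "transform": list(stack.transform),
        "nodata": stack.nodata,
        "date_tag": stack.date_tag,
    })


def read_band_stack(path, band_ids=None) -> BandStack:
    cube, meta = _read(path)
    if cube.ndim == 2:
        cube = cube[None]
    ids = meta.get("bands", band_ids)
    if ids is None:
        raise ConfigurationError(f"{path}: band ids unknown (no sidecar; pass band_ids)")
    if len(ids) != cube.shape[0]:
        raise DataError(f"{path}: {cube.shape[0]} planes but {len(ids)} band ids")
    return BandStack(
        bands={int(b): cube[i] for i, b in enumerate(ids)},
        transform=Affine(*meta.get("transform", DEFAULT_TRANSFORM)),
        nodata=int(meta.get("nodata", DEFAULT_BAND_NODATA)),
        date_tag=meta.get("date_tag", ""),
    )


def write_vi_raster(path, vi: ViRaster) -> None:
    _write(path, vi.grid, {
        "kind": "vi_raster",
        "index_name": vi.index_name,
        "transform": list(vi.transform),
        "nodata": vi.nodata,
        "date_tag": vi.date_tag,
    })


def read_vi_raster(path) -> ViRaster:
    grid, meta = _read(path)
    return ViRaster(
        index_name=meta.get("index_name", ""),
        grid=grid,
        transform=Affine(*meta.get("transform", DEFAULT_TRANSFORM)),
        nodata=int(meta.get("nodata", DEFAULT_INDEX_NODATA)),
        date_tag=meta.get("date_tag", ""),
    )


def write_dvi_raster(path, dvi: DviRaster) -> None:
    _write(path, dvi.grid, {
        "kind": "dvi_raster",
        "index_name": dvi.index_name,
        "transform": list(dvi.transform),
        "nodata": dvi.nodata,
    })


def read_dvi_raster(path) -> DviRaster:
    grid, meta = _read(path)
    return DviRaster(
        index_name=meta.get("index_name", ""),
        grid=grid,
        transform=Affine(*meta.get("transform", DEFAULT_TRANSFORM)),
        nodata=int(meta.get("nodata", DEFAULT_INDEX_NODATA)),
    )


def write_mask(path, mask: PixelMask) -> None:
    _write(path, mask.grid.astype(np.uint8), {"kind": "mask", "mask_kind": mask.kind})


def read_mask(path, kind=None) -> PixelMask:
    grid, meta = _read(path)
    return PixelMask(grid.astype(bool), kind=kind or meta.get("mask_kind", "qa_clear"))


def write_float_raster(path, grid: np.ndarray, meta: dict | None = None) -> None:
    _write(path, np.asarray(grid, dtype=np.float32), {"kind": "float_raster", **(meta or {})})


def read_float_raster(path) -> np.ndarray:
    grid, _ = _read(path)
    return np.asarray(grid, dtype=float)
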