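"""Vegetation-index raster algebra: index computation, masking, change
detection and multi-date stability screening.

Five indices built from the NIR/SWIR/red reflectance bands of a 30 m sensor:

========  =======================  =========================
index     formula (reflectance)    sensitivity
========  =======================  =========================
MID       B6 + B7                  SWIR brightness, rises with canopy loss
MSI       B6 / B5                  moisture stress, rises with water stress
NDMI      (B5 - B6) / (B5 + B6)    canopy moisture
NDVI      (B5 - B4) / (B5 + B4)    greenness
NBR       (B5 - B7) / (B5 + B7)    burn/defoliation ratio
========  =======================  =========================

Reflectance arrives integer-scaled by 10^4, so MID is already on that scale;
the ratio and normalized-difference indices are likewise multiplied by 10^4
and rounded (ties away from zero) so every index raster is an integer grid on
a common x10^4 scale.  The change predictor is dVI = VI(pre) - VI(post).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError
from .rasters import BandStack, DviRaster, PixelMask, ViRaster, DEFAULT_INDEX_NODATA
from .util import round_half_away

SCALE = 10_000

INDEX_NAMES = ("MID", "MSI", "NDMI", "NDVI", "NBR")

#: bands required per index (Landsat-8 style numbering: 4=red, 5=NIR, 6=SWIR1, 7=SWIR2)
REQUIRED_BANDS = {
    "MID": (6, 7),
    "MSI": (5, 6),
    "NDMI": (5, 6),
    "NDVI": (4, 5),
    "NBR": (5, 7),
}


def canonical_index(name: str) -> str:
    """Normalize an index name; accepts the change-raster spelling ('dMSI')."""
    base = name[1:] if name.startswith("d") else name
    base = base.upper()
    if base not in INDEX_NAMES:
        raise ConfigurationError(f"unknown index {name!r}; expected one of {INDEX_NAMES}")
    return base


def compute_vi(stack: BandStack, index_name: str, nodata: int = DEFAULT_INDEX_NODATA) -> ViRaster:
    """Compute one vegetation index over a band stack.

    Pixels where any required band is nodata stay nodata; a zero denominator
    in a ratio index sets that pixel to nodata and is tallied in
    ``ViRaster.meta['zero_denominator_pixels']``.
    """
    name = canonical_index(index_name)
    need = REQUIRED_BANDS[name]
    missing = [b for b in need if b not in stack.bands]
    if missing:
        raise ConfigurationError(f"index {name} needs band(s) {missing}, not present in stack")

    valid = np.ones(stack.shape, dtype=bool)
    for b in need:
        valid &= stack.bands[b] != stack.nodata
    f = {b: stack.bands[b].astype(float) for b in need}

    zero_denom = 0
    if name == "MID":
        values = f[6] + f[7]  # already on the x10^4 reflectance scale
    else:
        if name == "MSI":
            num, den = f[6], f[5]
        elif name == "NDMI":
            num, den = f[5] - f[6], f[5] + f[6]
        elif name == "NDVI":
            num, den = f[5] - f[4], f[5] + f[4]
        else:  # NBR
            num, den = f[5] - f[7], f[5] + f[7]
        bad_den = valid & (den == 0)
        zero_denom = int(bad_den.sum())
        valid &= den != 0
        with np.errstate(divide="ignore", invalid="ignore"):
            values = round_half_away(num / np.where(den == 0, np.nan, den) * SCALE)

    grid = np.full(stack.shape, nodata, dtype=np.int32)
    grid[valid] = values[valid].astype(np.int32)
    return ViRaster(
        index_name=name,
        grid=grid,
        transform=stack.transform,
        nodata=nodata,
        date_tag=stack.date_tag,
        meta={"zero_denominator_pixels": zero_denom},
    )


def apply_masks(raster, masks: list[PixelMask]):
    """Set pixels failing any mask to nodata.

    Works on a :class:`BandStack` (all bands) or a Vi/Dvi raster.  Returns
    ``(masked_raster, n_masked)`` where ``n_masked`` counts pixels that were
    valid before this call and are nodata after it — so a second application
    of the same masks is a no-op with count 0.
    """
    import copy

    keep = np.ones(raster.shape, dtype=bool)
    for m in masks:
        if m.grid.shape != raster.shape:
            raise DataError(f"mask shape {m.grid.shape} != raster shape {raster.shape}")
        keep &= m.grid

    out = copy.deepcopy(raster)
    if isinstance(raster, BandStack):
        was_valid = raster.valid_mask()
        for b in out.bands:
            out.bands[b] = np.where(keep, out.bands[b], np.int32(out.nodata))
    else:
        was_valid = raster.valid_mask()
        out.grid = np.where(keep, out.grid, np.int32(out.nodata)).astype(np.int32)
    n_masked = int((was_valid & ~keep).sum())
    return out, n_masked


def _dates_ordered(pre_tag: str, post_tag: str) -> bool | None:
    """Compare ISO-style date tags; None when the tags are not comparable."""
    import re

    iso = re.compile(r"^\d{4}-\d{2}-\d{2}$")
    if iso.match(pre_tag or "") and iso.match(post_tag or ""):
        return pre_tag < post_tag
    return None


def compute_dvi(vi_pre: ViRaster, vi_post: ViRaster) -> DviRaster:
    """Change raster dVI = VI(pre) − VI(post); nodata wherever either input is."""
    if vi_pre.index_name != vi_post.index_name:
        raise ConfigurationError(
            f"index mismatch: {vi_pre.index_name!r} vs {vi_post.index_name!r}"
        )
    if vi_pre.shape != vi_post.shape:
        raise DataError(f"shape mismatch: {vi_pre.shape} vs {vi_post.shape}")
    if vi_pre.transform != vi_post.transform:
        raise DataError("georeference mismatch between pre and post rasters")
    ordered = _dates_ordered(vi_pre.date_tag, vi_post.date_tag)
    if ordered is False:
        raise ConfigurationError(
            f"pre date {vi_pre.date_tag} is not earlier than post date {vi_post.date_tag}"
        )

    valid = vi_pre.valid_mask() & vi_post.valid_mask()
    diff = vi_pre.grid.astype(np.int64) - vi_post.grid.astype(np.int64)
    grid = np.where(valid, diff, vi_pre.nodata).astype(np.int32)
    return DviRaster(
        index_name=f"d{canonical_index(vi_pre.index_name)}",
        grid=grid,
        transform=vi_pre.transform,
        nodata=vi_pre.nodata,
    )


@dataclass
class StabilityReport:
    """Per-date masked means and pairwise relative changes of one index."""

    index_name: str
    date_tags: list[str]
    means: list[float]
    rel_changes: list[tuple[int, int, float]]  # (i, j, |m_j - m_i| / |m_i|)
    rel_tolerance: float
    unstable_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def stable(self) -> bool:
        return not self.unstable_pairs


def temporal_stability_check(series: list[ViRaster], rel_tolerance: float = 0.10) -> StabilityReport:
    """Screen a multi-date series of one index for abrupt changes.

    Intended for pre-disturbance years: computes the masked mean per date and
    flags the series unstable if any pairwise relative change of the mean
    exceeds ``rel_tolerance`` (default 10%).
    """
    if len(series) < 2:
        raise ConfigurationError("stability check needs at least two dates")
    names = {vi.index_name for vi in series}
    if len(names) != 1:
        raise ConfigurationError(f"mixed indices in series: {sorted(names)}")

    means = []
    for vi in series:
        valid = vi.valid_mask()
        if not valid.any():
            raise DataError(f"no valid pixels for date {vi.date_tag!r}")
        means.append(float(vi.grid[valid].mean()))

    rel_changes, unstable = [], []
    for i in range(len(series)):
        for j in range(i + 1, len(series)):
            if means[i] == 0.0:
                rel = 0.0 if means[j] == 0.0 else float("inf")
            else:
                rel = abs(means[j] - means[i]) / abs(means[i])
            rel_changes.append((i, j, rel))
            if rel > rel_tolerance:
                unstable.append((i, j))

    return StabilityReport(
        index_name=series[0].index_name,
        date_tags=[vi.date_tag for vi in series],
        means=means,
        rel_changes=rel_changes,
        rel_tolerance=rel_tolerance,
        unstable_pairs=unstable,
    )
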