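"""Synthetic paired-date multispectral scenes with a known defoliation field.

The generator emulates the data structure of a pre-/post-outbreak pair of
30 m surface-reflectance stacks over a pine-dominated landscape:

* a latent defoliation fraction field ``f`` in [0, 1] (patchy blobs, a
  linear gradient, or a constant),
* healthy-pine reflectance baselines per band, perturbed by additive white
  noise, for the pre-outbreak date,
* a post-outbreak date whose band ``b`` responds linearly to ``f``:
  ``post_b = pre_b * (1 + coef_b * f) + noise`` (NIR falls, red and both
  SWIR bands rise as canopy is lost and moisture stress sets in),
* a cloud patch (QA mask False, bright pixels) and a non-forest patch
  (forest mask False, soil-like reflectance, ``f = 0``).

Ground truth emulates grid-cell photo-interpretation: the true fraction at a
drawn pixel is converted to percent and rounded to the interpreter's 5%
grid, then binned to a severity class; cells are drawn without replacement
to meet per-class quotas (default 10/23/8/9, n = 50).

Everything is a deterministic function of the parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DataError
from .ground_truth import (
    DEFAULT_CELL_AREA,
    GroundTruthCell,
    SEVERITY_CLASSES,
    SEVERITY_UPPER_PCT,
    bin_severity,
    write_cells_csv,
)
from .rasters import (
    BandStack,
    DEFAULT_TRANSFORM,
    PixelMask,
    REFLECTANCE_MAX,
    write_band_stack,
    write_float_raster,
    write_mask,
)
from .util import round_half_away, round_to_multiple

#: healthy-pine mean reflectance per band (x10^4 scale)
DEFAULT_BASELINES = {4: 300, 5: 2800, 6: 1600, 7: 900}

#: fractional band response at full defoliation (f = 1)
DEFAULT_RESPONSE = {4: +0.40, 5: -0.50, 6: +0.30, 7: +0.35}

#: soil/urban-like reflectance used for non-forest pixels, both dates
NONFOREST_BASELINES = {4: 1600, 5: 2200, 6: 2600, 7: 2300}

CLOUD_REFLECTANCE = 7000

#: per-class cell quotas of the reference calibration campaign (n = 50)
DEFAULT_QUOTAS = {"nil": 10, "low": 23, "medium": 8, "high": 9}

PRE_DATE = "2015-09-20"
POST_DATE = "2016-03-30"


@dataclass
class SceneParams:
    """Parameters of one synthetic paired-date scene."""

    shape: tuple[int, int] = (300, 300)
    defoliation_field: object = "patchy"  # "patchy" | "gradient" | float constant
    band_baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    response_coefs: dict = field(default_factory=lambda: dict(DEFAULT_RESPONSE))
    noise_sd: float = 50.0
    cloud_fraction: float = 0.05
    nonforest_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        rows, cols = self.shape
        if rows < 4 or cols < 4:
            raise ConfigurationError(f"scene shape {self.shape} too small")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for frac, name in ((self.cloud_fraction, "cloud_fraction"), (self.nonforest_fraction, "nonforest_fraction")):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if isinstance(self.defoliation_field, (int, float)):
            if not 0.0 <= float(self.defoliation_field) <= 1.0:
                raise ConfigurationError("constant defoliation fraction must be in [0, 1]")
        elif self.defoliation_field not in ("patchy", "gradient"):
            raise ConfigurationError(f"unknown defoliation_field {self.defoliation_field!r}")
        if set(self.band_baselines) != set(self.response_coefs):
            raise ConfigurationError("band_baselines and response_coefs must cover the same bands")
        for b, v in self.band_baselines.items():
            if not 0 <= v <= REFLECTANCE_MAX:
                raise ConfigurationError(f"baseline for band {b} outside [0, {REFLECTANCE_MAX}]")


@dataclass
class SyntheticScene:
    """Paired pre/post stacks plus the latent truth and masks behind them."""

    pre: BandStack
    post: BandStack
    true_f: np.ndarray
    qa: PixelMask
    forest: PixelMask
    params: SceneParams

    @property
    def shape(self):
        return self.true_f.shape


def _defoliation_field(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    rows, cols = params.shape
    spec = params.defoliation_field
    if isinstance(spec, (int, float)):
        return np.full((rows, cols), float(spec))
    if spec == "gradient":
        return np.tile(np.linspace(0.0, 1.0, cols), (rows, 1))
    # patchy: clipped sum of Gaussian outbreak foci over an undefoliated
    # background; the first focus always reaches full defoliation so every
    # severity class is represented regardless of seed
    f = np.zeros((rows, cols))
    rr, cc = np.mgrid[0:rows, 0:cols]
    side = min(rows, cols)
    n_bumps = max(4, (rows * cols) // 9000)
    for k in range(n_bumps):
        cy = rng.uniform(0.15 * rows, 0.85 * rows)
        cx = rng.uniform(0.15 * cols, 0.85 * cols)
        if k == 0:
            sigma, amp = side / 8.0, 1.0
        else:
            sigma = rng.uniform(side / 25.0, side / 10.0)
            amp = rng.uniform(0.4, 1.0)
        f += amp * np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2.0 * sigma**2))
    return np.clip(f, 0.0, 1.0)


def _random_patch(shape, fraction, rng: np.random.Generator) -> np.ndarray:
    """Boolean rectangle covering about ``fraction`` of the grid."""
    rows, cols = shape
    patch = np.zeros(shape, dtype=bool)
    if fraction <= 0:
        return patch
    if fraction >= 1:
        return ~patch
    area = fraction * rows * cols
    aspect = rng.uniform(0.5, 2.0)
    h = int(np.clip(round_half_away(np.sqrt(area * aspect)), 1, rows))
    w = int(np.clip(round_half_away(area / h), 1, cols))
    r0 = int(rng.integers(0, rows - h + 1))
    c0 = int(rng.integers(0, cols - w + 1))
    patch[r0 : r0 + h, c0 : c0 + w] = True
    return patch


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Deterministically build a scene from its parameters and seed."""
    rng = np.random.default_rng(params.seed)
    rows, cols = params.shape

    f = _defoliation_field(params, rng)
    cloud = _random_patch(params.shape, params.cloud_fraction, rng)
    nonforest = _random_patch(params.shape, params.nonforest_fraction, rng)
    forest = ~nonforest
    f = np.where(forest, f, 0.0)

    def noisy(base: np.ndarray) -> np.ndarray:
        if params.noise_sd > 0:
            base = base + rng.normal(0.0, params.noise_sd, (rows, cols))
        return np.clip(round_half_away(base), 0, REFLECTANCE_MAX).astype(np.int32)

    pre_bands, post_bands = {}, {}
    for b in sorted(params.band_baselines):
        base = np.where(forest, float(params.band_baselines[b]), float(NONFOREST_BASELINES.get(b, 2000)))
        pre = noisy(base)
        post = noisy(pre.astype(float) * (1.0 + params.response_coefs[b] * f))
        pre[cloud] = CLOUD_REFLECTANCE
        post[cloud] = CLOUD_REFLECTANCE
        pre_bands[b] = pre
        post_bands[b] = post

    qa = PixelMask(~cloud, kind="qa_clear")
    forest_mask = PixelMask(forest, kind="forest_pine")
    pre_stack = BandStack(pre_bands, transform=DEFAULT_TRANSFORM, date_tag=PRE_DATE)
    post_stack = BandStack(post_bands, transform=DEFAULT_TRANSFORM, date_tag=POST_DATE)
    return SyntheticScene(pre=pre_stack, post=post_stack, true_f=f, qa=qa, forest=forest_mask, params=params)


def generate_ground_truth(
    scene: SyntheticScene,
    class_quotas: dict[str, int] | None = None,
    interpreter_interval: float | None = 5.0,
    seed: int = 0,
) -> list[GroundTruthCell]:
    """Draw interpreted cells meeting per-class quotas from clear forest pixels.

    ``interpreter_interval`` is the visual-interpretation rounding step in
    percent (default 5); ``None`` keeps the exact percent, which is only
    valid when the field values already sit on the 5% grid.
    """
    quotas = dict(DEFAULT_QUOTAS if class_quotas is None else class_quotas)
    unknown = set(quotas) - set(SEVERITY_CLASSES)
    if unknown:
        raise ConfigurationError(f"unknown severity classes in quotas: {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    pct = 100.0 * scene.true_f
    if interpreter_interval:
        pct = round_to_multiple(pct, interpreter_interval)
    eligible = scene.qa.grid & scene.forest.grid

    # vectorized severity binning of the percent grid
    cls_of = np.full(scene.shape, -1, dtype=int)
    lower = 0.0
    for k, cls in enumerate(SEVERITY_CLASSES):
        upper = SEVERITY_UPPER_PCT[cls]
        cls_of[(pct > lower - 1e-9) & (pct <= upper + 1e-9) & (cls_of == -1)] = k
        lower = upper

    cells: list[GroundTruthCell] = []
    i = 0
    for k, cls in enumerate(SEVERITY_CLASSES):
        quota = int(quotas.get(cls, 0))
        if quota == 0:
            continue
        pool = np.flatnonzero(eligible & (cls_of == k))
        if pool.size < quota:
            raise DataError(
                f"class {cls!r}: only {pool.size} eligible pixels for a quota of {quota}"
            )
        chosen = np.sort(rng.choice(pool, size=quota, replace=False))
        for flat in chosen:
            r, c = divmod(int(flat), scene.shape[1])
            i += 1
            cells.append(
                GroundTruthCell(
                    cell_id=f"c{i:03d}",
                    row=r,
                    col=c,
                    defoliated_area=float(scene.true_f[r, c]) * DEFAULT_CELL_AREA,
                    cell_area=DEFAULT_CELL_AREA,
                    defoliation_pct=float(pct[r, c]),
                    severity=cls,
                )
            )
    return cells


def simulate_logistic_samples(
    a: float,
    b: float,
    n: int = 50,
    class_mix: dict[str, int] | None = None,
    interpreter_interval: float | None = 5.0,
    seed: int = 0,
):
    """Calibration samples drawn exactly from a known logistic curve.

    Per class, true fractions are drawn uniformly over the class's y-range
    (clipped away from 0 and 1 so the curve is invertible), mapped to x
    through the inverse logistic, and the observed response is the true
    fraction rounded to the interpreter's grid — so interpreter rounding is
    the only noise source.  Class counts follow ``class_mix`` (default the
    10/23/8/9 reference mix) rescaled to ``n``.
    """
    from .calibration import invert_threshold, LogisticFit
    from .ground_truth import CalibrationSample

    if b == 0:
        raise ConfigurationError("slope b must be nonzero")
    mix = dict(DEFAULT_QUOTAS if class_mix is None else class_mix)
    total = sum(mix.values())
    if total <= 0:
        raise ConfigurationError("class mix must have positive total")
    rng = np.random.default_rng(seed)
    fit = LogisticFit("", a, b, 0.0, n, -1.0, -2.0)

    # y-ranges per class under 5% interpreter rounding
    ranges = {"nil": (0.005, 0.075), "low": (0.075, 0.325), "medium": (0.325, 0.675), "high": (0.675, 0.995)}
    samples = []
    i = 0
    for cls in SEVERITY_CLASSES:
        k = int(round_half_away(n * mix.get(cls, 0) / total))
        lo, hi = ranges[cls]
        for _ in range(k):
            y_true = rng.uniform(lo, hi)
            x = invert_threshold(fit, y_true)
            if interpreter_interval:
                y_obs = float(round_to_multiple(100.0 * y_true, interpreter_interval)) / 100.0
            else:
                y_obs = y_true
            i += 1
            samples.append(
                CalibrationSample(cell_id=f"s{i:04d}", x=x, y=y_obs, severity=bin_severity(round_to_multiple(100 * y_true, 5)))
            )
    return samples


# ---------------------------------------------------------------------------
# presets


@dataclass
class SceneFixture:
    """A generated scene with (optionally) its ground-truth cells."""

    preset: str
    scene: SyntheticScene
    cells: list | None
    expected: dict = field(default_factory=dict)


def _closed_form_indices(params: SceneParams, f: float) -> dict[str, float]:
    """Noiseless per-pixel index values at defoliation fraction ``f`` (x10^4)."""
    b = {k: v * (1.0 + params.response_coefs[k] * f) for k, v in params.band_baselines.items()}
    return {
        "MID": b[6] + b[7],
        "MSI": 1e4 * b[6] / b[5],
        "NDMI": 1e4 * (b[5] - b[6]) / (b[5] + b[6]),
        "NDVI": 1e4 * (b[5] - b[4]) / (b[5] + b[4]),
        "NBR": 1e4 * (b[5] - b[7]) / (b[5] + b[7]),
    }


def make_fixture(preset: str, seed: int = 0) -> SceneFixture:
    """Canned scenes: ``tiny`` for unit tests, ``default`` for pipeline-scale
    runs, ``stress`` for degenerate inputs (fully clouded, constant field)."""
    if preset == "tiny":
        params = SceneParams(shape=(60, 60), noise_sd=20.0, seed=seed)
        scene = generate_scene(params)
        cells = generate_ground_truth(scene, seed=seed + 1)
    elif preset == "default":
        params = SceneParams(shape=(300, 300), seed=seed)
        scene = generate_scene(params)
        cells = generate_ground_truth(scene, seed=seed + 1)
    elif preset == "stress":
        params = SceneParams(
            shape=(60, 60),
            defoliation_field=0.5,
            noise_sd=0.0,
            cloud_fraction=1.0,
            nonforest_fraction=0.0,
            seed=seed,
        )
        scene = generate_scene(params)
        cells = None
    else:
        raise ConfigurationError(f"unknown preset {preset!r}; expected tiny/default/stress")

    expected = {
        "healthy_indices": _closed_form_indices(params, 0.0),
        "full_defoliation_indices": _closed_form_indices(params, 1.0),
    }
    return SceneFixture(preset=preset, scene=scene, cells=cells, expected=expected)


def write_scene(out_dir, scene: SyntheticScene, cells=None) -> None:
    """Write pre/post stacks, masks, truth field and cell table to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_band_stack(out / "pre.tif", scene.pre)
    write_band_stack(out / "post.tif", scene.post)
    write_mask(out / "qa.tif", scene.qa)
    write_mask(out / "forest.tif", scene.forest)
    write_float_raster(out / "true_f.tif", scene.true_f, {"description": "latent defoliation fraction"})
    params = asdict(scene.params)
    params["shape"] = list(params["shape"])
    (out / "params.json").write_text(json.dumps(params, indent=1, sort_keys=True) + "\n")
    if cells is not None:
        write_cells_csv(out / "truth.csv", cells)
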