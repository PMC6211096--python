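"""End-to-end workflow: indices -> masking -> change -> calibration -> map -> accuracy.

``run_pipeline`` wires the stages in the order of the underlying field
protocol: compute each vegetation index for the pre- and post-outbreak
dates, mask unusable pixels, difference the dates, pair the change rasters
with interpreted ground-truth cells, fit one logistic calibration per index,
rank the fits by McFadden R^2, invert the best fit into threshold limits,
classify the change raster into a severity map and score it against the
observed classes.  The run is a pure function of (inputs, config, seed) and
writes a deterministic JSON manifest plus per-stage outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .calibration import (
    compare_models,
    derive_threshold_set,
    fit_logistic,
    fit_to_dict,
    slope_sign_warning,
    thresholds_to_dict,
    write_fit_json,
    write_thresholds_json,
)
from .errors import ConfigurationError
from .ground_truth import class_histogram, extract_samples, read_cells_csv, write_samples_csv
from .rasters import read_band_stack, read_mask
from .severity_map import accuracy_metrics, classify_dvi, confusion_matrix, report_to_dict, write_report_json, write_severity_map
from .synthetic_scene import generate_ground_truth, generate_scene, SceneParams, write_scene
from .vi_engine import INDEX_NAMES, apply_masks, compute_dvi, compute_vi, temporal_stability_check

logger = logging.getLogger("defolmap")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``preset``/``seed`` (synthetic scene) or the explicit input paths
    (``pre_path``, ``post_path``, ``truth_path``, optional masks) must be set.
    """

    out_dir: str = "defolmap_run"
    indices: tuple = INDEX_NAMES
    boundaries_y: tuple = (0.10, 0.35, 0.70)
    stability_tol: float = 0.10
    seed: int = 0
    preset: str | None = "default"
    pre_path: str | None = None
    post_path: str | None = None
    qa_path: str | None = None
    forest_path: str | None = None
    truth_path: str | None = None
    extra_pre_paths: tuple = ()  # additional pre-outbreak dates for stability check

    def __post_init__(self):
        from .vi_engine import canonical_index

        self.indices = tuple(canonical_index(i) for i in self.indices)
        explicit = self.pre_path and self.post_path and self.truth_path
        if not self.preset and not explicit:
            raise ConfigurationError(
                "config needs either a synthetic preset or pre/post/truth input paths"
            )


def _load_inputs(config: RunConfig, out: Path):
    if config.pre_path:
        pre = read_band_stack(config.pre_path)
        post = read_band_stack(config.post_path)
        masks = []
        if config.qa_path:
            masks.append(read_mask(config.qa_path, kind="qa_clear"))
        if config.forest_path:
            masks.append(read_mask(config.forest_path, kind="forest_pine"))
        cells = read_cells_csv(config.truth_path)
        return pre, post, masks, cells, {"source": "files", "pre": config.pre_path, "post": config.post_path}
    from .synthetic_scene import make_fixture

    fixture = make_fixture(config.preset, seed=config.seed)
    scene, cells = fixture.scene, fixture.cells
    write_scene(out / "inputs", scene, cells)
    masks = [scene.qa, scene.forest]
    return scene.pre, scene.post, masks, cells, {"source": "synthetic", "preset": config.preset, "seed": config.seed}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": {"name": "defolmap", "version": __version__},
        "config": {
            "indices": list(config.indices),
            "boundaries_y": list(config.boundaries_y),
            "stability_tol": config.stability_tol,
            "seed": config.seed,
            "preset": config.preset,
        },
        "stages": {},
        "warnings": [],
    }

    pre, post, masks, cells, source = _load_inputs(config, out)
    manifest["stages"]["inputs"] = {**source, "n_cells": len(cells), "class_histogram": class_histogram(cells)}
    logger.info("inputs: %d ground-truth cells (%s)", len(cells), source["source"])

    fits = []
    dvis = {}
    for index in config.indices:
        vi_pre = compute_vi(pre, index)
        vi_post = compute_vi(post, index)
        vi_pre, n_masked_pre = apply_masks(vi_pre, masks)
        vi_post, n_masked_post = apply_masks(vi_post, masks)
        dvi = compute_dvi(vi_pre, vi_post)
        dvis[index] = dvi
        samples = extract_samples(dvi, cells)
        write_samples_csv(out / f"samples_d{index}.csv", samples)
        fit = fit_logistic(samples, index_name=f"d{index}")
        write_fit_json(out / f"fit_d{index}.json", fit)
        fits.append(fit)
        warn = slope_sign_warning(fit)
        if warn:
            manifest["warnings"].append(warn)
        manifest["stages"][f"index_{index}"] = {
            "masked_pixels_pre": n_masked_pre,
            "masked_pixels_post": n_masked_post,
            "zero_denominator_pixels": vi_pre.meta.get("zero_denominator_pixels", 0),
            "n_samples": len(samples),
            "fit": fit_to_dict(fit),
        }
        logger.info("d%s: fit a=%.6g b=%.6g R2=%.3f (%d iter)", index, fit.a, fit.b, fit.r2_mcfadden, fit.n_iter)

    ranking = compare_models(fits)
    best = ranking.best
    manifest["stages"]["comparison"] = {
        "ranking": [{"index_name": f.index_name, "r2_mcfadden": f.r2_mcfadden} for f in ranking.fits],
        "best": best.index_name,
        "ties": [list(t) for t in ranking.ties],
    }
    logger.info("best index by McFadden R^2: %s (%.3f)", best.index_name, best.r2_mcfadden)

    thresholds = derive_threshold_set(best, config.boundaries_y)
    write_thresholds_json(out / "thresholds_best.json", thresholds)
    manifest["stages"]["thresholds"] = thresholds_to_dict(thresholds)

    best_index = best.index_name.lstrip("d")
    severity = classify_dvi(dvis[best_index], thresholds)
    write_severity_map(out / "severity.tif", severity)
    manifest["stages"]["severity_map"] = {"class_counts": severity.class_counts()}

    observed = [c.severity for c in cells]
    predicted = [severity.class_at(c.row, c.col) for c in cells]
    report = accuracy_metrics(confusion_matrix(observed, predicted))
    write_report_json(out / "accuracy.json", report)
    manifest["stages"]["accuracy"] = report_to_dict(report)
    logger.info("overall accuracy at ground-truth cells: %.3f", report.overall)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def run_stability(series_stacks, index: str, masks=(), rel_tolerance: float = 0.10):
    """Multi-date stability screening of one index over pre-outbreak stacks."""
    vis = []
    for stack in series_stacks:
        vi = compute_vi(stack, index)
        if masks:
            vi, _ = apply_masks(vi, list(masks))
        vis.append(vi)
    return temporal_stability_check(vis, rel_tolerance=rel_tolerance)
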