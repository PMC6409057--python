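"""End-to-end segmentation pipeline: VOI crop -> initialization search ->
regulated level-set evolution -> evaluation -> artifact writing.

The VOI is an input contract (0-based, half-open voxel bounding box); there
is no automatic tumor detection.  Every output directory is self-describing:
it contains the mask, the per-iteration trace CSV, the metric report and an
echo of the fully resolved configuration including the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import io as dio
from .levelset import EnergyConfig, LevelSetField, evolve, init_sdf_ball
from .metrics import evaluate
from .regulation import OracleClassifier, RegulationConfig, select_initialization
from .volume import ScalarVolume

logger = logging.getLogger("drls")

__all__ = ["run_pipeline", "crop_voi", "parse_voi"]


def parse_voi(text: str) -> tuple[slice, slice, slice]:
    """Parse ``x0,y0,z0,x1,y1,z1`` (0-based, half-open) into slices."""
    parts = [int(p) for p in text.split(",")]
    if len(parts) != 6:
        raise ValueError("VOI must be 6 comma-separated integers x0,y0,z0,x1,y1,z1")
    lo, hi = parts[:3], parts[3:]
    if any(h <= l for l, h in zip(lo, hi)):
        raise ValueError(f"empty VOI {text!r}")
    return tuple(slice(l, h) for l, h in zip(lo, hi))  # type: ignore[return-value]


def crop_voi(volume: ScalarVolume, voi) -> ScalarVolume:
    if voi is None:
        return volume
    data = volume.data[voi]
    if data.size == 0:
        raise ValueError("VOI does not intersect the volume")
    return ScalarVolume(data, volume.spacing, volume.origin)


def run_pipeline(
    volume: ScalarVolume,
    voi=None,
    classifier=None,
    gt_mask: np.ndarray | None = None,
    energy: EnergyConfig | None = None,
    regulation: RegulationConfig | None = None,
    init_radius: float | None = None,
    seed: int = 0,
    out_dir=None,
):
    """Run one segmentation.  Returns ``(SegmentationResult, MetricReport | None)``.

    If ``init_radius`` is given the initialization is that SDF ball at the
    VOI center; otherwise the candidate-radius search with the classifier
    picks it (a classifier is then required).  ``gt_mask`` (already at VOI
    scale) enables the Dice trace and the metric report.
    """
    energy = energy or EnergyConfig()
    regulation = regulation or RegulationConfig()
    try:
        vol = crop_voi(volume, voi)
    except ValueError as exc:
        raise ValueError(f"stage voi-crop failed: {exc}") from exc
    gt = None if gt_mask is None else np.asarray(gt_mask, dtype=bool)
    if gt is not None and gt.shape != vol.shape:
        raise ValueError(
            f"stage voi-crop failed: GT shape {gt.shape} != VOI shape {vol.shape}"
        )
    center = tuple((s - 1) / 2.0 for s in vol.shape)

    if init_radius is not None:
        phi0 = init_sdf_ball(vol.shape, center, init_radius)
        init_records = [(float(init_radius), None)]
    else:
        if classifier is None:
            raise ValueError(
                "stage initialization failed: automatic initialization needs a "
                "classifier; pass init_radius for fixed-parameter runs"
            )
        phi0, init_records = select_initialization(
            vol, center, regulation.candidate_radii, classifier
        )
    logger.info("initialization selected; starting evolution")

    result = evolve(vol, phi0, energy, classifier=classifier, gt_mask=gt,
                    regulation_cfg=regulation)
    logger.info(
        "evolution finished: %d iterations, converged=%s (%s)",
        result.iterations_run, result.converged, result.diagnosis,
    )

    report = None
    if gt is not None and gt.any():
        report = evaluate(result.mask, gt, vol.spacing)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dio.write_mask(result.mask, out / "mask.nii.gz", vol.spacing)
        result.trace_dataframe().to_csv(out / "trace.csv", index=False)
        echo = {
            "seed": seed,
            "energy": dataclasses.asdict(energy),
            "regulation": dataclasses.asdict(regulation),
            "init_candidates": [
                {"radius": r, "p": None if p is None else list(p.as_tuple())}
                for r, p in init_records
            ],
            "iterations_run": result.iterations_run,
            "converged": result.converged,
            "diagnosis": result.diagnosis,
        }
        dio.save_config(echo, out / "config_echo.yaml")
        if report is not None:
            with open(out / "metrics.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
    return result, report
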