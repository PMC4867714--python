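"""End-to-end pipeline: detect → grow-cut segment → ellipse-approximate.

:func:`run_pipeline` is the programmatic core of the ``odseg run`` command:
it writes the detection JSON, the raw grow-cut mask, the ellipse-approximated
mask and the ellipse parameters, and returns everything in memory as well.
All steps are deterministic, so identical inputs and config reproduce
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as _io
from .config import Config
from .detect import DetectionResult, detect_od
from .ellipse import EllipseFit, boundary_points, fit_ellipse, rasterize_fit
from .growcut import SegmentationResult, segment_od
from .preprocess import FundusImage, preprocess

__all__ = ["PipelineResult", "run_pipeline", "segment_image"]

logger = logging.getLogger("odseg")


@dataclass(frozen=True)
class PipelineResult:
    detection: DetectionResult
    growcut: SegmentationResult
    fit: EllipseFit
    ellipse_mask: np.ndarray


def segment_image(
    img: FundusImage, cfg: Config | None = None, *, circle: bool = False
) -> PipelineResult:
    """Run detection, grow-cut and ellipse approximation on one image."""
    if cfg is None:
        cfg = Config()
    det = detect_od(img, cfg)
    logger.info(
        "detected center (%d, %d) r=%.1f at sensitivity level %.2f",
        det.native_center_row, det.native_center_col,
        det.native_radius, det.sensitivity_level,
    )
    pre = preprocess(img, cfg)
    seg = segment_od(pre.i_sc, det, cfg)
    logger.info(
        "grow-cut: %d iterations, converged=%s", seg.iterations, seg.converged
    )
    fit = fit_ellipse(boundary_points(seg.mask), circle=circle)
    ellipse_mask = rasterize_fit(fit, seg.mask.shape)
    return PipelineResult(detection=det, growcut=seg, fit=fit, ellipse_mask=ellipse_mask)


def _detection_json(det: DetectionResult) -> dict:
    return {
        "native_center_row": det.native_center_row,
        "native_center_col": det.native_center_col,
        "native_radius": round(det.native_radius, 2),
        "scale": det.scale,
        "strength": det.circle.strength,
        "sensitivity_level": det.sensitivity_level,
        "working_circle": dataclasses.asdict(det.circle),
    }


def run_pipeline(
    input_path: str | Path,
    out_dir: str | Path,
    cfg: Config | None = None,
    *,
    circle: bool = False,
) -> PipelineResult:
    """Process one image file and write all artifacts into ``out_dir``.

    Artifacts (``<stem>`` is the input file stem): ``<stem>_detection.json``,
    ``<stem>_growcut_mask.png``, ``<stem>_ellipse_mask.png``,
    ``<stem>_ellipse.json``.
    """
    if cfg is None:
        cfg = Config()
    input_path = Path(input_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("config: %s", json.dumps(cfg.to_flat_dict(), sort_keys=True))
    img = _io.read_fundus(input_path)
    result = segment_image(img, cfg, circle=circle)
    stem = input_path.stem
    (out_dir / f"{stem}_detection.json").write_text(
        json.dumps(_detection_json(result.detection), indent=2, sort_keys=True) + "\n"
    )
    _io.write_mask(out_dir / f"{stem}_growcut_mask.png", result.growcut.mask)
    _io.write_mask(out_dir / f"{stem}_ellipse_mask.png", result.ellipse_mask)
    (out_dir / f"{stem}_ellipse.json").write_text(
        json.dumps(
            {
                **dataclasses.asdict(result.fit),
                "growcut_iterations": result.growcut.iterations,
                "growcut_converged": result.growcut.converged,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return result
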