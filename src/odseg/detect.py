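"""Optic-disc localization by morphology and the circular Hough transform.

The vasculature radiating from the disc is the main distractor for circle
finding, so it is filled in first with a grayscale closing whose disc element
is wider than the thickest vessel. The image is then resized to a common
working width so that one radius band — 29–50 px — describes the optic disc
across cameras and resolutions, and a circular Hough transform accumulates
edge votes over that band. Candidate circles are ranked by accumulator
strength; a ladder of decreasing strictness is walked until the first level
that yields any circle, and the strongest circle at that level is the
detection.

Coordinates are 0-based ``(row, col)``; the result carries both the circle at
working resolution and its center mapped back to native pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, morphology, transform

from .config import Config, DetectConfig
from .errors import DetectionFailureError, InvalidInputError, ParameterError
from .preprocess import FundusImage, preprocess

__all__ = [
    "CircleHypothesis",
    "DetectionResult",
    "remove_vessels",
    "resize_to_working",
    "hough_circles",
    "detect_od",
]


@dataclass(frozen=True)
class CircleHypothesis:
    """A candidate optic-disc circle at working resolution.

    ``strength`` is the normalized Hough accumulator score: the fraction of
    the full circle perimeter supported by edge votes (1.0 = every perimeter
    pixel voted).
    """

    center_row: int
    center_col: int
    radius: int
    strength: float


@dataclass(frozen=True)
class DetectionResult:
    circle: CircleHypothesis
    #: Ratio native / working resolution.
    scale: float
    native_center_row: int
    native_center_col: int
    native_radius: float
    #: Accumulator-threshold fraction of the ladder level that fired.
    sensitivity_level: float


def remove_vessels(i_sc: np.ndarray, se_radius: int = 15) -> np.ndarray:
    """Grayscale closing with a disc element; fills dark structures (vessels)
    narrower than the disc diameter. Extensive: output >= input pointwise."""
    i_sc = np.asarray(i_sc, dtype=np.float64)
    if se_radius < 1:
        raise ParameterError(f"structuring-element radius must be >= 1, got {se_radius}")
    return morphology.closing(
        i_sc, morphology.disk(int(se_radius), decomposition="sequence")
    )


def resize_to_working(
    raster: np.ndarray, target_width: int = 565
) -> tuple[np.ndarray, float]:
    """Bilinear resize to ``target_width`` preserving aspect ratio.

    Returns ``(resized, scale)`` with ``scale = native_width / target_width``
    mapping working coordinates back to native pixels.
    """
    raster = np.asarray(raster, dtype=np.float64)
    if raster.ndim != 2:
        raise InvalidInputError("expected a 2-D raster")
    if target_width < 128:
        raise ParameterError(f"working width must be >= 128, got {target_width}")
    h, w = raster.shape
    if w == target_width:
        return raster, 1.0
    scale = w / target_width
    target_height = max(1, round(h / scale))
    resized = transform.resize(
        raster, (target_height, target_width), order=1,
        anti_aliasing=scale > 1.0, preserve_range=True,
    )
    return resized, scale


def _edge_map(raster: np.ndarray, sigma: float) -> np.ndarray:
    # Gaussian-derivative gradient + non-maximum suppression + hysteresis.
    # Quantile thresholds keep edge extraction contrast-adaptive: the shade-
    # corrected disc rim can be a weak (but locally dominant) gradient.
    return feature.canny(
        raster, sigma=sigma, use_quantiles=True,
        low_threshold=0.80, high_threshold=0.95,
    )


def hough_circles(
    raster: np.ndarray,
    r_min: int = 29,
    r_max: int = 50,
    sensitivity: float = 0.5,
    *,
    sigma: float = 2.0,
    edges: np.ndarray | None = None,
    accumulator: np.ndarray | None = None,
) -> list[CircleHypothesis]:
    """Bright-circle hypotheses over the radius band ``[r_min, r_max]``.

    ``sensitivity`` in [0, 1] sets the accumulator threshold to
    ``1 − sensitivity`` of the theoretical full-perimeter vote count: higher
    sensitivity → lower threshold → more circles. Hypotheses are the local
    maxima of the normalized ``(row, col, r)`` accumulator above threshold,
    sorted by strength descending (ties: smaller radius, then row, then col),
    so the set at a stricter level is a subset of any more permissive level.

    An empty list is a valid return (no circle supported at this level).
    """
    raster = np.asarray(raster, dtype=np.float64)
    if r_min > r_max or r_min < 1:
        raise ParameterError(f"invalid radius band [{r_min}, {r_max}]")
    if not 0.0 <= sensitivity <= 1.0:
        raise ParameterError(f"sensitivity must lie in [0, 1], got {sensitivity}")
    radii = np.arange(int(r_min), int(r_max) + 1)
    if accumulator is None:
        if edges is None:
            edges = _edge_map(raster, sigma)
        accumulator = transform.hough_circle(edges, radii, normalize=True)
    threshold = 1.0 - sensitivity
    # Local maxima in the (r, row, col) accumulator (plateaus keep all points).
    local_max = accumulator >= ndi.maximum_filter(accumulator, size=3, mode="constant")
    candidates = np.argwhere(local_max & (accumulator >= max(threshold, 1e-9)))
    hypotheses = [
        CircleHypothesis(
            center_row=int(r), center_col=int(c),
            radius=int(radii[ri]), strength=float(accumulator[ri, r, c]),
        )
        for ri, r, c in candidates
    ]
    hypotheses.sort(key=lambda h: (-h.strength, h.radius, h.center_row, h.center_col))
    return hypotheses


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def detect_od(
    img: FundusImage | np.ndarray, cfg: Config | None = None
) -> DetectionResult:
    """Full optic-disc localization.

    preprocess → vessel-removing closing → resize to working width → circular
    Hough transform, walking the sensitivity ladder from strict to permissive
    and keeping the strongest circle of the first non-empty level.

    Raises
    ------
    DetectionFailureError
        If even the most permissive ladder level yields no circle.
    """
    if cfg is None:
        cfg = Config()
    dcfg: DetectConfig = cfg.detect
    pre = preprocess(img, cfg)
    closed = remove_vessels(pre.i_sc, dcfg.close_radius)
    work, scale = resize_to_working(closed, dcfg.working_width)
    edges = _edge_map(work, dcfg.canny_sigma)
    radii = np.arange(dcfg.rmin, dcfg.rmax + 1)
    accumulator = transform.hough_circle(edges, radii, normalize=True)
    for level in dcfg.sensitivity_ladder:
        hyps = hough_circles(
            work, dcfg.rmin, dcfg.rmax, sensitivity=1.0 - level,
            accumulator=accumulator,
        )
        if hyps:
            best = hyps[0]
            h, w = np.asarray(img.pixels if isinstance(img, FundusImage) else img).shape[:2]
            nr = min(max(_round_half_up(best.center_row * scale), 0), h - 1)
            nc = min(max(_round_half_up(best.center_col * scale), 0), w - 1)
            return DetectionResult(
                circle=best, scale=scale,
                native_center_row=nr, native_center_col=nc,
                native_radius=best.radius * scale,
                sensitivity_level=level,
            )
    raise DetectionFailureError(
        "no circle found in the radius band at any sensitivity level"
    )
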