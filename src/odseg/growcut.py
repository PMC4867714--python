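"""Grow-cut cellular-automaton segmentation of the optic disc.

Each pixel is a cell carrying a triplet ``(label, strength, value)``: label in
{+1 disc, −1 background, 0 undefined}, strength θ ∈ [0, 1] measuring how
certain the cell is of its label, and value C — here the shade-corrected green
intensity. Seeds start with strength 1 and are immovable. At every synchronous
sweep each labeled neighbor x of a cell p mounts an attack of force

    λ(x) = g(x) · θ(x),      g(x) = 1 − |C_p − C_x| / C_max,

and p is conquered by the strongest attacker whose λ exceeds p's own strength,
adopting that label with strength λ. Similar intensities attack at almost full
force, so labels flood uniform regions and stall at intensity edges — which is
exactly where the disc rim is. The automaton terminates when a sweep changes
nothing.

The segmentation entry point :func:`segment_od` seeds the foreground with a
small disk at the detected disc center, the background with everything far
from it, evolves the automaton on the shade-corrected image at working
resolution, and keeps the connected foreground component containing the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure, transform

from .config import Config, GrowCutConfig
from .detect import DetectionResult, resize_to_working
from .errors import InvalidInputError, InvalidSeedError, ParameterError, SegmentationFailureError

__all__ = [
    "SeedSpec",
    "GrowCutGrid",
    "SegmentationResult",
    "init_grid",
    "attack_strength",
    "evolve",
    "segment_od",
]

# Neighbor offsets in row-major scan order; this order is the documented
# tie-break among equally strong attackers.
_OFFSETS_8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
_OFFSETS_4 = ((-1, 0), (0, -1), (0, 1), (1, 0))


@dataclass(frozen=True)
class SeedSpec:
    """Seed geometry: a foreground disk and a far background region.

    Cells within Euclidean distance ``fg_radius`` of the center are +1 seeds;
    cells at distance >= ``bg_radius`` are −1 seeds. Requires
    ``0 < fg_radius < bg_radius``.
    """

    fg_center_row: int
    fg_center_col: int
    fg_radius: float
    bg_radius: float

    def __post_init__(self) -> None:
        if not 0 < self.fg_radius < self.bg_radius:
            raise InvalidSeedError(
                f"need 0 < fg_radius < bg_radius, got {self.fg_radius}, {self.bg_radius}"
            )


@dataclass
class GrowCutGrid:
    """Automaton state: per-cell label/strength/value plus bookkeeping."""

    labels: np.ndarray      # int8, {−1, 0, +1}
    strengths: np.ndarray   # float64 in [0, 1]
    values: np.ndarray      # float64 intensities
    c_max: float = 1.0
    iterations: int = 0
    last_changed: int = -1
    converged: bool = False
    #: Cells seeded at strength 1; immutable by construction of the rule.
    seed_mask: np.ndarray = field(default=None)  # type: ignore[assignment]


@dataclass(frozen=True)
class SegmentationResult:
    """Boolean optic-disc mask plus automaton diagnostics."""

    mask: np.ndarray
    iterations: int
    converged: bool


def init_grid(i_sc: np.ndarray, seeds: SeedSpec) -> GrowCutGrid:
    """Initialize the automaton: all cells (label 0, strength 0, value = pixel
    intensity), then plant the foreground disk and far-background seeds at
    strength 1."""
    values = np.asarray(i_sc, dtype=np.float64)
    if values.ndim != 2:
        raise InvalidInputError("expected a 2-D raster")
    h, w = values.shape
    rr, cc = np.ogrid[:h, :w]
    dist = np.hypot(rr - seeds.fg_center_row, cc - seeds.fg_center_col)
    fg = dist <= seeds.fg_radius
    bg = dist >= seeds.bg_radius
    if not fg.any():
        raise InvalidSeedError("foreground seed disk does not intersect the grid")
    if not bg.any():
        raise InvalidSeedError("background seed region is empty on this grid")
    labels = np.zeros((h, w), dtype=np.int8)
    strengths = np.zeros((h, w), dtype=np.float64)
    labels[fg] = 1
    strengths[fg] = 1.0
    labels[bg] = -1
    strengths[bg] = 1.0
    return GrowCutGrid(
        labels=labels, strengths=strengths, values=values, seed_mask=fg | bg
    )


def attack_strength(c_p, c_x, c_max: float = 1.0):
    """Attack attenuation ``g = 1 − |c_p − c_x| / c_max`` in [0, 1].

    Monotonically decreasing in the intensity difference: g = 1 iff the
    intensities are equal, g = 0 iff they differ by the full dynamic range
    ``c_max`` (1.0 for [0, 1] rasters, ``2**L − 1`` for L-bit integers).
    """
    if c_max <= 0:
        raise ParameterError(f"c_max must be positive, got {c_max}")
    return 1.0 - np.abs(np.asarray(c_p, dtype=np.float64) - c_x) / c_max


def _shift(arr: np.ndarray, dr: int, dc: int, fill) -> np.ndarray:
    """View of ``arr`` shifted so position p holds arr[p + (dr, dc)]."""
    out = np.full_like(arr, fill)
    h, w = arr.shape
    rs_dst = slice(max(0, -dr), min(h, h - dr))
    cs_dst = slice(max(0, -dc), min(w, w - dc))
    rs_src = slice(max(0, dr), min(h, h + dr))
    cs_src = slice(max(0, dc), min(w, w + dc))
    out[rs_dst, cs_dst] = arr[rs_src, cs_src]
    return out


def step(grid: GrowCutGrid, neighborhood: int = 8) -> int:
    """One synchronous sweep; returns the number of cells taken over.

    All attacks are computed from the previous sweep's state. Among multiple
    successful attackers the largest λ wins; exact ties go to the earliest
    neighbor in row-major scan order.
    """
    offsets = _OFFSETS_8 if neighborhood == 8 else _OFFSETS_4
    lab, theta, val = grid.labels, grid.strengths, grid.values
    best_lambda = np.zeros_like(theta)
    best_label = np.zeros_like(lab)
    for dr, dc in offsets:
        lx = _shift(lab, dr, dc, 0)
        tx = _shift(theta, dr, dc, 0.0)
        cx = _shift(val, dr, dc, 0.0)
        g = 1.0 - np.abs(val - cx) / grid.c_max
        lam = g * tx
        win = (lx != 0) & (lam > best_lambda)
        best_lambda[win] = lam[win]
        best_label[win] = lx[win]
    conquered = best_lambda > theta
    grid.labels = np.where(conquered, best_label, lab)
    grid.strengths = np.where(conquered, best_lambda, theta)
    grid.iterations += 1
    grid.last_changed = int(conquered.sum())
    return grid.last_changed


def evolve(
    grid: GrowCutGrid, max_iter: int = 500, neighborhood: int = 8
) -> tuple[GrowCutGrid, int]:
    """Run sweeps until a sweep changes nothing or ``max_iter`` is reached.

    Non-convergence at ``max_iter`` is reported through ``grid.converged``
    (False), not an exception.
    """
    if neighborhood not in (4, 8):
        raise ParameterError(f"neighborhood must be 4 or 8, got {neighborhood}")
    if not (grid.labels == 1).any() or not (grid.labels == -1).any():
        raise InvalidSeedError("evolve requires at least one seed of each class")
    used = 0
    for _ in range(max_iter):
        changed = step(grid, neighborhood)
        used += 1
        if changed == 0:
            grid.converged = True
            break
    else:
        grid.converged = False
    return grid, used


def segment_od(
    i_sc: np.ndarray, det: DetectionResult, cfg: Config | None = None
) -> SegmentationResult:
    """Segment the optic disc from a detection result.

    The shade-corrected raster is brought to the working resolution the
    detection used, seeded with a foreground disk of ``fg_scale * r`` and
    background beyond ``bg_scale * r`` around the detected circle, evolved to
    convergence, and the +1 component containing the seed center is returned
    as a boolean mask at the input raster's native shape.
    """
    if cfg is None:
        cfg = Config()
    gcfg: GrowCutConfig = cfg.growcut
    i_sc = np.asarray(i_sc, dtype=np.float64)
    native_shape = i_sc.shape
    work, scale = resize_to_working(i_sc, cfg.detect.working_width)
    h, w = work.shape
    cr, cc = det.circle.center_row, det.circle.center_col
    r = det.circle.radius
    fg_r = gcfg.fg_scale * r
    bg_r = gcfg.bg_scale * r

    # The automaton only moves inside the bg ring, so evolve on that crop.
    pad = int(np.ceil(bg_r)) + 2
    r0, r1 = max(0, cr - pad), min(h, cr + pad + 1)
    c0, c1 = max(0, cc - pad), min(w, cc + pad + 1)
    roi = work[r0:r1, c0:c1]
    rr, ccg = np.ogrid[: roi.shape[0], : roi.shape[1]]
    dist = np.hypot(rr - (cr - r0), ccg - (cc - c0))
    # Near a border the far ring may be clipped away; pull it in just enough
    # to keep at least the farthest cells as background seeds.
    bg_r_eff = min(bg_r, float(dist.max()))
    if bg_r_eff <= fg_r:
        raise SegmentationFailureError("no room for background seeds around the disc")
    seeds = SeedSpec(cr - r0, cc - c0, fg_r, bg_r_eff)
    grid = init_grid(roi, seeds)
    grid, _ = evolve(grid, gcfg.max_iter, gcfg.neighborhood)

    fg_mask = grid.labels == 1
    comp = measure.label(fg_mask, connectivity=2)
    center_label = comp[cr - r0, cc - c0]
    if center_label == 0:
        raise SegmentationFailureError("seed center lost from the foreground")
    roi_mask = comp == center_label

    mask_work = np.zeros((h, w), dtype=bool)
    mask_work[r0:r1, c0:c1] = roi_mask
    if mask_work.shape != native_shape:
        mask = transform.resize(
            mask_work.astype(np.float64), native_shape, order=0,
            anti_aliasing=False, preserve_range=True,
        ) > 0.5
    else:
        mask = mask_work
    if not mask.any():
        raise SegmentationFailureError("empty segmentation mask")
    return SegmentationResult(
        mask=mask, iterations=grid.iterations, converged=grid.converged
    )
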