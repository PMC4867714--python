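"""Elliptical approximation of the grow-cut boundary.

The raw grow-cut mask follows the intensity edge exactly, including vessel
indentations at the disc rim. The reported boundary is instead a direct
least-squares ellipse fitted to the traced outer contour of the mask, which
restores the anatomically smooth disc outline; a circle constraint is
available for the circular-approximation variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .errors import EllipseFitError, InvalidInputError

__all__ = ["EllipseFit", "boundary_points", "fit_ellipse", "fit_circle", "rasterize_fit"]

# Moore neighbors in clockwise order starting due north, for contour tracing.
_CLOCKWISE = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


@dataclass(frozen=True)
class EllipseFit:
    """Fitted ellipse: center (row, col), semi-axes (px), angle in [0, π).

    ``angle`` is measured from the row axis toward the column axis;
    ``semi_major >= semi_minor > 0``.
    """

    center_row: float
    center_col: float
    semi_major: float
    semi_minor: float
    angle: float


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab = measure.label(mask, connectivity=2)
    if lab.max() == 0:
        raise InvalidInputError("mask has no foreground pixel")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == int(np.argmax(sizes))


def boundary_points(mask: np.ndarray) -> list[tuple[int, int]]:
    """Ordered outer-contour pixels (8-connected Moore trace) of the largest
    foreground component. Interior holes are ignored; an isolated pixel yields
    a single-point contour."""
    mask = np.asarray(mask, dtype=bool)
    comp = _largest_component(mask)
    comp = ndi.binary_fill_holes(comp)
    h, w = comp.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and comp[r, c]

    # Row-major scan finds the topmost-leftmost pixel; we arrived "from the
    # west", so the backtrack direction is west.
    start = tuple(int(v) for v in np.argwhere(comp)[0])
    contour: list[tuple[int, int]] = [start]
    seen_states: set[tuple[tuple[int, int], int]] = set()
    cur = start
    back_dir = 6  # index of (0, -1) in _CLOCKWISE
    while True:
        found = False
        for k in range(1, 9):
            idx = (back_dir + k) % 8
            nr, nc = cur[0] + _CLOCKWISE[idx][0], cur[1] + _CLOCKWISE[idx][1]
            if fg(nr, nc):
                # Backtrack for the next step: direction from the new pixel
                # to the last background pixel examined before it.
                prev_idx = (back_dir + k - 1) % 8
                br = cur[0] + _CLOCKWISE[prev_idx][0] - nr
                bc = cur[1] + _CLOCKWISE[prev_idx][1] - nc
                back_dir = _CLOCKWISE.index((br, bc))
                cur = (nr, nc)
                found = True
                break
        if not found:
            return [start]  # isolated pixel
        state = (cur, back_dir)
        if state in seen_states:
            break
        seen_states.add(state)
        if cur != contour[0] or len(contour) == 1:
            contour.append(cur)
        if cur == start and len(contour) > 1:
            break
    # Deduplicate (thin protrusions are traced on both sides) keeping order.
    seen: set[tuple[int, int]] = set()
    out = []
    for p in contour:
        if p not in seen:
            seen.add(p)
            out.append(p)
    return out


def fit_ellipse(points, *, circle: bool = False) -> EllipseFit:
    """Direct least-squares ellipse through ``points`` (row, col).

    Requires at least 5 non-degenerate points (3 for the circle constraint).
    The algebraic-error conic fit is ellipse-constrained; axes are normalized
    so ``semi_major >= semi_minor`` with the angle folded into [0, π).
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise EllipseFitError("points must be an (N, 2) array of (row, col)")
    if circle:
        return fit_circle(pts)
    if pts.shape[0] < 5:
        raise EllipseFitError(f"need at least 5 points, got {pts.shape[0]}")
    # EllipseModel is coordinate-agnostic; feed (row, col) as (x, y).
    model = measure.EllipseModel.from_estimate(pts)
    if not model:
        raise EllipseFitError("degenerate point configuration")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not np.all(np.isfinite([xc, yc, a, b, theta])):
        raise EllipseFitError("degenerate point configuration")
    if a <= 0 or b <= 0:
        raise EllipseFitError("degenerate point configuration")
    if b > a:
        a, b = b, a
        theta += np.pi / 2.0
    theta = float(np.mod(theta, np.pi))
    return EllipseFit(float(xc), float(yc), float(a), float(b), theta)


def fit_circle(points) -> EllipseFit:
    """Algebraic least-squares circle (Kåsa fit), returned as an equal-axis
    :class:`EllipseFit`."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.shape[0] < 3:
        raise EllipseFitError(f"need at least 3 points for a circle, got {pts.shape[0]}")
    r, c = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * r, 2 * c, np.ones_like(r)])
    b = r**2 + c**2
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise EllipseFitError("degenerate point configuration") from exc
    cr, cc, k = sol
    rad2 = k + cr**2 + cc**2
    if not np.isfinite(rad2) or rad2 <= 0:
        raise EllipseFitError("degenerate point configuration")
    radius = float(np.sqrt(rad2))
    return EllipseFit(float(cr), float(cc), radius, radius, 0.0)


def rasterize_fit(fit: EllipseFit, shape: tuple[int, int]) -> np.ndarray:
    """Filled-ellipse boolean mask on an ``shape`` grid, clipped to bounds."""
    h, w = int(shape[0]), int(shape[1])
    rr, cc = np.ogrid[:h, :w]
    dr = rr - fit.center_row
    dc = cc - fit.center_col
    cos_t, sin_t = np.cos(fit.angle), np.sin(fit.angle)
    u = dr * cos_t + dc * sin_t
    v = -dr * sin_t + dc * cos_t
    return (u / fit.semi_major) ** 2 + (v / fit.semi_minor) ** 2 <= 1.0
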