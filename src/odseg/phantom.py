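"""Seeded synthetic fundus phantoms with exact ground-truth disc masks.

The generator renders the structures that drive (and stress) optic-disc
localization: a dark circular field of view, a smooth background with an
optional linear illumination gradient, a bright slightly-elliptical disc with
a Gaussian-blurred rim (the ground truth is the exact ellipse *before* blur),
dark vessel curves converging at the disc center, optional bright exudate
blobs away from the disc, and one of three noise models (Gaussian, salt &
pepper, speckle) applied last. Noise and vessels are stressors only — they
never alter the ground-truth mask.

Default geometry is DRIVE-like (584×565), so the working-resolution radius
band 29–50 px maps one-to-one onto native pixels, and every default-jitter
disc radius stays inside that band after resizing. All randomness flows from
``rng_seed``; identical specs render bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import ndimage as ndi

from .errors import InvalidInputError, ParameterError
from .preprocess import FundusImage

__all__ = ["PhantomSpec", "generate", "generate_batch", "DEFAULT_JITTER"]

_NOISE_MODELS = ("none", "gaussian", "salt_pepper", "speckle")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; every field has a realistic default."""

    width: int = 565
    height: int = 584
    disc_center: tuple[int, int] = (280, 190)   # (row, col); disc sits nasally
    disc_radius: float = 40.0
    disc_intensity: float = 0.85
    background_intensity: float = 0.45
    #: Minor/major axis ratio of the rendered disc ellipse.
    ellipticity: float = 0.92
    vessel_count: int = 5
    vessel_width: float = 3.0
    #: How much darker vessels are than the local background.
    vessel_contrast: float = 0.18
    #: Amplitude of the linear illumination ramp across the field of view.
    illumination_gradient: float = 0.10
    exudate_count: int = 0
    exudate_radius_range: tuple[float, float] = (4.0, 10.0)
    exudate_intensity: float = 0.80
    #: Gaussian sigma of the disc rim blur, pixels.
    edge_sigma: float = 2.0
    noise_model: str = "none"
    #: sigma for gaussian, pixel fraction for salt_pepper, variance for speckle.
    noise_param: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ParameterError("phantom must be at least 64×64")
        if self.noise_model not in _NOISE_MODELS:
            raise ParameterError(
                f"noise_model must be one of {_NOISE_MODELS}, got {self.noise_model!r}"
            )
        if not 0.7 < self.ellipticity <= 1.0:
            raise ParameterError("ellipticity must lie in (0.7, 1.0]")
        for name in ("disc_intensity", "background_intensity", "exudate_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.illumination_gradient <= 0.5:
            raise ParameterError("illumination_gradient must lie in [0, 0.5]")
        fov_r = 0.48 * min(self.height, self.width)
        ctr = np.hypot(
            self.disc_center[0] - self.height / 2.0,
            self.disc_center[1] - self.width / 2.0,
        )
        if ctr + self.disc_radius >= fov_r:
            raise ParameterError("disc must lie fully inside the field of view")


def _fov(spec: PhantomSpec) -> tuple[np.ndarray, float, tuple[float, float]]:
    h, w = spec.height, spec.width
    rr, cc = np.ogrid[:h, :w]
    center = (h / 2.0, w / 2.0)
    radius = 0.48 * min(h, w)
    mask = np.hypot(rr - center[0], cc - center[1]) <= radius
    return mask, radius, center


def _disc_mask(spec: PhantomSpec, angle: float) -> np.ndarray:
    rr, cc = np.ogrid[: spec.height, : spec.width]
    dr = rr - spec.disc_center[0]
    dc = cc - spec.disc_center[1]
    u = dr * np.cos(angle) + dc * np.sin(angle)
    v = -dr * np.sin(angle) + dc * np.cos(angle)
    a = spec.disc_radius
    b = spec.disc_radius * spec.ellipticity
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _stamp_curve(
    mask: np.ndarray, pts: np.ndarray, half_width: float
) -> None:
    """Mark ``mask`` true within ``half_width`` of the sampled curve."""
    h, w = mask.shape
    rad = max(1, int(np.ceil(half_width)))
    drr, dcc = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    stamp = np.hypot(drr, dcc) <= half_width
    offs = np.argwhere(stamp) - rad
    px = np.unique(np.round(pts).astype(int), axis=0)
    coords = (px[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    keep = (
        (coords[:, 0] >= 0) & (coords[:, 0] < h)
        & (coords[:, 1] >= 0) & (coords[:, 1] < w)
    )
    coords = coords[keep]
    mask[coords[:, 0], coords[:, 1]] = True


def _vessel_mask(spec: PhantomSpec, fov_radius: float, rng: np.random.Generator) -> np.ndarray:
    """Quadratic Bézier curves from the disc center out to the FOV rim."""
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    p0 = np.asarray(spec.disc_center, dtype=float)
    fov_center = np.array([spec.height / 2.0, spec.width / 2.0])
    for _ in range(spec.vessel_count):
        ang = rng.uniform(0.0, 2.0 * np.pi)
        p2 = fov_center + (fov_radius - 2.0) * np.array([np.sin(ang), np.cos(ang)])
        mid = (p0 + p2) / 2.0
        chord = p2 - p0
        norm = np.linalg.norm(chord)
        perp = np.array([-chord[1], chord[0]]) / max(norm, 1e-9)
        p1 = mid + perp * rng.uniform(-0.25, 0.25) * norm
        t = np.linspace(0.0, 1.0, 400)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
        _stamp_curve(mask, pts, spec.vessel_width / 2.0)
    return mask


def _exudate_mask(
    spec: PhantomSpec, fov_radius: float, rng: np.random.Generator
) -> np.ndarray:
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    fov_center = np.array([spec.height / 2.0, spec.width / 2.0])
    disc_center = np.asarray(spec.disc_center, dtype=float)
    lo, hi = spec.exudate_radius_range
    placed = 0
    attempts = 0
    while placed < spec.exudate_count and attempts < 50 * max(1, spec.exudate_count):
        attempts += 1
        pos = fov_center + (rng.uniform(0, 0.85 * fov_radius)) * _unit(rng)
        if np.linalg.norm(pos - disc_center) < 1.6 * spec.disc_radius:
            continue
        radius = rng.uniform(lo, hi)
        rr, cc = np.ogrid[: spec.height, : spec.width]
        mask |= np.hypot(rr - pos[0], cc - pos[1]) <= radius
        placed += 1
    return mask


def _unit(rng: np.random.Generator) -> np.ndarray:
    ang = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([np.sin(ang), np.cos(ang)])


def _apply_noise(green: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_model == "none":
        return green
    if spec.noise_model == "gaussian":
        out = green + rng.normal(0.0, spec.noise_param, green.shape)
    elif spec.noise_model == "speckle":
        out = green * (1.0 + rng.normal(0.0, np.sqrt(spec.noise_param), green.shape))
    else:  # salt_pepper
        out = green.copy()
        u = rng.random(green.shape)
        out[u < spec.noise_param / 2.0] = 0.0
        out[(u >= spec.noise_param / 2.0) & (u < spec.noise_param)] = 1.0
    return np.clip(out, 0.0, 1.0)


def generate(spec: PhantomSpec) -> tuple[FundusImage, np.ndarray]:
    """Render one phantom; returns ``(image, truth_mask)``.

    The truth mask is the exact disc ellipse prior to rim blur and noise, so
    it is identical across noise models of an otherwise equal spec.
    """
    rng = np.random.default_rng(spec.rng_seed)
    fov, fov_radius, _ = _fov(spec)

    cols = np.arange(spec.width, dtype=np.float64)[None, :]
    ramp = (cols - spec.width / 2.0) / spec.width
    green = np.full((spec.height, spec.width), spec.background_intensity)
    green = green + spec.illumination_gradient * ramp

    disc_angle = rng.uniform(0.0, np.pi)
    truth = _disc_mask(spec, disc_angle)
    disc_soft = ndi.gaussian_filter(truth.astype(np.float64), spec.edge_sigma)
    green = green * (1.0 - disc_soft) + spec.disc_intensity * disc_soft

    vessels = _vessel_mask(spec, fov_radius, rng)
    vessel_soft = ndi.gaussian_filter(vessels.astype(np.float64), 0.8)
    vessel_level = max(0.05, spec.background_intensity - spec.vessel_contrast)
    green = green * (1.0 - vessel_soft) + vessel_level * vessel_soft

    if spec.exudate_count > 0:
        ex = _exudate_mask(spec, fov_radius, rng)
        ex_soft = ndi.gaussian_filter(ex.astype(np.float64), 1.0)
        green = green * (1.0 - ex_soft) + spec.exudate_intensity * ex_soft

    green = np.where(fov, green, 0.03)
    green = _apply_noise(np.clip(green, 0.0, 1.0), spec, rng)

    red = np.clip(green * 1.2, 0.0, 1.0)
    blue = green * 0.5
    rgb = np.stack([red, green, blue], axis=-1)
    pixels = np.floor(rgb * 255.0 + 0.5).astype(np.uint8)
    return FundusImage(pixels), truth


DEFAULT_JITTER: dict[str, tuple[float, float]] = {
    "disc_radius": (-8.0, 8.0),
    "disc_center_row": (-60.0, 60.0),
    "disc_center_col": (-40.0, 40.0),
    "disc_intensity": (-0.08, 0.05),
    "background_intensity": (-0.05, 0.05),
    "ellipticity": (-0.12, 0.08),
}


def generate_batch(
    n: int,
    base_spec: PhantomSpec | None = None,
    jitter: dict[str, tuple[float, float]] | None = None,
    rng_seed: int = 0,
) -> list[tuple[FundusImage, np.ndarray, PhantomSpec]]:
    """Render ``n`` phantoms with uniformly jittered geometry and contrast.

    ``jitter`` maps spec fields to uniform ``(lo, hi)`` additive ranges;
    ``DEFAULT_JITTER`` varies disc position, radius, contrast and ellipticity
    while keeping every radius inside the detector's 29–50 px working band.
    Fully reproducible from ``rng_seed``.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if base_spec is None:
        base_spec = PhantomSpec()
    if jitter is None:
        jitter = DEFAULT_JITTER
    rng = np.random.default_rng(rng_seed)
    out = []
    if not jitter:
        # Zero jitter reproduces the base spec exactly, seed included.
        for _ in range(n):
            img, truth = generate(base_spec)
            out.append((img, truth, base_spec))
        return out
    for _ in range(n):
        changes: dict[str, object] = {}
        center = list(base_spec.disc_center)
        for key, (lo, hi) in jitter.items():
            delta = rng.uniform(lo, hi)
            if key == "disc_center_row":
                center[0] = int(round(base_spec.disc_center[0] + delta))
            elif key == "disc_center_col":
                center[1] = int(round(base_spec.disc_center[1] + delta))
            else:
                base = getattr(base_spec, key)
                value = base + delta
                if key == "ellipticity":
                    value = float(np.clip(value, 0.75, 1.0))
                elif key.endswith("intensity"):
                    value = float(np.clip(value, 0.0, 1.0))
                changes[key] = value
        changes["disc_center"] = (center[0], center[1])
        changes["rng_seed"] = int(rng.integers(0, 2**31 - 1))
        spec = replace(base_spec, **changes)
        img, truth = generate(spec)
        out.append((img, truth, spec))
    return out
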