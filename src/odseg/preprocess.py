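"""Illumination-normalizing preprocessing of the fundus green channel.

Retinal photographs vary strongly in luminosity and pigmentation, both between
images and across one image (vignetting, uneven flash). The pipeline here
produces a *shade-corrected* green channel ``I_SC`` on which the optic disc is
the brightest structure over a flat background:

1. extract the green channel (highest disc/background contrast) scaled to [0, 1];
2. grayscale-open it with a small disc element ``I_open`` (suppresses thin
   bright structures such as specular reflexes on vessels);
3. estimate the background ``I_bg`` with a large arithmetic-mean kernel — large
   enough that the blurred image contains no visible disc, vessels or lesions;
4. subtract: ``I_norm = I_open − I_bg``;
5. shade-correct with a global linear map that moves the modal (background)
   intensity of ``I_norm`` to 0.5, clamping to [0, 1]:
   ``I_SC = clip(I_norm − mode(I_norm) + 0.5, 0, 1)``.

After step 5 the background of any image sits at 0.5 regardless of the original
illumination, which is what makes a single set of downstream thresholds usable
across cameras and acquisition conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .config import Config, PreprocessConfig
from .errors import InvalidInputError, ParameterError

__all__ = [
    "FundusImage",
    "PreprocessedImage",
    "extract_green",
    "estimate_background",
    "open_green",
    "normalize",
    "shade_correct",
    "preprocess",
]


@dataclass(frozen=True)
class FundusImage:
    """An 8-bit RGB fundus photograph.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` array of uint8 intensities, H and W at least 64.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InvalidInputError(
                f"fundus image must be H×W×3, got shape {px.shape}"
            )
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise InvalidInputError(
                f"fundus image must be at least 64×64 pixels, got {px.shape[:2]}"
            )
        if px.dtype != np.uint8:
            if np.nanmin(px) < 0 or np.nanmax(px) > 255:
                raise InvalidInputError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class PreprocessedImage:
    """All intermediate rasters of the normalization pipeline (each H×W).

    ``green``, ``i_open``, ``i_bg``, ``i_norm`` and ``i_sc`` share one shape;
    ``i_sc`` lies in [0, 1]; ``mode_intensity`` is the modal intensity of
    ``i_norm`` (the background level removed by shade correction).
    """

    green: np.ndarray
    i_open: np.ndarray
    i_bg: np.ndarray
    i_norm: np.ndarray
    i_sc: np.ndarray
    mode_intensity: float


def extract_green(img: FundusImage) -> np.ndarray:
    """Return the green channel rescaled from [0, 255] to [0, 1]."""
    if not isinstance(img, FundusImage):
        img = FundusImage(np.asarray(img))
    return img.pixels[:, :, 1].astype(np.float64) / 255.0


def estimate_background(green: np.ndarray, kernel: int = 89) -> np.ndarray:
    """Arithmetic-mean filter with replicate border padding.

    ``kernel`` must be odd, at least 3 and no larger than the shorter image
    side. Replicate padding avoids the artificial dark vignette a zero pad
    would create at the field-of-view border.
    """
    green = np.asarray(green, dtype=np.float64)
    if green.ndim != 2:
        raise InvalidInputError("expected a 2-D raster")
    if kernel % 2 == 0 or kernel < 3 or kernel > min(green.shape):
        raise ParameterError(
            f"mean kernel must be odd, >=3 and <=min(H, W); got {kernel} "
            f"for shape {green.shape}"
        )
    return ndi.uniform_filter(green, size=kernel, mode="nearest")


def _disk(radius: int) -> np.ndarray | tuple:
    # Sequence decomposition trades the exact disc for a fast octagonal
    # approximation; all opening/closing identities hold regardless.
    return morphology.disk(radius, decomposition="sequence")


def open_green(green: np.ndarray, se_radius: int = 8) -> np.ndarray:
    """Grayscale opening with a disc structuring element.

    Removes bright structures thinner than the disc diameter; anti-extensive
    (output <= input pointwise) and idempotent.
    """
    green = np.asarray(green, dtype=np.float64)
    if se_radius < 1:
        raise ParameterError(f"structuring-element radius must be >= 1, got {se_radius}")
    return morphology.opening(green, _disk(int(se_radius)))


def normalize(i_open: np.ndarray, i_bg: np.ndarray) -> np.ndarray:
    """Background subtraction ``I_norm = I_open − I_bg`` (may be negative)."""
    i_open = np.asarray(i_open, dtype=np.float64)
    i_bg = np.asarray(i_bg, dtype=np.float64)
    if i_open.shape != i_bg.shape:
        raise InvalidInputError(
            f"shape mismatch: {i_open.shape} vs {i_bg.shape}"
        )
    return i_open - i_bg


def shade_correct(
    i_norm: np.ndarray, hist_bins: int = 256
) -> tuple[np.ndarray, float]:
    """Global linear shade correction.

    The modal intensity of ``i_norm`` — the value taken by the most pixels,
    i.e. the background level — is found on a ``hist_bins`` equal-width
    histogram spanning the raster's range (ties toward the lowest bin, mode =
    bin center). The raster is shifted so that level lands at 0.5 and clamped
    to [0, 1]:

    ``I_SC = clip(I_norm − mode + 0.5, 0, 1)``

    Returns
    -------
    (i_sc, mode_intensity)
    """
    i_norm = np.asarray(i_norm, dtype=np.float64)
    if i_norm.size == 0:
        raise InvalidInputError("empty raster")
    if not np.all(np.isfinite(i_norm)):
        raise InvalidInputError("raster contains non-finite values")
    lo = float(i_norm.min())
    hi = float(i_norm.max())
    if hi == lo:
        mode = lo
    else:
        counts, edges = np.histogram(i_norm, bins=int(hist_bins), range=(lo, hi))
        idx = int(np.argmax(counts))  # argmax takes the lowest tied bin
        mode = float((edges[idx] + edges[idx + 1]) / 2.0)
    i_adjusted = i_norm - mode + 0.5
    i_sc = np.clip(i_adjusted, 0.0, 1.0)
    return i_sc, mode


def preprocess(
    img: FundusImage | np.ndarray, cfg: Config | PreprocessConfig | None = None
) -> PreprocessedImage:
    """Run the full normalization pipeline on an RGB fundus image."""
    if cfg is None:
        cfg = PreprocessConfig()
    elif isinstance(cfg, Config):
        cfg = cfg.preprocess
    green = extract_green(img)
    # On images narrower than the configured kernel, fall back to the largest
    # odd kernel that fits; the kernel only needs to blur out all structures.
    kernel = min(cfg.kernel, min(green.shape))
    if kernel % 2 == 0:
        kernel -= 1
    # Impulse (salt & pepper) noise must go before any erosion/dilation: a
    # single dark impulse would otherwise be smeared to the element's size.
    denoised = (
        ndi.median_filter(green, size=2 * cfg.median_radius + 1, mode="nearest")
        if cfg.median_radius > 0
        else green
    )
    i_open = open_green(denoised, cfg.open_radius)
    i_bg = estimate_background(denoised, kernel)
    i_norm = normalize(i_open, i_bg)
    i_sc, mode = shade_correct(i_norm, cfg.hist_bins)
    return PreprocessedImage(
        green=green, i_open=i_open, i_bg=i_bg, i_norm=i_norm, i_sc=i_sc,
        mode_intensity=mode,
    )
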