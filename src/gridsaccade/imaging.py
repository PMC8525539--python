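"""Raster image I/O and robustness transforms.

Images are 2-D float64 numpy arrays of luminance in [0, 1] ("GrayImage"),
indexed ``img[row, col]``. A *location* is an ``(x, y) = (col, row)`` pair
with the origin at the top-left corner; this convention is used throughout
the package. The canonical working size is 440x440 pixels, matching the
extent of the grid-cell rate maps.

Two stimulus degradations are provided: rectangular occlusion covering a
fixed fraction of the image area (1/2, 1/3 or 1/4 in the standard probe
sets), and uniform downscaling of the whole image onto a constant-background
canvas of the canonical size (ratios 1/2, 1/4, 1/5), which downstream is
compensated by a matching saccade-gain factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.transform import resize

CANONICAL_SIZE = 440

#: ITU-R 601 luma weights for colour -> luminance conversion.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def validate_image(img: np.ndarray, name: str = "image") -> np.ndarray:
    """Check that *img* is a finite 2-D luminance array in [0, 1]."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {img.shape}")
    if img.size == 0:
        raise ValueError(f"{name} has zero size")
    if not np.all(np.isfinite(img)):
        raise ValueError(f"{name} contains non-finite values")
    if img.min() < 0 or img.max() > 1:
        raise ValueError(f"{name} values must lie in [0, 1]")
    return img


def to_gray(arr: np.ndarray) -> np.ndarray:
    """Convert an array as read from disk to a float luminance image in [0, 1]."""
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr.astype(np.float64) @ _LUMA_WEIGHTS
    else:
        arr = arr.astype(np.float64)
    if arr.size == 0 or min(arr.shape) == 0:
        raise ValueError("zero-dimension image")
    # integer inputs scale by dtype range; float inputs are assumed in [0,1]
    if np.issubdtype(np.asarray(arr).dtype, np.floating):
        hi = arr.max()
        if hi > 1.0:
            arr = arr / max(hi, 255.0)
    return np.clip(arr, 0.0, 1.0)


def load_image(path: str | Path, target_size: int = CANONICAL_SIZE) -> np.ndarray:
    """Read a PNG/BMP/JPEG file as a GrayImage resampled to target_size**2.

    Colour inputs are converted with ITU-R 601 weights; pixel values are
    rescaled to [0, 1]. Resampling is bilinear.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoding failure
        raise OSError(f"could not read image file {path!s}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.dtype.kind in "ui":
        img = to_gray(raw.astype(np.float64) / np.iinfo(raw.dtype).max)
    else:
        img = to_gray(raw)
    if img.shape != (target_size, target_size):
        img = resize(img, (target_size, target_size), order=1,
                     anti_aliasing=img.shape[0] > target_size,
                     preserve_range=True)
    return np.clip(img, 0.0, 1.0)


def save_image(path: str | Path, img: np.ndarray) -> None:
    """Write a GrayImage as an 8-bit grayscale PNG."""
    img = validate_image(img)
    iio.imwrite(Path(path), np.round(img * 255).astype(np.uint8), extension=".png")


@dataclass(frozen=True)
class OcclusionSpec:
    """Rectangular occlusion covering ``fraction`` of the image area.

    occluder: "texture" for a seeded smooth-noise patch, or a constant
        luminance in [0, 1].
    anchor: "random" places the rectangle uniformly at random; "bottom" /
        "top" force a full-width band at that edge; an ``(x, y)`` pair fixes
        the top-left corner of the occluder.
    """

    fraction: float
    occluder: str | float = "texture"
    anchor: str | tuple[int, int] = "random"

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError(f"occlusion fraction must be in (0, 1), got {self.fraction}")


def _texture_patch(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Smooth random texture in [0, 1] standing in for real-world occluders."""
    noise = rng.normal(size=shape)
    patch = ndimage.gaussian_filter(noise, sigma=6.0, mode="reflect")
    lo, hi = patch.min(), patch.max()
    if hi - lo < 1e-12:
        return np.full(shape, 0.5)
    return (patch - lo) / (hi - lo)


def occlude(img: np.ndarray, spec: OcclusionSpec, seed: int = 0) -> np.ndarray:
    """Replace a ``spec.fraction`` area fraction of *img* with occluder content.

    The occluded region is a single axis-aligned rectangle whose area matches
    ``fraction * H * W`` to within one pixel row. Pixels outside it are
    bit-identical to the input; the result is deterministic under ``seed``.
    """
    img = validate_image(img)
    h, w = img.shape
    rng = np.random.default_rng(seed)

    if spec.anchor in ("bottom", "top"):
        oh, ow = int(round(spec.fraction * h)), w
        r0 = h - oh if spec.anchor == "bottom" else 0
        c0 = 0
    else:
        area = spec.fraction * h * w
        # random-ish aspect around square-root shape, clamped to the image
        aspect = rng.uniform(0.8, 1.25) if spec.anchor == "random" else 1.0
        ow = int(np.clip(round(np.sqrt(area) * aspect), 1, w))
        oh = int(np.clip(round(area / ow), 1, h))
        ow = int(np.clip(round(area / oh), 1, w))
        if isinstance(spec.anchor, tuple):
            c0, r0 = spec.anchor
            if not (0 <= r0 <= h - oh and 0 <= c0 <= w - ow):
                raise ValueError("occluder anchor pushes rectangle off the image")
        else:
            r0 = int(rng.integers(0, h - oh + 1))
            c0 = int(rng.integers(0, w - ow + 1))

    out = img.copy()
    if spec.occluder == "texture":
        fill = _texture_patch((oh, ow), rng)
    else:
        level = float(spec.occluder)
        if not 0.0 <= level <= 1.0:
            raise ValueError("constant occluder level must be in [0, 1]")
        fill = np.full((oh, ow), level)
    out[r0:r0 + oh, c0:c0 + ow] = fill
    return out


@dataclass(frozen=True)
class ScaleSpec:
    """Uniform downscaling of the whole image onto the canonical canvas.

    ratio: linear scaling factor in (0, 1]; the content occupies a
        ``round(440 * ratio)`` square.
    placement: ``(x, y)`` top-left offset of the content on the canvas, or
        None for centred placement.
    background: canvas fill outside the content.
    """

    ratio: float
    placement: tuple[int, int] | None = None
    background: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio <= 1.0:
            raise ValueError(f"scale ratio must be in (0, 1], got {self.ratio}")

    def content_side(self, size: int = CANONICAL_SIZE) -> int:
        return int(round(size * self.ratio))

    def offset(self, size: int = CANONICAL_SIZE) -> tuple[int, int]:
        """Top-left ``(x, y)`` of the content region on the canvas."""
        if self.placement is not None:
            return self.placement
        pad = (size - self.content_side(size)) // 2
        return (pad, pad)


def downscale_on_canvas(img: np.ndarray, spec: ScaleSpec) -> np.ndarray:
    """Downscale *img* by ``spec.ratio`` and place it on a constant canvas.

    The output canvas keeps the input's size; ratio 1 returns the input
    unchanged. Content resampling is bilinear with anti-aliasing.
    """
    img = validate_image(img)
    size = img.shape[0]
    if img.shape[0] != img.shape[1]:
        raise ValueError("downscale_on_canvas expects a square image")
    if spec.ratio == 1.0:
        return img.copy()
    side = spec.content_side(size)
    x0, y0 = spec.offset(size)
    if not (0 <= x0 <= size - side and 0 <= y0 <= size - side):
        raise ValueError("placement pushes downscaled content off the canvas")
    content = resize(img, (side, side), order=1, anti_aliasing=True,
                     preserve_range=True)
    canvas = np.full((size, size), float(spec.background))
    canvas[y0:y0 + side, x0:x0 + side] = np.clip(content, 0.0, 1.0)
    return canvas


def map_location_to_scaled(loc: tuple[int, int], spec: ScaleSpec,
                           size: int = CANONICAL_SIZE) -> tuple[int, int]:
    """Map a full-scale ``(x, y)`` location to its position on the scaled canvas."""
    x0, y0 = spec.offset(size)
    return (int(round(x0 + spec.ratio * loc[0])),
            int(round(y0 + spec.ratio * loc[1])))
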