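"""Histogram-of-oriented-gradients descriptor and 2-D correlation.

The descriptor follows the classic pipeline: gamma (power-law) contrast
normalisation, central-difference gradients with [-1, 0, 1] kernels, unsigned
orientation (folded into [0, 180) degrees), magnitude-weighted votes into
``n_bins`` orientation bins per cell, and overlapping block L2 normalisation.
The resulting global feature vector is compared between images with the
mean-centred normalised cross-correlation ``corr2``; the gallery identity
with the maximal correlation supplies the recognition loop's first
hypothesis.

Votes use hard bin assignment (no bilinear interpolation across bins or
cells); gradients at the border are taken with replicate-edge padding so the
gradient field covers every pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .imaging import validate_image


@dataclass(frozen=True)
class HOGParams:
    """Parameters of the HOG descriptor.

    Defaults follow the Dalal-Triggs conventions: 8x8-pixel cells, 2x2-cell
    blocks with stride 1, 9 unsigned bins over 0-180 degrees, gamma 0.5.
    """

    gamma: float = 0.5
    cell_size: int = 8
    block_size: int = 2
    block_stride: int = 1
    n_bins: int = 9
    signed: bool = False
    eps: float = 1e-5
    weighted: bool = True  # magnitude-weighted votes; False -> unit counts

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if min(self.cell_size, self.block_size, self.block_stride) < 1:
            raise ValueError("cell_size, block_size, block_stride must be >= 1")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    @property
    def angle_range(self) -> float:
        return 360.0 if self.signed else 180.0


@dataclass
class GradientField:
    """Per-pixel gradients: components, magnitude and folded orientation."""

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    orientation: np.ndarray  # degrees, in [0, 180) when unsigned


def gamma_normalize(img: np.ndarray, gamma: float) -> np.ndarray:
    """Raise every pixel to the power ``gamma`` (contrast normalisation)."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    img = validate_image(img)
    if gamma == 1.0:
        return img.copy()
    return np.power(img, gamma)


def compute_gradients(img: np.ndarray, signed: bool = False) -> GradientField:
    """Central-difference gradients with [-1, 0, 1] kernels.

    Interior: gx(x, y) = I(x+1, y) - I(x-1, y) and gy(x, y) = I(x, y+1) -
    I(x, y-1) (no 1/2 factor); borders use replicate-edge padding so the
    field is defined on every pixel. Orientation is atan2(gy, gx) in
    degrees, folded into [0, 180) for the unsigned variant.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    padded = np.pad(img, 1, mode="edge")
    gx = padded[1:-1, 2:] - padded[1:-1, :-2]
    gy = padded[2:, 1:-1] - padded[:-2, 1:-1]
    magnitude = np.hypot(gx, gy)
    theta = np.degrees(np.arctan2(gy, gx))
    if signed:
        orientation = np.mod(theta, 360.0)
    else:
        orientation = np.mod(theta, 180.0)
        orientation[orientation >= 180.0] = 0.0  # fold the 180-degree edge
    return GradientField(gx=gx, gy=gy, magnitude=magnitude, orientation=orientation)


def orientation_bin(theta: float, n_bins: int = 9, angle_range: float = 180.0) -> int:
    """1-based index of the half-open orientation bin containing ``theta``.

    Bins are [k * w, (k+1) * w) with w = angle_range / n_bins; for the
    default 9 unsigned bins an orientation of 50 degrees lands in bin 3.
    """
    if not 0.0 <= theta < angle_range:
        raise ValueError(f"orientation {theta} outside [0, {angle_range})")
    return int(theta // (angle_range / n_bins)) + 1


def cell_histograms(field: GradientField, params: HOGParams) -> np.ndarray:
    """Accumulate per-cell orientation histograms.

    Each pixel votes for the bin of its orientation in its containing cell
    with a weight equal to its gradient magnitude (or 1 if unweighted). Any
    rows/columns beyond the last full cell are ignored. Returns an array of
    shape (cells_y, cells_x, n_bins).
    """
    mag = field.magnitude
    h, w = mag.shape
    cs = params.cell_size
    cells_y, cells_x = h // cs, w // cs
    if cells_y < 1 or cells_x < 1:
        raise ValueError("image smaller than one cell")
    hy, wx = cells_y * cs, cells_x * cs
    mag = mag[:hy, :wx]
    ori = field.orientation[:hy, :wx]

    bin_width = params.angle_range / params.n_bins
    bins = np.minimum((ori // bin_width).astype(np.intp), params.n_bins - 1)
    cell_r = (np.arange(hy) // cs)[:, None]
    cell_c = (np.arange(wx) // cs)[None, :]
    flat = (cell_r * cells_x + cell_c) * params.n_bins + bins
    weights = mag if params.weighted else np.ones_like(mag)
    hist = np.bincount(flat.ravel(), weights=weights.ravel(),
                       minlength=cells_y * cells_x * params.n_bins)
    return hist.reshape(cells_y, cells_x, params.n_bins)


def block_normalize(hist_grid: np.ndarray, params: HOGParams) -> np.ndarray:
    """L2-normalise overlapping blocks of cells and concatenate them.

    Blocks of ``block_size`` x ``block_size`` cells are taken with stride
    ``block_stride``; each block's concatenated histograms are divided by
    sqrt(||v||^2 + eps^2), and all blocks are flattened row-major into the
    final 1-D descriptor.
    """
    cells_y, cells_x, n_bins = hist_grid.shape
    bs, stride = params.block_size, params.block_stride
    if bs > cells_y or bs > cells_x:
        raise ValueError("block larger than the cell grid")
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(hist_grid, (bs, bs, n_bins))[::stride, ::stride, 0]
    blocks_y, blocks_x = win.shape[:2]
    flat = win.reshape(blocks_y, blocks_x, bs * bs * n_bins)
    norms = np.sqrt(np.sum(flat ** 2, axis=-1, keepdims=True) + params.eps ** 2)
    return (flat / norms).ravel()


def descriptor_length(image_side: int, params: HOGParams) -> int:
    """Closed-form descriptor length for a square image."""
    cells = image_side // params.cell_size
    blocks = (cells - params.block_size) // params.block_stride + 1
    return blocks * blocks * params.block_size ** 2 * params.n_bins


def hog_descriptor(img: np.ndarray, params: HOGParams | None = None) -> np.ndarray:
    """Full HOG pipeline: gamma -> gradients -> cell histograms -> block norm."""
    params = params or HOGParams()
    normalized = gamma_normalize(img, params.gamma)
    field = compute_gradients(normalized, signed=params.signed)
    grid = cell_histograms(field, params)
    return block_normalize(grid, params)


def corr2(a: np.ndarray, b: np.ndarray) -> float:
    """Mean-centred normalised cross-correlation of two equal-shape arrays.

    Equals the Pearson correlation of the flattened arrays, in [-1, 1].
    If either array is constant the correlation is undefined; 0.0 is
    returned with a warning (treated downstream as "no evidence").
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    am = a - a.mean()
    bm = b - b.mean()
    denom = np.sqrt(np.sum(am * am) * np.sum(bm * bm))
    if denom == 0.0:
        warnings.warn("corr2 of constant input(s); returning 0", stacklevel=2)
        return 0.0
    return float(np.clip(np.sum(am * bm) / denom, -1.0, 1.0))


def hog_hypothesis(
    probe: np.ndarray,
    gallery_descriptors: dict[str, np.ndarray] | list[tuple[str, np.ndarray]],
    params: HOGParams | None = None,
) -> tuple[str, float]:
    """Pick the gallery identity whose HOG descriptor best correlates with the probe.

    Ties break toward the lexicographically lowest identity. Returns
    ``(identity, correlation)``.
    """
    if isinstance(gallery_descriptors, dict):
        items = sorted(gallery_descriptors.items())
    else:
        items = sorted(gallery_descriptors)
    if not items:
        raise ValueError("gallery is empty")
    probe_desc = hog_descriptor(probe, params)
    best_id, best_corr = None, -np.inf
    for identity, desc in items:
        c = corr2(probe_desc, desc)
        if c > best_corr:
            best_id, best_corr = identity, c
    return best_id, float(best_corr)
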