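"""Uniform local binary pattern descriptor.

A pixel's LBP code thresholds its ``p`` evenly spaced circular neighbours at
radius ``r`` against the centre gray level (neighbour >= centre scores 1)
and packs the bits in fixed angular order. Codes whose circular bit string
has at most two 0/1 transitions are *uniform*; for p = 8 there are 58 of
them. The descriptor partitions the image into a ``block_grid`` x
``block_grid`` grid and concatenates per-block histograms with one bin per
uniform code (ascending code order) plus a final catch-all bin for
non-uniform codes — 59 bins per block for p = 8.

At r = 1 the neighbours are the 8-connected integer pixels (no sub-pixel
interpolation); the angular order starts east and proceeds
counter-clockwise. Pixels within r of the image border are skipped rather
than padded.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .imaging import validate_image


@dataclass(frozen=True)
class LBPParams:
    p: int = 8          # neighbours per circle
    r: int = 1          # radius, pixels
    block_grid: int = 5  # blocks per image side

    def __post_init__(self) -> None:
        if self.p < 4:
            raise ValueError("p must be >= 4")
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if self.block_grid < 1:
            raise ValueError("block_grid must be >= 1")


def _circular_transitions(code: int, p: int) -> int:
    bits = [(code >> k) & 1 for k in range(p)]
    return sum(bits[k] != bits[(k + 1) % p] for k in range(p))


def count_uniform_patterns(p: int) -> int:
    """Number of p-bit circular codes with at most two 0/1 transitions.

    Computed by exhaustive enumeration of all 2**p codes.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    return sum(1 for code in range(2 ** p) if _circular_transitions(code, p) <= 2)


@lru_cache(maxsize=None)
def _uniform_code_table(p: int) -> np.ndarray:
    """Map code -> histogram bin: uniform codes in ascending order, catch-all last."""
    uniform = [c for c in range(2 ** p) if _circular_transitions(c, p) <= 2]
    table = np.full(2 ** p, len(uniform), dtype=np.intp)
    for i, c in enumerate(uniform):
        table[c] = i
    return table


def _neighbor_offsets(p: int, r: int) -> list[tuple[int, int]]:
    """(dx, dy) integer offsets, starting east, counter-clockwise (y axis down)."""
    offsets = []
    for k in range(p):
        ang = 2.0 * np.pi * k / p
        offsets.append((int(round(r * np.cos(ang))), -int(round(r * np.sin(ang)))))
    return offsets


def lbp_code(img: np.ndarray, x: int, y: int,
             params: LBPParams | None = None) -> tuple[int, bool]:
    """LBP code and uniformity flag at centre location ``(x, y) = (col, row)``.

    Neighbour >= centre scores bit 1 (ties count as >=); bit k is the k-th
    neighbour counter-clockwise from east.
    """
    params = params or LBPParams()
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    if not (params.r <= x < w - params.r and params.r <= y < h - params.r):
        raise ValueError(f"centre ({x}, {y}) within {params.r} px of the border")
    center = img[y, x]
    code = 0
    for k, (dx, dy) in enumerate(_neighbor_offsets(params.p, params.r)):
        if img[y + dy, x + dx] >= center:
            code |= 1 << k
    return code, _circular_transitions(code, params.p) <= 2


def _code_image(img: np.ndarray, params: LBPParams) -> np.ndarray:
    """Vectorised LBP codes for all interior pixels (border rows/cols are -1)."""
    h, w = img.shape
    r = params.r
    codes = np.zeros((h, w), dtype=np.int64)
    center = img
    for k, (dx, dy) in enumerate(_neighbor_offsets(params.p, params.r)):
        shifted = np.full_like(img, np.nan)
        src_r = slice(max(0, dy), h + min(0, dy))
        dst_r = slice(max(0, -dy), h + min(0, -dy))
        src_c = slice(max(0, dx), w + min(0, dx))
        dst_c = slice(max(0, -dx), w + min(0, -dx))
        shifted[dst_r, dst_c] = img[src_r, src_c]
        with np.errstate(invalid="ignore"):
            codes |= (shifted >= center).astype(np.int64) << k
    codes[:r, :] = -1
    codes[-r:, :] = -1
    codes[:, :r] = -1
    codes[:, -r:] = -1
    return codes


def lbp_descriptor(img: np.ndarray, params: LBPParams | None = None) -> np.ndarray:
    """Concatenated per-block uniform-LBP histograms, blocks row-major.

    Each block contributes ``count_uniform_patterns(p) + 1`` bins; a block's
    histogram mass equals the number of its pixels lying at least ``r``
    pixels inside the image border.
    """
    params = params or LBPParams()
    img = validate_image(img)
    h, w = img.shape
    g = params.block_grid
    if min(h, w) < g * (2 * params.r + 1):
        raise ValueError("image too small for the requested block grid")
    table = _uniform_code_table(params.p)
    n_bins = int(table.max()) + 1  # uniform count + catch-all
    codes = _code_image(img, params)
    row_edges = [i * h // g for i in range(g + 1)]
    col_edges = [j * w // g for j in range(g + 1)]
    hists = []
    for i in range(g):
        for j in range(g):
            block = codes[row_edges[i]:row_edges[i + 1],
                          col_edges[j]:col_edges[j + 1]].ravel()
            block = block[block >= 0]
            hists.append(np.bincount(table[block], minlength=n_bins))
    return np.concatenate(hists).astype(np.float64)
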