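"""One-shot Hebbian associative memory of foveal features.

Training an identity stores nine *feature-label cells*: each binds a square
foveal template cropped at a salient location to the grid-cell population
activity at that location (a single outer-product Hebbian association, so
the stored grid weights equal the encoding activity exactly), and links to
the identity's accumulator cell. Salient locations are drawn one per block
of an even 3x3 partition of the image, inset so the fovea fits; a manual
list of landmark coordinates may be supplied instead.

At test time a foveal patch is compared against stored templates with the
mean-centred correlation ``corr2``; a softmax over similarities followed by
a threshold yields a sparse activation map, and summing activations per
identity gives the competing identity drives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .gridcells import GridPopulation, encode_location
from .imaging import validate_image

DEFAULT_FOVEA = 101       # pixels per fovea side; 61 supported for the sweep
N_FEATURES = 9            # feature-label cells stored per identity
DEFAULT_SOFTMAX_TEMP = 0.05
DEFAULT_LABEL_THRESHOLD = 0.2


@dataclass
class FeatureLabelCell:
    """A stored foveal template bound to the grid code at its location."""

    cell_id: int
    identity_id: str
    location: tuple[int, int]          # (x, y) of the template centre
    template: np.ndarray               # f x f luminance patch
    grid_weights: np.ndarray           # Hebbian weights = encoding activity


@dataclass
class IdentityCell:
    """Per-identity evidence accumulator."""

    identity_id: str
    feature_cell_ids: list[int] = field(default_factory=list)
    accumulator: float = 0.0
    threshold: float = 0.9


class MemoryStore:
    """All feature-label and identity cells of a trained model."""

    def __init__(self, fovea_size: int = DEFAULT_FOVEA,
                 softmax_temp: float = DEFAULT_SOFTMAX_TEMP,
                 label_threshold: float = DEFAULT_LABEL_THRESHOLD):
        if fovea_size % 2 == 0:
            raise ValueError("fovea size must be odd")
        self.fovea_size = fovea_size
        self.softmax_temp = softmax_temp
        self.label_threshold = label_threshold
        self.feature_cells: list[FeatureLabelCell] = []
        self.identity_cells: dict[str, IdentityCell] = {}
        self._template_matrix: np.ndarray | None = None  # centred templates
        self._template_norms: np.ndarray | None = None

    @property
    def identities(self) -> list[str]:
        return sorted(self.identity_cells)

    def features_of(self, identity_id: str) -> list[FeatureLabelCell]:
        ids = self.identity_cells[identity_id].feature_cell_ids
        return [self.feature_cells[i] for i in ids]

    def _invalidate(self) -> None:
        self._template_matrix = None
        self._template_norms = None

    def _ensure_matrix(self) -> None:
        if self._template_matrix is None:
            flat = np.stack([c.template.ravel() for c in self.feature_cells])
            flat = flat - flat.mean(axis=1, keepdims=True)
            self._template_matrix = flat
            self._template_norms = np.linalg.norm(flat, axis=1)

    # -- persistence ---------------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "fovea_size": self.fovea_size,
            "softmax_temp": self.softmax_temp,
            "label_threshold": self.label_threshold,
            "identities": {
                ident: {"feature_cell_ids": cell.feature_cell_ids,
                        "threshold": cell.threshold}
                for ident, cell in self.identity_cells.items()
            },
            "cells": [
                {"cell_id": c.cell_id, "identity_id": c.identity_id,
                 "location": list(c.location)}
                for c in self.feature_cells
            ],
        }
        (out / "store.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        np.savez(out / "store_arrays.npz",
                 templates=np.stack([c.template for c in self.feature_cells]),
                 grid_weights=np.stack([c.grid_weights for c in self.feature_cells]))

    @classmethod
    def load(cls, in_dir: str | Path) -> "MemoryStore":
        in_dir = Path(in_dir)
        manifest = json.loads((in_dir / "store.json").read_text())
        arrays = np.load(in_dir / "store_arrays.npz")
        store = cls(fovea_size=manifest["fovea_size"],
                    softmax_temp=manifest["softmax_temp"],
                    label_threshold=manifest["label_threshold"])
        for spec in manifest["cells"]:
            i = spec["cell_id"]
            store.feature_cells.append(FeatureLabelCell(
                cell_id=i, identity_id=spec["identity_id"],
                location=tuple(spec["location"]),
                template=arrays["templates"][i],
                grid_weights=arrays["grid_weights"][i]))
        for ident, info in manifest["identities"].items():
            store.identity_cells[ident] = IdentityCell(
                identity_id=ident, feature_cell_ids=list(info["feature_cell_ids"]),
                threshold=info["threshold"])
        return store


_SALIENCY_SMOOTH_SIGMA = 6.0


class SalientSampler:
    """Bottom-up salient-location selection over the 3x3 block partition.

    Saliency is smoothed gradient energy; within each margin-inset block the
    selected location is the saliency peak (argmax), so repeated looks at
    the same image land on the same high-contrast structure — the property
    that lets the bottom-up variant re-find its stored features. Build once
    per image; ``sample_all`` returns one location per block in raster
    order, and ``sample_block`` serves a randomly chosen block at test
    time.
    """

    def __init__(self, img: np.ndarray, fovea_size: int = DEFAULT_FOVEA):
        img = validate_image(img)
        self.shape = img.shape
        h, w = img.shape
        margin = fovea_size // 2
        gy, gx = np.gradient(img)
        sal = ndimage.gaussian_filter(np.hypot(gx, gy), _SALIENCY_SMOOTH_SIGMA)
        self._peaks: list[tuple[int, int]] = []
        for bi in range(3):
            for bj in range(3):
                r0, r1 = bi * h // 3, (bi + 1) * h // 3
                c0, c1 = bj * w // 3, (bj + 1) * w // 3
                r_lo, r_hi = max(r0, margin), min(r1, h - margin)
                c_lo, c_hi = max(c0, margin), min(c1, w - margin)
                if r_lo >= r_hi or c_lo >= c_hi:
                    raise ValueError(
                        "fovea does not fit inside a 3x3 block with margins")
                s = sal[r_lo:r_hi, c_lo:c_hi]
                idx = int(np.argmax(s))
                self._peaks.append((c_lo + idx % s.shape[1],
                                    r_lo + idx // s.shape[1]))

    def sample_block(self, block: int,
                     rng: np.random.Generator | None = None) -> tuple[int, int]:
        return self._peaks[block]

    def sample_all(self, rng: np.random.Generator | None = None,
                   ) -> list[tuple[int, int]]:
        return list(self._peaks)


def select_salient_features(img: np.ndarray, n: int = N_FEATURES, seed: int = 0,
                            fovea_size: int = DEFAULT_FOVEA,
                            manual: list[tuple[int, int]] | None = None,
                            ) -> list[tuple[int, int]]:
    """Select one salient location per block of an even 3x3 image partition.

    Each location is the smoothed-gradient-energy peak of its block, inset
    by the fovea half-width so the centred crop always fits inside the
    image; block raster order (left-to-right, top-to-bottom); deterministic
    (the ``seed`` is accepted for interface stability). ``manual`` overrides
    selection with a fixed landmark list.
    """
    img = validate_image(img)
    if manual is not None:
        if len(manual) != n:
            raise ValueError(f"manual override must supply {n} locations")
        return [tuple(map(int, loc)) for loc in manual]
    if n != 9:
        raise ValueError("salient sampling uses the 3x3 block partition (n = 9)")
    sampler = SalientSampler(img, fovea_size)
    return sampler.sample_all(np.random.default_rng(seed))


def extract_fovea(img: np.ndarray, loc: tuple[int, int], f: int,
                  ) -> tuple[np.ndarray, tuple[int, int]]:
    """Centred f x f crop at ``loc = (x, y)``; near-border centres are clamped.

    Returns ``(patch, actual_centre)`` where the centre is the (possibly
    clamped) location the crop is taken around. ``f`` must be odd.
    """
    img = np.asarray(img)
    if f % 2 == 0:
        raise ValueError("fovea side must be odd")
    h, w = img.shape
    if f > min(h, w):
        raise ValueError("fovea larger than the image")
    half = f // 2
    x = int(np.clip(round(loc[0]), half, w - 1 - half))
    y = int(np.clip(round(loc[1]), half, h - 1 - half))
    return img[y - half:y + half + 1, x - half:x + half + 1], (x, y)


def learn_stimulus(img: np.ndarray, identity_id: str, pop: GridPopulation,
                   store: MemoryStore, seed: int = 0,
                   manual_locations: list[tuple[int, int]] | None = None,
                   ) -> MemoryStore:
    """One-shot training of a single identity from a single image.

    Creates nine feature-label cells (template = foveal crop, grid weights =
    population activity at the crop centre) and one identity cell. Training
    the same identity twice is an error.
    """
    img = validate_image(img)
    if identity_id in store.identity_cells:
        raise ValueError(f"identity {identity_id!r} already trained")
    locations = select_salient_features(img, N_FEATURES, seed=seed,
                                        fovea_size=store.fovea_size,
                                        manual=manual_locations)
    identity = IdentityCell(identity_id=identity_id)
    for loc in locations:
        patch, center = extract_fovea(img, loc, store.fovea_size)
        cell = FeatureLabelCell(
            cell_id=len(store.feature_cells),
            identity_id=identity_id,
            location=center,
            template=patch.copy(),
            grid_weights=encode_location(pop, center),
        )
        store.feature_cells.append(cell)
        identity.feature_cell_ids.append(cell.cell_id)
    store.identity_cells[identity_id] = identity
    store._invalidate()
    return store


def raw_similarities(patch: np.ndarray, store: MemoryStore,
                     restrict_to: str | None = None) -> dict[int, float]:
    """corr2 of the patch against every (or one identity's) stored template."""
    if patch.shape != (store.fovea_size, store.fovea_size):
        raise ValueError(
            f"patch shape {patch.shape} does not match fovea {store.fovea_size}")
    store._ensure_matrix()
    v = patch.astype(np.float64).ravel()
    v = v - v.mean()
    vnorm = np.linalg.norm(v)
    cells = (store.feature_cells if restrict_to is None
             else store.features_of(restrict_to))
    sims: dict[int, float] = {}
    for c in cells:
        denom = vnorm * store._template_norms[c.cell_id]
        if denom == 0.0:
            sims[c.cell_id] = 0.0
        else:
            num = float(store._template_matrix[c.cell_id] @ v)
            sims[c.cell_id] = float(np.clip(num / denom, -1.0, 1.0))
    return sims


def match_fovea(patch: np.ndarray, store: MemoryStore,
                restrict_to: str | None = None) -> dict[int, float]:
    """Sparse feature-label activations for a foveal patch.

    Softmax over ``corr2 / softmax_temp`` across the considered cells, with
    activations below ``label_threshold`` zeroed (dropped). The surviving
    activations lie in [0, 1] and sum to at most 1; the map may be empty.
    """
    sims = raw_similarities(patch, store, restrict_to)
    if not sims:
        return {}
    ids = list(sims)
    logits = np.array([sims[i] for i in ids]) / store.softmax_temp
    logits -= logits.max()
    weights = np.exp(logits)
    probs = weights / weights.sum()
    return {i: float(p) for i, p in zip(ids, probs) if p >= store.label_threshold}


def drive_identities(activations: dict[int, float], store: MemoryStore,
                     ) -> dict[str, float]:
    """Per-identity drive: the sum of its feature cells' activations."""
    drives = {ident: 0.0 for ident in store.identity_cells}
    for cell_id, act in activations.items():
        drives[store.feature_cells[cell_id].identity_id] += act
    return drives
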