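"""Grid-cell population code over the image plane.

Each grid cell carries a precomputed periodic rate map over the canonical
440x440 visual field — the idealised triangular firing pattern formed by
rectifying a sum of three plane-wave cosines at 60-degree separations, peak-
normalised to 1. Cells are organised in modules sharing a grating period and
orientation but differing in spatial phase; several modules with distinct
periods make the population code for a location unique across the map.

Encoding a fixation location is a per-cell rate-map lookup. Decoding the
saccade (displacement) vector between two encoded locations is done
functionally — the role the distance/displace cells play in the biological
circuit — by scoring every map position against each activity vector and
subtracting the two maximum-likelihood positions. A uniform ``gain``
multiplier on decoded displacements supports recognition of uniformly
downscaled stimuli.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .imaging import CANONICAL_SIZE

DEFAULT_N_MODULES = 5
DEFAULT_BASE_PERIOD = 28.0
DEFAULT_PERIOD_RATIO = 1.42
DEFAULT_CELLS_PER_MODULE = 25


@dataclass(frozen=True)
class GridModuleSpec:
    """One grid module: shared period/orientation, per-cell phase offsets."""

    period: float                 # grating spacing, pixels
    orientation: float = 0.0      # degrees
    phase_offsets: tuple[tuple[float, float], ...] = ()  # (x, y) pixels per cell

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be > 0")


@dataclass(frozen=True)
class SaccadeVector:
    """A decoded eye-movement vector ``(dx, dy)`` with a uniform gain."""

    dx: float
    dy: float
    gain: float = 1.0

    def applied(self) -> tuple[int, int]:
        """Integer pixel displacement actually applied to the fixation."""
        return (int(round(self.gain * self.dx)), int(round(self.gain * self.dy)))


def default_module_specs(
    n_modules: int = DEFAULT_N_MODULES,
    base_period: float = DEFAULT_BASE_PERIOD,
    period_ratio: float = DEFAULT_PERIOD_RATIO,
    cells_per_module: int = DEFAULT_CELLS_PER_MODULE,
    seed: int = 0,
) -> list[GridModuleSpec]:
    """Geometric-progression module periods with seeded uniform phase sets."""
    rng = np.random.default_rng(seed)
    specs = []
    for m in range(n_modules):
        period = base_period * period_ratio ** m
        phases = rng.uniform(0.0, period, size=(cells_per_module, 2))
        specs.append(GridModuleSpec(period=period, orientation=0.0,
                                    phase_offsets=tuple(map(tuple, phases))))
    return specs


def _rate_map(period: float, orientation: float, phase: tuple[float, float],
              size: int) -> np.ndarray:
    """Rectified three-cosine grid pattern, peak-normalised to 1."""
    theta0 = np.deg2rad(orientation)
    xs = np.arange(size, dtype=np.float64)
    X, Y = np.meshgrid(xs, xs)  # X = col, Y = row
    dx = X - phase[0]
    dy = Y - phase[1]
    k_mag = 4.0 * np.pi / (np.sqrt(3.0) * period)
    s = np.zeros((size, size))
    for i in range(3):
        ang = theta0 + i * np.pi / 3.0
        s += np.cos(k_mag * (np.cos(ang) * dx + np.sin(ang) * dy))
    return np.maximum(s, 0.0) / 3.0


class GridPopulation:
    """Bank of grid-cell rate-map lookup tables over a square map.

    ``rate_maps`` has shape (n_cells, size, size) with values in [0, 1].
    A flattened float32 copy is kept for fast maximum-likelihood position
    decoding; decoded positions of frequently queried activity vectors
    (e.g. stored feature weights) are memoised.
    """

    def __init__(self, specs: list[GridModuleSpec], rate_maps: np.ndarray,
                 seed: int = 0):
        self.specs = list(specs)
        self.rate_maps = rate_maps
        self.seed = seed
        self.size = rate_maps.shape[1]
        self.n_cells = rate_maps.shape[0]
        self._flat = rate_maps.reshape(self.n_cells, -1).T.astype(np.float32)
        self._flat = np.ascontiguousarray(self._flat)          # (pixels, cells)
        self._sqnorm = np.einsum("pc,pc->p", self._flat, self._flat)
        self._decode_cache: dict[bytes, tuple[int, int]] = {}

    # -- persistence ---------------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "seed": self.seed,
            "size": self.size,
            "modules": [
                {"period": s.period, "orientation": s.orientation,
                 "phase_offsets": [list(p) for p in s.phase_offsets]}
                for s in self.specs
            ],
        }
        (out / "population.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    @classmethod
    def load(cls, in_dir: str | Path) -> "GridPopulation":
        manifest = json.loads((Path(in_dir) / "population.json").read_text())
        specs = [
            GridModuleSpec(period=m["period"], orientation=m["orientation"],
                           phase_offsets=tuple(tuple(p) for p in m["phase_offsets"]))
            for m in manifest["modules"]
        ]
        return build_population(specs, map_size=manifest["size"], seed=manifest["seed"])


def build_population(specs: list[GridModuleSpec] | None = None,
                     map_size: int = CANONICAL_SIZE,
                     seed: int = 0) -> GridPopulation:
    """Precompute all rate maps for the given module specs.

    With ``specs=None`` the default 5-module, 125-cell geometry is built
    from ``seed``. Duplicate (period, orientation, phase) cells are
    rejected.
    """
    if specs is None:
        specs = default_module_specs(seed=seed)
    if len({s.period for s in specs}) < 2:
        raise ValueError("need at least 2 modules with distinct periods")
    seen = set()
    for s in specs:
        for phase in s.phase_offsets:
            key = (round(s.period, 9), round(s.orientation, 9),
                   round(phase[0], 9), round(phase[1], 9))
            if key in seen:
                raise ValueError(f"duplicate grid cell {key}")
            seen.add(key)
    maps = [
        _rate_map(s.period, s.orientation, phase, map_size)
        for s in specs
        for phase in s.phase_offsets
    ]
    return GridPopulation(specs, np.stack(maps).astype(np.float32), seed=seed)


def encode_location(pop: GridPopulation, loc: tuple[int, int]) -> np.ndarray:
    """Population activity vector at ``loc = (x, y)`` (rate-map lookup)."""
    x, y = int(round(loc[0])), int(round(loc[1]))
    if not (0 <= x < pop.size and 0 <= y < pop.size):
        raise ValueError(f"location {loc} outside the {pop.size}x{pop.size} map")
    return pop.rate_maps[:, y, x].astype(np.float64)


def _decode_position(pop: GridPopulation, activity: np.ndarray) -> tuple[int, int]:
    """Maximum-likelihood map position for an activity vector.

    Minimises the summed per-cell squared error between the activity and
    every map position's rates; ties break toward the smallest flat index
    (row-major), deterministically.
    """
    a = np.asarray(activity, dtype=np.float32)
    if a.shape != (pop.n_cells,):
        raise ValueError("activity length does not match population size")
    if not np.any(a):
        raise ValueError("all-zero activity: location not encodable")
    key = a.tobytes()
    cached = pop._decode_cache.get(key)
    if cached is not None:
        return cached
    score = 2.0 * (pop._flat @ a) - pop._sqnorm  # = const - squared error
    idx = int(np.argmax(score))
    pos = (idx % pop.size, idx // pop.size)
    if len(pop._decode_cache) < 4096:
        pop._decode_cache[key] = pos
    return pos


def decode_displacement(pop: GridPopulation, from_activity: np.ndarray,
                        to_activity: np.ndarray) -> SaccadeVector:
    """Displacement vector between two grid-encoded locations.

    Functionally models the distance/displace-cell readout: both activity
    vectors are position-decoded by exhaustive map scoring and the decoded
    positions are subtracted, so decode(B, A) = -decode(A, B) exactly.
    """
    fx, fy = _decode_position(pop, from_activity)
    tx, ty = _decode_position(pop, to_activity)
    return SaccadeVector(dx=float(tx - fx), dy=float(ty - fy), gain=1.0)


def apply_gain(v: SaccadeVector, gain: float) -> SaccadeVector:
    """Attach a uniform displacement gain (> 0) to a saccade vector."""
    if gain <= 0:
        raise ValueError("gain must be > 0")
    return SaccadeVector(dx=v.dx, dy=v.dy, gain=gain)
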