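"""Batch experiment harness: variant sweeps and robustness curves.

Reproduces the comparison structure of the model study at desk scale on
synthetic stimuli: the three loop variants (G, HG, HG-lesion) crossed with
fovea sizes and seeds, and accuracy curves under occlusion fractions and
downscaling ratios (the latter run with the loop gain set to the known
scale ratio). Per-probe rows and per-condition aggregates are returned as
pandas DataFrames and can be written to CSV/JSON.

Metric definitions: *accuracy* is the fraction of probes whose final
accepted identity is correct; *fixations* counts every fixation including
reset re-fixations; *first accuracy* is the fraction of probes whose first
hypothesis was correct, reported both over all probes and over the probes
that finished without any reset (the two readings of the headline metric).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .gridcells import GridPopulation, build_population
from .hog import HOGParams, hog_descriptor
from .imaging import OcclusionSpec, ScaleSpec, downscale_on_canvas, occlude
from .loop import LoopParams, recognize
from .memory import MemoryStore, learn_stimulus
from .synth import Dataset, make_dataset

ROW_COLUMNS = [
    "condition", "variant", "fovea", "seed", "identity", "predicted",
    "succeeded", "correct", "fixations", "saccades", "resets",
    "first_hypothesis", "first_hypothesis_correct",
]


@lru_cache(maxsize=2)
def _cached_population(seed: int) -> GridPopulation:
    return build_population(seed=seed)


def train_model(gallery: dict[str, np.ndarray], pop: GridPopulation,
                fovea_size: int = 101, seed: int = 0,
                hog_params: HOGParams | None = None,
                ) -> tuple[MemoryStore, dict[str, np.ndarray]]:
    """One-shot-train a store on a gallery and compute its HOG descriptors."""
    rng = np.random.default_rng(seed)
    store = MemoryStore(fovea_size=fovea_size)
    descriptors = {}
    for ident in sorted(gallery):
        learn_stimulus(gallery[ident], ident, pop, store,
                       seed=int(rng.integers(2 ** 31)))
        descriptors[ident] = hog_descriptor(gallery[ident], hog_params)
    return store, descriptors


@dataclass
class ExperimentResult:
    """Per-probe rows plus per-condition aggregates."""

    rows: pd.DataFrame
    aggregates: pd.DataFrame

    def save(self, report_csv, summary_json=None) -> None:
        self.rows.to_csv(report_csv, index=False)
        if summary_json is not None:
            self.aggregates.to_json(summary_json, orient="records", indent=2)


def _aggregate(rows: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    groups = []
    for key, g in rows.groupby(by, sort=True):
        no_reset = g[g["resets"] == 0]
        entry = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        per_seed_acc = g.groupby("seed")["correct"].mean() * 100.0
        entry.update({
            "n_probes": len(g),
            "accuracy_pct": g["correct"].mean() * 100.0,
            "accuracy_std_pct": float(per_seed_acc.std(ddof=0)),
            "mean_fixations": g["fixations"].mean(),
            "mean_saccades": g["saccades"].mean(),
            "mean_resets": g["resets"].mean(),
            "first_accuracy_all_pct": g["first_hypothesis_correct"].mean() * 100.0,
            "first_accuracy_no_reset_pct": (
                no_reset["first_hypothesis_correct"].mean() * 100.0
                if len(no_reset) else float("nan")),
        })
        groups.append(entry)
    return pd.DataFrame(groups)


def _run_probe_set(probes: Iterable, store: MemoryStore, pop: GridPopulation,
                   descriptors: dict[str, np.ndarray], params: LoopParams,
                   rng: np.random.Generator, meta: dict) -> list[dict]:
    rows = []
    for probe in probes:
        trace = recognize(probe.image, store, pop, descriptors, params,
                          seed=int(rng.integers(2 ** 31)),
                          true_identity=probe.identity)
        rows.append({
            **meta,
            "identity": probe.identity,
            "predicted": trace.final_identity,
            "succeeded": trace.succeeded,
            "correct": trace.final_identity == probe.identity,
            "fixations": trace.n_fixations,
            "saccades": trace.saccades,
            "resets": trace.resets,
            "first_hypothesis": trace.first_hypothesis,
            "first_hypothesis_correct": bool(trace.first_hypothesis_correct),
        })
    return rows


def run_variant_sweep(
    variants: Sequence[str] = ("G", "HG", "HG-lesion"),
    fovea_sizes: Sequence[int] = (101,),
    seeds: Sequence[int] = (0,),
    dataset_factory: Callable[[int], Dataset] | None = None,
    n_identities: int = 10,
    n_variants: int = 5,
    difficulty: str = "medium",
) -> ExperimentResult:
    """Full cross of loop variants x fovea sizes x seeds.

    Each seed regenerates the dataset (via ``dataset_factory`` or the
    default synthetic generator), retrains the models, and runs every probe
    through every (variant, fovea) cell. Aggregates are grouped by
    (variant, fovea).
    """
    if dataset_factory is None:
        dataset_factory = lambda s: make_dataset(  # noqa: E731
            n_identities=n_identities, n_variants=n_variants,
            difficulty=difficulty, seed=s)
    all_rows: list[dict] = []
    for seed in seeds:
        ds = dataset_factory(seed)
        if not ds.probes:
            raise ValueError("dataset has no probes")
        pop = _cached_population(ds.seed % 1000)
        for fovea in fovea_sizes:
            store, descriptors = train_model(ds.gallery, pop,
                                             fovea_size=fovea, seed=seed)
            for variant in variants:
                params = LoopParams(variant=variant)
                rng = np.random.default_rng(seed + 7919)
                meta = {"condition": "clean", "variant": variant,
                        "fovea": fovea, "seed": seed}
                all_rows.extend(_run_probe_set(ds.probes, store, pop,
                                               descriptors, params, rng, meta))
    rows = pd.DataFrame(all_rows, columns=ROW_COLUMNS)
    return ExperimentResult(rows=rows,
                            aggregates=_aggregate(rows, ["variant", "fovea"]))


def compare_with_external(result: ExperimentResult, predictions: pd.DataFrame,
                          model_name: str = "external") -> pd.DataFrame:
    """Side-by-side accuracy table against externally supplied predictions.

    ``predictions`` needs ``identity`` and ``predicted`` columns, one row
    per probe (e.g. the per-probe output of a baseline classifier run
    elsewhere). Returns a two-row accuracy summary; no baseline is
    re-implemented here.
    """
    if not {"identity", "predicted"} <= set(predictions.columns):
        raise ValueError("predictions need 'identity' and 'predicted' columns")
    ext_acc = (predictions["identity"] == predictions["predicted"]).mean() * 100
    return pd.DataFrame([
        {"model": "gridsaccade", "n_probes": len(result.rows),
         "accuracy_pct": result.rows["correct"].mean() * 100.0},
        {"model": model_name, "n_probes": len(predictions),
         "accuracy_pct": ext_acc},
    ])


@dataclass
class _TransformedProbe:
    identity: str
    image: np.ndarray


def run_robustness_curves(
    occlusion_fractions: Sequence[float] = (1 / 4, 1 / 3, 1 / 2),
    scale_ratios: Sequence[float] = (1 / 2, 1 / 4, 1 / 5),
    seeds: Sequence[int] = (0,),
    variant: str = "HG",
    fovea_size: int = 101,
    include_control: bool = True,
    dataset_factory: Callable[[int], Dataset] | None = None,
    n_identities: int = 10,
    n_variants: int = 5,
    difficulty: str = "medium",
) -> ExperimentResult:
    """Accuracy under occlusion fractions and known-gain downscaling.

    Occluded probes get a seeded texture occluder at a random position;
    downscaled probes are placed centred on a mid-gray canvas and the loop
    gain is set to the scale ratio. ``include_control`` adds the untouched
    (ratio 1, no occlusion) condition.
    """
    if dataset_factory is None:
        dataset_factory = lambda s: make_dataset(  # noqa: E731
            n_identities=n_identities, n_variants=n_variants,
            difficulty=difficulty, seed=s)
    all_rows: list[dict] = []
    for seed in seeds:
        ds = dataset_factory(seed)
        pop = _cached_population(ds.seed % 1000)
        store, descriptors = train_model(ds.gallery, pop,
                                         fovea_size=fovea_size, seed=seed)
        conditions: list[tuple[str, float]] = []
        if include_control:
            conditions.append(("control", 1.0))
        conditions += [("occlusion", f) for f in occlusion_fractions]
        conditions += [("scale", r) for r in scale_ratios]
        for kind, level in conditions:
            t_rng = np.random.default_rng(seed * 31 + int(level * 1000))
            gain = 1.0
            if kind == "occlusion":
                spec = OcclusionSpec(fraction=level)
                probes = [_TransformedProbe(
                    p.identity, occlude(p.image, spec,
                                        seed=int(t_rng.integers(2 ** 31))))
                    for p in ds.probes]
            elif kind == "scale" and level != 1.0:
                spec = ScaleSpec(ratio=level)
                probes = [_TransformedProbe(
                    p.identity, downscale_on_canvas(p.image, spec))
                    for p in ds.probes]
                gain = level
            else:
                probes = [_TransformedProbe(p.identity, p.image)
                          for p in ds.probes]
            params = LoopParams(variant=variant, gain=gain)
            rng = np.random.default_rng(seed + 7919)
            meta = {"condition": f"{kind}:{level:.4g}", "variant": variant,
                    "fovea": fovea_size, "seed": seed}
            all_rows.extend(_run_probe_set(probes, store, pop, descriptors,
                                           params, rng, meta))
    rows = pd.DataFrame(all_rows, columns=ROW_COLUMNS)
    return ExperimentResult(rows=rows,
                            aggregates=_aggregate(rows, ["condition"]))
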