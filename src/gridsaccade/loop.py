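"""The saccadic recognition loop.

One recognition episode alternates perception and action: form a first
identity hypothesis, saccade to the hypothesized identity's stored feature
locations using the grid-cell displacement code, correlate each foveal patch
with the expected template, and accumulate rectified match evidence in the
identity cell until it reaches the decision threshold (0.9). If a
hypothesis exhausts its features below threshold it is *reset*: the
identity with the largest cumulative feature-label drive over all fixations
so far (excluding already-rejected identities) becomes the new hypothesis
and its evidence starts from zero. An episode fails ("unrecognized") when
the reset budget is exhausted.

Three variants are supported:

- ``HG``  — first hypothesis from HOG descriptor correlation; grid-guided
  saccades (the improved model).
- ``G``   — first hypothesis from a single salient foveal match (the
  original bottom-up model); grid-guided saccades.
- ``HG-lesion`` — HOG first hypothesis, but the grid code is disconnected
  from the feature-label cells: saccade targets cannot be computed, so each
  step re-fixates a randomly sampled salient location.

Uniformly downscaled probes are handled with a known ``gain``: decoded
displacements are multiplied by the gain, foveal patches are extracted at
the scaled size and resampled to the template size, and the HOG hypothesis
is computed on the probe rescaled to canonical size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .gridcells import (GridPopulation, SaccadeVector, apply_gain,
                        decode_displacement, encode_location)
from .hog import HOGParams, hog_hypothesis
from .memory import (MemoryStore, SalientSampler, drive_identities,
                     extract_fovea, raw_similarities)

VARIANTS = ("G", "HG", "HG-lesion")


@dataclass(frozen=True)
class LoopParams:
    """Knobs of one recognition episode."""

    variant: str = "HG"
    decision_threshold: float = 0.9
    max_saccades_per_hypothesis: int = 9
    max_resets: int = 3
    gain: float = 1.0                      # displacement multiplier (scale ratio)
    increment_rule: str = "rectified-corr"  # or "binary"
    binary_cutoff: float = 0.5
    #: matches below this leave the feature-label cell silent; the feature is
    #: treated as unobserved (e.g. occluded) and the decision threshold is
    #: prorated to the features that responded
    silent_floor: float = 0.45
    #: a decision is never taken on fewer responding features than this
    min_observed: int = 3
    hog_params: HOGParams = field(default_factory=HOGParams)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not 0.0 < self.decision_threshold <= 1.0:
            raise ValueError("decision_threshold must be in (0, 1]")
        if self.max_resets < 0:
            raise ValueError("max_resets must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")


@dataclass
class FixationRecord:
    """One fixation: where the eye landed and what the match produced."""

    index: int
    location: tuple[int, int]
    matched_feature: int | None
    match_quality: float
    hypothesis: str
    accumulator_after: float
    was_reset: bool = False


@dataclass
class RecognitionTrace:
    """Full record of one recognition episode."""

    fixations: list[FixationRecord]
    resets: int
    saccades: int
    first_hypothesis: str
    first_hypothesis_correct: bool | None
    final_identity: str
    succeeded: bool

    @property
    def n_fixations(self) -> int:
        return len(self.fixations)

    def to_json(self) -> str:
        payload = {
            "first_hypothesis": self.first_hypothesis,
            "first_hypothesis_correct": self.first_hypothesis_correct,
            "final_identity": self.final_identity,
            "succeeded": self.succeeded,
            "resets": self.resets,
            "saccades": self.saccades,
            "fixations": [
                {"index": f.index, "location": list(f.location),
                 "matched_feature": f.matched_feature,
                 "match_quality": round(f.match_quality, 6),
                 "hypothesis": f.hypothesis,
                 "accumulator_after": round(f.accumulator_after, 6),
                 "was_reset": f.was_reset}
                for f in self.fixations
            ],
        }
        return json.dumps(payload, sort_keys=True)


# -- scale/gain geometry -----------------------------------------------------

def _scale_offset(size: int, gain: float) -> int:
    """Top-left offset of centred downscaled content on the canvas."""
    return (size - int(round(size * gain))) // 2


def _probe_to_model(loc: tuple[int, int], size: int, gain: float) -> tuple[int, int]:
    if gain == 1.0:
        return loc
    o = _scale_offset(size, gain)
    x = int(np.clip(round((loc[0] - o) / gain), 0, size - 1))
    y = int(np.clip(round((loc[1] - o) / gain), 0, size - 1))
    return (x, y)


def _model_to_probe(loc: tuple[int, int], size: int, gain: float) -> tuple[int, int]:
    if gain == 1.0:
        return loc
    o = _scale_offset(size, gain)
    x = int(np.clip(round(o + gain * loc[0]), 0, size - 1))
    y = int(np.clip(round(o + gain * loc[1]), 0, size - 1))
    return (x, y)


def _rescale_to_canonical(probe: np.ndarray, gain: float) -> np.ndarray:
    """Undo a known centred downscaling so HOG sees canonical content."""
    size = probe.shape[0]
    side = int(round(size * gain))
    o = _scale_offset(size, gain)
    content = probe[o:o + side, o:o + side]
    out = resize(content, (size, size), order=1, anti_aliasing=False,
                 preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def _extract_patch(probe: np.ndarray, loc: tuple[int, int], store: MemoryStore,
                   gain: float) -> tuple[np.ndarray, tuple[int, int]]:
    """Fovea crop at probe coordinates, resampled to template size if gain != 1."""
    f = store.fovea_size
    if gain == 1.0:
        return extract_fovea(probe, loc, f)
    fp = int(round(f * gain))
    fp = max(3, fp + (1 - fp % 2))  # odd-ify
    patch, center = extract_fovea(probe, loc, fp)
    patch = resize(patch, (f, f), order=1, anti_aliasing=gain < 1.0,
                   preserve_range=True)
    return np.clip(patch, 0.0, 1.0), center


# -- evidence ----------------------------------------------------------------

def accumulate_evidence(accumulator: float, match_quality: float,
                        params: LoopParams, n_features: int = 9) -> float:
    """Add one fixation's evidence; the accumulator never decreases.

    Default rule: ``max(0, match_quality) / n_features`` so nine perfect
    matches reach exactly 1.0; the "binary" rule adds ``1/n_features`` when
    the match clears ``binary_cutoff``.
    """
    if params.increment_rule == "rectified-corr":
        inc = max(0.0, match_quality) / n_features
    elif params.increment_rule == "binary":
        inc = (1.0 / n_features) if match_quality >= params.binary_cutoff else 0.0
    else:
        raise ValueError(f"unknown increment rule {params.increment_rule!r}")
    return accumulator + inc


def _activations_from_sims(sims: dict[int, float], store: MemoryStore,
                           ) -> dict[int, float]:
    """Softmax + threshold sparsification of raw similarities (see match_fovea)."""
    if not sims:
        return {}
    ids = list(sims)
    logits = np.array([sims[i] for i in ids]) / store.softmax_temp
    logits -= logits.max()
    weights = np.exp(logits)
    probs = weights / weights.sum()
    return {i: float(p) for i, p in zip(ids, probs) if p >= store.label_threshold}


def _argmax_identity(scores: dict[str, float]) -> str:
    """Highest-scoring identity; ties break toward the lowest label."""
    return max(sorted(scores), key=lambda i: scores[i])


def _sample_salient(sampler: SalientSampler,
                    rng: np.random.Generator) -> tuple[int, int]:
    """One random salient location (random block of the 3x3 partition)."""
    block = int(rng.integers(9))
    return sampler.sample_block(block, rng)


# -- first hypothesis --------------------------------------------------------

def first_hypothesis(probe: np.ndarray, store: MemoryStore,
                     gallery_descriptors: dict[str, np.ndarray] | None,
                     params: LoopParams, seed: int = 0,
                     ) -> tuple[str, tuple[int, int]]:
    """Form the initial identity hypothesis and pick the first fixation.

    HG / HG-lesion: global HOG correlation against the gallery; the first
    fixation is the hypothesized identity's first stored feature location
    (HG) or a randomly sampled salient location (lesion). G: a salient
    location is fixated and the foveal match drives the hypothesis.
    """
    if not store.identity_cells:
        raise ValueError("memory store is untrained")
    rng = np.random.default_rng(seed)
    sampler = (SalientSampler(probe, store.fovea_size)
               if params.variant != "HG" else None)
    hyp, fix, _, _ = _first_hypothesis_impl(probe, store, gallery_descriptors,
                                            params, rng, sampler)
    return hyp, fix


def _first_hypothesis_impl(probe, store, gallery_descriptors, params, rng,
                           sampler):
    """Returns (hypothesis, fixation, patch_sims_or_None, fixation_centre)."""
    if params.variant in ("HG", "HG-lesion"):
        if gallery_descriptors is None:
            raise ValueError("HOG variants require gallery descriptors")
        probe_for_hog = (probe if params.gain == 1.0
                         else _rescale_to_canonical(probe, params.gain))
        hyp, _ = hog_hypothesis(probe_for_hog, gallery_descriptors,
                                params.hog_params)
        if params.variant == "HG":
            feature0 = store.features_of(hyp)[0]
            fix = _model_to_probe(feature0.location, probe.shape[0], params.gain)
        else:
            fix = _sample_salient(sampler, rng)
        return hyp, fix, None, None
    # G: bottom-up foveal hypothesis
    fix = _sample_salient(sampler, rng)
    patch, center = _extract_patch(probe, fix, store, params.gain)
    sims = raw_similarities(patch, store)
    acts = _activations_from_sims(sims, store)
    drives = drive_identities(acts, store)
    if max(drives.values()) > 0.0:
        hyp = _argmax_identity(drives)
    else:  # no activation survived the threshold: fall back on raw best match
        best_cell = max(sorted(sims), key=lambda c: sims[c])
        hyp = store.feature_cells[best_cell].identity_id
    return hyp, fix, sims, center


# -- saccade computation -----------------------------------------------------

def next_saccade(current: tuple[int, int], target_cell_id: int,
                 store: MemoryStore, pop: GridPopulation, params: LoopParams,
                 ) -> tuple[SaccadeVector, int]:
    """Grid-decoded saccade from the current fixation to a stored feature.

    The current fixation (probe coordinates) is mapped to model coordinates,
    encoded, and the displacement to the target's stored grid weights is
    decoded, then scaled by ``params.gain``. Unavailable under the grid
    lesion.
    """
    if params.variant == "HG-lesion":
        raise RuntimeError("grid decoding is disconnected in the lesion variant")
    cell = store.feature_cells[target_cell_id]
    cur_model = _probe_to_model(current, pop.size, params.gain)
    a_cur = encode_location(pop, cur_model)
    vec = decode_displacement(pop, a_cur, cell.grid_weights)
    return apply_gain(vec, params.gain), target_cell_id


# -- the full episode --------------------------------------------------------

def recognize(probe: np.ndarray, store: MemoryStore, pop: GridPopulation,
              gallery_descriptors: dict[str, np.ndarray] | None,
              params: LoopParams | None = None, seed: int = 0,
              true_identity: str | None = None) -> RecognitionTrace:
    """Run one full recognition episode and return its trace.

    Deterministic under ``(probe, store, pop, params, seed)``. If
    ``true_identity`` is given the trace's ``first_hypothesis_correct``
    flag is filled in.
    """
    params = params or LoopParams()
    if not store.identity_cells:
        raise ValueError("memory store is untrained")
    rng = np.random.default_rng(seed)
    size = probe.shape[0]
    n_features = len(store.features_of(store.identities[0]))
    sampler = (SalientSampler(probe, store.fovea_size)
               if params.variant != "HG" else None)

    records: list[FixationRecord] = []
    cumulative_drive = {ident: 0.0 for ident in store.identity_cells}
    rejected: set[str] = set()
    resets = 0
    saccades = 0
    accumulator = 0.0
    visited: set[int] = set()
    hyp_saccades = 0
    n_silent = 0  # visited features whose match left the label cell silent

    def decision_level() -> float:
        """Threshold prorated to the features that actually responded."""
        observed = n_features - n_silent
        if observed < params.min_observed:
            return float("inf")  # too few responsive features to decide
        return params.decision_threshold * observed / n_features

    def process_fixation(fix, target_cid, was_reset, precomputed_sims=None):
        """Extract the fovea, match, update drives, accumulate evidence."""
        nonlocal accumulator, n_silent
        if precomputed_sims is None:
            patch, center = _extract_patch(probe, fix, store, params.gain)
            sims = raw_similarities(patch, store)
        else:
            sims, center = precomputed_sims
        acts = _activations_from_sims(sims, store)
        for ident, d in drive_identities(acts, store).items():
            cumulative_drive[ident] += d
        if target_cid is None:
            # hypothesis-forming fixation (variant G): generates competing
            # hypotheses only; identity evidence starts with the saccade
            # sweep over the hypothesized identity's stored features
            matched = max(sorted(sims), key=lambda c: sims[c])
            quality = sims[matched]
        else:
            matched = target_cid
            quality = sims[target_cid]
            visited.add(target_cid)
            if quality < params.silent_floor:
                n_silent += 1
            accumulator = accumulate_evidence(accumulator, quality, params,
                                              n_features)
        records.append(FixationRecord(
            index=len(records), location=center or fix, matched_feature=matched,
            match_quality=quality, hypothesis=hypothesis,
            accumulator_after=accumulator, was_reset=was_reset))

    def lesion_fixate(was_reset):
        """Lesion step: random salient re-fixation, best unvisited feature."""
        nonlocal accumulator, n_silent
        fix = _sample_salient(sampler, rng)
        patch, center = _extract_patch(probe, fix, store, params.gain)
        sims = raw_similarities(patch, store)
        acts = _activations_from_sims(sims, store)
        for ident, d in drive_identities(acts, store).items():
            cumulative_drive[ident] += d
        own = [c for c in store.identity_cells[hypothesis].feature_cell_ids
               if c not in visited]
        matched = max(own, key=lambda c: sims[c])
        visited.add(matched)
        # no silent-feature proration here: treating a weak match as "feature
        # unobserved" presumes the eye was guided to the feature's stored
        # location, which the disconnected grid code cannot do
        accumulator = accumulate_evidence(accumulator, sims[matched], params,
                                          n_features)
        records.append(FixationRecord(
            index=len(records), location=center, matched_feature=matched,
            match_quality=sims[matched], hypothesis=hypothesis,
            accumulator_after=accumulator, was_reset=was_reset))

    # --- first fixation -----------------------------------------------------
    hypothesis, fix, g_sims, g_center = _first_hypothesis_impl(
        probe, store, gallery_descriptors, params, rng, sampler)
    first_hyp = hypothesis
    if params.variant == "HG":
        feature0 = store.features_of(hypothesis)[0]
        process_fixation(fix, feature0.cell_id, was_reset=False)
    elif params.variant == "HG-lesion":
        lesion_fixate(was_reset=False)
    else:  # G: the sampled patch forms the hypothesis; no feature marked visited
        process_fixation(fix, None, was_reset=False,
                         precomputed_sims=(g_sims, g_center))
    fix = records[-1].location

    # --- saccade / accumulate / reset cycle ---------------------------------
    final = "unrecognized"
    succeeded = False
    while True:
        if accumulator >= decision_level():
            final, succeeded = hypothesis, True
            break
        unvisited = [c for c in store.identity_cells[hypothesis].feature_cell_ids
                     if c not in visited]
        if not unvisited or hyp_saccades >= params.max_saccades_per_hypothesis:
            # hypothesis exhausted below threshold -> reset or fail
            rejected.add(hypothesis)
            if resets >= params.max_resets:
                break
            candidates = [i for i in store.identities if i not in rejected]
            if not candidates:
                break
            resets += 1
            hypothesis = _argmax_identity(
                {i: cumulative_drive[i] for i in candidates})
            accumulator = 0.0
            visited.clear()
            hyp_saccades = 0
            n_silent = 0
            # reset-induced re-fixation (bookkept separately from saccades)
            if params.variant == "HG-lesion":
                lesion_fixate(was_reset=True)
            else:
                target = store.identity_cells[hypothesis].feature_cell_ids[0]
                vec, _ = next_saccade(fix, target, store, pop, params)
                dx, dy = vec.applied()
                fix = (int(np.clip(fix[0] + dx, 0, size - 1)),
                       int(np.clip(fix[1] + dy, 0, size - 1)))
                process_fixation(fix, target, was_reset=True)
            fix = records[-1].location
            continue
        # ordinary within-hypothesis saccade
        if params.variant == "HG-lesion":
            saccades += 1
            hyp_saccades += 1
            lesion_fixate(was_reset=False)
        else:
            target = unvisited[0]  # stored (block-raster) visit order
            vec, _ = next_saccade(fix, target, store, pop, params)
            dx, dy = vec.applied()
            fix = (int(np.clip(fix[0] + dx, 0, size - 1)),
                   int(np.clip(fix[1] + dy, 0, size - 1)))
            saccades += 1
            hyp_saccades += 1
            process_fixation(fix, target, was_reset=False)
        fix = records[-1].location

    return RecognitionTrace(
        fixations=records,
        resets=resets,
        saccades=saccades,
        first_hypothesis=first_hyp,
        first_hypothesis_correct=(None if true_identity is None
                                  else first_hyp == true_identity),
        final_identity=final,
        succeeded=succeeded,
    )
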