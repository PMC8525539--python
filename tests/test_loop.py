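"""The saccadic recognition loop: evidence, saccades, resets, variants."""

import numpy as np
import pytest

import gridsaccade as gs
from gridsaccade.loop import LoopParams, accumulate_evidence, next_saccade


class TestAccumulate:
    def test_nine_perfect_matches_cross_threshold(self):
        params = LoopParams()
        acc = 0.0
        for _ in range(9):
            acc = accumulate_evidence(acc, 1.0, params)
        assert acc == pytest.approx(1.0)
        assert acc >= 0.9

    def test_mediocre_matches_insufficient(self):
        params = LoopParams()
        acc = 0.0
        for _ in range(9):
            acc = accumulate_evidence(acc, 0.5, params)
        assert acc == pytest.approx(0.5)
        assert acc < 0.9

    def test_negative_match_does_not_decrease(self):
        params = LoopParams()
        assert accumulate_evidence(0.4, -0.8, params) == 0.4

    def test_binary_rule(self):
        params = LoopParams(increment_rule="binary", binary_cutoff=0.5)
        assert accumulate_evidence(0.0, 0.6, params) == pytest.approx(1 / 9)
        assert accumulate_evidence(0.0, 0.4, params) == 0.0


@pytest.fixture(scope="module")
def episode_setup(dataset, pop, trained):
    store, descriptors = trained
    return dataset, pop, store, descriptors


class TestRecognizeTrainedImages:
    @pytest.mark.parametrize("variant", ["HG", "G"])
    def test_one_shot_recall(self, episode_setup, variant):
        dataset, pop, store, descriptors = episode_setup
        params = LoopParams(variant=variant)
        for i, ident in enumerate(dataset.identities):
            trace = gs.recognize(dataset.gallery[ident], store, pop,
                                 descriptors, params, seed=40 + i,
                                 true_identity=ident)
            assert trace.succeeded
            assert trace.final_identity == ident
            assert trace.resets == 0
            if variant == "HG":
                assert trace.saccades <= 9

    def test_trace_bookkeeping(self, episode_setup):
        dataset, pop, store, descriptors = episode_setup
        trace = gs.recognize(dataset.gallery["id00"], store, pop, descriptors,
                             LoopParams(variant="HG"), seed=1,
                             true_identity="id00")
        assert trace.first_hypothesis_correct is True
        # fixations = 1 initial + saccades + reset re-fixations
        assert trace.n_fixations == 1 + trace.saccades + trace.resets


class TestDeterminism:
    def test_identical_seeds_identical_traces(self, episode_setup):
        dataset, pop, store, descriptors = episode_setup
        probe = dataset.probes[0]
        for variant in ("G", "HG", "HG-lesion"):
            params = LoopParams(variant=variant)
            t1 = gs.recognize(probe.image, store, pop, descriptors, params,
                              seed=77, true_identity=probe.identity)
            t2 = gs.recognize(probe.image, store, pop, descriptors, params,
                              seed=77, true_identity=probe.identity)
            assert t1.to_json() == t2.to_json()


class TestResets:
    def test_no_reset_budget_gives_unrecognized(self, dataset, pop):
        # a probe of pure noise cannot drive any identity to threshold
        store = gs.MemoryStore(fovea_size=101)
        for ident in dataset.identities[:3]:
            gs.learn_stimulus(dataset.gallery[ident], ident, pop, store,
                              seed=0)
        descriptors = {i: gs.hog_descriptor(dataset.gallery[i])
                       for i in dataset.identities[:3]}
        noise = np.random.default_rng(0).random((440, 440))
        params = LoopParams(variant="HG", max_resets=0)
        trace = gs.recognize(noise, store, pop, descriptors, params, seed=5)
        assert not trace.succeeded
        assert trace.final_identity == "unrecognized"
        assert trace.resets == 0

    def test_accumulator_monotone_within_episode(self, episode_setup):
        dataset, pop, store, descriptors = episode_setup
        probe = dataset.probes[7]
        trace = gs.recognize(probe.image, store, pop, descriptors,
                             LoopParams(variant="G"), seed=13,
                             true_identity=probe.identity)
        prev = 0.0
        for f in trace.fixations:
            if f.was_reset:
                prev = 0.0
            assert f.accumulator_after >= prev - 1e-12
            prev = f.accumulator_after


class TestSaccades:
    def test_zero_vector_when_already_at_target(self, episode_setup):
        dataset, pop, store, descriptors = episode_setup
        cell = store.feature_cells[4]
        vec, cid = next_saccade(cell.location, 4, store, pop,
                                LoopParams(variant="HG"))
        assert cid == 4
        assert vec.applied() == (0, 0)

    def test_saccades_land_on_stored_features(self, episode_setup):
        dataset, pop, store, descriptors = episode_setup
        ident = "id05"
        trace = gs.recognize(dataset.gallery[ident], store, pop, descriptors,
                             LoopParams(variant="HG"), seed=3,
                             true_identity=ident)
        stored = {c.cell_id: c.location for c in store.features_of(ident)}
        for f in trace.fixations:
            if f.matched_feature in stored:
                sx, sy = stored[f.matched_feature]
                assert abs(f.location[0] - sx) <= 2
                assert abs(f.location[1] - sy) <= 2

    def test_lesion_disconnects_grid_decoding(self, episode_setup):
        _, pop, store, _ = episode_setup
        with pytest.raises(RuntimeError):
            next_saccade((100, 100), 0, store, pop,
                         LoopParams(variant="HG-lesion"))


class TestScaledProbes:
    def test_half_scale_fixations_land_on_scaled_features(self, episode_setup):
        dataset, pop, store, descriptors = episode_setup
        ident = "id02"
        spec = gs.ScaleSpec(ratio=0.5)
        probe = gs.downscale_on_canvas(dataset.gallery[ident], spec)
        params = LoopParams(variant="HG", gain=0.5)
        trace = gs.recognize(probe, store, pop, descriptors, params, seed=9,
                             true_identity=ident)
        stored = {c.cell_id: c.location for c in store.features_of(ident)}
        checked = 0
        for f in trace.fixations:
            if f.matched_feature in stored:
                ex, ey = gs.imaging.map_location_to_scaled(
                    stored[f.matched_feature], spec)
                assert abs(f.location[0] - ex) <= 3
                assert abs(f.location[1] - ey) <= 3
                checked += 1
        assert checked >= 5

    def test_half_scale_trained_image_recognized(self, episode_setup):
        dataset, pop, store, descriptors = episode_setup
        ident = "id06"
        probe = gs.downscale_on_canvas(dataset.gallery[ident],
                                       gs.ScaleSpec(ratio=0.5))
        trace = gs.recognize(probe, store, pop, descriptors,
                             LoopParams(variant="HG", gain=0.5), seed=2,
                             true_identity=ident)
        assert trace.final_identity == ident


class TestFirstHypothesis:
    def test_hg_training_image_maps_to_itself(self, episode_setup):
        dataset, pop, store, descriptors = episode_setup
        ident, fix = gs.first_hypothesis(dataset.gallery["id03"], store,
                                         descriptors,
                                         LoopParams(variant="HG"), seed=0)
        assert ident == "id03"
        assert fix == store.features_of("id03")[0].location

    def test_g_single_identity_forced(self, dataset, pop):
        store = gs.MemoryStore(fovea_size=101)
        gs.learn_stimulus(dataset.gallery["id00"], "id00", pop, store, seed=0)
        ident, _ = gs.first_hypothesis(dataset.gallery["id07"], store, None,
                                       LoopParams(variant="G"), seed=0)
        assert ident == "id00"

    def test_untrained_store_rejected(self, dataset):
        with pytest.raises(ValueError):
            gs.first_hypothesis(dataset.gallery["id00"], gs.MemoryStore(),
                                {}, LoopParams(variant="G"), seed=0)

    def test_invalid_variant_rejected(self):
        with pytest.raises(ValueError):
            LoopParams(variant="X")
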