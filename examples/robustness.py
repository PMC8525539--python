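"""Recognition under occlusion and uniform downscaling.

Occludes a probe with a texture rectangle and downscales another onto a
mid-gray canvas, then recognizes both: occlusion is absorbed by treating
silent features as unobserved, downscaling by applying the known scale
ratio as a uniform gain on every saccade vector.
"""

import gridsaccade as gs

ds = gs.make_dataset(n_identities=5, n_variants=1, difficulty="medium", seed=11)
pop = gs.build_population(seed=11)
store, descriptors = gs.train_model(ds.gallery, pop, seed=11)

probe = ds.probes[0]

occluded = gs.occlude(probe.image, gs.OcclusionSpec(fraction=1 / 4), seed=2)
t = gs.recognize(occluded, store, pop, descriptors,
                 gs.LoopParams(variant="HG"), seed=1,
                 true_identity=probe.identity)
print(f"1/4-occluded probe of {probe.identity}: recognized as "
      f"{t.final_identity} ({t.n_fixations} fixations, {t.resets} resets)")

scaled = gs.downscale_on_canvas(probe.image, gs.ScaleSpec(ratio=0.5))
t = gs.recognize(scaled, store, pop, descriptors,
                 gs.LoopParams(variant="HG", gain=0.5), seed=1,
                 true_identity=probe.identity)
print(f"half-scale probe with gain 0.5: recognized as {t.final_identity} "
      f"({t.n_fixations} fixations)")
print("Occluded features fall silent and stop vetoing the decision; scaled")
print("probes reuse the full-scale memory by scaling every eye movement.")
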