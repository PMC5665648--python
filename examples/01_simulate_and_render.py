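"""Build a ground-truth scene and render it to EMCCD camera volumes.

A compact field of view keeps the example fast; the optics, photon budget
and noise model are the study defaults (97.7 nm pixels, 261 nm z-steps
after deskew, 850 ms volumes, EMCCD excess noise).
"""

from dataclasses import replace

import numpy as np

from escrtdyn import (build_scene, default_camera, default_egfp,
                      default_geometry, default_psf, render_volume_series,
                      snf7_params)

geom = replace(default_geometry(), volume_shape=(16, 64, 64),
               planes_per_volume=16, n_volumes=20)
rng = np.random.default_rng(1)

scene = build_scene(geom, {"eGFP": snf7_params()}, rng,
                    n_class_i=5, n_class_ii=1)
vols, truth = render_volume_series(scene, geom, default_camera(),
                                   {"eGFP": default_egfp()}, default_psf(),
                                   rng)

vol = vols["eGFP"]
print(f"rendered {vol.data.shape} volume series "
      f"({geom.frame_interval:.0f} ms per volume)")
print(f"{len(scene.emitters)} emitters: "
      f"{sum(e.class_label == 'I' for e in scene.emitters)} mobile class I, "
      f"{sum(e.class_label == 'II' for e in scene.emitters)} static class II")
on = truth[truth.molecules > 0]
print(f"ground truth: {len(on)} emitter-frames with signal, "
      f"median {on.molecules.median():.0f} molecules per spot")
print(f"camera counts: background ~{np.median(vol.data):.0f}, "
      f"max {vol.data.max():.0f}")
# the median class I spot carries tens of molecules; class II clusters sum
# several events and are several-fold brighter
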