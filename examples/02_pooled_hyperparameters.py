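"""Pool per-pixel hyperparameters into per-crop and global averages.

Generates a small multi-crop scene, samples parcels per crop class, trains
hyperparameters pixel by pixel on the sample, and averages the log-triples
per crop and over all pixels — the precalculated sets a whole scene can
then be reconstructed with, without any further optimization.
"""

import numpy as np

import phenofill as pf

cfg = pf.SceneConfig(height=30, width=30, parcel_height=10, parcel_width=10,
                     seed=3)
stack, crop_map, _ = pf.generate_scene(cfg)
print(f"scene: {cfg.height}x{cfg.width} px, {stack.times.size} acquisitions, "
      f"{len(crop_map.class_ids)} crop classes")

parcels = pf.sample_parcels(crop_map, n_parcels=1, min_pixels=50, seed=1)
rng = np.random.default_rng(1)
pixels = {cid: np.concatenate(pl)[rng.choice(len(np.concatenate(pl)), 6,
                                             replace=False)]
          for cid, pl in parcels.items() if pl}
per_pixel = pf.train_per_pixel(stack, pixels, seed=2, n_restarts=3)
thetas = pf.average_hyperparameters(per_pixel)

print(f"\ntrained {len(per_pixel)} pixels; pooled averages (log scale):")
print(f"{'crop':<11}{'log(1/l)':>10}{'log(s_f)':>10}{'log(s_n)':>10}")
for cid, th in thetas.per_crop.items():
    print(f"{crop_map.legend[cid]:<11}{th.log_inv_l:>10.3f}"
          f"{th.log_sigma_f:>10.3f}{th.log_sigma_n:>10.3f}")
g = thetas.global_theta
print(f"{'global':<11}{g.log_inv_l:>10.3f}{g.log_sigma_f:>10.3f}"
      f"{g.log_sigma_n:>10.3f}")
# the global row is the pixel-weighted mean over all trained pixels, which
# is why it differs (slightly) from the mean of the crop rows above

ref = pf.reference_thetas()
print(f"\npackaged reference global theta (from a published Sentinel-2 LAI "
      f"study):\n  log(1/l)={ref.global_theta.log_inv_l}, "
      f"log(s_f)={ref.global_theta.log_sigma_f}, "
      f"log(s_n)={ref.global_theta.log_sigma_n}")
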