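# olfactomap

Topographic analysis of the peripheral olfactory system: odor-evoked
calcium activity maps of the olfactory bulb, angle-resolved amyloid-β
(A11/DAB) immunohistochemistry, odor-guided behavior, and the statistics
that tie them together — built for studying region-specific olfactory
pathology (e.g. early amyloid accumulation in 5xFAD mice), and validated
end-to-end against a ground-truthed synthetic-data generator.

## The problem and the model

Olfactory sensory neurons project topographically: neurons in the
endoturbinate target **dorsal** olfactory-bulb glomeruli, neurons in the
ectoturbinate target **ventral** glomeruli. Pathology that accumulates
unevenly along this dorsoventral axis should therefore impair some odors
and spare others. Testing that idea requires putting three very different
measurements — widefield fura-2 imaging (380 nm excitation, where
activation *lowers* fluorescence), DAB-stained sections from a different
anatomical plane, and cage behavior — onto a single spatial coordinate.

`olfactomap`'s core is that coordinate: every point on the glomerular
layer is assigned an angle θ. On sagittal sections
θ = 180·s/S, the normalized arc length from the dorsal-most point (0°)
to the ventral-most (180°); on coronal sections θ is the polar angle
about the section center from the dorsal zero landmark, in [0°, 360°).
Dorsal means θ within 80° of 0°, ventral within 80° of 180°. On this
axis the package computes:

* **ΔF/F₀ activity maps** — baseline F₀ from the 3 s before stimulus
  pooled over 10 trials, ΔF/F₀ = (F − F₀)/F₀, trial-averaged and binned
  per second, summarized over the 2-s stimulus window on a 10 (AP) × 180
  (DV) grid with 200-µm ROI outlines;
* **angle-resolved immunoreactivity** — H-DAB color deconvolution
  (OD = −log₁₀(I/255), standard stain vectors), percent staining area,
  reciprocal intensity, and per-degree DAB profiles;
* **cross-modal statistics** — Spearman ρ (average ranks, Gaussian-
  approximation p, Fisher-z CI) between angle-matched profiles (180 pairs
  at 1° binning), OLS regression with 95% confidence bands, odor-map
  correlation matrices with average-linkage clustering, Student t tests
  and genotype × region ANOVA with Bonferroni post-hoc contrasts;
* **behavior** — three-compartment zone occupancy from 30-fps nose
  tracking, the performance index PI = %time(odorant) − %time(control),
  occupancy heat maps, WT-normalized food-seeking latency and Y-maze
  alternation.

See `docs/methods.md` for definitions, defaults and limitations.

## Worked example

```python
import numpy as np
from olfactomap import (
    SimConfig, simulate_odorant_trials, generate_histology_profile,
    average_trials, response_image, build_grid, grid_dv_profile,
    angle_matched_correlation,
)
from olfactomap.geometry import bulb_mask

cfg = SimConfig(seed=1, genotype="5xFAD")          # default study conditions
ts, truth = simulate_odorant_trials(cfg, "H")      # heptanal: ventral group
dmap = average_trials(ts)                          # 10 trials -> 20 x H x W
resp = response_image(dmap, sign="raw")            # activation-negative
grid = build_grid(np.where(bulb_mask(cfg.fov_px), resp, np.nan),
                  bulb_mask(cfg.fov_px))           # 10 x 180 sections
a11, _, _ = generate_histology_profile(cfg, "sagittal")
rho, reg = angle_matched_correlation(a11, grid_dv_profile(grid))
print(f"planted peak dip {truth['peak_dff']:.3f}, "
      f"measured {np.nanmax(np.abs(grid)):.3f}")
print(f"A11 x calcium: rho={rho.rho:.3f}, n={rho.n_pairs}, p={rho.p_two_tailed:.2e}")
```

Output:

```
planted peak dip 0.044, measured 0.041
A11 x calcium: rho=-0.743, n=180, p=2.86e-23
```

The planted response of this ventral-group odorant (amplitude suppressed
by 70% in the 5xFAD condition) is recovered to within a few percent, and
its activity correlates negatively with ventral-enriched A11
immunoreactivity over the 180 angle-matched dorsoventral sections —
high-amyloid angles are exactly where the odor-evoked signal is weak.

More narrative scripts live in `examples/` (one per capability), and a
thin CLI wraps the common entry points:

```bash
olfactomap simulate --seed 1 --genotype 5xFAD --out data/
olfactomap dff --dataset data/dataset_seed1_5xFAD --odorant H --out maps/
olfactomap run --config run.yaml --out results/
```

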