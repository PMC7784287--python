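"""Simulate one animal's imaging trials and build an odor activity map.

Generates ten 20-s fura-2 trials for lyral (a dorsally projecting
odorant), computes the trial-averaged stimulus-window response, detects
ROIs and builds the 10 x 180 analysis grid.
"""

import numpy as np

from olfactomap import (
    SimConfig,
    analyze_trialset,
    simulate_odorant_trials,
)
from olfactomap.geometry import bulb_mask

cfg = SimConfig(seed=0, genotype="WT")
trialset, truth = simulate_odorant_trials(cfg, "L")
amap = analyze_trialset(trialset, bulb_mask(cfg.fov_px))

print(f"grid shape: {amap.grid.shape}  (anterior-posterior x dorsoventral)")
print(f"detected ROIs: {len(amap.rois)}")
print(f"planted peak |dF/F0|: {truth['peak_dff']:.4f}")
print(f"measured grid peak:   {np.nanmax(amap.grid):.4f}")
print(f"planted focus angles: {np.round(truth['focus_angles_deg'], 1)} deg")

# The measured peak tracks the planted fluorescence dip (fura-2 at 380 nm
# DECREASES on activation; the map reports magnitude), and the foci sit
# near the dorsal group's 40-degree center.
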