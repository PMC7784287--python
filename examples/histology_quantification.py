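"""Quantify amyloid staining on a rendered H-DAB section.

Renders a synthetic 5xFAD coronal section (ventral A11 enrichment planted
at 2x), recovers the angular DAB profile by color deconvolution, and
compares dorsal vs ventral staining.
"""

from olfactomap import SimConfig, angular_immunoreactivity, percent_stain_area, region_ratio
from olfactomap.geometry import coronal_contour
from olfactomap.histology import color_deconvolve
from olfactomap.synthetic import generate_histology_profile, section_band_mask
from olfactomap.topography import profile_region_summary

cfg = SimConfig(seed=42, genotype="5xFAD", fov_px=96)
_, rgb, truth = generate_histology_profile(cfg, "coronal", render_image=True)
mask = section_band_mask(cfg, "coronal")

profile = angular_immunoreactivity(rgb, coronal_contour(cfg.fov_px), tissue_mask=mask)
summary = profile_region_summary(profile)
dab = color_deconvolve(rgb)[..., 1]
area = percent_stain_area(dab, threshold=0.15, mask=mask)

print(f"mean DAB OD  dorsal: {summary['dorsal']:.3f}   ventral: {summary['ventral']:.3f}")
print(f"ventral/dorsal ratio: {summary['ventral'] / summary['dorsal']:.2f} "
      f"(planted gain {truth['ab_ventral_gain']:.1f})")
print(f"DAB-positive area in the glomerular band: {area:.1f}%")

# The deconvolved ventral/dorsal ratio recovers the planted ventral
# amyloid enrichment from the rendered RGB pixels alone.
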