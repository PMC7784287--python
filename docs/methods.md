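# Methods

`olfactomap` implements a topographic analysis of early amyloid pathology in
the peripheral olfactory system: it registers measurements made on the
glomerular layer of the olfactory bulb (OB) onto a common dorsoventral
angular axis, quantifies odor-evoked calcium activity and DAB-stained
amyloid-β (A11) immunoreactivity on that axis, correlates the two
modalities bin by bin, and scores odor-guided behavior. Because the animal
data behind this design are not public, the package ships a synthetic-data
generator that emulates the raw inputs with known ground truth; every
analysis stage is validated by recovering what the generator planted.

## The angular ("numeric scale") registration

The glomerular layer is traced as an ordered contour. On a sagittal
section the layer is an open arc: its dorsal-most point is defined as 0°
and its ventral-most point as 180°, and any measurement point is assigned
the angle `180 · s / S`, where `s` is the arc length from the zero
landmark to the point's nearest-point projection on the contour and `S`
the total arc length. Arc length — rather than a polar angle — is the only
construction that guarantees the full 0–180° sweep on an open contour of
arbitrary shape. On a coronal section the layer rings the tissue, and the
angle is the polar angle about the section center measured from the ray
through the zero landmark (the point on the upper rostral-migratory-stream
track), in [0°, 360°), increasing in the direction the contour is
ordered. Pixel coordinates are used throughout (origin top-left, y down,
so dorsal = smaller y).

Angular profiles use contiguous 1° bins (per-bin mean, with the
contributing count recorded and empty bins missing-coded as NaN). Regions
are classified as **dorsal** within 80° of 0° and **ventral** within 80°
of 180°; angles in between are unassigned. All region summaries are
missing-aware means over classified bins.

Open design point: sections at different anterior-posterior positions may
each carry their own zero landmark. The implementation registers each
frame against its own contour and merges by angle, which is the
conservative reading; users supplying multi-frame data should verify
landmark consistency.

## Calcium imaging analysis

Input movies are single-wavelength fura-2 recordings at 380 nm excitation,
where a rise in intracellular calcium **decreases** fluorescence. A trial
is 20 s at 25–125 Hz with a 2-s odor stimulus; ten trials per odorant.

* **Baseline** `F0`: per-pixel mean over the 3 s immediately preceding
  stimulus onset, pooled across all (non-excluded) trials.
* **ΔF/F₀**: `(F(t) − F0) / F0` per pixel; pixels with non-positive `F0`
  are masked and counted.
* **Trial averaging**: mean across trials, then mean within each 1-s bin
  (20 bins per trial). Since ΔF/F₀ is linear in `F`, frames are averaged
  across trials before normalization — mathematically identical and one
  pass over the data. Artifact trials are removed via an explicit
  exclusion list; no automatic artifact detection is attempted.
* **Response summary**: mean (optionally sum, the "cumulated signal"
  reading) of the bins covering the 2-s stimulus window. Summaries carry a
  sign flag: `magnitude` (absolute response, used for activity maps and
  clustering) or `raw` (activation-negative, used for the cross-modal
  correlation — see below).
* **ROI detection**: a stand-in for interactive peak-picking plugins —
  local maxima of the response magnitude above `median + 3·MAD`, minimum
  mutual separation 200 µm, each outlined by a 200-µm disk clipped to the
  image. The threshold factor is configurable because the original
  plugin's internals are not published.
* **Grid**: the bulb bounding box is divided into 10 equal
  anterior-posterior × 180 equal dorsoventral sections; each cell holds
  the mean response of its in-mask area. With a 128-px field of view
  (a 256-px camera at 2×2 binning over 2.3 mm) the bulb spans ~115 pixel
  rows, fewer than 180 sections, so cells are filled by integer subpixel
  replication — an area-weighted partition that leaves no section empty
  inside the mask. When sections are at least one pixel tall this reduces
  exactly to the per-cell pixel mean (oracle-tested). Cells outside the
  bulb are NaN and excluded downstream. Collapsing the grid across the
  anterior-posterior axis reads the 180 dorsoventral sections as the 1°
  bins of the sagittal angular scale.

## Histology quantification

Color deconvolution uses the standard optical-density model
`OD = −log10(I/255)` per RGB channel with the published H-DAB unit
vectors (hematoxylin `[0.650, 0.704, 0.286]`, DAB
`[0.269, 0.568, 0.778]`, residual their cross product; configurable).
Unmixing multiplies by the inverse stain matrix and clips small negative
loadings to zero. The forward model (`stains_to_rgb`) renders per-stain
ODs back to RGB; the unquantized round trip is exact to 1e-6 OD.

Percent staining area is the fraction of in-mask pixels whose DAB OD
exceeds a positivity threshold (default 0.15 OD — no threshold is given
in the source protocols, so it is explicit and configurable). Reciprocal
intensity is operationalized as `255 − mean 8-bit intensity` per mm²;
both conventions are recorded in outputs. Angle-resolved immunoreactivity
composes deconvolution → per-pixel angle assignment → 1° binning, and can
emit either the per-bin mean OD (default, used by the correlation
analyses) or the per-bin positive-area fraction. Region ratios divide all
four genotype × region means by the wild-type dorsal mean, so WT-dorsal
is 1.00 by construction. Cell-count operations consume already-labeled
tables (counting was manual in the source workflow); no nucleus detector
is included.

## Behavior

The odor-detection test tracks four points of interest (nose, both ears,
tail) at 30 frames/s in a cage split into three equal compartments along
its long axis. Occupancy is the fraction of valid frames whose tracked
point (nose by default — the sniffing end; the 4-point centroid is also
selectable) lies in each compartment; missing frames are dropped, never
interpolated, and counted. The performance index is
`PI = %time(odorant compartment, test) − %time(same compartment, control)`
with percentages taken over valid session time (configurable to
in-compartment time). Food-seeking latencies are divided by the wild-type
mean latency; observations at the 10-min recording cutoff are flagged
censored. Y-maze alternation is `100 · (# of length-3 entry windows
visiting all three arms) / (N − 2)`.

## Cross-modal statistics

* **Spearman correlation** uses average ranks for ties, pairwise-complete
  deletion (the retained pair count is always reported), a two-tailed p
  from the Gaussian approximation `z = ρ√(n−1)`, and a 95% CI from the
  Fisher z transform with variance `1/(n−3)`.
* **Angle-matched correlation** pairs a histology profile and a calcium
  profile bin by bin on identical 1° edges (180 pairs on the sagittal
  domain when no bin is missing) and adds an OLS line with slope/intercept
  CIs and a pointwise 95% confidence band. Both the rank-correlation CI
  and the regression CIs are emitted, labeled, since either may be wanted.
  The calcium profile enters with the **raw** (activation-negative) sign:
  ventrally evoked activity then ranks low exactly where ventral A11 is
  high, giving the negative ventral-group correlations and non-negative
  dorsal-group correlations that the magnitude convention would invert.
* **Odor-map clustering**: pairwise Spearman between activity-map grids,
  average-linkage hierarchical clustering on `1 − ρ`, cut at k = 2. The
  algorithm choice is fixed for reproducibility and checked against an
  exhaustive-partition oracle at n = 7.
* **Group tests**: two-tailed Student (equal-variance) t with
  `df = n₁ + n₂ − 2`; balanced two-way ANOVA (genotype × region, with
  interaction) followed by per-region genotype contrasts with Bonferroni
  adjustment `min(1, m·p)`. Degenerate all-equal tables report `F = 0,
  p = 1` rather than 0/0.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the analyses are validated under.

**Imaging.** The bulb is an ellipse filling 90% of a 128-px field of view
at 18 µm/px (a 256-px sensor with 2×2 binning over a 2.3-mm field);
baseline fluorescence is flat at 1000 a.u. Each odorant evokes (a) three
compact glomerular foci — isotropic Gaussians, σ = 100 µm, combined by
maximum so the planted peak is exact — placed on the glomerular arc at
angles drawn `N(group center, 10°)`, insetted slightly from the rim and
snapped to the pixel grid, and (b) a diffuse component decaying with
angular distance from the group center (σ = 40°, amplitude half the focal
dip). The diffuse term reflects the spatially graded input signal seen in
widefield recordings; without it most dorsoventral bins would be pure
noise and strong rank correlations would be unreachable in principle.
Group centers default to 40° (lyral, acetophenone, eugenol) and 150°
(geraniol, allyl phenylacetate, heptanoic acid, heptanal). Activation is
a fluorescence decrease (peak focal dip 10% of baseline, diffuse 5%),
constant over the 2-s stimulus with a 1-s exponential decay afterwards —
the simplest testable kinetics. Per-frame Gaussian noise has SD 2% of
baseline. In 5xFAD animals, ventral-group response amplitudes are scaled
by `1 − ventral_suppression` (default 0.7, making the suppression
unambiguous at default noise). Movies are clipped to a small positive
floor, so fluorescence is never non-positive.

**Histology.** The A11 angular profile is flat at 0.30 DAB OD for
wild-type; 5xFAD multiplies ventral bins (180° ± 80°) by
`ab_ventral_gain` (default 2.0). Per-bin noise SD is 0.03 OD. Rendered
sections paint the profile onto a glomerular-layer band and push it
through the forward H-DAB model, so deconvolution recovers it; no attempt
is made to render nuclei or realistic optics.

**Behavior.** Nose position follows a sticky renewal process over the
three compartments (per-frame switch probability 0.02, i.e. ~1.7-s
visits) whose stationary odor-compartment probability is 0.6 for a
detecting animal and 1/3 (chance) otherwise; wild-type animals detect all
seven odorants, 5xFAD only the dorsal group. Ears and tail are jittered
offsets from the nose, clipped to the cage.

**Counts.** Per-animal marker values are truncated-normal draws. OMP
percentages use the study's printed per-region means ± SDs; TH uses the
reported normalized region means; Ki67 and TUNEL plant the reported
twofold ectoturbinate changes at plausible absolute scales (30 and 5
cells/mm²) since no absolute values are printed. An `effect_scale`
parameter interpolates every 5xFAD mean toward its wild-type counterpart;
0 gives the null configuration used for type-I-error calibration.

All draws come from per-artifact seeded streams
(`SeedSequence([seed, stream, index])`), so one odorant can be simulated
without the rest and identical configs produce identical bytes on disk.

## What the synthetic conditions do and do not show

Passing recovery tests shows the pipeline correctly inverts its own
forward model under realistic noise: planted response amplitudes are
recovered within 10%, the ventral A11 gain within 10%, the planted
dorsal/ventral group structure is recovered by clustering in ≥19/20
seeds, and the sign pattern of the angle-matched correlations (negative
for ventral-group odorants, non-negative for dorsal-group) holds in 20/20
seeded 5xFAD animals. It does not show robustness to features the
generator omits: optical blur and photobleaching, motion, glomerular
shape irregularity, non-flat baselines, staining batch effects, or
tracking dropouts. Magnitudes of the real correlations depend on
biological effect sizes that are not reproducible from printed summaries;
only definitional and structural quantities (pair counts, degrees of
freedom, PI endpoints, grid shape) are checked as exact values.

## Numerical choices and problem sizes

Movies are generated and averaged in float32 (final ΔF/F₀ in float64;
`compute_dff` itself works in float64 to avoid cancellation on small
signals). Ties in ROI ranking are broken by detection order (decreasing
peak magnitude); bin boundaries are half-open `[lo, hi)` with the top
edge closed. The heavy validation suites run 20 simulated animals per
genotype at the full default conditions (7 odorants × 10 trials × 500
frames × 128² pixels each); unit tests use smaller fields of view and
trial counts, chosen purely to keep the feedback loop fast — the
acceptance-grade checks always run at the default conditions.
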