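"""Synthetic-data generator: every input the pipeline consumes.

The generator plants the effects the analysis is designed to recover:

* odor-evoked glomerular foci whose dorsoventral angles cluster near 40
  degrees for group-A odorants (lyral, acetophenone, eugenol) and near 150
  degrees for group-B odorants (geraniol, allyl phenylacetate, heptanoic
  acid, heptanal), on top of a broad diffuse response component centered on
  the same angle;
* fura-2 single-wavelength (380 nm) sign convention — activation is a
  fluorescence DECREASE;
* in the 5xFAD genotype, group-B response amplitudes scaled by
  ``1 - ventral_suppression`` and ventral (180 +/- 80 degrees) A11
  immunoreactivity multiplied by ``ab_ventral_gain``;
* detection-dependent odor-seeking behavior (wild-type animals detect all
  seven odorants, 5xFAD animals only group A);
* marker count tables whose default means/SDs follow the study's printed
  summaries.

Everything is drawn from integer-seeded generators: an identical
:class:`~olfactomap.config.SimConfig` reproduces identical arrays and
identical bytes on disk. A :class:`GroundTruth` record sufficient to score
parameter recovery is emitted alongside every dataset.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .behavior import POIS, TrajectorySession
from .calcium import ImagingTrial, TrialSet
from .config import GROUP_A, ODORANTS, SimConfig, odorant_group
from .geometry import bulb_mask, coronal_contour, point_at_angle, sagittal_contour
from .histology import StainVectors, stains_to_rgb
from .topography import AngularProfile, GlomerularContour, assign_angles

__all__ = [
    "GroundTruth",
    "generate_imaging_dataset",
    "simulate_odorant_trials",
    "generate_histology_profile",
    "generate_trajectory",
    "generate_count_tables",
    "write_dataset",
    "read_trialset",
]

# rng stream tags, combined with the config seed so that every artifact
# draws from an independent, reproducible stream
_STREAM_IMAGING = 1
_STREAM_HISTOLOGY = 2
_STREAM_COUNTS = 3
_STREAM_BEHAVIOR = 4


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *stream]))


@dataclass
class GroundTruth:
    """Planted parameters emitted alongside every synthetic dataset."""

    imaging: dict = field(default_factory=dict)
    histology: dict = field(default_factory=dict)
    behavior: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True, default=float)
        )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# imaging


_angle_map_cache: dict[int, np.ndarray] = {}


def _pixel_angle_map(fov_px: int) -> np.ndarray:
    """Dorsoventral angle of every FOV pixel (nearest point on the
    sagittal glomerular contour), cached per FOV size."""
    if fov_px not in _angle_map_cache:
        contour = sagittal_contour(fov_px)
        yy, xx = np.mgrid[0:fov_px, 0:fov_px]
        pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        ang, _ = assign_angles(pts, contour)
        _angle_map_cache[fov_px] = ang.reshape(fov_px, fov_px)
    return _angle_map_cache[fov_px]


def planted_response_field(
    cfg: SimConfig, odorant: str, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    """Noise-free relative-dip field for one odorant.

    The field holds the fractional fluorescence decrease at full stimulus
    drive: compact Gaussian foci (combined by maximum, so the focal peak
    equals ``focal_dip``) plus a diffuse component that decays with angular
    distance from the odor group's center. Genotype scaling is applied.
    """
    center = cfg.group_center(odorant)
    contour = sagittal_contour(cfg.fov_px)
    sigma_px = cfg.focus_sigma_um / cfg.um_per_px
    yy, xx = np.mgrid[0 : cfg.fov_px, 0 : cfg.fov_px]
    focal = np.zeros((cfg.fov_px, cfg.fov_px))
    angles = []
    for _ in range(cfg.n_foci):
        theta = float(
            np.clip(center + rng.normal(0.0, cfg.angle_jitter_deg), 0.0, 180.0)
        )
        angles.append(theta)
        # inset the focus slightly from the rim (glomeruli have depth) and
        # snap to the pixel grid so the planted peak amplitude is attained
        # exactly at one in-mask pixel
        p = point_at_angle(contour, theta)
        c = np.array([(cfg.fov_px - 1) / 2.0] * 2)
        fx, fy = np.round(c + 0.94 * (p - c))
        d2 = (xx - fx) ** 2 + (yy - fy) ** 2
        focal = np.maximum(focal, cfg.focal_dip * np.exp(-d2 / (2 * sigma_px**2)))
    ang_map = _pixel_angle_map(cfg.fov_px)
    diffuse = cfg.diffuse_dip * np.exp(
        -((ang_map - center) ** 2) / (2 * cfg.diffuse_sigma_deg**2)
    )
    mask = bulb_mask(cfg.fov_px)
    scale = cfg.amplitude_scale(odorant)
    field_arr = scale * np.where(mask, focal + diffuse, 0.0)
    truth = {
        "focus_angles_deg": angles,
        "group_center_deg": center,
        "amplitude_scale": scale,
        "peak_dff": float(field_arr.max()),
    }
    return field_arr, truth


def _stimulus_profile(cfg: SimConfig) -> np.ndarray:
    """Temporal drive: 0 before onset, 1 during the stimulus, exponential
    decay (tau = ``decay_tau_s``) afterwards."""
    t = np.arange(round(cfg.trial_length_s * cfg.frame_rate)) / cfg.frame_rate
    s = np.zeros_like(t)
    on = (t >= cfg.stim_onset_s) & (t < cfg.stim_onset_s + cfg.stim_duration_s)
    s[on] = 1.0
    off = t >= cfg.stim_onset_s + cfg.stim_duration_s
    s[off] = np.exp(-(t[off] - cfg.stim_onset_s - cfg.stim_duration_s) / cfg.decay_tau_s)
    return s


def simulate_odorant_trials(
    cfg: SimConfig, odorant: str
) -> tuple[TrialSet, dict]:
    """Repeated imaging trials for one odorant, plus its ground truth.

    Each trial is ``trial_length_s`` at ``frame_rate`` Hz with a 2-s
    stimulus; fluorescence never drops below a small positive floor.
    """
    odorant_group(odorant)  # validate label
    idx = ODORANTS.index(odorant)
    rng = _rng(cfg.seed, _STREAM_IMAGING, idx)
    field_arr, truth = planted_response_field(cfg, odorant, rng)
    s = _stimulus_profile(cfg).astype(np.float32)
    base = np.float32(cfg.baseline_f)
    clean = base * (1.0 - s[:, None, None] * field_arr.astype(np.float32))
    trials = []
    for _ in range(cfg.n_trials):
        if cfg.noise_sd > 0:
            frames = rng.standard_normal(clean.shape, dtype=np.float32)
            frames *= np.float32(cfg.noise_sd) * base
            frames += clean
        else:
            frames = clean.copy()
        np.maximum(frames, np.float32(1e-3), out=frames)
        trials.append(
            ImagingTrial(
                frames=frames,
                frame_rate=cfg.frame_rate,
                stim_onset_s=cfg.stim_onset_s,
                stim_duration_s=cfg.stim_duration_s,
                trial_length_s=cfg.trial_length_s,
            )
        )
    ts = TrialSet(
        odorant=odorant, trials=trials, um_per_px=cfg.um_per_px, genotype=cfg.genotype
    )
    return ts, truth


def generate_imaging_dataset(
    cfg: SimConfig,
) -> tuple[dict[str, TrialSet], GroundTruth]:
    """All odorants' trial sets for one simulated animal."""
    gt = GroundTruth()
    sets: dict[str, TrialSet] = {}
    for od in cfg.odorants:
        sets[od], gt.imaging[od] = simulate_odorant_trials(cfg, od)
    return sets, gt


# ---------------------------------------------------------------------------
# histology


def _true_a11_profile(cfg: SimConfig, bin_centers: np.ndarray) -> np.ndarray:
    base = np.full(bin_centers.shape, cfg.hist_baseline_od)
    if cfg.genotype == "5xFAD":
        d_ventral = np.abs(((bin_centers - 180.0) + 180.0) % 360.0 - 180.0)
        base = np.where(d_ventral <= 80.0, base * cfg.ab_ventral_gain, base)
    return base


def generate_histology_profile(
    cfg: SimConfig,
    plane: str = "sagittal",
    render_image: bool = False,
) -> tuple[AngularProfile, np.ndarray | None, dict]:
    """Angle-resolved A11 (DAB) intensity profile, optionally rendered as
    an H-DAB section image.

    The wild-type profile is flat; the 5xFAD profile multiplies ventral
    bins (within 80 degrees of 180) by ``ab_ventral_gain``. When an image
    is requested, the profile is painted onto a glomerular-layer band and
    pushed through the forward H-DAB optical-density mixing model so that
    color deconvolution recovers it.
    """
    if plane not in ("sagittal", "coronal"):
        raise ValueError("plane must be 'sagittal' or 'coronal'")
    rng = _rng(cfg.seed, _STREAM_HISTOLOGY, 0 if plane == "sagittal" else 1)
    span = 180 if plane == "sagittal" else 360
    edges = np.arange(span + 1, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    true_vals = _true_a11_profile(cfg, centers)
    observed = true_vals + rng.normal(0.0, cfg.hist_noise_sd, size=true_vals.shape)
    observed = np.clip(observed, 0.0, None)
    profile = AngularProfile(plane, edges, observed, np.ones(span, dtype=int))
    truth = {
        "plane": plane,
        "true_profile": true_vals.tolist(),
        "baseline_od": cfg.hist_baseline_od,
        "ab_ventral_gain": cfg.ab_ventral_gain if cfg.genotype == "5xFAD" else 1.0,
    }
    image = None
    if render_image:
        image = _render_section(cfg, plane, centers, true_vals, rng)
    return profile, image, truth


def _render_section(
    cfg: SimConfig,
    plane: str,
    bin_centers: np.ndarray,
    dab_profile: np.ndarray,
    rng: np.random.Generator,
    band_px: float = 5.0,
    hematoxylin_od: float = 0.35,
) -> np.ndarray:
    n = cfg.fov_px
    contour = sagittal_contour(n) if plane == "sagittal" else coronal_contour(n)
    yy, xx = np.mgrid[0:n, 0:n]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    angles, accepted = assign_angles(pts, contour, max_dist=band_px)
    in_band = accepted.reshape(n, n)
    ang_img = angles.reshape(n, n)
    dab = np.zeros((n, n))
    idx = np.clip(
        np.floor(np.nan_to_num(ang_img, nan=0.0)).astype(int), 0, len(dab_profile) - 1
    )
    dab[in_band] = dab_profile[idx[in_band]]
    dab[in_band] += rng.normal(0.0, cfg.hist_noise_sd, size=int(in_band.sum()))
    dab = np.clip(dab, 0.0, None)
    hema = np.where(in_band, hematoxylin_od, 0.0)
    stains = np.stack([hema, dab, np.zeros_like(dab)], axis=-1)
    return stains_to_rgb(stains, StainVectors(), quantize=True)


def section_band_mask(cfg: SimConfig, plane: str, band_px: float = 5.0) -> np.ndarray:
    """Mask of the rendered glomerular-layer band (for round-trip tests)."""
    n = cfg.fov_px
    contour = sagittal_contour(n) if plane == "sagittal" else coronal_contour(n)
    yy, xx = np.mgrid[0:n, 0:n]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    _, accepted = assign_angles(pts, contour, max_dist=band_px)
    return accepted.reshape(n, n)


# ---------------------------------------------------------------------------
# behavior


def generate_trajectory(
    detects: bool | None = None,
    duration_s: float = 120.0,
    seed: int = 0,
    fps: float = 30.0,
    cage_size: tuple[float, float] = (30.0, 15.0),
    odor_zone: int = 0,
    p_odor: float | None = None,
    switch_prob: float = 0.02,
    condition: str = "odorant",
) -> tuple[TrajectorySession, dict]:
    """Four-POI tracked session in the three-compartment test cage.

    The nose occupies the odorant compartment with long-run probability
    ``p_odor`` (default 0.6 for a detecting animal, 1/3 — chance — for a
    non-detecting one); zone membership follows a sticky renewal process so
    visits last a realistic fraction of a second. Frame count equals
    ``duration_s * fps``.
    """
    if p_odor is None:
        if detects is None:
            raise ValueError("give either `detects` or an explicit `p_odor`")
        p_odor = 0.6 if detects else 1.0 / 3.0
    if not 0.0 <= p_odor <= 1.0:
        raise ValueError("p_odor must lie in [0, 1]")
    rng = _rng(seed, _STREAM_BEHAVIOR)
    n = int(round(duration_s * fps))
    probs = np.full(3, (1.0 - p_odor) / 2.0)
    probs[odor_zone] = p_odor
    resample = rng.random(n) < switch_prob
    resample[0] = True
    draws = rng.choice(3, size=n, p=probs)
    zone = np.zeros(n, dtype=int)
    current = draws[0]
    for i in range(n):
        if resample[i]:
            current = draws[i]
        zone[i] = current
    lx, ly = cage_size
    third = lx / 3.0
    margin = 0.05 * third
    x = zone * third + margin + rng.random(n) * (third - 2 * margin)
    y = 0.1 * ly + rng.random(n) * 0.8 * ly
    cols = {"t_s": np.arange(n) / fps}
    # the nose IS the drawn trajectory (it decides zone membership);
    # ears and tail are jittered body offsets
    cols["nose_x"], cols["nose_y"] = x, y
    offsets = {"earL": (-1.0, -1.0), "earR": (-1.0, 1.0), "tail": (-6.0, 0.0)}
    for poi, (dx, dy) in offsets.items():
        jitter = rng.normal(0.0, 0.2, size=(n, 2))
        cols[f"{poi}_x"] = np.clip(x + dx + jitter[:, 0], 0.0, lx)
        cols[f"{poi}_y"] = np.clip(y + dy + jitter[:, 1], 0.0, ly)
    session = TrajectorySession(
        pd.DataFrame(cols),
        fps=fps,
        cage_size=cage_size,
        odor_zone=odor_zone,
        condition=condition,
    )
    truth = {"p_odor": p_odor, "odor_zone": odor_zone, "n_frames": n}
    return session, truth


def detects_odorant(genotype: str, odorant: str) -> bool:
    """Planted behavioral rule: wild-type animals detect every odorant;
    5xFAD animals detect only group A."""
    return genotype == "WT" or odorant in GROUP_A


# ---------------------------------------------------------------------------
# marker count tables

# (mean, sd) per marker / region / genotype; OMP follows the study's
# printed per-region summaries, the remaining markers use the reported
# fold-changes at plausible absolute scales
COUNT_DEFAULTS: dict[str, dict] = {
    "OMP": {
        "unit": "%OMP",
        "values": {
            ("endo", "WT"): (65.29, 5.10),
            ("endo", "5xFAD"): (62.70, 4.04),
            ("ecto", "WT"): (71.11, 3.95),
            ("ecto", "5xFAD"): (52.74, 5.25),
        },
    },
    "TH": {
        "unit": "cells per 5 glomeruli",
        "values": {
            ("dorsal", "WT"): (1.00, 0.15),
            ("dorsal", "5xFAD"): (1.13, 0.17),
            ("ventral", "WT"): (1.67, 0.25),
            ("ventral", "5xFAD"): (0.61, 0.09),
        },
    },
    "Ki67": {
        "unit": "cells/mm2",
        "values": {
            ("endo", "WT"): (30.0, 4.5),
            ("endo", "5xFAD"): (30.0, 4.5),
            ("ecto", "WT"): (30.0, 4.5),
            ("ecto", "5xFAD"): (15.0, 2.25),
        },
    },
    "TUNEL": {
        "unit": "cells/mm2",
        "values": {
            ("endo", "WT"): (5.0, 1.0),
            ("endo", "5xFAD"): (5.0, 1.0),
            ("ecto", "WT"): (5.0, 1.0),
            ("ecto", "5xFAD"): (10.0, 2.0),
        },
    },
}


def generate_count_tables(
    cfg: SimConfig,
    n_animals: int = 6,
    effect_scale: float = 1.0,
    markers: tuple[str, ...] = ("OMP", "TH", "Ki67", "TUNEL"),
) -> tuple[pd.DataFrame, dict]:
    """Per-animal marker counts for both genotypes.

    ``effect_scale`` interpolates every 5xFAD mean between the matched
    wild-type mean (0, the null configuration used for calibration) and
    the default planted effect (1). Values are normal draws truncated at
    zero; one row per animal x region x marker x genotype.
    """
    rng = _rng(cfg.seed, _STREAM_COUNTS)
    rows = []
    truth: dict[str, dict] = {}
    for marker in markers:
        spec_m = COUNT_DEFAULTS[marker]
        truth[marker] = {}
        regions = sorted({r for r, _ in spec_m["values"]})
        for region in regions:
            wt_mean, wt_sd = spec_m["values"][(region, "WT")]
            tg_mean, tg_sd = spec_m["values"][(region, "5xFAD")]
            eff_mean = wt_mean + effect_scale * (tg_mean - wt_mean)
            for genotype, (mu, sd) in (
                ("WT", (wt_mean, wt_sd)),
                ("5xFAD", (eff_mean, tg_sd)),
            ):
                vals = np.clip(rng.normal(mu, sd, size=n_animals), 0.0, None)
                truth[marker][f"{region}/{genotype}"] = {"mean": mu, "sd": sd}
                for a, v in enumerate(vals):
                    rows.append(
                        {
                            "animal_id": f"{genotype}-{a + 1}",
                            "genotype": genotype,
                            "region": region,
                            "marker": marker,
                            "value": float(v),
                            "unit": spec_m["unit"],
                        }
                    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# dataset directory I/O


def write_dataset(cfg: SimConfig, out_dir) -> Path:
    """Materialize a full synthetic dataset directory.

    Layout: one multi-page TIFF per trial, a ``trials.csv`` manifest, the
    glomerular contour, the A11 profile (and rendered coronal section),
    per-odorant trajectory CSVs, ``counts.csv`` and ``ground_truth.json``.
    """
    out = Path(out_dir) / f"dataset_seed{cfg.seed}_{cfg.genotype}"
    (out / "imaging").mkdir(parents=True, exist_ok=True)
    (out / "behavior").mkdir(exist_ok=True)
    gt = GroundTruth()
    manifest = []
    for od in cfg.odorants:
        ts, gt.imaging[od] = simulate_odorant_trials(cfg, od)
        for i, tr in enumerate(ts.trials):
            rel = f"imaging/{od}_trial{i:02d}.tif"
            tifffile.imwrite(out / rel, tr.frames)
            manifest.append(
                {
                    "odorant": od,
                    "trial": i,
                    "path": rel,
                    "frame_rate_hz": tr.frame_rate,
                    "stim_onset_s": tr.stim_onset_s,
                    "stim_duration_s": tr.stim_duration_s,
                    "trial_length_s": tr.trial_length_s,
                    "um_per_px": cfg.um_per_px,
                    "genotype": cfg.genotype,
                }
            )
    pd.DataFrame(manifest).to_csv(out / "trials.csv", index=False)
    sagittal_contour(cfg.fov_px).to_csv(out / "contour_sagittal.csv")
    coronal_contour(cfg.fov_px).to_csv(out / "contour_coronal.csv")

    profile, image, gt.histology = generate_histology_profile(
        cfg, plane="sagittal", render_image=False
    )
    profile.to_csv(out / "a11_profile.csv")
    _, coronal_img, _ = generate_histology_profile(
        cfg, plane="coronal", render_image=True
    )
    tifffile.imwrite(out / "section_coronal.tif", coronal_img)

    for k, od in enumerate(cfg.odorants):
        test, t_truth = generate_trajectory(
            detects=detects_odorant(cfg.genotype, od),
            seed=cfg.seed * 1009 + 2 * k,
            condition=od,
        )
        ctrl, c_truth = generate_trajectory(
            detects=False, seed=cfg.seed * 1009 + 2 * k + 1, condition="MO"
        )
        test.to_csv(out / "behavior" / f"{od}_test.csv")
        ctrl.to_csv(out / "behavior" / f"{od}_control.csv")
        gt.behavior[od] = {"test": t_truth, "control": c_truth}

    counts, gt.counts = generate_count_tables(cfg)
    counts.to_csv(out / "counts.csv", index=False)
    gt.to_json(out / "ground_truth.json")
    (out / "sim_config.json").write_text(
        json.dumps(cfg.to_dict(), indent=2, sort_keys=True)
    )
    return out


def read_trialset(dataset_dir, odorant: str) -> TrialSet:
    """Load one odorant's trials back from a dataset directory."""
    root = Path(dataset_dir)
    manifest = pd.read_csv(root / "trials.csv")
    rows = manifest[manifest["odorant"] == odorant].sort_values("trial")
    if rows.empty:
        raise ValueError(f"no trials for odorant {odorant!r} in {root}")
    trials = [
        ImagingTrial(
            frames=tifffile.imread(root / r.path),
            frame_rate=float(r.frame_rate_hz),
            stim_onset_s=float(r.stim_onset_s),
            stim_duration_s=float(r.stim_duration_s),
            trial_length_s=float(r.trial_length_s),
        )
        for r in rows.itertuples()
    ]
    first = rows.iloc[0]
    return TrialSet(
        odorant=odorant,
        trials=trials,
        um_per_px=float(first["um_per_px"]),
        genotype=str(first["genotype"]),
    )
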