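"""Trial movies to odor activity maps.

Implements the widefield fura-2 analysis chain: pooled pre-stimulus
baseline (F0), per-frame relative change dF/F0, trial averaging with 1-s
binning, response-peak ROI detection with fixed 200-um outlines, and the
10 (anterior-posterior) x 180 (dorsoventral) analysis grid.

Single-wavelength fura-2 at 380-nm excitation DECREASES in fluorescence
when intracellular calcium rises, so raw activation is negative-going.
Summaries carry a ``sign`` flag: ``"raw"`` keeps that convention,
``"magnitude"`` reports absolute response size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy import ndimage

from .topography import AngularProfile

__all__ = [
    "ImagingTrial",
    "TrialSet",
    "DeltaFMap",
    "ActivityMap",
    "compute_baseline",
    "compute_dff",
    "average_trials",
    "response_image",
    "detect_activity_rois",
    "build_grid",
    "grid_dv_profile",
    "analyze_trialset",
]


@dataclass
class ImagingTrial:
    """One 20-s odor presentation recorded as a T x H x W movie."""

    frames: np.ndarray
    frame_rate: float
    stim_onset_s: float
    stim_duration_s: float = 2.0
    trial_length_s: float = 20.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if np.any(self.frames < 0):
            raise ValueError("fluorescence intensities must be non-negative")
        if self.stim_onset_s + self.stim_duration_s > self.trial_length_s:
            raise ValueError("stimulus extends past the end of the trial")
        expected = round(self.trial_length_s * self.frame_rate)
        if self.frames.shape[0] != expected:
            raise ValueError(
                f"expected {expected} frames for {self.trial_length_s} s at "
                f"{self.frame_rate} Hz, got {self.frames.shape[0]}"
            )

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.frames.shape[0]) / self.frame_rate


@dataclass
class TrialSet:
    """Repeated trials of one odorant for one animal."""

    odorant: str
    trials: list[ImagingTrial]
    um_per_px: float
    genotype: str = "WT"

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("a TrialSet needs at least one trial")
        shapes = {t.frames.shape for t in self.trials}
        rates = {t.frame_rate for t in self.trials}
        if len(shapes) != 1 or len(rates) != 1:
            raise ValueError("all trials must share shape and frame rate")

    @property
    def frame_rate(self) -> float:
        return self.trials[0].frame_rate


@dataclass
class DeltaFMap:
    """dF/F0 binned per second: S x H x W with S = trial_length bins."""

    dff: np.ndarray
    bin_edges_s: np.ndarray
    sign: str = "raw"  # "raw": activation-negative (380-nm fura-2)
    stim_onset_s: float | None = None
    stim_duration_s: float | None = None


@dataclass
class ActivityMap:
    """Per-ROI and gridded odor-evoked response summary."""

    grid: np.ndarray  # (10, 180): anterior-posterior x dorsoventral, NaN-coded
    rois: list[dict]
    roi_values: np.ndarray
    sign: str
    statistic: str
    odorant: str = ""
    genotype: str = ""

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("grid", data=self.grid)
            f.create_dataset("roi_values", data=self.roi_values)
            centers = np.array(
                [r["center_xy"] for r in self.rois], dtype=float
            ).reshape(-1, 2)
            f.create_dataset("roi_centers_xy", data=centers)
            f.attrs.update(
                sign=self.sign,
                statistic=self.statistic,
                odorant=self.odorant,
                genotype=self.genotype,
            )

    def grid_to_csv(self, path) -> None:
        n_ap, n_dv = self.grid.shape
        ap, dv = np.meshgrid(np.arange(n_ap), np.arange(n_dv), indexing="ij")
        pd.DataFrame(
            {
                "ap_bin": ap.ravel(),
                "dv_bin": dv.ravel(),
                "value": self.grid.ravel(),
            }
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------


def compute_baseline(
    trialset: TrialSet,
    window_s: float = 3.0,
    exclude_trials: tuple[int, ...] = (),
) -> np.ndarray:
    """Baseline F0: per-pixel mean over the pre-stimulus window pooled
    across trials.

    The window is the ``window_s`` seconds immediately before stimulus
    onset; every trial must have at least that much pre-stimulus time.
    """
    chunks = []
    for i, tr in enumerate(trialset.trials):
        if i in exclude_trials:
            continue
        if tr.stim_onset_s < window_s - 1e-9:
            raise ValueError(
                f"trial {i}: stimulus onset {tr.stim_onset_s} s leaves less "
                f"than the {window_s}-s baseline window"
            )
        i1 = int(round(tr.stim_onset_s * tr.frame_rate))
        i0 = i1 - int(round(window_s * tr.frame_rate))
        chunks.append(tr.frames[i0:i1].astype(np.float64).sum(axis=0))
    n_frames = sum(
        int(round(window_s * tr.frame_rate))
        for i, tr in enumerate(trialset.trials)
        if i not in exclude_trials
    )
    if not chunks:
        raise ValueError("no trials left after exclusion")
    return np.sum(chunks, axis=0) / n_frames


def compute_dff(
    trial: ImagingTrial, f0: np.ndarray
) -> tuple[np.ndarray, int]:
    """Per-frame relative change (F - F0) / F0.

    Pixels with non-positive F0 are masked to NaN; their count is returned
    alongside the T x H x W dF/F0 array.
    """
    f0 = np.asarray(f0, dtype=np.float64)
    bad = ~(f0 > 0)
    n_bad = int(bad.sum())
    safe = np.where(bad, 1.0, f0)
    dff = (trial.frames.astype(np.float64) - safe) / safe
    if n_bad:
        dff[:, bad] = np.nan
    return dff, n_bad


def _bin_per_second(dff: np.ndarray, frame_rate: float, length_s: float) -> tuple[np.ndarray, np.ndarray]:
    n_bins = int(round(length_s))
    t = np.arange(dff.shape[0]) / frame_rate
    edges = np.arange(n_bins + 1, dtype=float)
    idx = np.searchsorted(t, edges)
    binned = np.stack(
        [dff[idx[k] : idx[k + 1]].mean(axis=0) for k in range(n_bins)]
    )
    return binned, edges


def average_trials(
    trialset: TrialSet,
    f0: np.ndarray | None = None,
    exclude_trials: tuple[int, ...] = (),
) -> DeltaFMap:
    """Trial-averaged dF/F0, binned per second over the full trial.

    Trials listed in ``exclude_trials`` (manually identified artifacts)
    are dropped from both the baseline pool and the average. The mean
    across trials is taken per frame, then frames are averaged within each
    1-s bin.
    """
    keep = [
        tr for i, tr in enumerate(trialset.trials) if i not in exclude_trials
    ]
    if not keep:
        raise ValueError("no trials left after exclusion")
    if f0 is None:
        f0 = compute_baseline(trialset, exclude_trials=exclude_trials)
    # dF/F0 is linear in F, so averaging frames across trials first is
    # identical to averaging per-trial dF/F0 maps (one pass instead of n)
    acc = np.zeros(keep[0].frames.shape, dtype=np.float32)
    for tr in keep:
        acc += tr.frames
    acc = acc.astype(np.float64) / len(keep)
    f0_arr = np.asarray(f0, dtype=np.float64)
    bad = ~(f0_arr > 0)
    safe = np.where(bad, 1.0, f0_arr)
    mean_dff = (acc - safe) / safe
    if bad.any():
        mean_dff[:, bad] = np.nan
    ref = keep[0]
    binned, edges = _bin_per_second(mean_dff, ref.frame_rate, ref.trial_length_s)
    return DeltaFMap(
        dff=binned,
        bin_edges_s=edges,
        sign="raw",
        stim_onset_s=ref.stim_onset_s,
        stim_duration_s=ref.stim_duration_s,
    )


def response_image(
    dmap: DeltaFMap,
    sign: str = "magnitude",
    statistic: str = "mean",
) -> np.ndarray:
    """Collapse the stimulus-window bins into one H x W response image.

    ``statistic`` is ``"mean"`` (default) or ``"sum"`` ("cumulated
    signal") over the bins covering [onset, onset + stimulus duration).
    ``sign="magnitude"`` returns absolute values; ``"raw"`` keeps the
    activation-negative convention.
    """
    if dmap.stim_onset_s is None:
        raise ValueError("DeltaFMap lacks stimulus timing metadata")
    lo = dmap.stim_onset_s
    hi = dmap.stim_onset_s + (dmap.stim_duration_s or 0.0)
    centers = 0.5 * (dmap.bin_edges_s[:-1] + dmap.bin_edges_s[1:])
    sel = (centers >= lo) & (centers < hi)
    if not sel.any():
        raise ValueError("no bins fall inside the stimulus window")
    img = dmap.dff[sel].sum(axis=0) if statistic == "sum" else dmap.dff[sel].mean(axis=0)
    if statistic not in ("mean", "sum"):
        raise ValueError("statistic must be 'mean' or 'sum'")
    if sign == "magnitude":
        return np.abs(img)
    if sign == "raw":
        return img
    raise ValueError("sign must be 'raw' or 'magnitude'")


def detect_activity_rois(
    resp: np.ndarray,
    um_per_px: float,
    k_mad: float = 3.0,
    min_separation_um: float = 200.0,
    radius_um: float = 200.0,
) -> list[dict]:
    """Detect response peaks and outline each with a fixed 200-um disk.

    A stand-in for interactive peak-picking plugins: local maxima of the
    response magnitude exceeding ``median + k_mad * MAD``, kept in
    decreasing order of magnitude with a minimum mutual separation. Each
    ROI is a disk of ``radius_um`` clipped to the image.
    """
    a = np.abs(np.asarray(resp, dtype=float))
    finite = a[np.isfinite(a)]
    if finite.size == 0:
        return []
    med = float(np.median(finite))
    mad = float(np.median(np.abs(finite - med)))
    thr = med + k_mad * mad
    work = np.where(np.isfinite(a), a, -np.inf)
    footprint = np.ones((3, 3), dtype=bool)
    is_peak = (ndimage.maximum_filter(work, footprint=footprint) == work) & (
        work > thr
    )
    ys, xs = np.nonzero(is_peak)
    if len(ys) == 0:
        return []
    order = np.argsort(work[ys, xs])[::-1]
    min_sep_px = min_separation_um / um_per_px
    radius_px = int(round(radius_um / um_per_px))
    kept: list[tuple[float, float]] = []
    rois: list[dict] = []
    for j in order:
        cy, cx = float(ys[j]), float(xs[j])
        if any(math.hypot(cy - ky, cx - kx) < min_sep_px for ky, kx in kept):
            continue
        kept.append((cy, cx))
        rois.append(
            {
                "center_xy": (cx, cy),
                "radius_px": radius_px,
                "peak_value": float(work[int(cy), int(cx)]),
            }
        )
    return rois


def roi_mask(roi: dict, shape: tuple[int, int]) -> np.ndarray:
    """Boolean disk mask for one detected ROI, clipped to the image."""
    cx, cy = roi["center_xy"]
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= roi["radius_px"] ** 2


def build_grid(
    resp: np.ndarray,
    mask: np.ndarray,
    n_ap: int = 10,
    n_dv: int = 180,
) -> np.ndarray:
    """Average the response over a grid of equal sections of the bulb.

    The bulb's bounding box is split into ``n_ap`` equal anterior-posterior
    columns and ``n_dv`` equal dorsoventral rows; each cell holds the mean
    response of its in-mask area. When sections are finer than a pixel the
    image is replicated to subpixel resolution first, so each cell's value
    is the area-weighted mean of the pixels it overlaps; cells whose area
    contains no bulb are NaN ("missing"). Returns an (n_ap, n_dv) matrix.
    """
    resp = np.asarray(resp, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if resp.shape != mask.shape:
        raise ValueError("response and mask shapes differ")
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    if rows.size == 0:
        raise ValueError("empty bulb mask")
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    sub_r = resp[r0:r1, c0:c1]
    sub_m = mask[r0:r1, c0:c1]
    h, w = sub_m.shape
    fy = max(1, math.ceil(n_dv / h))
    fx = max(1, math.ceil(n_ap / w))
    if fy > 1 or fx > 1:
        sub_r = np.repeat(np.repeat(sub_r, fy, axis=0), fx, axis=1)
        sub_m = np.repeat(np.repeat(sub_m, fy, axis=0), fx, axis=1)
        h, w = sub_m.shape
    dv_idx = np.minimum((np.arange(h) * n_dv) // h, n_dv - 1)
    ap_idx = np.minimum((np.arange(w) * n_ap) // w, n_ap - 1)
    cell_of = ap_idx[None, :] * n_dv + dv_idx[:, None]
    valid = sub_m & np.isfinite(sub_r)
    flat_cells = cell_of[valid]
    counts = np.bincount(flat_cells, minlength=n_ap * n_dv)
    sums = np.bincount(flat_cells, weights=sub_r[valid], minlength=n_ap * n_dv)
    with np.errstate(invalid="ignore"):
        grid = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return grid.reshape(n_ap, n_dv)


def grid_dv_profile(grid: np.ndarray, plane: str = "sagittal") -> AngularProfile:
    """Collapse the grid to a dorsoventral angular profile.

    The 180 dorsoventral sections are read as the 1-degree bins of the
    sagittal 0-180 scale; each bin is the missing-aware mean over the
    anterior-posterior sections.
    """
    n_ap, n_dv = grid.shape
    span = 180.0 if plane == "sagittal" else 360.0
    edges = np.linspace(0.0, span, n_dv + 1)
    n = np.isfinite(grid).sum(axis=0)
    with np.errstate(invalid="ignore"):
        vals = np.nanmean(np.where(np.isfinite(grid), grid, np.nan), axis=0)
    vals = np.where(n > 0, vals, np.nan)
    return AngularProfile(plane, edges, vals, n)


def analyze_trialset(
    trialset: TrialSet,
    mask: np.ndarray,
    exclude_trials: tuple[int, ...] = (),
    sign: str = "magnitude",
    statistic: str = "mean",
    detect_rois: bool = True,
) -> ActivityMap:
    """Full per-odorant chain: baseline -> dF/F0 -> trial average ->
    stimulus-window response -> ROIs + 10 x 180 grid."""
    dmap = average_trials(trialset, exclude_trials=exclude_trials)
    resp = response_image(dmap, sign=sign, statistic=statistic)
    rois = (
        detect_activity_rois(resp, trialset.um_per_px) if detect_rois else []
    )
    roi_values = np.array([r["peak_value"] for r in rois])
    grid = build_grid(np.where(mask, resp, np.nan), mask)
    return ActivityMap(
        grid=grid,
        rois=rois,
        roi_values=roi_values,
        sign=sign,
        statistic=statistic,
        odorant=trialset.odorant,
        genotype=trialset.genotype,
    )
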