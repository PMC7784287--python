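"""Stain quantification: H-DAB color deconvolution, percent staining area,
reciprocal intensity, angle-resolved immunoreactivity profiles, normalized
region ratios, and marker-count summaries.

Color deconvolution follows the standard optical-density model: a
transmitted 8-bit RGB intensity ``I`` corresponds to
``OD = -log10(I / 255)`` per channel, and the OD vector of a pixel is a
non-negative mixture of unit stain vectors (hematoxylin, DAB, residual).
Unmixing multiplies the OD vector by the inverse of the stain matrix;
small negative loadings from noise are clipped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .topography import (
    AngularProfile,
    GlomerularContour,
    assign_angles,
    build_profile,
    profile_region_summary,
)

_EPS_I = 1e-6  # intensity floor inside the log; a 255 pixel maps to OD 0

__all__ = [
    "StainVectors",
    "color_deconvolve",
    "stains_to_rgb",
    "percent_stain_area",
    "reciprocal_intensity",
    "angular_immunoreactivity",
    "region_ratio",
    "summarize_counts",
]


@dataclass
class StainVectors:
    """Unit optical-density vectors of the stains (rows: H, DAB, residual)."""

    matrix: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.matrix is None:
            h = np.array([0.650, 0.704, 0.286])
            dab = np.array([0.269, 0.568, 0.778])
            res = np.cross(h, dab)
            self.matrix = np.stack([h, dab, res])
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        norms = np.linalg.norm(self.matrix, axis=1)
        if np.any(norms <= 0):
            raise ValueError("stain vectors must be non-zero")
        self.matrix = self.matrix / norms[:, None]
        if abs(np.linalg.det(self.matrix)) < 1e-8:
            raise ValueError("stain matrix is singular")

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Per-channel optical density of an RGB image (any float/int dtype,
    0-255 scale)."""
    img = np.asarray(rgb, dtype=float)
    return -np.log10(np.maximum(img, _EPS_I) / 255.0)


def od_to_rgb(od: np.ndarray, quantize: bool = True) -> np.ndarray:
    """Transmitted intensity for a per-channel OD image (Beer-Lambert)."""
    inten = 255.0 * np.power(10.0, -np.asarray(od, dtype=float))
    if quantize:
        return np.clip(np.round(inten), 0, 255).astype(np.uint8)
    return inten


def stains_to_rgb(
    stain_od: np.ndarray,
    vectors: StainVectors | None = None,
    quantize: bool = True,
) -> np.ndarray:
    """Forward model: render per-stain ODs (..., 3) as an RGB image."""
    vectors = vectors or StainVectors()
    od_rgb = np.asarray(stain_od, dtype=float) @ vectors.matrix
    return od_to_rgb(od_rgb, quantize=quantize)


def color_deconvolve(
    rgb: np.ndarray, vectors: StainVectors | None = None
) -> np.ndarray:
    """Unmix an RGB image into per-stain optical densities.

    Returns an array with shape ``rgb.shape`` where the last axis indexes
    (hematoxylin, DAB, residual); negative loadings are clipped to zero.
    """
    vectors = vectors or StainVectors()
    img = np.asarray(rgb)
    if img.shape[-1] != 3:
        raise ValueError("expected an RGB image with a trailing size-3 axis")
    od = rgb_to_od(img)
    stains = od @ vectors.inverse
    return np.clip(stains, 0.0, None)


def percent_stain_area(
    stain_od: np.ndarray,
    threshold: float = 0.15,
    mask: np.ndarray | None = None,
) -> float:
    """Percent of the region whose stain OD exceeds the positivity
    threshold."""
    od = np.asarray(stain_od, dtype=float)
    if mask is None:
        mask = np.ones(od.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty region")
    return 100.0 * float((od[mask] > threshold).sum()) / n


def reciprocal_intensity(
    gray: np.ndarray,
    mask: np.ndarray | None = None,
    area_mm2: float = 1.0,
) -> float:
    """Reciprocal staining intensity per unit area.

    Operationalized as ``(255 - mean 8-bit intensity of the region)``
    divided by the region area in square millimeters, so darker (more
    stained) regions score higher.
    """
    img = np.asarray(gray, dtype=float)
    if mask is None:
        mask = np.ones(img.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region")
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    return (255.0 - float(img[mask].mean())) / area_mm2


def angular_immunoreactivity(
    rgb: np.ndarray,
    contour: GlomerularContour,
    tissue_mask: np.ndarray | None = None,
    vectors: StainVectors | None = None,
    bin_width_deg: float = 1.0,
    max_dist_px: float | None = None,
    value: str = "mean_od",
    area_threshold: float = 0.15,
) -> AngularProfile:
    """Angle-resolved DAB immunoreactivity of a stained section.

    Deconvolves the image, assigns every in-mask pixel an angular position
    along the glomerular-layer contour, and bins the DAB signal into
    1-degree sections. ``value`` selects the per-bin statistic:
    ``"mean_od"`` (default, used by the correlation analyses) or
    ``"area_fraction"`` (fraction of pixels above the positivity
    threshold).
    """
    stains = color_deconvolve(rgb, vectors)
    dab = stains[..., 1]
    if tissue_mask is None:
        tissue_mask = np.ones(dab.shape, dtype=bool)
    ys, xs = np.nonzero(np.asarray(tissue_mask, dtype=bool))
    pts = np.column_stack([xs, ys]).astype(float)
    angles, _ = assign_angles(pts, contour, max_dist=max_dist_px)
    vals = dab[ys, xs]
    if value == "area_fraction":
        vals = (vals > area_threshold).astype(float)
    elif value != "mean_od":
        raise ValueError("value must be 'mean_od' or 'area_fraction'")
    return build_profile(angles, vals, plane=contour.plane, bin_width_deg=bin_width_deg)


def region_ratio(
    wt_profile: AngularProfile, tg_profile: AngularProfile
) -> dict[str, float]:
    """Region means of both genotypes normalized so WT-dorsal equals 1.00.

    Returns the quadruple ``wt_dorsal`` (=1), ``tg_dorsal``,
    ``wt_ventral``, ``tg_ventral``.
    """
    wt = profile_region_summary(wt_profile)
    tg = profile_region_summary(tg_profile)
    ref = wt["dorsal"]
    if not np.isfinite(ref) or ref == 0:
        raise ValueError("WT dorsal mean is missing or zero; cannot normalize")
    return {
        "wt_dorsal": wt["dorsal"] / ref,
        "tg_dorsal": tg["dorsal"] / ref,
        "wt_ventral": wt["ventral"] / ref,
        "tg_ventral": tg["ventral"] / ref,
    }


def summarize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean, SD, SEM and n by marker x region x genotype.

    SEM (and SD) are missing for single-animal groups.
    """
    needed = {"genotype", "region", "marker", "value"}
    missing = needed - set(counts.columns)
    if missing:
        raise ValueError(f"count table lacks columns {sorted(missing)}")
    g = counts.groupby(["marker", "region", "genotype"])["value"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out
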