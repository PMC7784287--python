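"""Angular ("numeric scale") registration of the glomerular layer.

Any measurement made on or near the glomerular layer of the olfactory bulb —
an imaging ROI, a DAB-stained pixel — is mapped to a degree position along
the dorsoventral extent of the layer, so that measurements from different
anatomical planes and modalities become comparable on a common axis.

Two constructions are used, matching the two section geometries:

* ``sagittal`` — the glomerular layer is an open contour swept from its
  dorsal-most point (``0``, the "degree of zero") to its ventral-most point
  (``180``). A point is projected onto the contour and its angle is the
  normalized arc length of the projection: ``180 * s / S``.
* ``coronal`` — the layer rings the section; the angle is the polar angle
  of the point about the section center, measured from the ray through the
  zero landmark (the point on the upper rostral-migratory-stream track),
  in ``[0, 360)`` and increasing in the direction the contour is ordered.

Image pixel coordinates are used throughout (origin top-left, y increasing
downward, so dorsal structures have smaller y).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GlomerularContour",
    "AngularProfile",
    "assign_angle",
    "assign_angles",
    "build_profile",
    "region_classify",
    "profile_region_summary",
]


@dataclass
class GlomerularContour:
    """An ordered trace of the glomerular layer in one section.

    Parameters
    ----------
    plane:
        ``"sagittal"`` (open contour, angles on [0, 180]) or ``"coronal"``
        (closed ring, angles on [0, 360)).
    points:
        ``(n, 2)`` array of ``(x, y)`` pixel coordinates, ordered along the
        layer starting at the zero landmark for sagittal contours.
    zero_index:
        Index of the zero landmark ("top of the glomeruli").
    center:
        Section center for the coronal polar construction; defaults to the
        contour centroid.
    """

    plane: str
    points: np.ndarray
    zero_index: int = 0
    center: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.plane not in ("sagittal", "coronal"):
            raise ValueError("plane must be 'sagittal' or 'coronal'")
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.points) < 3:
            raise ValueError("a contour needs at least 3 points")
        if not 0 <= self.zero_index < len(self.points):
            raise ValueError("zero_index must index a contour point")
        if self.center is not None:
            self.center = np.asarray(self.center, dtype=float)

    # -- derived geometry -------------------------------------------------

    @property
    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at each vertex (starts at 0)."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        return float(self.arc_lengths[-1])

    def effective_center(self) -> np.ndarray:
        if self.center is not None:
            return self.center
        return self.points.mean(axis=0)

    def orientation(self) -> float:
        """+1 if the ring is ordered counterclockwise in (x, y), else -1.

        In image coordinates (y down) a visually clockwise sweep from
        dorsal through lateral to ventral is counterclockwise in raw
        (x, y) algebra; the sign only fixes which way angles increase.
        """
        pts = self.points
        x, y = pts[:, 0], pts[:, 1]
        area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        return 1.0 if area2 > 0 else -1.0

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.points, columns=["x", "y"])
        df["is_zero_landmark"] = 0
        df.loc[self.zero_index, "is_zero_landmark"] = 1
        if self.center is not None:
            df["center_x"] = self.center[0]
            df["center_y"] = self.center[1]
        df.insert(0, "plane", self.plane)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GlomerularContour":
        df = pd.read_csv(path)
        plane = str(df["plane"].iloc[0])
        zero = int(df.index[df["is_zero_landmark"] == 1][0])
        center = None
        if "center_x" in df.columns:
            center = np.array([df["center_x"].iloc[0], df["center_y"].iloc[0]])
        return cls(plane, df[["x", "y"]].to_numpy(), zero, center)


@dataclass
class AngularProfile:
    """Values indexed by angular position along the glomerular layer."""

    plane: str
    bin_edges: np.ndarray  # (n_bins + 1,) degrees, contiguous, equal width
    values: np.ndarray  # (n_bins,), NaN where no data
    n_contributing: np.ndarray  # (n_bins,) ints

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_contributing = np.asarray(self.n_contributing, dtype=int)
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("bins must have equal width")
        if len(self.values) != len(self.bin_edges) - 1:
            raise ValueError("values/bin_edges length mismatch")
        if len(self.n_contributing) != len(self.values):
            raise ValueError("n_contributing/values length mismatch")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "bin_start_deg": self.bin_edges[:-1],
                "bin_end_deg": self.bin_edges[1:],
                "value": self.values,
                "n": self.n_contributing,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, plane: str = "sagittal") -> "AngularProfile":
        df = pd.read_csv(path)
        edges = np.concatenate(
            [df["bin_start_deg"].to_numpy(), [df["bin_end_deg"].iloc[-1]]]
        )
        return cls(plane, edges, df["value"].to_numpy(), df["n"].to_numpy())


def domain_span(plane: str) -> float:
    return 180.0 if plane == "sagittal" else 360.0


def _project_to_polyline(
    points: np.ndarray, poly: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Project query points onto a polyline.

    Returns ``(arc, dist)``: arc length of each projection foot measured
    from the first vertex, and the projection distance.
    """
    p0 = poly[:-1]  # (S, 2)
    seg = poly[1:] - p0  # (S, 2)
    seg_len2 = np.maximum((seg**2).sum(axis=1), 1e-300)
    q = np.asarray(points, dtype=float)[:, None, :]  # (P, 1, 2)
    t = ((q - p0) * seg).sum(axis=2) / seg_len2  # (P, S)
    t = np.clip(t, 0.0, 1.0)
    foot = p0 + t[..., None] * seg  # (P, S, 2)
    d2 = ((q - foot) ** 2).sum(axis=2)  # (P, S)
    best = np.argmin(d2, axis=1)
    idx = np.arange(len(q))
    seg_len = np.sqrt(seg_len2)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    arc = cum[best] + t[idx, best] * seg_len[best]
    dist = np.sqrt(d2[idx, best])
    return arc, dist


def assign_angles(
    points: np.ndarray,
    contour: GlomerularContour,
    max_dist: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`assign_angle`.

    Returns ``(angles_deg, accepted)``; rejected points (farther than
    ``max_dist`` from the contour, in the same units as the coordinates)
    carry NaN angles and ``accepted=False``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if contour.plane == "sagittal":
        arc, dist = _project_to_polyline(pts, contour.points)
        total = contour.total_length
        if total <= 0:
            raise ValueError("degenerate contour with zero length")
        ang = 180.0 * arc / total
    else:
        c = contour.effective_center()
        zero_vec = contour.points[contour.zero_index] - c
        phi0 = np.arctan2(zero_vec[1], zero_vec[0])
        v = pts - c
        phi = np.arctan2(v[:, 1], v[:, 0])
        ang = np.degrees(contour.orientation() * (phi - phi0)) % 360.0
        _, dist = _project_to_polyline(pts, contour.points)
    accepted = np.ones(len(pts), dtype=bool)
    if max_dist is not None:
        accepted = dist <= max_dist
        ang = np.where(accepted, ang, np.nan)
    return ang, accepted


def assign_angle(
    point, contour: GlomerularContour, max_dist: float | None = None
) -> float:
    """Map one point to its degree position along the glomerular layer.

    Sagittal: normalized arc length of the nearest-point projection,
    scaled to [0, 180]. Coronal: polar angle about the section center,
    from the zero-landmark ray, in [0, 360).

    Raises ``ValueError`` if the point lies farther than ``max_dist`` from
    the contour.
    """
    ang, ok = assign_angles(np.asarray(point)[None, :], contour, max_dist)
    if not ok[0]:
        raise ValueError(
            f"point {tuple(np.asarray(point))} is farther than {max_dist} "
            "from the contour; excluded"
        )
    return float(ang[0])


def build_profile(
    angles_deg,
    values,
    plane: str = "sagittal",
    bin_width_deg: float = 1.0,
) -> AngularProfile:
    """Bin values by angular position (per-bin mean).

    Empty bins are NaN ("missing-coded"); ``n_contributing`` sums to the
    number of accepted (finite-angle, finite-value) inputs.
    """
    angles = np.asarray(angles_deg, dtype=float).ravel()
    vals = np.asarray(values, dtype=float).ravel()
    if angles.shape != vals.shape:
        raise ValueError("angles and values must have the same length")
    span = domain_span(plane)
    n_bins = int(round(span / bin_width_deg))
    if not np.isclose(n_bins * bin_width_deg, span):
        raise ValueError("bin width must divide the angular domain evenly")
    edges = np.linspace(0.0, span, n_bins + 1)
    ok = np.isfinite(angles) & np.isfinite(vals)
    angles, vals = angles[ok], vals[ok]
    if plane == "coronal":
        angles = angles % 360.0
    idx = np.clip(np.floor(angles / bin_width_deg).astype(int), 0, n_bins - 1)
    n = np.bincount(idx, minlength=n_bins)
    s = np.bincount(idx, weights=vals, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    return AngularProfile(plane, edges, mean, n)


def region_classify(
    angle_deg: float, plane: str = "sagittal", half_width_deg: float = 80.0
) -> str:
    """Classify an angle as ``dorsal`` (0 ± 80°), ``ventral`` (180 ± 80°),
    or ``unassigned``."""
    span = domain_span(plane)
    a = float(angle_deg) % 360.0 if plane == "coronal" else float(angle_deg)
    if plane == "coronal":
        d_dorsal = min(a, 360.0 - a)
        d_ventral = abs(a - 180.0)
    else:
        if not 0.0 <= a <= span:
            raise ValueError("sagittal angles must lie in [0, 180]")
        d_dorsal = a
        d_ventral = abs(a - 180.0)
    if d_dorsal <= half_width_deg:
        return "dorsal"
    if d_ventral <= half_width_deg:
        return "ventral"
    return "unassigned"


def profile_region_summary(
    profile: AngularProfile, half_width_deg: float = 80.0
) -> dict[str, float]:
    """Missing-aware mean of profile values over the dorsal and ventral
    angular regions."""
    out: dict[str, list[float]] = {"dorsal": [], "ventral": []}
    for center, value in zip(profile.bin_centers, profile.values):
        if not np.isfinite(value):
            continue
        region = region_classify(center, profile.plane, half_width_deg)
        if region in out:
            out[region].append(value)
    return {
        k: (float(np.mean(v)) if v else float("nan")) for k, v in out.items()
    }
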