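"""Idealized olfactory-bulb geometry shared by the generator and tests.

The lateral (sagittal) view of one bulb is modeled as a filled ellipse
centered in the field of view. The glomerular layer available to the
dorsoventral angular sweep is the anterior half of the rim, traced from the
dorsal-most point (0 degrees) to the ventral-most point (180 degrees). A
coronal section is modeled as a full elliptical ring with the zero landmark
at the top (on the upper rostral-migratory-stream track).
"""

from __future__ import annotations

import numpy as np

from .topography import GlomerularContour


def bulb_mask(fov_px: int, fill: float = 0.9) -> np.ndarray:
    """Boolean mask of the bulb: an ellipse spanning ``fill`` of the FOV."""
    c = (fov_px - 1) / 2.0
    a = fill * fov_px / 2.0  # anterior-posterior semi-axis (x)
    b = fill * fov_px / 2.0  # dorsoventral semi-axis (y)
    yy, xx = np.mgrid[0:fov_px, 0:fov_px]
    return ((xx - c) / a) ** 2 + ((yy - c) / b) ** 2 <= 1.0


def sagittal_contour(fov_px: int, fill: float = 0.9, n: int = 361) -> GlomerularContour:
    """Anterior semicircular glomerular-layer contour, dorsal to ventral."""
    c = (fov_px - 1) / 2.0
    a = fill * fov_px / 2.0
    b = fill * fov_px / 2.0
    t = np.linspace(0.0, np.pi, n)
    x = c - a * np.sin(t)  # sweeps toward the anterior (left) rim
    y = c - b * np.cos(t)  # dorsal (top) at t=0, ventral (bottom) at t=pi
    return GlomerularContour("sagittal", np.column_stack([x, y]), zero_index=0)


def coronal_contour(fov_px: int, fill: float = 0.8, n: int = 361) -> GlomerularContour:
    """Closed ring contour with the zero landmark at the top of the section."""
    c = (fov_px - 1) / 2.0
    r = fill * fov_px / 2.0
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    x = c + r * np.sin(t)
    y = c - r * np.cos(t)  # starts dorsal, proceeds through x>center side
    return GlomerularContour(
        "coronal", np.column_stack([x, y]), zero_index=0, center=np.array([c, c])
    )


def point_at_angle(contour: GlomerularContour, angle_deg: float) -> np.ndarray:
    """Inverse of the sagittal arc-length parameterization.

    Returns the (x, y) point whose normalized arc length corresponds to
    ``angle_deg`` on the [0, 180] scale.
    """
    if contour.plane != "sagittal":
        raise ValueError("point_at_angle is defined for sagittal contours")
    s = contour.total_length * float(angle_deg) / 180.0
    arcs = contour.arc_lengths
    x = np.interp(s, arcs, contour.points[:, 0])
    y = np.interp(s, arcs, contour.points[:, 1])
    return np.array([x, y])
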