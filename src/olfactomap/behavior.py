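"""Behavioral readouts: zone occupancy, performance index, occupancy heat
maps, normalized food-seeking latency, and Y-maze alternation.

A tracked session is a table of point-of-interest coordinates (nose, both
ears, tail) at 30 frames/s in a rectangular test cage divided into three
equal compartments along its long axis; the odorant (cotton-tip) compartment
is identified in the session metadata. The performance index (PI) is the
percentage of session time spent in the odorant compartment under the
experimental odorant minus the same percentage under the mineral-oil
control: PI = 100 means definitive detection, PI near 0 means the odor was
not distinguished from control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POIS = ("nose", "earL", "earR", "tail")

__all__ = [
    "TrajectorySession",
    "zone_occupancy",
    "performance_index",
    "occupancy_heatmap",
    "normalize_latency",
    "ymaze_alternation",
]


@dataclass
class TrajectorySession:
    """Time-stamped POI coordinates plus cage and zone geometry.

    ``frames`` columns: ``t_s`` and ``<poi>_x``/``<poi>_y`` for each of
    nose, earL, earR, tail. Coordinates outside the cage must be
    missing-coded (NaN). ``odor_zone`` indexes the compartment (0, 1, 2
    along the long axis) holding the scented cotton tip.
    """

    frames: pd.DataFrame
    fps: float = 30.0
    cage_size: tuple[float, float] = (30.0, 15.0)  # (long, short) axis, cm
    odor_zone: int = 0
    condition: str = "odorant"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.odor_zone not in (0, 1, 2):
            raise ValueError("odor_zone must be 0, 1 or 2")
        needed = {"t_s"} | {f"{p}_{ax}" for p in POIS for ax in ("x", "y")}
        missing = needed - set(self.frames.columns)
        if missing:
            raise ValueError(f"trajectory table lacks columns {sorted(missing)}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def point(self, poi: str = "nose") -> np.ndarray:
        """(n, 2) coordinates of one POI, or the 4-POI centroid."""
        if poi == "centroid":
            xs = np.mean([self.frames[f"{p}_x"].to_numpy() for p in POIS], axis=0)
            ys = np.mean([self.frames[f"{p}_y"].to_numpy() for p in POIS], axis=0)
            return np.column_stack([xs, ys])
        if poi not in POIS:
            raise ValueError(f"unknown POI {poi!r}")
        return self.frames[[f"{poi}_x", f"{poi}_y"]].to_numpy()

    def to_csv(self, path) -> None:
        df = self.frames.copy()
        df.insert(0, "frame", np.arange(len(df)))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kw) -> "TrajectorySession":
        df = pd.read_csv(path)
        df = df.drop(columns=[c for c in ("frame",) if c in df.columns])
        return cls(df, **kw)


def _zone_of(x: np.ndarray, cage_long: float) -> np.ndarray:
    """Compartment index (0, 1, 2) of each x position along the long axis."""
    z = np.floor(3.0 * x / cage_long).astype(float)
    z[~np.isfinite(x)] = np.nan
    return np.clip(z, 0, 2)


def zone_occupancy(
    session: TrajectorySession, poi: str = "nose"
) -> dict:
    """Fraction of valid frames spent in each of the three compartments.

    Frames whose tracked point is missing are excluded from the
    denominator and counted separately. Fractions sum to 1 over valid
    frames.
    """
    xy = session.point(poi)
    zones = _zone_of(xy[:, 0], session.cage_size[0])
    valid = np.isfinite(zones)
    n_valid = int(valid.sum())
    fractions = np.zeros(3)
    if n_valid:
        counts = np.bincount(zones[valid].astype(int), minlength=3)
        fractions = counts / n_valid
    return {
        "fractions": fractions,
        "odor_zone_fraction": float(fractions[session.odor_zone]),
        "n_valid": n_valid,
        "n_missing": int((~valid).sum()),
    }


def performance_index(pct_exp: float, pct_ctrl: float) -> float:
    """PI = percentage of time on the experimental odorant minus the
    percentage in the control condition (percentage points, in
    [-100, 100])."""
    for name, v in (("pct_exp", pct_exp), ("pct_ctrl", pct_ctrl)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must be a percentage in [0, 100]")
    return float(pct_exp) - float(pct_ctrl)


def session_pi(
    test: TrajectorySession,
    control: TrajectorySession,
    poi: str = "nose",
) -> float:
    """PI from a matched pair of sessions (experimental odorant vs
    mineral-oil control), as percent of valid session time."""
    occ_t = zone_occupancy(test, poi)
    occ_c = zone_occupancy(control, poi)
    return performance_index(
        100.0 * occ_t["odor_zone_fraction"], 100.0 * occ_c["odor_zone_fraction"]
    )


def occupancy_heatmap(
    session: TrajectorySession,
    grid: tuple[int, int] = (30, 15),
    poi: str = "nose",
) -> np.ndarray:
    """Dwell time (seconds) per spatial cell; cells tile the cage.

    The total over cells equals the valid-frame duration
    ``n_valid / fps``.
    """
    nx, ny = grid
    xy = session.point(poi)
    lx, ly = session.cage_size
    valid = np.isfinite(xy).all(axis=1)
    ix = np.clip((xy[valid, 0] / lx * nx).astype(int), 0, nx - 1)
    iy = np.clip((xy[valid, 1] / ly * ny).astype(int), 0, ny - 1)
    counts = np.bincount(iy * nx + ix, minlength=nx * ny).reshape(ny, nx)
    return counts / session.fps


def normalize_latency(
    latencies_s,
    wt_latencies_s,
    cutoff_s: float = 600.0,
) -> pd.DataFrame:
    """Normalize food-seeking latencies by the wild-type mean latency.

    Observations at the recording cutoff (10 min by default) are flagged
    as censored; they still enter the normalization as recorded, matching
    the fixed-cutoff protocol.
    """
    lat = np.asarray(latencies_s, dtype=float)
    wt = np.asarray(wt_latencies_s, dtype=float)
    if wt.size == 0 or not np.isfinite(wt).any():
        raise ValueError("need at least one wild-type latency")
    wt_mean = float(np.nanmean(wt))
    if wt_mean <= 0:
        raise ValueError("wild-type mean latency must be positive")
    return pd.DataFrame(
        {
            "latency_s": lat,
            "normalized_latency": lat / wt_mean,
            "censored": lat >= cutoff_s,
        }
    )


def ymaze_alternation(entries) -> float:
    """Spontaneous alternation percentage from an arm-entry sequence.

    An actual alternation is a window of three consecutive entries visiting
    all three arms; the score is
    ``100 * actual / (total entries - 2)``. Undefined (NaN) for fewer than
    three entries.
    """
    seq = [str(e) for e in entries]
    bad = set(seq) - {"A", "B", "C"}
    if bad:
        raise ValueError(f"unknown arm labels: {sorted(bad)}")
    n = len(seq)
    if n < 3:
        return float("nan")
    actual = sum(
        1 for i in range(n - 2) if len({seq[i], seq[i + 1], seq[i + 2]}) == 3
    )
    return 100.0 * actual / (n - 2)
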