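"""Simulation and run configuration.

The synthetic generator emulates the study conditions of a widefield
olfactory-bulb imaging / histology / behavior experiment in 3-month-old
wild-type and 5xFAD mice: seven odorants whose glomerular activity foci fall
into a dorsal group (lyral, acetophenone, eugenol) and a ventral group
(geraniol, allyl phenylacetate, heptanoic acid, heptanal), ventral
amyloid-beta (A11) enrichment and ventral calcium suppression in the
transgenic genotype, and detection-dependent odor-seeking behavior.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

ODORANTS: tuple[str, ...] = ("L", "A", "E", "G", "AP", "HA", "H")
#: dorsally projecting odorants (lyral, acetophenone, eugenol)
GROUP_A: tuple[str, ...] = ("L", "A", "E")
#: ventrally projecting odorants (geraniol, allyl phenylacetate,
#: heptanoic acid, heptanal)
GROUP_B: tuple[str, ...] = ("G", "AP", "HA", "H")

GENOTYPES = ("WT", "5xFAD")


def odorant_group(odorant: str) -> str:
    """Return ``"A"`` or ``"B"`` for a known odorant label."""
    if odorant in GROUP_A:
        return "A"
    if odorant in GROUP_B:
        return "B"
    raise ValueError(
        f"unknown odorant label {odorant!r}; expected one of {ODORANTS}"
    )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic-data generator.

    Attributes
    ----------
    seed:
        Integer seed; identical configs produce byte-identical outputs.
    genotype:
        ``"WT"`` or ``"5xFAD"``. The transgenic genotype scales group-B
        response amplitudes by ``1 - ventral_suppression`` and multiplies
        ventral A11 immunoreactivity by ``ab_ventral_gain``.
    odorants:
        Subset of the seven odorant labels.
    group_a_center_deg, group_b_center_deg:
        Dorsoventral angular centers of the two odor groups (degrees on the
        sagittal 0-180 scale; 0 = dorsal extreme, 180 = ventral extreme).
    ventral_suppression:
        Fraction in [0, 1] removed from group-B response amplitude in 5xFAD.
    ab_ventral_gain:
        Multiplicative A11 enrichment applied to ventral angular bins
        (within 80 degrees of 180) in 5xFAD sections.
    noise_sd:
        Per-frame imaging noise, as a fraction of baseline fluorescence.
    frame_rate:
        Acquisition rate in Hz, within the instrument's 25-125 Hz range.
    fov_px, um_per_px:
        Field of view (square, pixels) and pixel size. Defaults match a
        256-pixel camera with 2x2 binning over a 2.3-mm field.
    """

    seed: int = 0
    genotype: str = "WT"
    odorants: tuple[str, ...] = ODORANTS
    group_a_center_deg: float = 40.0
    group_b_center_deg: float = 150.0
    ventral_suppression: float = 0.7
    ab_ventral_gain: float = 2.0
    noise_sd: float = 0.02
    frame_rate: float = 25.0
    fov_px: int = 128
    um_per_px: float = 18.0

    # --- imaging trial structure (single-wavelength fura-2, 380 nm) ---
    trial_length_s: float = 20.0
    stim_onset_s: float = 5.0
    stim_duration_s: float = 2.0
    n_trials: int = 10
    baseline_f: float = 1000.0

    # --- planted response shape ---
    #: peak relative fluorescence DECREASE at a glomerular focus center
    focal_dip: float = 0.10
    #: peak of the broad diffuse response component (fraction of baseline)
    diffuse_dip: float = 0.05
    #: angular width of the diffuse component (degrees)
    diffuse_sigma_deg: float = 40.0
    n_foci: int = 3
    #: isotropic spatial sigma of a glomerular focus (micrometers)
    focus_sigma_um: float = 100.0
    #: across-animal angular jitter of focus positions (degrees, normal)
    angle_jitter_deg: float = 10.0
    #: post-stimulus single-exponential decay constant (seconds)
    decay_tau_s: float = 1.0

    # --- histology ---
    #: baseline DAB optical density of the A11 signal per angular bin
    hist_baseline_od: float = 0.30
    #: additive per-bin OD noise (standard deviation)
    hist_noise_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        for od in self.odorants:
            odorant_group(od)  # raises on unknown labels
        if not 0.0 <= self.ventral_suppression <= 1.0:
            raise ValueError("ventral_suppression must lie in [0, 1]")
        if not 25.0 <= self.frame_rate <= 125.0:
            raise ValueError("frame_rate must lie in [25, 125] Hz")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.stim_onset_s + self.stim_duration_s > self.trial_length_s:
            raise ValueError("stimulus must end before the trial does")
        if self.baseline_f <= 0:
            raise ValueError("baseline fluorescence must be positive")
        if self.fov_px < 16:
            raise ValueError("fov_px too small")

    def group_center(self, odorant: str) -> float:
        return (
            self.group_a_center_deg
            if odorant_group(odorant) == "A"
            else self.group_b_center_deg
        )

    def amplitude_scale(self, odorant: str) -> float:
        """Genotype-dependent response-amplitude factor for one odorant."""
        if self.genotype == "5xFAD" and odorant_group(odorant) == "B":
            return 1.0 - self.ventral_suppression
        return 1.0

    def replace(self, **kw) -> "SimConfig":
        d = asdict(self)
        d.update(kw)
        if isinstance(d.get("odorants"), list):
            d["odorants"] = tuple(d["odorants"])
        return SimConfig(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["odorants"] = list(self.odorants)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        d = dict(d)
        if "odorants" in d:
            d["odorants"] = tuple(d["odorants"])
        return cls(**d)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
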