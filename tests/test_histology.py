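"""H-DAB deconvolution, staining quantification, and angular
immunoreactivity profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from olfactomap.config import SimConfig
from olfactomap.histology import (
    StainVectors,
    angular_immunoreactivity,
    color_deconvolve,
    percent_stain_area,
    reciprocal_intensity,
    region_ratio,
    stains_to_rgb,
    summarize_counts,
)
from olfactomap.synthetic import generate_histology_profile
from olfactomap.topography import AngularProfile, GlomerularContour, profile_region_summary


class TestDeconvolution:
    def test_white_pixel_has_zero_od(self):
        img = np.full((1, 1, 3), 255, dtype=np.uint8)
        stains = color_deconvolve(img)
        np.testing.assert_allclose(stains, 0.0, atol=1e-3)

    def test_pure_dab_forward_inverse(self):
        od = np.zeros((1, 1, 3))
        od[0, 0, 1] = 0.8
        rgb = stains_to_rgb(od, quantize=False)
        stains = color_deconvolve(rgb)
        assert stains[0, 0, 1] == pytest.approx(0.8, abs=1e-6)
        assert abs(stains[0, 0, 0]) < 1e-6 and abs(stains[0, 0, 2]) < 1e-6

    def test_hematoxylin_only_pixel_has_no_dab(self):
        od = np.zeros((1, 1, 3))
        od[0, 0, 0] = 0.5
        stains = color_deconvolve(stains_to_rgb(od, quantize=False))
        assert stains[0, 0, 0] == pytest.approx(0.5, abs=1e-6)
        assert stains[0, 0, 1] == pytest.approx(0.0, abs=1e-6)

    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_of_random_mixtures(self, seed):
        r = np.random.default_rng(seed)
        od = r.uniform(0, 1.2, size=(4, 4, 3))
        rec = color_deconvolve(stains_to_rgb(od, quantize=False))
        np.testing.assert_allclose(rec, od, atol=1e-6)

    def test_singular_matrix_rejected(self):
        m = np.array([[0.6, 0.7, 0.3], [0.6, 0.7, 0.3], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="singular"):
            StainVectors(m)


class TestAreaAndIntensity:
    def test_empty_region_errors(self):
        with pytest.raises(ValueError, match="empty region"):
            percent_stain_area(np.ones((5, 5)), mask=np.zeros((5, 5), bool))

    def test_saturated_region_is_100(self):
        assert percent_stain_area(np.full((5, 5), 1.0), threshold=0.15) == 100.0

    def test_half_filled_disk(self):
        yy, xx = np.mgrid[0:101, 0:101]
        disk = (xx - 50) ** 2 + (yy - 50) ** 2 <= 40**2
        od = np.where(yy < 50, 1.0, 0.0)  # upper half stained
        pct = percent_stain_area(od, threshold=0.15, mask=disk)
        oracle = 100.0 * (disk & (yy < 50)).sum() / disk.sum()
        assert pct == pytest.approx(oracle)
        assert pct == pytest.approx(50.0, abs=2.0)

    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_threshold(self, seed):
        r = np.random.default_rng(seed)
        od = r.uniform(0, 1, size=(20, 20))
        pcts = [percent_stain_area(od, thr) for thr in (0.8, 0.5, 0.2, 0.05)]
        assert all(a <= b for a, b in zip(pcts, pcts[1:]))

    def test_reciprocal_intensity_white_and_black(self):
        assert reciprocal_intensity(np.full((10, 10), 255.0)) == 0.0
        assert reciprocal_intensity(np.zeros((10, 10)), area_mm2=1.0) == 255.0

    def test_reciprocal_intensity_mean_oracle(self, rng):
        img = rng.uniform(0, 255, size=(30, 30))
        mask = rng.random((30, 30)) < 0.5
        got = reciprocal_intensity(img, mask=mask, area_mm2=0.25)
        assert got == pytest.approx((255.0 - img[mask].mean()) / 0.25, rel=1e-12)


@pytest.fixture(scope="module")
def tg_section():
    cfg = SimConfig(seed=11, genotype="5xFAD", fov_px=96)
    _, img, truth = generate_histology_profile(cfg, "coronal", render_image=True)
    return cfg, img, truth


class TestAngularImmunoreactivity:
    def test_5xfad_section_ventral_exceeds_dorsal(self, tg_section):
        from olfactomap.geometry import coronal_contour
        from olfactomap.synthetic import section_band_mask

        cfg, img, _ = tg_section
        contour = coronal_contour(cfg.fov_px)
        mask = section_band_mask(cfg, "coronal")
        prof = angular_immunoreactivity(img, contour, tissue_mask=mask)
        s = profile_region_summary(prof)
        assert s["ventral"] > 1.5 * s["dorsal"]

    def test_wt_section_flat(self):
        from olfactomap.geometry import coronal_contour
        from olfactomap.synthetic import section_band_mask

        cfg = SimConfig(seed=12, genotype="WT", fov_px=96)
        _, img, _ = generate_histology_profile(cfg, "coronal", render_image=True)
        prof = angular_immunoreactivity(
            img, coronal_contour(cfg.fov_px), tissue_mask=section_band_mask(cfg, "coronal")
        )
        s = profile_region_summary(prof)
        assert s["ventral"] == pytest.approx(s["dorsal"], rel=0.1)

    def test_sagittal_profile_has_180_one_degree_bins(self):
        cfg = SimConfig(seed=13, fov_px=96)
        from olfactomap.geometry import sagittal_contour
        from olfactomap.synthetic import section_band_mask

        _, img, _ = generate_histology_profile(cfg, "sagittal", render_image=True)
        prof = angular_immunoreactivity(
            img,
            sagittal_contour(cfg.fov_px),
            tissue_mask=section_band_mask(cfg, "sagittal"),
        )
        assert len(prof.values) == 180
        assert np.allclose(np.diff(prof.bin_edges), 1.0)

    def test_quarter_turn_rotation_invariance(self, tg_section):
        from olfactomap.geometry import coronal_contour
        from olfactomap.synthetic import section_band_mask

        cfg, img, _ = tg_section
        n = cfg.fov_px
        contour = coronal_contour(n)
        mask = section_band_mask(cfg, "coronal")
        prof0 = angular_immunoreactivity(img, contour, tissue_mask=mask)
        # rotate image, mask, contour and center by 90 degrees
        img_r = np.rot90(img, axes=(0, 1)).copy()
        mask_r = np.rot90(mask).copy()
        pts = contour.points.copy()
        rot = np.column_stack([pts[:, 1], (n - 1) - pts[:, 0]])
        contour_r = GlomerularContour(
            "coronal",
            rot,
            zero_index=contour.zero_index,
            center=np.array(
                [contour.center[1], (n - 1) - contour.center[0]]
            ),
        )
        prof_r = angular_immunoreactivity(img_r, contour_r, tissue_mask=mask_r)
        np.testing.assert_allclose(prof_r.values, prof0.values, atol=1e-9)


class TestRegionRatioAndCounts:
    def _flat(self, value):
        edges = np.arange(181.0)
        return AngularProfile(
            "sagittal", edges, np.full(180, value), np.ones(180, int)
        )

    def test_identical_flat_profiles(self):
        r = region_ratio(self._flat(1.0), self._flat(1.0))
        assert r == {
            "wt_dorsal": 1.0,
            "tg_dorsal": 1.0,
            "wt_ventral": 1.0,
            "tg_ventral": 1.0,
        }

    def test_doubled_tg_ventral(self):
        tg = self._flat(1.0)
        centers = tg.bin_centers
        tg.values[np.abs(centers - 180.0) <= 80.0] = 2.0
        r = region_ratio(self._flat(1.0), tg)
        assert r["tg_ventral"] == pytest.approx(2.0)
        assert r["wt_ventral"] == pytest.approx(1.0)

    def test_generator_defaults_recover_gain(self):
        wt, _, _ = generate_histology_profile(SimConfig(seed=21, genotype="WT"))
        tg, _, _ = generate_histology_profile(SimConfig(seed=21, genotype="5xFAD"))
        r = region_ratio(wt, tg)
        assert r["tg_ventral"] / r["wt_ventral"] == pytest.approx(2.0, rel=0.1)

    def test_summarize_counts_single_animal_sem_missing(self):
        df = pd.DataFrame(
            [{"genotype": "WT", "region": "endo", "marker": "OMP", "value": 3.0}]
        )
        out = summarize_counts(df)
        assert np.isnan(out["sem"].iloc[0])

    def test_duplicated_rows_shrink_sem(self, rng):
        rows = [
            {"genotype": "WT", "region": "endo", "marker": "OMP", "value": v}
            for v in rng.normal(10, 2, size=6)
        ]
        df = pd.DataFrame(rows)
        base = summarize_counts(df)
        doubled = summarize_counts(pd.concat([df, df], ignore_index=True))
        assert doubled["mean"].iloc[0] == pytest.approx(base["mean"].iloc[0])
        ratio = base["sem"].iloc[0] / doubled["sem"].iloc[0]
        # doubling n halves the variance of the mean (up to the ddof=1 SD)
        assert ratio == pytest.approx(np.sqrt(2), rel=0.05)

    def test_groupby_oracle(self, rng):
        df = pd.DataFrame(
            {
                "genotype": rng.choice(["WT", "5xFAD"], 40),
                "region": rng.choice(["endo", "ecto"], 40),
                "marker": "TH",
                "value": rng.normal(size=40),
            }
        )
        out = summarize_counts(df).set_index(["region", "genotype"])
        for (reg, gen), grp in df.groupby(["region", "genotype"]):
            assert out.loc[(reg, gen), "mean"] == pytest.approx(grp["value"].mean())
            assert out.loc[(reg, gen), "n"] == len(grp)
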