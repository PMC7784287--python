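"""Rank correlation, map clustering, angle-matched regression and group
statistics, each checked against an independent oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from olfactomap.crossmodal import (
    angle_matched_correlation,
    cluster_odorants,
    odor_map_correlation,
    spearman,
    two_way_anova_bonferroni,
    unpaired_t,
)
from olfactomap.topography import AngularProfile


def rank_oracle(v):
    """Average ranks computed from first principles (sort + tie groups)."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    rx, ry = rank_oracle(x), rank_oracle(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        x = np.arange(10.0)
        assert spearman(x, -x).rho == pytest.approx(-1.0)

    def test_tied_vectors_match_exhaustive_rank_oracle(self, rng):
        x = rng.integers(0, 5, size=20).astype(float)  # heavy ties
        y = rng.integers(0, 5, size=20).astype(float)
        res = spearman(x, y)
        assert res.rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_pairwise_deletion(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 3.0, np.nan, 5.0, 7.0])
        res = spearman(x, y)
        assert res.n_pairs == 4

    def test_gaussian_approximation_p(self):
        x = np.arange(30.0)
        y = x + np.sin(x)
        res = spearman(x, y)
        z = res.rho * np.sqrt(res.n_pairs - 1)
        assert res.p_two_tailed == pytest.approx(2 * sps.norm.sf(abs(z)))

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=15)
        y = r.normal(size=15)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
        assert spearman(x, y**3).rho == pytest.approx(base, abs=1e-12)

    def test_too_few_pairs_undefined(self):
        res = spearman([1.0, 2.0], [2.0, 1.0])
        assert np.isnan(res.rho)


class TestOdorMapCorrelation:
    def test_unit_diagonal_and_symmetry(self, rng):
        maps = {k: rng.normal(size=(10, 18)) for k in "LAEG"}
        corr = odor_map_correlation(maps)
        np.testing.assert_allclose(np.diag(corr.to_numpy()), 1.0)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)

    def test_disjoint_foci_maps_anticorrelate(self):
        yy, xx = np.mgrid[0:40, 0:40]
        a = np.exp(-((xx - 10) ** 2 + (yy - 10) ** 2) / 50.0)
        b = np.exp(-((xx - 30) ** 2 + (yy - 30) ** 2) / 50.0)
        corr = odor_map_correlation({"a": a, "b": b})
        assert corr.loc["a", "b"] < 0


def best_two_partition_oracle(d: np.ndarray):
    """Exhaustively choose the 2-partition minimizing mean within-group
    distance (ties broken toward the first found)."""
    n = d.shape[0]
    best, best_score = None, np.inf
    for size in range(1, n // 2 + 1):
        for group in itertools.combinations(range(n), size):
            g1 = set(group)
            g2 = set(range(n)) - g1
            within = [
                d[i, j]
                for g in (g1, g2)
                for i in g
                for j in g
                if i < j
            ]
            score = np.mean(within) if within else 0.0
            if score < best_score:
                best, best_score = (frozenset(g1), frozenset(g2)), score
    return best


class TestClustering:
    def test_planted_two_block_matrix_recovered(self):
        labels = list("LAEGPHQ")
        n = len(labels)
        block = [0, 0, 0, 1, 1, 1, 1]
        mat = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                mat[i, j] = 1.0 if i == j else (0.8 if block[i] == block[j] else -0.3)
        corr = pd.DataFrame(mat, index=labels, columns=labels)
        got = cluster_odorants(corr, k=2)
        groups = {}
        for lab, g in got.items():
            groups.setdefault(g, set()).add(lab)
        d = 1.0 - mat
        np.fill_diagonal(d, 0.0)
        oracle = best_two_partition_oracle(d)
        assert frozenset(frozenset(g) for g in groups.values()) == frozenset(
            frozenset(labels[i] for i in part) for part in oracle
        )

    def test_k1_single_group(self):
        corr = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        assert set(cluster_odorants(corr, k=1).values()) == {0}

    def test_invalid_k(self):
        corr = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError):
            cluster_odorants(corr, k=5)


class TestAngleMatched:
    def _profile(self, values):
        v = np.asarray(values, dtype=float)
        edges = np.arange(len(v) + 1, dtype=float) * (180.0 / len(v))
        return AngularProfile("sagittal", edges, v, np.ones(len(v), int))

    def test_identity_profiles(self):
        x = np.linspace(0, 1, 180)
        res, reg = angle_matched_correlation(self._profile(x), self._profile(x))
        assert res.rho == pytest.approx(1.0)
        assert res.n_pairs == 180
        assert reg["slope"] == pytest.approx(1.0)
        assert reg["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_bins_reduce_pairs(self):
        x = np.linspace(0, 1, 180)
        y = x.copy()
        y[:10] = np.nan
        res, _ = angle_matched_correlation(self._profile(x), self._profile(y))
        assert res.n_pairs == 170

    def test_mismatched_edges_rejected(self):
        with pytest.raises(ValueError, match="bin edges"):
            angle_matched_correlation(
                self._profile(np.ones(180)), self._profile(np.ones(90))
            )

    def test_confidence_band_brackets_fit(self, rng):
        x = rng.normal(size=60)
        y = 2 * x + rng.normal(scale=0.5, size=60)
        _, reg = angle_matched_correlation(self._profile(x), self._profile(y))
        assert np.all(reg["band_low"] <= reg["fitted"] + 1e-12)
        assert np.all(reg["fitted"] <= reg["band_high"] + 1e-12)
        assert reg["slope_ci95"][0] < 2.0 < reg["slope_ci95"][1]


class TestGroupStats:
    def test_df_for_six_vs_six(self, rng):
        res = unpaired_t(rng.normal(size=6), rng.normal(size=6))
        assert res.df == 10

    def test_identical_samples(self):
        res = unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_closed_form_oracle(self):
        a = np.array([4.0, 5.0, 6.0, 7.0])
        b = np.array([1.0, 2.0, 3.0, 8.0])
        res = unpaired_t(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert res.statistic == pytest.approx(t_oracle, rel=1e-12)
        assert res.p == pytest.approx(
            2 * sps.t.sf(abs(t_oracle), na + nb - 2), rel=1e-9
        )

    def test_all_equal_table_gives_zero_f(self):
        df = pd.DataFrame(
            {
                "genotype": ["WT", "WT", "5xFAD", "5xFAD"] * 3,
                "region": ["endo", "ecto"] * 6,
                "value": 5.0,
            }
        )
        anova, posthoc = two_way_anova_bonferroni(df)
        assert all(r.statistic == 0.0 and r.p == 1.0 for r in anova)
        assert all(r.p == 1.0 for r in posthoc)

    def test_balanced_2x2_matches_hand_sums_of_squares(self, rng):
        # 2 genotypes x 2 regions, n=5 per cell
        n = 5
        rows = []
        for g in ("WT", "5xFAD"):
            for r in ("endo", "ecto"):
                mu = {"WT": 10.0, "5xFAD": 8.0}[g] + (1.5 if r == "ecto" else 0.0)
                for v in rng.normal(mu, 1.0, size=n):
                    rows.append({"genotype": g, "region": r, "value": v})
        df = pd.DataFrame(rows)
        anova, posthoc = two_way_anova_bonferroni(df)
        y = df["value"].to_numpy()
        grand = y.mean()
        means_g = df.groupby("genotype")["value"].mean()
        means_r = df.groupby("region")["value"].mean()
        means_gr = df.groupby(["genotype", "region"])["value"].mean()
        ss_a = 2 * n * ((means_g - grand) ** 2).sum()
        ss_b = 2 * n * ((means_r - grand) ** 2).sum()
        ss_cells = n * ((means_gr - grand) ** 2).sum()
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = sum(
            ((grp["value"] - grp["value"].mean()) ** 2).sum()
            for _, grp in df.groupby(["genotype", "region"])
        )
        ms_err = ss_err / (4 * (n - 1))
        by_label = {r.label: r for r in anova}
        assert by_label["genotype"].statistic == pytest.approx(ss_a / ms_err, rel=1e-9)
        assert by_label["region"].statistic == pytest.approx(ss_b / ms_err, rel=1e-9)
        assert by_label["genotype:region"].statistic == pytest.approx(
            ss_ab / ms_err, rel=1e-9
        )
        # Bonferroni: m = number of region levels
        for r in posthoc:
            region = r.label.split("=")[-1]
            sub = df[df["region"] == region]
            raw = unpaired_t(
                sub[sub["genotype"] == "5xFAD"]["value"],
                sub[sub["genotype"] == "WT"]["value"],
            ).p
            assert r.p == pytest.approx(min(1.0, 2 * raw), rel=1e-9)
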