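"""Statistics tying the modalities together.

Spearman rank correlation (average ranks for ties, two-tailed p by the
Gaussian approximation, Fisher-z confidence interval), pairwise spatial
correlation of odor activity maps with average-linkage clustering,
angle-matched histology x calcium correlation with an ordinary
least-squares line and pointwise 95% confidence band, the two-sample
Student t test, and balanced two-way ANOVA with Bonferroni-adjusted
post-hoc genotype contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .topography import AngularProfile

__all__ = [
    "CorrelationResult",
    "StatResult",
    "spearman",
    "odor_map_correlation",
    "cluster_odorants",
    "angle_matched_correlation",
    "unpaired_t",
    "two_way_anova_bonferroni",
]


@dataclass
class CorrelationResult:
    rho: float
    n_pairs: int
    p_two_tailed: float
    ci95: tuple[float, float]

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_two_tailed < alpha


@dataclass
class StatResult:
    test: str
    statistic: float
    df: float
    p: float
    adjustment: str = "none"
    label: str = ""


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    Missing pairs are dropped pairwise. The two-tailed p value uses the
    Gaussian approximation ``z = rho * sqrt(n - 1)``; the 95% CI uses the
    Fisher z transform with rank-correlation variance ``1 / (n - 3)``.
    """
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 3:
        return CorrelationResult(float("nan"), n, float("nan"), (float("nan"),) * 2)
    rx = stats.rankdata(x)  # average ranks on ties
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return CorrelationResult(float("nan"), n, float("nan"), (float("nan"),) * 2)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    z = rho * np.sqrt(n - 1)
    p = 2.0 * stats.norm.sf(abs(z))
    if n > 3 and abs(rho) < 1:
        zr = np.arctanh(rho)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        ci = (float(np.tanh(zr - half)), float(np.tanh(zr + half)))
    else:
        ci = (float("nan"), float("nan"))
    return CorrelationResult(rho, n, float(p), ci)


def odor_map_correlation(maps: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Spearman correlation between odor activity maps.

    Maps (e.g. flattened 10 x 180 grids) are compared pairwise-complete
    over their finite cells. Returns a symmetric DataFrame with unit
    diagonal, indexed by odorant label.
    """
    labels = list(maps)
    flat = {k: np.asarray(v, dtype=float).ravel() for k, v in maps.items()}
    sizes = {v.size for v in flat.values()}
    if len(sizes) != 1:
        raise ValueError("all maps must have the same number of cells")
    n = len(labels)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = spearman(flat[labels[i]], flat[labels[j]]).rho
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=labels, columns=labels)


def cluster_odorants(corr: pd.DataFrame, k: int = 2) -> dict[str, int]:
    """Group odorants by average-linkage hierarchical clustering on the
    distance ``1 - rho``, cut at ``k`` clusters.

    Cluster ids are renumbered in order of first appearance, so the group
    containing the first odorant is always 0.
    """
    labels = list(corr.index)
    if k < 1 or k > len(labels):
        raise ValueError("k must lie between 1 and the number of odorants")
    if k == 1:
        return {lab: 0 for lab in labels}
    d = 1.0 - corr.to_numpy()
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(z, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    out = {}
    for lab, r in zip(labels, raw):
        if r not in remap:
            remap[r] = len(remap)
        out[lab] = remap[r]
    return out


def angle_matched_correlation(
    histology: AngularProfile,
    calcium: AngularProfile,
    alpha: float = 0.05,
) -> tuple[CorrelationResult, dict]:
    """Correlate immunoreactivity with calcium activity bin-by-bin.

    Both profiles must share bin edges; bins missing in either profile are
    dropped pairwise (the reported ``n_pairs`` is the number retained).
    Alongside the Spearman result, an ordinary least-squares line
    ``calcium ~ histology`` is fit, with slope/intercept confidence
    intervals and a pointwise ``1 - alpha`` confidence band.
    """
    if histology.plane != calcium.plane:
        raise ValueError("profiles come from different planes")
    if len(histology.bin_edges) != len(calcium.bin_edges) or not np.allclose(
        histology.bin_edges, calcium.bin_edges
    ):
        raise ValueError("profiles must share identical bin edges")
    x, y = _pairwise_complete(histology.values, calcium.values)
    corr = spearman(x, y)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X)
    band = pred.conf_int(alpha=alpha)
    ci_params = fit.conf_int(alpha=alpha)
    regression = {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "slope_ci95": (float(ci_params[1][0]), float(ci_params[1][1])),
        "intercept_ci95": (float(ci_params[0][0]), float(ci_params[0][1])),
        "x": x,
        "fitted": fit.fittedvalues,
        "band_low": band[:, 0],
        "band_high": band[:, 1],
    }
    return corr, regression


def unpaired_t(group_a, group_b, label: str = "") -> StatResult:
    """Two-tailed unpaired Student t test (equal variances).

    Degrees of freedom are ``n_a + n_b - 2``. Identical samples give
    ``t = 0, p = 1``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    res = stats.ttest_ind(a, b, equal_var=True)
    t = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(t):  # zero pooled variance
        t, p = 0.0, 1.0
    return StatResult(
        test="unpaired t (two-tailed)",
        statistic=t,
        df=float(len(a) + len(b) - 2),
        p=p,
        label=label,
    )


def two_way_anova_bonferroni(
    counts: pd.DataFrame,
    value: str = "value",
    factor_a: str = "genotype",
    factor_b: str = "region",
) -> tuple[list[StatResult], list[StatResult]]:
    """Two-factor ANOVA with interaction, plus Bonferroni post-hoc tests.

    Designed for the balanced genotype x region marker tables. Returns
    ``(anova_results, posthoc_results)``: F tests for both main effects
    and the interaction, then per-region genotype contrasts (Student t)
    with Bonferroni-adjusted p values ``min(1, m * p)``.

    Effects with zero sum of squares are reported as ``F = 0, p = 1``
    (degenerate all-equal tables have no evidence of any effect).
    """
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    df = counts.rename(columns={value: "_y", factor_a: "_fa", factor_b: "_fb"})[
        ["_y", "_fa", "_fb"]
    ].dropna()
    model = ols("_y ~ C(_fa) * C(_fb)", data=df).fit()
    table = anova_lm(model, typ=2)
    name_map = {
        "C(_fa)": factor_a,
        "C(_fb)": factor_b,
        "C(_fa):C(_fb)": f"{factor_a}:{factor_b}",
    }
    anova_results = []
    for key, label in name_map.items():
        row = table.loc[key]
        f, p = float(row["F"]), float(row["PR(>F)"])
        if row["sum_sq"] <= 1e-12:
            f, p = 0.0, 1.0
        anova_results.append(
            StatResult(
                test="two-way ANOVA",
                statistic=f,
                df=float(row["df"]),
                p=p,
                label=label,
            )
        )
    levels_b = sorted(df["_fb"].unique())
    levels_a = sorted(df["_fa"].unique())
    if len(levels_a) != 2:
        raise ValueError("post-hoc contrasts need exactly two genotype levels")
    m = len(levels_b)
    posthoc = []
    for lb in levels_b:
        sub = df[df["_fb"] == lb]
        res = unpaired_t(
            sub.loc[sub["_fa"] == levels_a[0], "_y"],
            sub.loc[sub["_fa"] == levels_a[1], "_y"],
            label=f"{levels_a[0]} vs {levels_a[1]} @ {factor_b}={lb}",
        )
        res.adjustment = "bonferroni"
        res.p = min(1.0, m * res.p)
        posthoc.append(res)
    return anova_results, posthoc
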