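"""Differential and descriptive statistics.

Implements the statistical toolbox of the pipeline: Welch's unequal-
variance two-sample t-test with Satterthwaite degrees of freedom,
log2 fold-changes as differences of group means, the published
significance rule (P < 0.05 and linear fold-change > 1.5 or < 1/1.5,
strictly, with no multiple-testing adjustment), Pearson and Spearman
correlation with t-approximation p-values, the Mann-Whitney rank-sum
test with tie and continuity corrections, a standard-deviation probe
filter, and complete-linkage hierarchical clustering of samples on
correlation distance (1 - Pearson R).

Test statistics are computed from the closed-form definitions here;
scipy supplies only the t and normal distribution functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .config import SampleDesign

__all__ = [
    "TestResult",
    "CorrStat",
    "welch_t_test",
    "log2_fold_change",
    "differential_table",
    "call_significant",
    "correlation",
    "rank_sum_test",
    "sd_filter",
    "ClusterResult",
    "hierarchical_cluster",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample test.

    ``undefined`` marks results that could not be computed (too few
    values); ``degenerate`` marks zero-variance edge cases resolved by
    convention rather than by the sampling distribution.
    """

    statistic: float
    df: float
    p: float
    n1: int
    n2: int
    undefined: bool = False
    degenerate: bool = False


@dataclass(frozen=True)
class CorrStat:
    method: str
    r: float
    p: float
    n: int
    undefined: bool = False


def _clean(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    return x[~np.isnan(x)]


def welch_t_test(x, y) -> TestResult:
    """Welch two-sample, two-sided t-test.

    t = (mx - my) / sqrt(sx^2/nx + sy^2/ny) with Welch–Satterthwaite
    degrees of freedom; the two-sided p comes from the t distribution.
    Missing values are dropped per group; fewer than two values in either
    group yields an undefined-marked result (NaN statistic and p) rather
    than an error.  Zero variance in both groups gives t=0, p=1 for equal
    means, and a degenerate-flagged p -> 0 for unequal means.
    """
    xs, ys = _clean(x), _clean(y)
    nx, ny = xs.size, ys.size
    if nx < 2 or ny < 2:
        return TestResult(np.nan, np.nan, np.nan, nx, ny, undefined=True)
    mx, my = xs.mean(), ys.mean()
    vx, vy = xs.var(ddof=1), ys.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if mx == my:
            return TestResult(0.0, float(nx + ny - 2), 1.0, nx, ny, degenerate=True)
        t = np.inf if mx > my else -np.inf
        return TestResult(float(t), float(nx + ny - 2), 0.0, nx, ny, degenerate=True)
    t = (mx - my) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(min(p, 1.0)), nx, ny)


def log2_fold_change(mean_num: float, mean_den: float) -> float:
    """log2 ratio of two group means already on the log2 scale.

    Equals log2 of the ratio of geometric means on the linear scale; the
    pipeline reports log2(SCC/ADC).
    """
    return float(mean_num) - float(mean_den)


def differential_table(matrix: pd.DataFrame, design: SampleDesign,
                       contrast: tuple[str, str] | None = None) -> pd.DataFrame:
    """Per-feature Welch test and fold-change between the two design groups.

    Parameters
    ----------
    matrix :
        Features x samples log2 matrix.
    contrast :
        ``(numerator_group, denominator_group)`` for the fold-change.
        Defaults to (second, first) group level of the design — for an
        ADC/SCC design this is log2(SCC/ADC), the published orientation.

    Returns
    -------
    DataFrame indexed by feature with columns ``mean_<den>``,
    ``mean_<num>``, ``log2fc``, ``t``, ``df``, ``p``, ``n_<den>``,
    ``n_<num>``, ``undefined``, ``degenerate``.
    """
    g1, g2 = design.require_two_groups()
    if contrast is None:
        contrast = (g2, g1)
    num, den = contrast
    if {num, den} != {g1, g2}:
        raise ValueError(f"contrast {contrast!r} does not match design groups "
                         f"({g1!r}, {g2!r})")
    cols_num = [s for s in matrix.columns if s in design.samples_in(num)]
    cols_den = [s for s in matrix.columns if s in design.samples_in(den)]
    if not cols_num or not cols_den:
        raise ValueError("matrix does not contain samples from both groups")

    rows = []
    for feat in matrix.index:
        xs = matrix.loc[feat, cols_num].to_numpy(dtype=float)
        ys = matrix.loc[feat, cols_den].to_numpy(dtype=float)
        res = welch_t_test(xs, ys)
        m_num = float(np.nanmean(xs)) if np.any(~np.isnan(xs)) else np.nan
        m_den = float(np.nanmean(ys)) if np.any(~np.isnan(ys)) else np.nan
        fc = log2_fold_change(m_num, m_den) if not (np.isnan(m_num) or np.isnan(m_den)) else np.nan
        rows.append((m_den, m_num, fc, res.statistic, res.df, res.p,
                     res.n2, res.n1, res.undefined, res.degenerate))
    out = pd.DataFrame(rows, index=matrix.index, columns=[
        f"mean_{den}", f"mean_{num}", "log2fc", "t", "df", "p",
        f"n_{den}", f"n_{num}", "undefined", "degenerate"])
    out.index.name = matrix.index.name or "feature"
    return out


def call_significant(table: pd.DataFrame, p_threshold: float = 0.05,
                     fc_linear_threshold: float = 1.5,
                     use_fc: bool = True) -> pd.DataFrame:
    """Add the ``called`` column using the published thresholds.

    called <=> p < p_threshold and, when ``use_fc``, linear fold-change
    strictly > fc_linear_threshold or < 1/fc_linear_threshold.  With
    ``use_fc=False`` the rule is P alone (the "P < 0.05" counts).
    No multiple-testing adjustment is applied.
    """
    out = table.copy()
    p_ok = out["p"] < p_threshold
    if use_fc:
        linear = np.power(2.0, out["log2fc"])
        fc_ok = (linear > fc_linear_threshold) | (linear < 1.0 / fc_linear_threshold)
        out["called"] = (p_ok & fc_ok).fillna(False)
    else:
        out["called"] = p_ok.fillna(False)
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0.0:
        return np.nan
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def correlation(x, y, method: str = "pearson") -> CorrStat:
    """Pearson or Spearman correlation with a t-approximation p-value.

    Pairs with a missing value in either vector are dropped (pairwise-
    complete).  Spearman ranks ties by their average rank and then applies
    the same t transform, t = r * sqrt((n-2)/(1-r^2)), two-sided.  Fewer
    than three complete pairs, or a constant vector, gives an undefined-
    marked result.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have the same length")
    ok = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[ok], ya[ok]
    n = xa.size
    if n < 3:
        return CorrStat(method, np.nan, np.nan, n, undefined=True)
    if method == "spearman":
        xa = sps.rankdata(xa)
        ya = sps.rankdata(ya)
    r = _pearson(xa, ya)
    if np.isnan(r):
        return CorrStat(method, np.nan, np.nan, n, undefined=True)
    if abs(r) >= 1.0:
        return CorrStat(method, r, 0.0, n)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return CorrStat(method, r, float(min(p, 1.0)), n)


def rank_sum_test(x, y) -> TestResult:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test, normal approximation.

    Uses the U statistic of the first sample, the tie-corrected variance,
    and a 0.5 continuity correction.  The reported ``statistic`` is U1 and
    ``df`` is NaN (the null is normal, not t).
    """
    xs, ys = _clean(x), _clean(y)
    n1, n2 = xs.size, ys.size
    if n1 < 1 or n2 < 1:
        return TestResult(np.nan, np.nan, np.nan, n1, n2, undefined=True)
    combined = np.concatenate([xs, ys])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    if n > 1:
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    else:
        sigma2 = 0.0
    if sigma2 <= 0.0:
        # all values tied: no evidence against the null
        return TestResult(float(u1), np.nan, 1.0, n1, n2, degenerate=True)
    z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(max(z, 0.0))
    return TestResult(float(u1), np.nan, float(min(p, 1.0)), n1, n2)


def sd_filter(matrix: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Keep features whose sample standard deviation is strictly > threshold.

    The SD uses the n-1 denominator over non-missing values; features with
    fewer than two observed values have undefined SD and are removed.
    """
    if matrix.shape[1] < 2:
        raise ValueError("sd_filter needs at least two samples")
    sds = matrix.std(axis=1, ddof=1, skipna=True)
    return matrix.loc[(sds > threshold).fillna(False)]


@dataclass
class ClusterResult:
    """Complete-linkage clustering of samples on correlation distance."""

    linkage: np.ndarray
    sample_order: list[str]
    labels: dict[str, int]
    newick: str
    n_features_used: int


def hierarchical_cluster(matrix: pd.DataFrame) -> ClusterResult:
    """Cluster sample columns with d = 1 - Pearson R, complete linkage.

    Features with any missing value are dropped before computing the
    sample-by-sample correlation; fewer than three complete features is an
    error.  Ties in merge heights break deterministically by sample order
    (scipy's linkage processes candidate merges in index order).  The
    two-cluster cut provides labels for comparison with the design.
    """
    complete = matrix.dropna(axis=0, how="any")
    if complete.shape[0] < 3:
        raise ValueError(f"only {complete.shape[0]} complete features; "
                         "need at least 3 for clustering")
    samples = list(matrix.columns)
    corr = np.corrcoef(complete.to_numpy(dtype=float), rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce exact symmetry
    z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    order = [samples[i] for i in hierarchy.leaves_list(z)]
    cut = hierarchy.fcluster(z, t=2, criterion="maxclust")
    labels = {s: int(c) for s, c in zip(samples, cut)}
    return ClusterResult(z, order, labels, _linkage_to_newick(z, samples),
                         complete.shape[0])


def _linkage_to_newick(z: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(leaf_names)
    heights = {i: 0.0 for i in range(n)}

    def build(node: int) -> str:
        if node < n:
            return leaf_names[node]
        left, right, height = int(z[node - n, 0]), int(z[node - n, 1]), z[node - n, 2]
        parts = []
        for child in (left, right):
            parts.append(f"{build(child)}:{height - heights[child]:.6g}")
        heights[node] = height
        return "(" + ",".join(parts) + ")"

    root = n + z.shape[0] - 1
    # initialize heights for internal nodes as we recurse (build fills them)
    for k in range(z.shape[0]):
        heights[n + k] = z[k, 2]
    return build(root) + ";"
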