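"""Differential promoter coverage screening between response groups.

Per promoter: two-sided Wilcoxon rank-sum on the normalized coverage of
the two groups, fold change with a pseudocount, Benjamini–Hochberg FDR
across all tested promoters, and a two-sided pass rule (FC >= t or
FC <= 1/t, FDR <= q). Passing promoters feed a per-gene z-score matrix
with agglomerative clustering (1 − Pearson distance, average linkage).

The rank-sum test uses the exact null distribution (dynamic-programming
count of rank arrangements) for tie-free data with combined n up to a
crossover (default 25) and a tie-corrected, continuity-corrected normal
approximation otherwise — the approximation regime a screen over many
samples needs, vectorized over promoters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .coverage import PromoterCoverageMatrix

EXACT_THRESHOLD = 25
GROUP_POS = "pCR"
GROUP_NEG = "non-pCR"


# ---------------------------------------------------------------------------
# rank-sum machinery
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _mwu_exact_cdf(n1: int, n2: int) -> np.ndarray:
    """CDF of the Mann-Whitney U statistic under the tie-free null.

    Counts rank arrangements by DP over ranks in increasing order: state
    (j = ranks assigned to group 1, u = accumulated U); assigning the next
    rank to group 1 adds the number of group-2 ranks already placed.
    """
    m = n1 * n2
    dp = np.zeros((n1 + 1, m + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for i in range(n1 + n2):
        new = np.zeros_like(dp)
        jmax = min(i, n1)
        for j in range(jmax, -1, -1):
            row = dp[j]
            new[j] += row  # rank goes to group 2
            if j < n1:
                shift = i - j  # group-2 ranks already placed
                if shift:
                    new[j + 1, shift:] += row[: m + 1 - shift]
                else:
                    new[j + 1] += row
        dp = new
    counts = dp[n1]
    return np.cumsum(counts) / counts.sum()


def rank_sum_pvalues(
    x: np.ndarray, y: np.ndarray, exact_threshold: int = EXACT_THRESHOLD
) -> np.ndarray:
    """Vectorized two-sided rank-sum p-values for row-paired samples.

    ``x`` (g, n1) and ``y`` (g, n2) hold one test per row. Rows with no
    ties and n1 + n2 <= *exact_threshold* use the exact distribution;
    other rows use the normal approximation with tie correction and a
    0.5 continuity correction. A row whose pooled values are all equal
    gets p = 1.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have the same number of rows")
    n1, n2 = x.shape[1], y.shape[1]
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups need at least one observation")
    n = n1 + n2
    m = n1 * n2
    data = np.concatenate([x, y], axis=1)
    ranks = _stats.rankdata(data, axis=1)
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0

    data_sorted = np.sort(data, axis=1)
    has_ties = (np.diff(data_sorted, axis=1) == 0).any(axis=1)
    p = np.empty(data.shape[0], dtype=np.float64)

    exact = (~has_ties) & (n <= exact_threshold)
    if exact.any():
        cdf = _mwu_exact_cdf(n1, n2)
        umin = np.minimum(u[exact], m - u[exact]).astype(np.int64)
        p[exact] = np.minimum(1.0, 2.0 * cdf[umin])

    approx = ~exact
    if approx.any():
        # sum of (t^3 - t) over tied groups, per row
        sub = data_sorted[approx]
        tie_term = np.zeros(sub.shape[0])
        for i, row in enumerate(sub):
            _, t = np.unique(row, return_counts=True)
            tie_term[i] = float(np.sum(t**3 - t))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        ua = u[approx]
        pa = np.ones(sub.shape[0])
        ok = sigma2 > 0
        z = np.maximum(np.abs(ua[ok] - m / 2.0) - 0.5, 0.0) / np.sqrt(sigma2[ok])
        pa[ok] = np.minimum(1.0, 2.0 * _stats.norm.sf(z))
        p[approx] = pa
    return p


def wilcoxon_rank_sum(x, y, exact_threshold: int = EXACT_THRESHOLD) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value for two samples."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    return float(rank_sum_pvalues(x[None, :], y[None, :], exact_threshold)[0])


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up FDR adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=np.float64).ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the screen
# ---------------------------------------------------------------------------

def _split_groups(values: pd.DataFrame, labels: Mapping[str, str] | pd.Series):
    labels = pd.Series(labels)
    pos = [s for s in values.columns if labels.get(s) == GROUP_POS]
    neg = [s for s in values.columns if labels.get(s) == GROUP_NEG]
    if not pos or not neg:
        raise ValueError("both response groups must be non-empty")
    return values[pos].to_numpy(), values[neg].to_numpy()


def differential_screen(
    matrix: PromoterCoverageMatrix | pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
    pseudocount: float | None = None,
    exact_threshold: int = EXACT_THRESHOLD,
) -> pd.DataFrame:
    """Screen promoters for differential coverage between pCR and non-pCR.

    Returns one row per gene: group means, fold change
    (mean_pCR + eps) / (mean_nonpCR + eps) with pseudocount
    eps = 0.01 × global matrix mean by default, two-sided rank-sum
    p-value, BH FDR over all tested genes, and the two-sided pass flag
    (FC >= t or FC <= 1/t) and FDR <= q.
    """
    values = matrix.values if isinstance(matrix, PromoterCoverageMatrix) else matrix
    x, y = _split_groups(values, labels)
    if pseudocount is None:
        pseudocount = 0.01 * float(values.to_numpy().mean())
    eps = max(pseudocount, 1e-12)
    mean_pos = x.mean(axis=1)
    mean_neg = y.mean(axis=1)
    fc = (mean_pos + eps) / (mean_neg + eps)
    p = rank_sum_pvalues(x, y, exact_threshold)
    q = benjamini_hochberg(p)
    passes = ((fc >= fc_threshold) | (fc <= 1.0 / fc_threshold)) & (q <= fdr_threshold)
    return pd.DataFrame(
        {
            "gene_id": values.index,
            "mean_pCR": mean_pos,
            "mean_nonpCR": mean_neg,
            "fold_change": fc,
            "log2_fold_change": np.log2(fc),
            "p_value": p,
            "fdr": q,
            "passes": passes,
        }
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# z-scores and clustering
# ---------------------------------------------------------------------------

@dataclass
class ZScoreMatrix:
    z: pd.DataFrame  # passing genes × samples
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    constant_genes: list[str] = field(default_factory=list)


def _correlation_linkage(rows: np.ndarray) -> np.ndarray:
    d = pdist(rows, metric="correlation")
    d = np.nan_to_num(d, nan=1.0)  # zero-variance vectors: neutral distance
    return _hier.linkage(d, method="average")


def zscore_and_cluster(values: pd.DataFrame) -> ZScoreMatrix:
    """Per-gene z-scores plus hierarchical clustering of rows and columns.

    Rows are z-scored across samples with the sample standard deviation
    (ddof=1); constant rows become all-zero and are flagged. Distance is
    1 − Pearson correlation with average linkage on both axes.
    """
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples to cluster")
    arr = values.to_numpy(dtype=np.float64)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    sd[sd == 0] = 1.0
    z = (arr - mu) / sd
    z[constant] = 0.0
    zdf = pd.DataFrame(z, index=values.index, columns=values.columns)
    row_link = _correlation_linkage(z)
    col_link = _correlation_linkage(z.T)
    return ZScoreMatrix(
        z=zdf,
        row_order=[values.index[i] for i in _hier.leaves_list(row_link)],
        col_order=[values.columns[i] for i in _hier.leaves_list(col_link)],
        row_linkage=row_link,
        col_linkage=col_link,
        constant_genes=list(values.index[constant]),
    )


def cut_columns(zmat: ZScoreMatrix, k: int) -> pd.Series:
    """Flat cluster assignment of samples from the column dendrogram."""
    labels = _hier.fcluster(zmat.col_linkage, k, criterion="maxclust")
    return pd.Series(labels, index=zmat.z.columns)


# ---------------------------------------------------------------------------
# composite-profile group test
# ---------------------------------------------------------------------------

def meta_profile_group_test(
    profiles: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    unit: str = "sample-means",
    exact_threshold: int = EXACT_THRESHOLD,
) -> float:
    """Rank-sum test for a group difference in composite profiles.

    *profiles* is the samples × offsets table from
    :func:`ppcet.coverage.meta_profiles_by_sample`. The default
    ``unit="sample-means"`` compares the per-sample window means, keeping
    samples the exchangeable unit (n = samples per group).
    ``unit="offset-means"`` instead ranks the two groups' per-offset mean
    signals across the whole window; it yields far smaller p-values but
    treats correlated offsets as independent observations — each sample's
    library-level baseline is shared by all its offsets, which makes this
    unit anticonservative (it can reject on null cohorts). It is kept for
    comparability with composite-profile figures, not for inference.
    """
    labels = pd.Series(labels)
    pos = [s for s in profiles.index if labels.get(s) == GROUP_POS]
    neg = [s for s in profiles.index if labels.get(s) == GROUP_NEG]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 samples per group")
    if unit == "offset-means":
        a = profiles.loc[pos].to_numpy().mean(axis=0)
        b = profiles.loc[neg].to_numpy().mean(axis=0)
    elif unit == "sample-means":
        a = profiles.loc[pos].to_numpy().mean(axis=1)
        b = profiles.loc[neg].to_numpy().mean(axis=1)
    else:
        raise ValueError(f"unknown unit {unit!r}")
    return wilcoxon_rank_sum(a, b, exact_threshold)
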