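"""Association analyses: rank tests, cumulative rank-scan curves, PCA.

Everything here is non-parametric, matching flow-cytometry expression
summaries whose distributions across genes are skewed: Spearman rank
correlations, Wilcoxon rank-sum group comparisons, Kruskal-Wallis for more
than two groups, Brown-Forsythe (median-centred Levene) for variance
differences, the cumulative rank-scan curve relating a ranked quantity (e.g.
noise) to the running mean of a covariate (e.g. regulator count), and PCA of
the gene x condition mean-expression matrix with a missingness filter.
All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with average-rank ties, two-sided p.

    For n <= 9 the p-value is computed exactly by enumerating all
    permutations of one rank vector; beyond that the usual t approximation
    is used.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        # exact permutation distribution of the rank correlation
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        obs = abs(rx_c @ ry_c)
        count = 0
        total = 0
        for perm in permutations(range(n)):
            stat = abs(rx_c @ ry_c[list(perm)])
            count += stat >= obs - 1e-12 * denom
            total += 1
        p = count / total
    else:
        t = r * np.sqrt((n - 2) / max(1e-300, 1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, p=min(1.0, float(p)), n=n)


def ranksum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact for small samples without ties; normal approximation with tie
    correction otherwise (scipy's ``method="auto"``).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue)


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> float:
    """Kruskal-Wallis chi-square p-value with tie correction.

    A fully degenerate input (all observations identical) carries no
    evidence against the null and is reported as p = 1.
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 observations")
    if np.ptp(values) == 0:
        return 1.0
    return float(stats.kruskal(*samples).pvalue)


def levene_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Brown-Forsythe test (Levene with median centring), two-sided p."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need at least 3 observations")
    return float(stats.levene(a, b, center="median").pvalue)


@dataclass
class CumulativeCurve:
    """Cumulative rank-scan curve.

    Genes are ranked by a quantity (descending); for each cutoff x — the
    quantity value of the gene at rank ``min_first, min_first+1, ..., n`` —
    the mean and standard error (sample SD / sqrt(n)) of a covariate are
    computed over all genes whose quantity is >= x.  Ties at a cutoff are
    all included, so the defining gene always belongs to its own point.
    """

    cutoffs: np.ndarray
    n_genes: np.ndarray
    mean_cov: np.ndarray
    se_cov: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "n": self.n_genes,
                "mean": self.mean_cov,
                "se": self.se_cov,
            }
        )


def cumulative_curve(
    noise: Sequence[float],
    covariate: Sequence[float],
    min_first: int = 6,
) -> CumulativeCurve:
    """Cumulative mean/SE of *covariate* scanning *noise* from high to low.

    The first (rightmost) cutoff sits at the noise level of the gene ranked
    ``min_first``, so every point aggregates at least that many genes; this
    avoids the unreliable means/SEs a 1- or 2-gene prefix would give.
    """
    noise = np.asarray(noise, dtype=np.float64)
    covariate = np.asarray(covariate, dtype=np.float64)
    if noise.shape != covariate.shape or noise.ndim != 1:
        raise ValueError("noise and covariate must align")
    n = len(noise)
    if n < min_first:
        raise ValueError(f"need at least {min_first} genes; got {n}")
    order = np.argsort(-noise, kind="stable")
    ns = noise[order]
    cutoffs, n_genes, means, ses = [], [], [], []
    for rank in range(min_first, n + 1):
        x = ns[rank - 1]
        mask = noise >= x
        vals = covariate[mask]
        cutoffs.append(x)
        n_genes.append(int(vals.size))
        means.append(float(np.mean(vals)))
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        ses.append(sd / np.sqrt(vals.size))
    return CumulativeCurve(
        cutoffs=np.asarray(cutoffs),
        n_genes=np.asarray(n_genes),
        mean_cov=np.asarray(means),
        se_cov=np.asarray(ses),
    )


def cumulative_plasticity_curve(
    noise: Sequence[float],
    plasticity: Sequence[float],
    min_first: int = 6,
) -> CumulativeCurve:
    """Rank-scan of noise against plasticity; same machinery as
    :func:`cumulative_curve` with plasticity as the covariate."""
    return cumulative_curve(noise, plasticity, min_first=min_first)


@dataclass
class PcaResult:
    kept_conditions: list
    kept_genes: list
    scores: np.ndarray  # conditions x components
    loadings: np.ndarray  # genes x components
    var_explained: np.ndarray

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(
            self.scores, index=self.kept_conditions, columns=cols
        )


def pca_expression(
    e_matrix: pd.DataFrame,
    max_missing_genes_per_condition: int = 4,
    scale: bool = False,
) -> PcaResult:
    """PCA of the mean-expression matrix with the missingness filter.

    *e_matrix* is genes x conditions with NaN where a (gene, condition) pair
    was unmeasurable (e.g. expression below the detection limit).  Conditions
    missing more than *max_missing_genes_per_condition* genes are excluded
    first; then only genes observed in every remaining condition are kept.
    Conditions are the observations; each gene (feature) is centred (and
    optionally scaled to unit variance).
    """
    missing_per_condition = e_matrix.isna().sum(axis=0)
    kept_conditions = [
        c
        for c in e_matrix.columns
        if missing_per_condition[c] <= max_missing_genes_per_condition
    ]
    if not kept_conditions:
        raise ValueError(
            "no condition survives the missingness filter; per-condition "
            f"missing-gene counts: {missing_per_condition.to_dict()}"
        )
    sub = e_matrix[kept_conditions]
    kept_genes = list(sub.index[sub.notna().all(axis=1)])
    if len(kept_conditions) < 3 or len(kept_genes) < 3:
        raise ValueError(
            f"matrix too small after filtering: {len(kept_genes)} genes x "
            f"{len(kept_conditions)} conditions; per-condition missing-gene "
            f"counts: {missing_per_condition.to_dict()}"
        )
    X = sub.loc[kept_genes].to_numpy(dtype=np.float64).T  # cond x gene
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = X / sd
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    eig = s**2
    total = eig.sum()
    var_explained = eig / total if total > 0 else eig
    return PcaResult(
        kept_conditions=kept_conditions,
        kept_genes=kept_genes,
        scores=u * s,
        loadings=vt.T,
        var_explained=var_explained,
    )
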