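"""Statistical-test oracles: exact small-sample p-values, hand-computed
Kruskal-Wallis, Brown-Forsythe vs ANOVA-on-deviations, brute-force cumulative
curves, and PCA reconstruction/missingness behaviour."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from noiseplast.assoc import (
    cumulative_curve,
    cumulative_plasticity_curve,
    kruskal_wallis,
    levene_test,
    pca_expression,
    ranksum_test,
    spearman,
)

# ---------------------------------------------------------------- spearman


def test_spearman_perfect_monotone():
    res = spearman([1, 2, 3, 4], [10, 20, 30, 40])
    assert res.r == pytest.approx(1.0)
    # exactly 2 of 4! = 24 permutations reach |r| = 1
    assert res.p == pytest.approx(2 / 24, abs=1e-12)
    res = spearman([1, 2, 3, 4], [4, 3, 2, 1])
    assert res.r == pytest.approx(-1.0)
    assert res.p == pytest.approx(2 / 24, abs=1e-12)


def test_spearman_monotone_transform_invariance():
    x = [1.0, 2.5, 3.1, 7.0, 9.2, 11.0]
    y = [0.2, 0.1, 0.5, 0.4, 0.9, 1.0]
    a = spearman(x, y)
    b = spearman(np.exp(x), y)  # strictly monotone transform of x
    assert a.r == pytest.approx(b.r, abs=1e-12)
    assert a.p == pytest.approx(b.p, abs=1e-12)


def test_spearman_ties_equal_rank_pearson():
    r = np.random.default_rng(0)
    x = np.round(r.normal(size=30), 1)  # heavy ties
    y = np.round(x + r.normal(size=30), 1)
    res = spearman(x, y)
    oracle = float(np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1])
    assert res.r == pytest.approx(oracle, abs=1e-12)
    # scipy agrees on both r and the t-approximation p at n = 30
    sp = stats.spearmanr(x, y)
    assert res.r == pytest.approx(float(sp.statistic), abs=1e-12)
    assert res.p == pytest.approx(float(sp.pvalue), rel=1e-6)


def test_spearman_exact_matches_scipy_permutation_small_n():
    r = np.random.default_rng(5)
    x = r.normal(size=7)
    y = r.normal(size=7)
    res = spearman(x, y)
    ref = stats.permutation_test(
        (y,),
        lambda yy: stats.spearmanr(x, yy).statistic,
        permutation_type="pairings",
        n_resamples=np.inf,
        alternative="two-sided",
    )
    assert res.p == pytest.approx(float(ref.pvalue), abs=1e-9)


def test_spearman_validation():
    with pytest.raises(ValueError):
        spearman([1, 2, 3], [3, 2, 1])  # fewer than 4 points
    with pytest.raises(ValueError):
        spearman([1, 1, 1, 1], [1, 2, 3, 4])  # constant vector


# ---------------------------------------------------------------- rank sum


def test_ranksum_exact_hand_example():
    # complete separation of 3 vs 3: exact two-sided p = 2/20 = 0.1
    assert ranksum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)


def test_ranksum_symmetry_gives_p_one():
    assert ranksum_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)


def test_ranksum_two_sidedness_symmetric_in_groups():
    a, b = [1.0, 2.0, 5.0, 7.0], [3.0, 4.0, 8.0, 9.0, 10.0]
    assert ranksum_test(a, b) == pytest.approx(ranksum_test(b, a), abs=1e-12)


def test_ranksum_detects_planted_shift():
    r = np.random.default_rng(1)
    hits = 0
    for _ in range(100):
        a = r.lognormal(0.0, 1.0, 22)
        b = r.lognormal(0.8, 1.0, 67)  # 0.8 natural-log-units shift
        hits += ranksum_test(a, b) < 0.05
    assert hits >= 80  # large majority of replicates significant


def test_ranksum_empty_group_rejected():
    with pytest.raises(ValueError):
        ranksum_test([], [1.0])


# ----------------------------------------------------------- kruskal-wallis


def test_kruskal_hand_computed():
    # three separated pairs {1,2} {10,11} {20,21}: rank sums give
    # H = 12/(6*7) * sum n_j (rbar_j - 3.5)^2 = 32/7 = 4.5714...,
    # p = chi2.sf(H, df=2) = 0.1017
    vals = [1, 2, 10, 11, 20, 21]
    grp = ["a", "a", "b", "b", "c", "c"]
    p = kruskal_wallis(vals, grp)
    H = 32.0 / 7.0
    assert p == pytest.approx(float(stats.chi2.sf(H, 2)), abs=1e-10)
    assert p == pytest.approx(0.10170139, abs=1e-6)


def test_kruskal_all_equal_is_one():
    assert kruskal_wallis([5.0] * 6, ["a", "a", "b", "b", "c", "c"]) == 1.0


def test_kruskal_two_groups_close_to_ranksum():
    r = np.random.default_rng(2)
    a = r.normal(0, 1, 30)
    b = r.normal(1, 1, 30)
    pk = kruskal_wallis(
        np.concatenate([a, b]), np.array(["a"] * 30 + ["b"] * 30)
    )
    pw = ranksum_test(a, b)
    # KW with 2 groups is the rank-sum test up to continuity correction
    assert pk == pytest.approx(pw, rel=0.1)


def test_kruskal_validation():
    with pytest.raises(ValueError):
        kruskal_wallis([1, 2, 3], ["a", "a", "a"])
    with pytest.raises(ValueError):
        kruskal_wallis([1, 2, 3], ["a", "a", "b"])  # singleton group


# ------------------------------------------------------------------ levene


def test_levene_equals_anova_on_median_deviations():
    r = np.random.default_rng(0)
    a = r.normal(0, 1, 50)
    b = r.normal(0, 10, 50)
    p = levene_test(a, b)
    za = np.abs(a - np.median(a))
    zb = np.abs(b - np.median(b))
    assert p == pytest.approx(float(stats.f_oneway(za, zb).pvalue), rel=1e-9)
    assert p < 0.01  # 10x spread difference detected


def test_levene_identical_groups():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    assert levene_test(a, a) == pytest.approx(1.0)


def test_levene_location_shift_invariance():
    r = np.random.default_rng(3)
    a = r.normal(0, 1, 40)
    b = r.normal(0, 1.2, 40)
    assert levene_test(a, b) == pytest.approx(levene_test(a + 100, b - 50), abs=1e-12)


# -------------------------------------------------------- cumulative curve


def test_cumulative_curve_hand_example():
    # 6 genes, noise 6..1 and covariate 6..1, first cutoff at the 6th gene:
    # single point covering all genes: mean 3.5, SE = SD/sqrt(6) = 0.7638
    c = cumulative_curve([6, 5, 4, 3, 2, 1], [6, 5, 4, 3, 2, 1])
    assert len(c.cutoffs) == 1
    assert c.n_genes[0] == 6
    assert c.mean_cov[0] == pytest.approx(3.5, abs=1e-12)
    assert c.se_cov[0] == pytest.approx(
        np.std([1, 2, 3, 4, 5, 6], ddof=1) / np.sqrt(6), abs=1e-12
    )


def test_cumulative_curve_constant_covariate():
    c = cumulative_curve(np.arange(10.0), np.full(10, 7.0))
    np.testing.assert_allclose(c.mean_cov, 7.0)
    np.testing.assert_allclose(c.se_cov, 0.0)


def test_cumulative_curve_brute_force_oracle():
    r = np.random.default_rng(4)
    for _ in range(20):
        n = int(r.integers(8, 40))
        noise = r.normal(size=n)
        cov = r.normal(size=n)
        c = cumulative_curve(noise, cov)
        order = np.argsort(-noise, kind="stable")
        for j, rank in enumerate(range(6, n + 1)):
            x = noise[order[rank - 1]]
            vals = cov[noise >= x]
            assert c.cutoffs[j] == pytest.approx(x)
            assert c.n_genes[j] == len(vals)
            assert c.mean_cov[j] == pytest.approx(np.mean(vals), abs=1e-12)
            se = np.std(vals, ddof=1) / np.sqrt(len(vals))
            assert c.se_cov[j] == pytest.approx(se, abs=1e-12)


def test_cumulative_curve_final_point_is_global():
    r = np.random.default_rng(6)
    noise, cov = r.normal(size=25), r.normal(size=25)
    c = cumulative_curve(noise, cov)
    assert c.n_genes[-1] == 25
    assert c.mean_cov[-1] == pytest.approx(np.mean(cov), abs=1e-12)


def test_cumulative_curve_needs_min_first_genes():
    with pytest.raises(ValueError):
        cumulative_curve([1, 2, 3], [1, 2, 3])


def test_cumulative_plasticity_alias():
    noise = [6.0, 5, 4, 3, 2, 1]
    cov = [1.0, 2, 3, 4, 5, 6]
    a = cumulative_curve(noise, cov)
    b = cumulative_plasticity_curve(noise, cov)
    np.testing.assert_allclose(a.mean_cov, b.mean_cov)


def test_cumulative_curve_planted_positive_coupling():
    r = np.random.default_rng(8)
    n = 60
    noise = r.normal(size=n)
    cov = 2.0 * noise + r.normal(size=n)
    c = cumulative_curve(noise, cov)
    # high-noise prefix mean exceeds the global mean
    assert c.mean_cov[0] > c.mean_cov[-1]


# --------------------------------------------------------------------- PCA


def _matrix(genes=20, conds=10, seed=0):
    r = np.random.default_rng(seed)
    X = r.normal(2.5, 0.4, size=(genes, conds))
    return pd.DataFrame(
        X,
        index=[f"g{i:03d}" for i in range(genes)],
        columns=[f"c{j:02d}" for j in range(conds)],
    )


def test_pca_missingness_filter():
    m = _matrix()
    # condition c00 misses 5 genes (> 4) -> excluded entirely
    m.iloc[0:5, 0] = np.nan
    # gene g010 missing in a kept condition -> that gene dropped
    m.iloc[10, 3] = np.nan
    res = pca_expression(m)
    assert "c00" not in res.kept_conditions
    assert len(res.kept_conditions) == 9
    assert "g010" not in res.kept_genes
    # the genes missing only in the excluded condition are retained
    for g in ("g000", "g004"):
        assert g in res.kept_genes


def test_pca_var_explained_sums_to_one():
    res = pca_expression(_matrix(seed=2))
    assert res.var_explained.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(res.var_explained) <= 1e-12)


def test_pca_rank_one_matrix():
    g = np.arange(1.0, 13.0)
    c = np.linspace(-1, 1, 8)
    m = pd.DataFrame(
        2.0 + np.outer(g, c),
        index=[f"g{i}" for i in range(12)],
        columns=[f"c{j}" for j in range(8)],
    )
    res = pca_expression(m)
    assert res.var_explained[0] == pytest.approx(1.0, abs=1e-9)


def test_pca_reconstruction():
    m = _matrix(genes=15, conds=7, seed=3)
    res = pca_expression(m)
    X = m.to_numpy().T
    Xc = X - X.mean(axis=0, keepdims=True)
    recon = res.scores @ res.loadings.T
    np.testing.assert_allclose(recon, Xc, atol=1e-9)
    # eigenvalue oracle
    eig = np.linalg.eigvalsh(Xc.T @ Xc)[::-1][: len(res.var_explained)]
    np.testing.assert_allclose(
        res.var_explained, eig / eig.sum(), atol=1e-9
    )


def test_pca_all_conditions_filtered_raises():
    m = _matrix(genes=10, conds=4)
    m.iloc[0:5, :] = np.nan  # every condition misses 5 genes
    with pytest.raises(ValueError, match="missing"):
        pca_expression(m)
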