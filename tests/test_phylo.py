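import numpy as np
import pytest
from scipy import stats as sps

from clawmorph import (
    PhyloCovariance,
    compare_pls,
    design_matrix,
    evolutionary_covariance,
    k_mult,
    lambda_transform,
    LandmarkPartition,
    modularity_cr,
    pgls_ml_lambda,
    phylo_anova_sim,
    phylo_covariance,
    phylo_paired_t,
    phylo_procrustes_anova,
    phylo_two_block_pls,
    read_newick,
    simulate_bm_traits,
    simulate_tree,
)
from clawmorph.errors import ValidationError


# ---------------------------------------------------------------------------
# phylogenetic covariance and lambda transform
# ---------------------------------------------------------------------------

def test_covariance_star_tree(star8):
    np.testing.assert_allclose(star8.C, np.eye(8), atol=1e-12)


def test_covariance_hand_bookkeeping():
    tree = read_newick("((A:1,B:1):1,C:2);")
    cov = phylo_covariance(tree, ["A", "B", "C"])
    assert cov.C[0, 1] == pytest.approx(1.0)
    assert cov.C[0, 0] == pytest.approx(2.0)
    assert cov.C[0, 2] == pytest.approx(0.0)


def test_covariance_ultrametric_diagonal(tree64):
    cov = phylo_covariance(tree64)
    np.testing.assert_allclose(np.diag(cov.C), 1.0, atol=1e-9)


def test_lambda_transform_endpoints(cov24):
    same = lambda_transform(cov24, 1.0)
    np.testing.assert_allclose(same.C, cov24.C, atol=1e-15)
    diag = lambda_transform(cov24, 0.0)
    np.testing.assert_allclose(diag.C, np.diag(np.diag(cov24.C)), atol=1e-15)


def test_lambda_transform_preserves_psd(cov24):
    for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
        evals = np.linalg.eigvalsh(lambda_transform(cov24, lam).C)
        assert evals.min() >= -1e-9 * np.trace(cov24.C)


def test_lambda_transform_bounds(cov24):
    with pytest.raises(ValidationError):
        lambda_transform(cov24, 1.5)


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

def test_pgls_star_tree_equals_ols(star8):
    rng = np.random.default_rng(0)
    x = rng.normal(size=8)
    y = 2.0 + 0.5 * x + rng.normal(size=8)
    X, names = design_matrix(covariates={"x": x})
    fit = pgls_ml_lambda(y, X, star8, coef_names=names)
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    np.testing.assert_allclose(fit.coefficients, beta_ols, atol=1e-10)
    # R^2 equals the OLS R^2 on a star tree
    resid = y - X @ beta_ols
    r2_ols = 1 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
    assert fit.r2 == pytest.approx(r2_ols, abs=1e-8)


def test_pgls_loglik_optimal_over_grid(cov24):
    rng = np.random.default_rng(1)
    x = simulate_bm_traits(cov24, [0.0], [[1.0]], 1.0, seed=5).to_numpy()[:, 0]
    y = 0.8 * x + simulate_bm_traits(cov24, [0.0], [[0.3]], 0.6, seed=6).to_numpy()[:, 0]
    X, names = design_matrix(covariates={"x": x})
    fit = pgls_ml_lambda(y, X, cov24, coef_names=names)
    from clawmorph.phylo import _gls_profile, _lambda_C

    for lam in rng.uniform(0, 1, size=100):
        ll = _gls_profile(y, X, _lambda_C(cov24.C, lam))[3]
        assert fit.log_likelihood >= ll - 1e-6


def test_pgls_factor_design(cov24):
    rng = np.random.default_rng(2)
    y = rng.normal(size=cov24.n)
    f = np.repeat(["u", "v", "w"], cov24.n // 3)
    X, names = design_matrix(factors={"grp": f})
    fit = pgls_ml_lambda(y, X, cov24, coef_names=names)
    assert len(fit.coefficients) == 3
    assert "grp[v]" in fit.coef_names


def test_pgls_rejects_overparameterized(star8):
    y = np.arange(8.0)
    X = np.random.default_rng(3).normal(size=(8, 9))
    with pytest.raises(ValidationError):
        pgls_ml_lambda(y, X, star8)


# ---------------------------------------------------------------------------
# phylogenetic ANOVA (simulation-based)
# ---------------------------------------------------------------------------

def test_phylo_anova_constant_response(cov24):
    y = np.full(cov24.n, 3.0)
    groups = np.repeat(["a", "b", "c"], cov24.n // 3)
    res = phylo_anova_sim(y, groups, cov24, n_sim=99, seed=0)
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_phylo_anova_strong_signal(cov24):
    rng = np.random.default_rng(4)
    groups = np.repeat(["a", "b"], cov24.n // 2)
    y = rng.normal(size=cov24.n) * 0.1 + np.where(groups == "a", 0.0, 10.0)
    res = phylo_anova_sim(y, groups, cov24, n_sim=199, seed=1)
    assert res.p_value == pytest.approx(1 / 200)


def test_phylo_anova_single_group_errors(cov24):
    with pytest.raises(ValidationError):
        phylo_anova_sim(np.ones(cov24.n), ["a"] * cov24.n, cov24, n_sim=99, seed=0)


# ---------------------------------------------------------------------------
# K_mult
# ---------------------------------------------------------------------------

def test_k_mult_star_tree_is_one(star8):
    Y = np.random.default_rng(5).normal(size=(8, 4))
    res = k_mult(Y, star8, n_perm=9, seed=0)
    assert res.statistic == pytest.approx(1.0, abs=1e-12)


def test_k_mult_univariate_matches_blomberg_oracle(cov24):
    y = simulate_bm_traits(cov24, [0.0], [[1.0]], 1.0, seed=7).to_numpy()
    res = k_mult(y, cov24, n_perm=9, seed=0)
    # independent brute-force Blomberg's K
    C = cov24.C
    n = C.shape[0]
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    a = (ones @ Cinv @ y[:, 0]) / (ones @ Cinv @ ones)
    e = y[:, 0] - a
    mse0 = e @ e / (n - 1)
    mse = e @ Cinv @ e / (n - 1)
    expected = (np.trace(C) - n / (ones @ Cinv @ ones)) / (n - 1)
    oracle = (mse0 / mse) / expected
    assert res.statistic == pytest.approx(oracle, abs=1e-10)


def test_k_mult_bm_expectation(cov64):
    ks = [
        k_mult(
            simulate_bm_traits(cov64, np.zeros(4), np.eye(4), 1.0, seed=r).to_numpy(),
            cov64,
            n_perm=9,
            seed=r,
        ).statistic
        for r in range(60)
    ]
    assert 0.9 <= np.mean(ks) <= 1.1


def test_k_mult_detects_signal(cov64):
    Y = simulate_bm_traits(cov64, np.zeros(3), np.eye(3), 1.0, seed=11).to_numpy()
    res = k_mult(Y, cov64, n_perm=199, seed=2)
    assert res.p_value <= 0.05


# ---------------------------------------------------------------------------
# phylogenetic Procrustes ANOVA
# ---------------------------------------------------------------------------

def test_ppa_detects_group_shift(cov24):
    rng = np.random.default_rng(8)
    groups = np.repeat(["a", "b"], cov24.n // 2)
    Y = rng.normal(size=(cov24.n, 6))
    Y[groups == "b"] += 5.0
    res = phylo_procrustes_anova(Y, None, groups, cov24, n_perm=199, seed=3)
    assert res["groups"].p_value == pytest.approx(1 / 200)


def test_ppa_zero_allometry_covariate(cov24):
    # shapes constructed exactly orthogonal to the covariate in GLS space
    from clawmorph.phylo import inv_sqrt_psd

    rng = np.random.default_rng(9)
    n = cov24.n
    groups = np.repeat(["a", "b"], n // 2)
    c = rng.normal(size=n)
    T = inv_sqrt_psd(cov24.C)
    ct = T @ c
    D = np.column_stack([T @ np.ones(n), ct])
    Yt = rng.normal(size=(n, 5))
    Yt -= D @ np.linalg.lstsq(D, Yt, rcond=None)[0]  # residualize
    Y = np.linalg.inv(T) @ Yt
    res = phylo_procrustes_anova(Y, c, groups, cov24, n_perm=199, seed=4)
    assert res["covariate"].details["ss"] == pytest.approx(0.0, abs=1e-10)
    assert res["covariate"].statistic < res["covariate"].null_mean


def test_ppa_rank_deficient_design(cov24):
    groups = ["a"] * cov24.n
    groups[0] = "b"
    Y = np.random.default_rng(10).normal(size=(cov24.n, 4))
    c = np.ones(cov24.n)  # collinear with the intercept
    with pytest.raises(ValidationError):
        phylo_procrustes_anova(Y, c, np.array(groups), cov24, n_perm=99, seed=0)


def test_ppa_pairwise_table_present(cov24):
    rng = np.random.default_rng(11)
    groups = np.repeat(["a", "b", "c"], cov24.n // 3)
    Y = rng.normal(size=(cov24.n, 4))
    res = phylo_procrustes_anova(Y, None, groups, cov24, n_perm=99, seed=5)
    assert set(res["groups"].details["pairwise_p"]) == {"a|b", "a|c", "b|c"}


# ---------------------------------------------------------------------------
# evolutionary covariance
# ---------------------------------------------------------------------------

def test_evolutionary_covariance_star_equals_ordinary(star8):
    Y = np.random.default_rng(12).normal(size=(8, 5))
    S = evolutionary_covariance(Y, star8)
    np.testing.assert_allclose(S, np.cov(Y, rowvar=False), atol=1e-10)


def test_evolutionary_covariance_brute_force():
    tree = simulate_tree(6, seed=3)
    cov = phylo_covariance(tree)
    Y = np.random.default_rng(13).normal(size=(6, 4))
    S = evolutionary_covariance(Y, cov)
    np.testing.assert_allclose(S, S.T, atol=1e-12)
    Cinv = np.linalg.inv(cov.C)
    ones = np.ones(6)
    a = np.linalg.solve(np.array([[ones @ Cinv @ ones]]), (ones @ Cinv @ Y)[None, :])[0]
    E = Y - a
    oracle = E.T @ Cinv @ E / 5
    np.testing.assert_allclose(S, oracle, atol=1e-10)
    assert np.linalg.eigvalsh(S).min() >= -1e-9 * np.trace(S)


# ---------------------------------------------------------------------------
# modularity (CR)
# ---------------------------------------------------------------------------

def test_cr_independent_blocks_low():
    rng = np.random.default_rng(14)
    part = LandmarkPartition.default()
    n = 200
    Y = rng.normal(size=(n, 166))  # all landmarks independent
    res = modularity_cr(Y, part, None, n_perm=199, seed=3)
    # exchangeable structure: CR near 1, not significantly modular
    assert res.statistic == pytest.approx(1.0, abs=0.1)
    assert res.p_value > 0.01


def test_cr_modular_structure_detected():
    rng = np.random.default_rng(15)
    part = LandmarkPartition.default()
    core = part.core_array()
    sheath = part.sheath_array()
    ccols = np.sort(np.concatenate([2 * core, 2 * core + 1]))
    scols = np.sort(np.concatenate([2 * sheath, 2 * sheath + 1]))
    n = 100
    f1, f2 = rng.normal(size=(n, 1)), rng.normal(size=(n, 1))
    Y = np.empty((n, 166))
    Y[:, ccols] = np.sqrt(0.9) * f1 + np.sqrt(0.1) * rng.normal(size=(n, 70))
    Y[:, scols] = np.sqrt(0.9) * f2 + np.sqrt(0.1) * rng.normal(size=(n, 96))
    res = modularity_cr(Y, part, None, n_perm=199, seed=1)
    assert res.p_value <= 0.05
    assert res.statistic < res.null_quantiles["q05"]


def test_cr_small_subset_errors():
    part = LandmarkPartition(frozenset({1}), frozenset(range(2, 84)))
    Y = np.random.default_rng(16).normal(size=(10, 166))
    with pytest.raises(ValidationError):
        modularity_cr(Y, part, None, n_perm=99, seed=0)


# ---------------------------------------------------------------------------
# two-block PLS and compare
# ---------------------------------------------------------------------------

def test_pls_perfect_integration(cov24):
    rng = np.random.default_rng(17)
    Y1 = simulate_bm_traits(cov24, np.zeros(4), np.eye(4), 1.0, seed=21).to_numpy()
    # full-rank scaled rotation: zero-noise coupling, so r-PLS is exactly 1
    M = 2.5 * np.linalg.qr(rng.normal(size=(4, 4)))[0]
    res = phylo_two_block_pls(Y1, Y1 @ M, cov24, n_perm=99, seed=0)
    assert res.statistic == pytest.approx(1.0, abs=1e-10)
    # a general full-rank map still yields near-perfect integration
    res2 = phylo_two_block_pls(Y1, Y1 @ rng.normal(size=(4, 4)), cov24, n_perm=99, seed=0)
    assert res2.statistic > 0.9


def test_pls_first_singular_value_matches_svd_oracle(cov24):
    Y1 = simulate_bm_traits(cov24, np.zeros(5), np.eye(5), 1.0, seed=22).to_numpy()
    Y2 = simulate_bm_traits(cov24, np.zeros(3), np.eye(3), 1.0, seed=23).to_numpy()
    res = phylo_two_block_pls(Y1, Y2, cov24, n_perm=9, seed=0)
    svals = np.asarray(res.details["singular_values"])
    # oracle: explicit evolutionary cross-covariance, brute-force SVD
    C = cov24.C
    Cinv = np.linalg.inv(C)
    ones = np.ones(cov24.n)
    T = np.linalg.eigh(C)[1] @ np.diag(np.linalg.eigvalsh(C) ** -0.5) @ np.linalg.eigh(C)[1].T
    a1 = (ones @ Cinv @ Y1) / (ones @ Cinv @ ones)
    a2 = (ones @ Cinv @ Y2) / (ones @ Cinv @ ones)
    S12 = (T @ (Y1 - a1)).T @ (T @ (Y2 - a2)) / (cov24.n - 1)
    oracle = np.linalg.svd(S12, compute_uv=False)
    frac = svals[0] ** 2 / (svals**2).sum()
    frac_oracle = oracle[0] ** 2 / (oracle**2).sum()
    assert frac == pytest.approx(frac_oracle, abs=1e-10)


def test_pls_constant_block_errors(cov24):
    Y1 = np.ones((cov24.n, 3))
    Y2 = np.random.default_rng(18).normal(size=(cov24.n, 3))
    with pytest.raises(ValidationError):
        phylo_two_block_pls(Y1, Y2, cov24, n_perm=9, seed=0)


def test_compare_pls_self_is_zero(cov24):
    Y1 = simulate_bm_traits(cov24, np.zeros(4), np.eye(4), 1.0, seed=24).to_numpy()
    Y2 = simulate_bm_traits(cov24, np.zeros(4), np.eye(4), 1.0, seed=25).to_numpy()
    res = phylo_two_block_pls(Y1, Y2, cov24, n_perm=99, seed=0)
    table = compare_pls({"a": res, "b": res})
    assert table["z"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert table["p_value"].iloc[0] == pytest.approx(1.0)


def test_compare_pls_monotone_in_coupling(cov24):
    zs = []
    for rho in (0.2, 0.6, 0.95):
        rng = np.random.default_rng(int(rho * 100))
        Y1 = simulate_bm_traits(cov24, np.zeros(4), np.eye(4), 1.0, seed=31).to_numpy()
        noise = rng.normal(size=Y1.shape)
        Y2 = rho * Y1 + np.sqrt(1 - rho**2) * noise
        res = phylo_two_block_pls(Y1, Y2, cov24, n_perm=199, seed=7)
        zs.append(res.effect_size_z)
    assert zs[0] < zs[1] < zs[2]


def test_compare_pls_missing_null_errors(cov24):
    from clawmorph import TestResult

    bad = TestResult(statistic=0.5, p_value=0.1, n_perm=99, seed=0)
    with pytest.raises(ValidationError):
        compare_pls({"a": bad, "b": bad})


# ---------------------------------------------------------------------------
# phylogenetic paired t
# ---------------------------------------------------------------------------

def test_paired_t_identical_inputs(cov24):
    x = np.random.default_rng(19).normal(size=cov24.n)
    res = phylo_paired_t(x, x, cov24)
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_paired_t_star_matches_scipy(star8):
    rng = np.random.default_rng(20)
    x1 = rng.normal(size=8)
    x2 = rng.normal(size=8)
    res = phylo_paired_t(x1, x2, star8)
    oracle = sps.ttest_rel(x1, x2)
    assert res.statistic == pytest.approx(oracle.statistic, abs=1e-8)
    assert res.p_value == pytest.approx(oracle.pvalue, abs=1e-8)


def test_paired_t_power(cov24):
    hits = 0
    R = 60
    for r in range(R):
        d = simulate_bm_traits(cov24, [0.0], [[1.0]], 1.0, seed=300 + r).to_numpy()[:, 0]
        sd = d.std()
        res = phylo_paired_t(d + 3 * sd, np.zeros_like(d), cov24)
        hits += res.p_value < 0.05
    assert hits / R >= 0.9


def test_paired_t_needs_three(star8):
    sub = PhyloCovariance(species=star8.species[:2], C=star8.C[:2, :2])
    with pytest.raises(ValidationError):
        phylo_paired_t(np.ones(2), np.zeros(2), sub)
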