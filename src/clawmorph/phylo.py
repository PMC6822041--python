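"""Phylogenetic comparative statistics.

Covers: the phylogenetic covariance matrix and Pagel's lambda transform,
PGLS with ML lambda, simulation-based phylogenetic ANOVA with pairwise
comparisons, multivariate phylogenetic signal (K_mult), phylogenetic
Procrustes ANOVA via GLS-transformed data and residual randomization,
evolutionary covariance matrices, the covariance-ratio modularity test,
phylogenetic two-block PLS with effect sizes, effect-size comparison
between PLS fits, and the phylogenetic paired t test.

All permutation and simulation tests take an explicit seed, use the
(count + 1) / (n_perm + 1) p-value convention, and summarize their null
distribution in the returned TestResult.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import LandmarkPartition, Phylogeny
from .errors import ValidationError


@dataclass
class PhyloCovariance:
    species: list[str]
    C: np.ndarray

    def __post_init__(self):
        self.C = np.asarray(self.C, float)
        n = len(self.species)
        if self.C.shape != (n, n):
            raise ValidationError("covariance shape does not match species list")
        if not np.allclose(self.C, self.C.T, atol=1e-10):
            raise ValidationError("phylogenetic covariance must be symmetric")
        evals = np.linalg.eigvalsh(self.C)
        if evals.min() < -1e-9 * max(np.trace(self.C), 1.0):
            raise ValidationError("phylogenetic covariance is not PSD")

    @property
    def n(self) -> int:
        return len(self.species)


def phylo_covariance(tree: Phylogeny, species=None) -> PhyloCovariance:
    """Shared root-to-MRCA path lengths among (a subset of) tips."""
    C, order = tree.covariance(species)
    return PhyloCovariance(species=list(order), C=C)


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Multiply off-diagonal entries by lambda; diagonal unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise ValidationError(f"lambda must be in [0, 1], got {lam}")
    C = cov.C * lam
    np.fill_diagonal(C, np.diag(cov.C))
    return PhyloCovariance(species=list(cov.species), C=C)


def _lambda_C(C: np.ndarray, lam: float) -> np.ndarray:
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


def inv_sqrt_psd(C: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition.

    Eigenvalues are clipped at 1e-12 * trace for numerical stability.
    """
    evals, evecs = np.linalg.eigh(C)
    floor = 1e-12 * np.trace(C)
    evals = np.clip(evals, floor, None)
    return evecs @ np.diag(evals**-0.5) @ evecs.T


def holm_correction(pvals: dict) -> dict:
    """Holm step-down adjustment of a family of p-values."""
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted = {}
    running = 0.0
    for rank, (key, p) in enumerate(items):
        adj = min(1.0, (m - rank) * p)
        running = max(running, adj)
        adjusted[key] = running
    return adjusted


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_perm: int
    seed: int
    effect_size_z: float | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    null_quantiles: dict[str, float] = field(default_factory=dict)
    details: dict = field(default_factory=dict)

    @classmethod
    def from_null(cls, statistic, null, p_value, n_perm, seed, z=None, **details):
        null = np.asarray(null, float)
        qs = np.quantile(null, [0.025, 0.05, 0.5, 0.95, 0.975])
        return cls(
            statistic=float(statistic),
            p_value=float(p_value),
            n_perm=n_perm,
            seed=seed,
            effect_size_z=None if z is None else float(z),
            null_mean=float(null.mean()),
            null_sd=float(null.std(ddof=1)) if len(null) > 1 else 0.0,
            null_quantiles={
                "q025": float(qs[0]),
                "q05": float(qs[1]),
                "q50": float(qs[2]),
                "q95": float(qs[3]),
                "q975": float(qs[4]),
            },
            details=details,
        )

    def summary(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "effect_size_z": self.effect_size_z,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "null_quantiles": self.null_quantiles,
            "details": _jsonable(self.details),
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# PGLS with ML Pagel's lambda
# ---------------------------------------------------------------------------

@dataclass
class PglsFit:
    coefficients: np.ndarray
    coef_names: list[str]
    lambda_hat: float
    log_likelihood: float
    r2: float
    sigma2: float
    residuals: np.ndarray
    fitted: np.ndarray
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    df_resid: int


def design_matrix(
    covariates: dict[str, np.ndarray] | None = None,
    factors: dict[str, np.ndarray] | None = None,
    n: int | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Intercept + continuous covariates + dummy-coded factors (drop first)."""
    cols, names = [], []
    covariates = covariates or {}
    factors = factors or {}
    for name, x in covariates.items():
        x = np.asarray(x, float)
        cols.append(x)
        names.append(name)
        n = len(x)
    for name, f in factors.items():
        f = np.asarray(f)
        levels = sorted(set(f.tolist()))
        for lev in levels[1:]:
            cols.append((f == lev).astype(float))
            names.append(f"{name}[{lev}]")
        n = len(f)
    if n is None:
        raise ValidationError("cannot infer n for design matrix")
    X = np.column_stack([np.ones(n)] + cols) if cols else np.ones((n, 1))
    return X, ["intercept"] + names


def _gls_profile(y: np.ndarray, X: np.ndarray, C: np.ndarray):
    """GLS fit at fixed covariance: returns (beta, resid, sigma2_ml, logLik, XtCiX)."""
    n = len(y)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"covariance not positive definite: {exc}") from exc
    Xs = np.linalg.solve(L, X)
    ys = np.linalg.solve(L, y)
    XtX = Xs.T @ Xs
    try:
        beta = np.linalg.solve(XtX, Xs.T @ ys)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"singular design (X' C^-1 X): {exc}") from exc
    resid = y - X @ beta
    rs = ys - Xs @ beta
    rss = float(rs @ rs)
    sigma2 = rss / n
    logdet = 2.0 * np.log(np.diag(L)).sum()
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return beta, resid, sigma2, loglik, XtX


def pgls_ml_lambda(
    y: np.ndarray,
    X: np.ndarray,
    cov: PhyloCovariance,
    coef_names: list[str] | None = None,
) -> PglsFit:
    """PGLS regression with Pagel's lambda estimated by maximum likelihood.

    The lambda profile log-likelihood is maximized over [0, 1] by bounded
    scalar optimization with explicit endpoint checks.  R^2 compares the
    GLS residual sum of squares against the intercept-only GLS fit at the
    same lambda; coefficient p-values use t statistics on n - p df.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if not np.all(np.isfinite(y)):
        raise ValidationError("non-finite response values")
    if n <= p:
        raise ValidationError(f"n = {n} must exceed number of predictors p = {p}")
    C = cov.C

    def negll(lam):
        return -_gls_profile(y, X, _lambda_C(C, lam))[3]

    res = optimize.minimize_scalar(
        negll, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-6}
    )
    candidates = [(negll(0.0), 0.0), (negll(1.0), 1.0), (res.fun, float(res.x))]
    _, lam_hat = min(candidates, key=lambda t: t[0])
    Clam = _lambda_C(C, lam_hat)
    beta, resid, sigma2, loglik, XtCiX = _gls_profile(y, X, Clam)
    # null (intercept-only) fit at the same lambda, for R^2
    ones = np.ones((n, 1))
    _, resid0, sigma2_0, _, _ = _gls_profile(y, ones, Clam)
    L = np.linalg.cholesky(Clam)
    rs = np.linalg.solve(L, resid)
    rs0 = np.linalg.solve(L, resid0)
    r2 = 1.0 - float(rs @ rs) / float(rs0 @ rs0)
    df = n - p
    sigma2_unbiased = float(rs @ rs) / df
    cov_beta = sigma2_unbiased * np.linalg.inv(XtCiX)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return PglsFit(
        coefficients=beta,
        coef_names=coef_names or [f"b{i}" for i in range(p)],
        lambda_hat=lam_hat,
        log_likelihood=loglik,
        r2=r2,
        sigma2=sigma2,
        residuals=resid,
        fitted=X @ beta,
        std_errors=se,
        t_values=tvals,
        p_values=pvals,
        df_resid=df,
    )


# ---------------------------------------------------------------------------
# Simulation-based phylogenetic ANOVA
# ---------------------------------------------------------------------------

def _anova_f(y: np.ndarray, groups: np.ndarray, labels) -> float:
    grand = y.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in labels:
        yg = y[groups == g]
        ss_between += len(yg) * (yg.mean() - grand) ** 2
        ss_within += ((yg - yg.mean()) ** 2).sum()
    df_b = len(labels) - 1
    df_w = len(y) - len(labels)
    if ss_within == 0:
        return 0.0 if ss_between == 0 else np.inf
    return (ss_between / df_b) / (ss_within / df_w)


def _pairwise_t(y, groups, a, b) -> float:
    ya, yb = y[groups == a], y[groups == b]
    na, nb = len(ya), len(yb)
    sp2 = (((ya - ya.mean()) ** 2).sum() + ((yb - yb.mean()) ** 2).sum()) / (
        na + nb - 2
    )
    if sp2 == 0:
        return 0.0
    return (ya.mean() - yb.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def phylo_anova_sim(
    y: np.ndarray,
    groups,
    cov: PhyloCovariance,
    n_sim: int = 1000,
    seed: int = 0,
) -> TestResult:
    """Phylogenetic ANOVA: observed one-way F against a Brownian-motion null.

    The null simulates BM on the tree at the ML rate estimated from y and
    recomputes F each time; pairwise t statistics are referred to their
    simulated nulls with Holm correction.
    """
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) < 2:
        raise ValidationError("phylogenetic ANOVA needs at least 2 groups")
    C = cov.C
    n = len(y)
    ones = np.ones((n, 1))
    _, _, sigma2, _, _ = _gls_profile(y, ones, C)
    Ci1 = np.linalg.solve(C, ones[:, 0])
    mu = float(Ci1 @ y) / float(Ci1 @ ones[:, 0])
    f_obs = _anova_f(y, groups, labels)
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    t_obs = {pr: _pairwise_t(y, groups, *pr) for pr in pairs}
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(C + 1e-12 * np.trace(C) / n * np.eye(n))
    f_null = np.empty(n_sim)
    t_counts = {pr: 0 for pr in pairs}
    for s in range(n_sim):
        ysim = mu + np.sqrt(sigma2) * (L @ rng.standard_normal(n))
        f_null[s] = _anova_f(ysim, groups, labels)
        for pr in pairs:
            if abs(_pairwise_t(ysim, groups, *pr)) >= abs(t_obs[pr]):
                t_counts[pr] += 1
    p = (np.count_nonzero(f_null >= f_obs) + 1) / (n_sim + 1)
    pair_p = {pr: (t_counts[pr] + 1) / (n_sim + 1) for pr in pairs}
    pair_p_holm = holm_correction(pair_p)
    return TestResult.from_null(
        f_obs,
        f_null,
        p,
        n_sim,
        seed,
        pairwise_t={f"{a}|{b}": t_obs[(a, b)] for a, b in pairs},
        pairwise_p={f"{a}|{b}": pair_p[(a, b)] for a, b in pairs},
        pairwise_p_holm={f"{a}|{b}": pair_p_holm[(a, b)] for a, b in pairs},
    )


# ---------------------------------------------------------------------------
# Multivariate phylogenetic signal
# ---------------------------------------------------------------------------

def _phylo_mean(Y: np.ndarray, Cinv: np.ndarray) -> np.ndarray:
    ones = np.ones(Y.shape[0])
    w = Cinv @ ones
    return (w @ Y) / float(ones @ w)


def k_mult(
    Y: np.ndarray,
    cov: PhyloCovariance,
    n_perm: int = 999,
    seed: int = 0,
) -> TestResult:
    """Multivariate phylogenetic signal statistic (expected 1 under BM).

    Permutation test shuffles rows of Y across the tips of the tree.
    """
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    if n < 4:
        raise ValidationError("K_mult needs at least 4 tips")
    C = cov.C
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"singular phylogenetic covariance: {exc}") from exc
    ones = np.ones(n)
    denom_scale = (np.trace(C) - n / float(ones @ Cinv @ ones)) / (n - 1)

    def k_of(Ymat):
        a = _phylo_mean(Ymat, Cinv)
        E = Ymat - a
        num = float((E * E).sum())
        den = float((E * (Cinv @ E)).sum())
        return (num / den) / denom_scale

    k_obs = k_of(Y)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = k_of(Y[rng.permutation(n)])
    p = (np.count_nonzero(null >= k_obs) + 1) / (n_perm + 1)
    return TestResult.from_null(k_obs, null, p, n_perm, seed)


# ---------------------------------------------------------------------------
# Phylogenetic Procrustes ANOVA (GLS + RRPP)
# ---------------------------------------------------------------------------

def _hat_fit(X: np.ndarray, Y: np.ndarray):
    """OLS fit returning (fitted, residuals) via lstsq (rank tolerant)."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ beta
    return fitted, Y - fitted


def phylo_procrustes_anova(
    Y: np.ndarray,
    covariate: np.ndarray | None,
    groups,
    cov: PhyloCovariance,
    n_perm: int = 999,
    seed: int = 0,
) -> dict[str, TestResult]:
    """Multivariate GLS (Procrustes) ANOVA with sequential sums of squares.

    Data and design are transformed by the symmetric inverse square root of
    the phylogenetic covariance; term significance uses residual
    randomization of the reduced model (RRPP); pairwise group comparisons
    use distances between group GLS means against their permuted
    distribution.  Keys of the result: 'covariate' (if given), 'groups'.
    """
    Y = np.asarray(Y, float)
    n, p = Y.shape
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    T = inv_sqrt_psd(cov.C)
    Yt = T @ Y
    ones = T @ np.ones((n, 1))
    terms = []
    Xs = [ones]
    if covariate is not None:
        covariate = np.asarray(covariate, float)
        Xs.append(np.column_stack([ones, T @ covariate[:, None]]))
        terms.append("covariate")
    G = np.column_stack([(groups == g).astype(float) for g in labels[1:]])
    Xs.append(np.column_stack([Xs[-1], T @ G]))
    terms.append("groups")
    dfs = [Xs[i + 1].shape[1] - Xs[i].shape[1] for i in range(len(terms))]
    full = Xs[-1]
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValidationError("rank-deficient design matrix")
    df_res = n - full.shape[1]
    if df_res <= 0:
        raise ValidationError("no residual degrees of freedom")

    def term_stats(Ymat):
        rss = []
        fits = []
        for X in Xs:
            fit, resid = _hat_fit(X, Ymat)
            rss.append(float((resid**2).sum()))
            fits.append((fit, resid))
        ss_res = rss[-1]
        out = []
        for i in range(len(terms)):
            ss = rss[i] - rss[i + 1]
            F = (ss / dfs[i]) / (ss_res / df_res) if ss_res > 0 else np.inf
            out.append((ss, F))
        return out, fits

    obs, fits = term_stats(Yt)
    rng = np.random.default_rng(seed)
    f_null = {t: np.empty(n_perm) for t in terms}
    counts = {t: 0 for t in terms}

    # pairwise group means (GLS lsmeans): distances between group means of
    # residuals from the covariate-only model added back per group
    def group_mean_dists(Ymat, reduced_fit, reduced_resid):
        dists = {}
        adj = reduced_resid
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                ma = adj[groups == a].mean(axis=0)
                mb = adj[groups == b].mean(axis=0)
                dists[(a, b)] = float(np.linalg.norm(ma - mb))
        return dists

    red_fit, red_resid = fits[-2]
    obs_dists = group_mean_dists(Yt, red_fit, red_resid)
    dist_counts = {pr: 0 for pr in obs_dists}

    for s in range(n_perm):
        perm = rng.permutation(n)
        for i, t in enumerate(terms):
            fit_r, resid_r = fits[i]  # reduced model for term i
            Yperm = fit_r + resid_r[perm]
            stats_perm, fits_perm = term_stats(Yperm)
            f_null[t][s] = stats_perm[i][1]
            if stats_perm[i][1] >= obs[i][1]:
                counts[t] += 1
            if t == "groups":
                d = group_mean_dists(Yperm, *fits_perm[-2])
                for pr in dist_counts:
                    if d[pr] >= obs_dists[pr]:
                        dist_counts[pr] += 1

    results: dict[str, TestResult] = {}
    for i, t in enumerate(terms):
        p_val = (counts[t] + 1) / (n_perm + 1)
        extra = {}
        if t == "groups":
            pair_p = {pr: (dist_counts[pr] + 1) / (n_perm + 1) for pr in dist_counts}
            extra = {
                "pairwise_dist": {f"{a}|{b}": obs_dists[(a, b)] for a, b in obs_dists},
                "pairwise_p": {f"{a}|{b}": pair_p[(a, b)] for a, b in pair_p},
                "pairwise_p_holm": {
                    f"{a}|{b}": v
                    for (a, b), v in holm_correction(pair_p).items()
                },
            }
        null = f_null[t]
        z = None
        if null.std(ddof=1) > 0:
            z = (obs[i][1] - null.mean()) / null.std(ddof=1)
        results[t] = TestResult.from_null(
            obs[i][1], null, p_val, n_perm, seed, z=z, ss=obs[i][0],
            df=dfs[i], df_res=df_res, **extra,
        )
    return results


# ---------------------------------------------------------------------------
# Evolutionary covariance, modularity, integration
# ---------------------------------------------------------------------------

def evolutionary_covariance(Y: np.ndarray, cov: PhyloCovariance) -> np.ndarray:
    """(Y - 1a)' C^-1 (Y - 1a) / (n - 1) with a the phylogenetic mean."""
    Y = np.asarray(Y, float)
    n = Y.shape[0]
    if n < 2:
        raise ValidationError("need n > 1")
    try:
        Cinv = np.linalg.inv(cov.C)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"singular phylogenetic covariance: {exc}") from exc
    E = Y - _phylo_mean(Y, Cinv)
    return E.T @ Cinv @ E / (n - 1)


def _cr_statistic(S: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> float:
    """Covariance ratio on coordinate blocks of a flattened (x,y) covariance.

    Within-module matrices have their per-landmark 2x2 diagonal blocks
    zeroed so CR ignores per-landmark variance inflation.
    """
    c1 = np.sort(np.concatenate([2 * idx1, 2 * idx1 + 1]))
    c2 = np.sort(np.concatenate([2 * idx2, 2 * idx2 + 1]))
    S12 = S[np.ix_(c1, c2)]

    def zeroed_norm(cols):
        B = S[np.ix_(cols, cols)].copy()
        for j in range(0, len(cols), 2):
            B[j:j + 2, j:j + 2] = 0.0
        return np.linalg.norm(B)

    denom = np.sqrt(zeroed_norm(c1) * zeroed_norm(c2))
    if denom == 0:
        return np.inf
    return float(np.linalg.norm(S12) / denom)


def modularity_cr(
    Y: np.ndarray,
    partition: LandmarkPartition,
    cov: PhyloCovariance | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> TestResult:
    """Covariance-ratio modularity test.

    Y holds flattened (x1, y1, x2, y2, ...) coordinates.  The null
    reassigns whole landmarks to the two subsets (original sizes kept);
    modularity is supported when the observed CR is low relative to the
    null: p = P(CR_null <= CR_obs).
    """
    Y = np.asarray(Y, float)
    n, p = Y.shape
    k = p // 2
    idx1 = partition.core_array()
    idx2 = partition.sheath_array()
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValidationError("each module needs at least 2 landmarks")
    if cov is not None:
        S = evolutionary_covariance(Y, cov)
    else:
        Yc = Y - Y.mean(axis=0)
        S = Yc.T @ Yc / (n - 1)
    cr_obs = _cr_statistic(S, idx1, idx2)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    all_lm = np.arange(k)
    for i in range(n_perm):
        perm = rng.permutation(all_lm)
        null[i] = _cr_statistic(S, np.sort(perm[: len(idx1)]), np.sort(perm[len(idx1):]))
    p_val = (np.count_nonzero(null <= cr_obs) + 1) / (n_perm + 1)
    sd = null.std(ddof=1)
    z = (cr_obs - null.mean()) / sd if sd > 0 else None
    return TestResult.from_null(cr_obs, null, p_val, n_perm, seed, z=z)


def _fisher_z(r: float) -> float:
    r = min(max(r, -0.999999999), 0.999999999)
    return float(np.arctanh(r))


def phylo_two_block_pls(
    Y1: np.ndarray,
    Y2: np.ndarray,
    cov: PhyloCovariance | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> TestResult:
    """Two-block PLS of the (evolutionary) cross-block covariance.

    r-PLS is the correlation of the paired first singular-vector scores;
    significance permutes the rows of Y2; the effect size is the
    standardized Fisher-z of r against its permuted null.
    """
    Y1 = np.asarray(Y1, float)
    Y2 = np.asarray(Y2, float)
    n = Y1.shape[0]
    if n < 4:
        raise ValidationError("two-block PLS needs n >= 4")
    if np.allclose(Y1.std(axis=0), 0) or np.allclose(Y2.std(axis=0), 0):
        raise ValidationError("a PLS block is constant")
    if cov is not None:
        T = inv_sqrt_psd(cov.C)
        Cinv = np.linalg.inv(cov.C)
        E1 = T @ (Y1 - _phylo_mean(Y1, Cinv))
        E2_obs = T @ (Y2 - _phylo_mean(Y2, Cinv))
    else:
        E1 = Y1 - Y1.mean(axis=0)
        E2_obs = Y2 - Y2.mean(axis=0)

    def pls_r(E2, return_vectors=False):
        S12 = E1.T @ E2 / (n - 1)
        U, svals, Vt = np.linalg.svd(S12, full_matrices=False)
        u1, v1 = U[:, 0], Vt[0]
        s1, s2 = E1 @ u1, E2 @ v1
        denom = s1.std() * s2.std()
        r = float(np.corrcoef(s1, s2)[0, 1]) if denom > 0 else 0.0
        if return_vectors:
            return r, u1, v1, s1, s2, svals
        return r

    r_obs, u1, v1, s1, s2, svals = pls_r(E2_obs, return_vectors=True)
    # permute rows of the (GLS-transformed) second block: transformed
    # residual rows are exchangeable under the no-association null
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = pls_r(E2_obs[rng.permutation(n)])
    p = (np.count_nonzero(null >= r_obs) + 1) / (n_perm + 1)
    z_null = np.array([_fisher_z(r) for r in null])
    sd = z_null.std(ddof=1)
    z = (_fisher_z(r_obs) - z_null.mean()) / sd if sd > 0 else None
    return TestResult.from_null(
        r_obs,
        null,
        p,
        n_perm,
        seed,
        z=z,
        left_vector=u1,
        right_vector=v1,
        left_scores=s1,
        right_scores=s2,
        singular_values=svals,
        fisher_z=_fisher_z(r_obs),
        fisher_z_null_sd=float(sd),
        fisher_z_null_mean=float(z_null.mean()),
    )


def compare_pls(results: dict[str, TestResult]) -> pd.DataFrame:
    """Pairwise comparison of PLS effect sizes.

    z_ab = |z_a - z_b| / sqrt(se_a^2 + se_b^2) with z the Fisher-transformed
    r-PLS and se the standard deviation of the Fisher-z permuted null;
    two-sided normal p-values.
    """
    if len(results) < 2:
        raise ValidationError("need at least 2 PLS results to compare")
    for name, res in results.items():
        if "fisher_z" not in res.details or "fisher_z_null_sd" not in res.details:
            raise ValidationError(f"PLS result {name!r} lacks a permuted null")
    names = list(results)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            za = results[a].details["fisher_z"]
            zb = results[b].details["fisher_z"]
            sa = results[a].details["fisher_z_null_sd"]
            sb = results[b].details["fisher_z_null_sd"]
            denom = np.sqrt(sa**2 + sb**2)
            z = abs(za - zb) / denom if denom > 0 else 0.0
            p = 2.0 * stats.norm.sf(z)
            rows.append({"a": a, "b": b, "z": z, "p_value": min(p, 1.0)})
    return pd.DataFrame(rows)


def phylo_paired_t(
    x1: np.ndarray,
    x2: np.ndarray,
    cov: PhyloCovariance,
) -> TestResult:
    """Phylogenetic paired t test on d = x1 - x2 with ML lambda."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    n = len(x1)
    if n < 3:
        raise ValidationError("paired t test needs n >= 3")
    d = x1 - x2
    ones = np.ones((n, 1))
    C = cov.C
    if np.ptp(d) == 0.0:
        # constant difference: zero residual variance; t is 0 (no shift) or
        # unbounded (exact shift), reported with the smallest positive p
        t = 0.0 if d[0] == 0 else np.inf
        return TestResult(
            statistic=float(t),
            p_value=1.0 if d[0] == 0 else np.finfo(float).tiny,
            n_perm=0,
            seed=0,
            details={"lambda_hat": 0.0, "mean_difference": float(d[0]), "df": n - 1},
        )

    def negll(lam):
        return -_gls_profile(d, ones, _lambda_C(C, lam))[3]

    res = optimize.minimize_scalar(
        negll, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-6}
    )
    candidates = [(negll(0.0), 0.0), (negll(1.0), 1.0), (res.fun, float(res.x))]
    _, lam_hat = min(candidates, key=lambda t: t[0])
    Clam = _lambda_C(C, lam_hat)
    Cinv = np.linalg.inv(Clam)
    Ci1 = Cinv @ np.ones(n)
    w = float(Ci1 @ np.ones(n))
    mu = float(Ci1 @ d) / w
    resid = d - mu
    sigma2 = float(resid @ Cinv @ resid) / n
    se = np.sqrt(sigma2 * n / (n - 1) / w)
    t = mu / se if se > 0 else 0.0
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TestResult(
        statistic=float(t),
        p_value=float(min(p, 1.0)),
        n_perm=0,
        seed=0,
        details={"lambda_hat": lam_hat, "mean_difference": mu, "df": n - 1},
    )
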