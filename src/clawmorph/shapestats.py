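"""Non-phylogenetic shape statistics: PCA, allometry, and disparity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .superimpose import ShapeSample


@dataclass
class PcaResult:
    scores: np.ndarray        # n x d
    loadings: np.ndarray      # d x p  (rows are component vectors)
    eigenvalues: np.ndarray   # d, non-increasing
    percent_variance: np.ndarray
    mean: np.ndarray          # p, column means of the input


@dataclass
class CacResult:
    cac_scores: np.ndarray
    direction: np.ndarray
    r2: float
    p_value: float
    n_perm: int
    seed: int
    null_r2: np.ndarray


@dataclass
class DisparityResult:
    group_pv: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]
    pairwise_delta: dict[tuple[str, str], float]
    n_perm: int
    seed: int


def _as_matrix(sample) -> np.ndarray:
    if isinstance(sample, ShapeSample):
        return sample.flattened()
    return np.asarray(sample, float)


def shape_pca(sample: ShapeSample | np.ndarray) -> PcaResult:
    """PCA of column-centered flattened coordinates (covariance based).

    Component signs are fixed by making the largest-magnitude loading of
    each component positive.
    """
    Y = _as_matrix(sample)
    n = Y.shape[0]
    if n < 2:
        raise ValidationError("PCA needs at least 2 observations")
    mean = Y.mean(axis=0)
    Yc = Y - mean
    cov = Yc.T @ Yc / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    d = min(n - 1, Y.shape[1])
    evals = evals[:d]
    evecs = evecs[:, :d]
    for j in range(d):
        i_max = np.argmax(np.abs(evecs[:, j]))
        if evecs[i_max, j] < 0:
            evecs[:, j] *= -1
    total = float(np.trace(cov))
    percent = 100.0 * evals / total if total > 0 else np.zeros(d)
    return PcaResult(
        scores=Yc @ evecs,
        loadings=evecs.T,
        eigenvalues=evals,
        percent_variance=percent,
        mean=mean,
    )


def common_allometric_component(
    sample: ShapeSample,
    n_perm: int = 999,
    seed: int = 0,
) -> CacResult:
    """Pooled regression of shape on log centroid size.

    The CAC direction is Y'c / c'c (normalized); R^2 is the Procrustes
    regression sum of squares over total; the permutation p-value shuffles
    specimen rows of Y against c.
    """
    Y = sample.flattened()
    n = Y.shape[0]
    if n < 3:
        raise ValidationError("allometry test needs n >= 3")
    c = sample.log_centroid_sizes()
    c = c - c.mean()
    css = float(c @ c)
    if css <= 1e-20 * n * max(1.0, float(np.abs(np.log(sample.centroid_sizes)).max()) ** 2):
        raise ValidationError("zero variance in log centroid size")
    Yc = Y - Y.mean(axis=0)
    tss = float((Yc**2).sum())

    def r2_of(Ymat):
        b = Ymat.T @ c / css
        ss_fit = css * float(b @ b)
        return ss_fit / tss

    b = Yc.T @ c / css
    norm_b = np.linalg.norm(b)
    direction = b / norm_b if norm_b > 0 else b
    cac_scores = Yc @ direction
    r2_obs = r2_of(Yc)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        null[i] = r2_of(Yc[perm])
    p = (np.count_nonzero(null >= r2_obs) + 1) / (n_perm + 1)
    return CacResult(
        cac_scores=cac_scores,
        direction=direction,
        r2=r2_obs,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        null_r2=null,
    )


def procrustes_variance(Y: np.ndarray) -> float:
    """Mean squared deviation from the group mean (divisor n, not n-1)."""
    Y = np.asarray(Y, float)
    mean = Y.mean(axis=0)
    return float(((Y - mean) ** 2).sum() / Y.shape[0])


def morphological_disparity(
    sample: ShapeSample | np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> DisparityResult:
    """Procrustes-variance disparity per group with permutation pairwise tests."""
    Y = _as_matrix(sample)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) < 2:
        raise ValidationError("disparity needs at least 2 groups")
    for g in labels:
        if np.count_nonzero(groups == g) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 members")

    def pvs(lbls):
        return {g: procrustes_variance(Y[lbls == g]) for g in labels}

    obs = pvs(groups)
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    obs_delta = {pr: abs(obs[pr[0]] - obs[pr[1]]) for pr in pairs}
    rng = np.random.default_rng(seed)
    counts = {pr: 0 for pr in pairs}
    for _ in range(n_perm):
        shuffled = groups[rng.permutation(len(groups))]
        null = pvs(shuffled)
        for pr in pairs:
            if abs(null[pr[0]] - null[pr[1]]) >= obs_delta[pr]:
                counts[pr] += 1
    pvals = {pr: (counts[pr] + 1) / (n_perm + 1) for pr in pairs}
    return DisparityResult(
        group_pv=obs,
        pairwise_p=pvals,
        pairwise_delta=obs_delta,
        n_perm=n_perm,
        seed=seed,
    )
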