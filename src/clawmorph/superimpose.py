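"""Generalized Procrustes Analysis and bending-energy semilandmark sliding."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import (
    CURVE_ANCHORS,
    CURVE_NAMES,
    CURVE_SLICES,
    ClawConfiguration,
    N_FIXED,
    N_LANDMARKS,
)
from .errors import ValidationError

log = logging.getLogger(__name__)


def centroid_size(config: np.ndarray | ClawConfiguration) -> float:
    """sqrt of summed squared distances of the points from their centroid."""
    coords = config.coords if isinstance(config, ClawConfiguration) else np.asarray(config, float)
    if not np.all(np.isfinite(coords)):
        raise ValidationError("non-finite coordinates")
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs <= 0:
        raise ValidationError("degenerate configuration: all points identical")
    return cs


def _optimal_rotation(X: np.ndarray, target: np.ndarray, allow_reflection: bool) -> np.ndarray:
    """Orthogonal R minimizing ||X R - target||_F; det(R)=+1 unless allowed."""
    U, _, Vt = np.linalg.svd(X.T @ target)
    R = U @ Vt
    if not allow_reflection and np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    return R


@dataclass
class ShapeSample:
    """A GPA-aligned sample: n x 83 x 2 coordinates plus size and metadata."""

    aligned: np.ndarray
    centroid_sizes: np.ndarray
    mean_shape: np.ndarray
    specimen_ids: list[str]
    species: list[str] = field(default_factory=list)
    ecology: list[str] = field(default_factory=list)
    slide_info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.aligned = np.asarray(self.aligned, float)
        self.centroid_sizes = np.asarray(self.centroid_sizes, float)
        n = self.aligned.shape[0]
        if n < 2:
            raise ValidationError("a shape sample needs at least 2 configurations")
        if self.aligned.shape[1:] != (N_LANDMARKS, 2):
            raise ValidationError(f"aligned array must be n x {N_LANDMARKS} x 2")
        if len(self.centroid_sizes) != n or np.any(self.centroid_sizes <= 0):
            raise ValidationError("centroid sizes must be positive, one per specimen")

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    def flattened(self) -> np.ndarray:
        """n x 166 row-major (x1, y1, x2, y2, ...) flattening."""
        return self.aligned.reshape(self.n, -1)

    def log_centroid_sizes(self) -> np.ndarray:
        return np.log(self.centroid_sizes)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{ax}{i + 1}" for i in range(N_LANDMARKS) for ax in ("x", "y")]
        df = pd.DataFrame(self.flattened(), columns=cols)
        df.insert(0, "specimen_id", self.specimen_ids)
        df["centroid_size"] = self.centroid_sizes
        if self.species:
            df["species"] = self.species
        if self.ecology:
            df["ecology"] = self.ecology
        return df


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two pre-aligned configurations."""
    return float(np.linalg.norm(a - b))


def gpa(
    configs: Sequence[ClawConfiguration] | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    allow_reflection: bool = False,
) -> ShapeSample:
    """Generalized Procrustes Analysis.

    Each configuration is centered, scaled to unit centroid size, and
    rotated to the iteratively re-estimated mean (renormalized to unit
    centroid size each round).  Rotations are proper (det +1) unless
    ``allow_reflection`` is set.
    """
    if isinstance(configs, np.ndarray):
        coords = np.asarray(configs, float)
        ids = [f"config_{i + 1}" for i in range(coords.shape[0])]
        species, ecology = [], []
    else:
        coords = np.stack([c.coords for c in configs])
        ids = [c.specimen_id for c in configs]
        species = [c.species for c in configs]
        ecology = [c.ecology.value for c in configs]
    n = coords.shape[0]
    if n < 2:
        raise ValidationError("GPA needs at least 2 configurations")

    sizes = np.empty(n)
    X = np.empty_like(coords)
    for i in range(n):
        centered = coords[i] - coords[i].mean(axis=0)
        cs = np.sqrt((centered**2).sum())
        if cs <= 0:
            raise ValidationError(f"degenerate configuration {ids[i]!r}")
        sizes[i] = cs
        X[i] = centered / cs

    # reference-free iteration: align to running mean
    mean = X[0].copy()
    mean /= np.linalg.norm(mean)
    for _ in range(max_iter):
        for i in range(n):
            R = _optimal_rotation(X[i], mean, allow_reflection)
            X[i] = X[i] @ R
        new_mean = X.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        new_mean /= np.linalg.norm(new_mean)
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            break
        mean = new_mean
    # final pass so every specimen is aligned to the converged mean
    for i in range(n):
        R = _optimal_rotation(X[i], mean, allow_reflection)
        X[i] = X[i] @ R
    return ShapeSample(
        aligned=X,
        centroid_sizes=sizes,
        mean_shape=mean,
        specimen_ids=ids,
        species=species,
        ecology=ecology,
    )


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Thin-plate-spline bending-energy matrix of an 83-point reference.

    Kernel U(r) = r^2 log(r^2) with U(0) = 0; the affine part is [1, x, y].
    Returns the upper-left k x k block of the inverse of the bordered TPS
    system.  Symmetric and PSD on the subspace orthogonal to affine
    configurations.
    """
    ref = np.asarray(reference, float)
    k = ref.shape[0]
    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(-1)
    if np.any(d2[~np.eye(k, dtype=bool)] == 0):
        raise ValidationError("repeated reference points make the TPS system singular")
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(d2 > 0, d2 * np.log(d2), 0.0)
    P = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"singular TPS system: {exc}") from exc
    B = Linv[:k, :k]
    return (B + B.T) / 2.0


def _semilandmark_tangents(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit tangents at each semilandmark (central difference along curve).

    Returns (indices, tangents): the 0-based point indices of the 77
    semilandmarks and their unit tangent vectors.
    """
    idx = []
    tangents = []
    for name in CURVE_NAMES:
        sl = CURVE_SLICES[name]
        start_anchor, end_anchor = CURVE_ANCHORS[name]
        pts = list(range(sl.start, sl.stop))
        chain = [start_anchor] + pts + [end_anchor]
        for j, p in enumerate(pts, start=1):
            prev_pt = coords[chain[j - 1]]
            next_pt = coords[chain[j + 1]]
            t = next_pt - prev_pt
            norm = np.linalg.norm(t)
            if norm == 0:
                t = np.array([1.0, 0.0])
            else:
                t = t / norm
            idx.append(p)
            tangents.append(t)
    return np.array(idx), np.array(tangents)


def total_bending_energy(aligned: np.ndarray, mean: np.ndarray) -> float:
    """Sum over specimens of the TPS bending energy from `mean` to each."""
    BE = bending_energy_matrix(mean)
    total = 0.0
    for X in aligned:
        D = X - mean
        total += float(D[:, 0] @ BE @ D[:, 0] + D[:, 1] @ BE @ D[:, 1])
    return total


def slide_semilandmarks(
    sample: ShapeSample,
    outer_iters: int = 3,
    allow_reflection: bool = False,
) -> ShapeSample:
    """Slide semilandmarks along their curve tangents to minimize the TPS
    bending energy relative to the sample mean; re-GPA after each sweep.

    Fixed landmarks (1-6) never move.  Records per-iteration total bending
    energy (before/after each sweep) in ``slide_info['bending_energy']``.
    """
    X = sample.aligned.copy()
    mean = sample.mean_shape.copy()
    history = []
    prev_state = None
    prev_after = np.inf
    for it in range(outer_iters):
        BE = bending_energy_matrix(mean)
        before = total_bending_energy(X, mean)
        for i in range(X.shape[0]):
            idx, T = _semilandmark_tangents(X[i])
            m = len(idx)
            # U maps slide amounts to flattened displacements: column j moves
            # point idx[j] by T[j]; energy separates over x/y with same BE.
            D0 = X[i] - mean
            # quadratic form: minimize (D0 + U t)' BE2 (D0 + U t)
            # A[j,l] = T_j . (BE[idx_j, idx_l]) T_l  componentwise per axis
            Bsub = BE[np.ix_(idx, idx)]
            A = Bsub * (T[:, 0][:, None] * T[:, 0][None, :]) + Bsub * (
                T[:, 1][:, None] * T[:, 1][None, :]
            )
            g = T[:, 0] * (BE[idx] @ D0[:, 0]) + T[:, 1] * (BE[idx] @ D0[:, 1])
            try:
                t = np.linalg.solve(A + 1e-12 * np.trace(A) / m * np.eye(m), -g)
            except np.linalg.LinAlgError:
                log.warning(
                    "singular sliding system for %s; skipping slide",
                    sample.specimen_ids[i],
                )
                continue
            Xi = X[i].copy()
            Xi[idx] += t[:, None] * T
            # guard: accept only energy-non-increasing slides
            e_old = float(D0[:, 0] @ BE @ D0[:, 0] + D0[:, 1] @ BE @ D0[:, 1])
            Dn = Xi - mean
            e_new = float(Dn[:, 0] @ BE @ Dn[:, 0] + Dn[:, 1] @ BE @ Dn[:, 1])
            if e_new <= e_old:
                X[i] = Xi
        after = total_bending_energy(X, mean)
        if after > prev_after and prev_state is not None:
            # mean update stopped paying off: converged; keep previous state
            X, mean = prev_state
            log.debug("sliding converged after %d outer iterations", it)
            break
        history.append({"iteration": it + 1, "before": before, "after": after})
        prev_after = after
        resample = gpa(X, allow_reflection=allow_reflection)
        X = resample.aligned
        mean = resample.mean_shape
        prev_state = (X.copy(), mean.copy())
    out = ShapeSample(
        aligned=X,
        centroid_sizes=sample.centroid_sizes,
        mean_shape=mean,
        specimen_ids=sample.specimen_ids,
        species=sample.species,
        ecology=sample.ecology,
        slide_info={"outer_iters": outer_iters, "bending_energy": history},
    )
    return out
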