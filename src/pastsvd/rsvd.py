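"""Exact and randomized truncated SVD of Casorati matrices.

Separating coherent tissue signal from noise rests on the singular value
decomposition S = U diag(s) V*. For RF stacks the spatial dimension
(n_x * n_z, often ~1e5) dwarfs the temporal one (n_t ~ 1e2), so a full SVD is
wasteful: a randomized range finder sketches the column space with a Gaussian
test matrix, orthonormalizes it with a pivoted QR, sharpens it with a few
power iterations, and the denoised data are the projection P = Q Q^T S.
All arithmetic is real (RF samples are real, so the conjugate transpose is a
plain transpose) and in double precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .data_io import CasoratiMatrix

__all__ = [
    "SVDFactors",
    "FilterMask",
    "full_svd",
    "svd_filter",
    "randomized_range_finder",
    "rsvd_denoise",
    "truncated_factors",
]


@dataclass
class SVDFactors:
    """SVD factors of a Casorati matrix.

    ``spatial_vectors`` (U) has orthonormal columns of length n_x*n_z,
    ``temporal_vectors`` (V) orthonormal columns of length n_t, and
    ``singular_values`` is nonnegative and descending.
    """

    spatial_vectors: np.ndarray
    singular_values: np.ndarray
    temporal_vectors: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.singular_values, dtype=float)
        if np.any(s < 0) or np.any(np.diff(s) > 0):
            raise ValueError("singular values must be nonnegative and descending")
        self.singular_values = s

    @property
    def rank(self) -> int:
        return len(self.singular_values)


@dataclass
class FilterMask:
    """Which singular components to keep: a boolean vector or a leading count."""

    keep: np.ndarray | int

    def as_bool(self, n: int) -> np.ndarray:
        if isinstance(self.keep, (int, np.integer)):
            k = int(self.keep)
            if k < 0 or k > n:
                raise ValueError(f"rank {k} out of range [0, {n}]")
            mask = np.zeros(n, dtype=bool)
            mask[:k] = True
            return mask
        mask = np.asarray(self.keep, dtype=bool)
        if mask.shape != (n,):
            raise ValueError(f"mask length {mask.shape} does not match {n} components")
        return mask


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Sign convention: largest-magnitude entry of each spatial vector positive.
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, V * signs


def full_svd(S: CasoratiMatrix) -> SVDFactors:
    """Economy SVD with a deterministic per-component sign convention."""
    values = np.asarray(S.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("Casorati matrix must be finite")
    U, s, Vh = np.linalg.svd(values, full_matrices=False)
    U, V = _fix_signs(U, Vh.T)
    return SVDFactors(spatial_vectors=U, singular_values=s, temporal_vectors=V)


def svd_filter(
    factors: SVDFactors, mask: FilterMask, S: CasoratiMatrix
) -> CasoratiMatrix:
    """Reconstruct S from a subset of singular components (S_F = U D I_F V^T)."""
    keep = mask.as_bool(factors.rank)
    U = factors.spatial_vectors[:, keep]
    V = factors.temporal_vectors[:, keep]
    s = factors.singular_values[keep]
    filtered = (U * s) @ V.T
    if filtered.size == 0 or not keep.any():
        filtered = np.zeros_like(np.asarray(S.values, dtype=float))
    return CasoratiMatrix(values=filtered, n_x=S.n_x, n_z=S.n_z)


def randomized_range_finder(
    S: CasoratiMatrix,
    k: int,
    oversample: int = 8,
    power_iterations: int = 2,
    seed: int | None = None,
) -> np.ndarray:
    """Orthonormal basis Q approximating the leading k-dimensional column space.

    Sketch S' = S R with R ~ N(0,1) i.i.d. of width k + oversample, then a
    pivoted QR of S' yields Q; each power-iteration round replaces Q by an
    orthonormal basis of S (S^T Q), re-orthonormalizing every round to avoid
    floating-point collapse of the small singular directions.
    """
    values = np.asarray(S.values, dtype=float)
    n_t = values.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k + oversample > n_t:
        raise ValueError(
            f"k + oversample = {k + oversample} exceeds n_t = {n_t}"
        )
    rng = np.random.default_rng(seed)
    R = rng.standard_normal((n_t, k + oversample))
    Q, _, _ = scipy.linalg.qr(values @ R, mode="economic", pivoting=True)
    for _ in range(power_iterations):
        Q, _, _ = scipy.linalg.qr(values @ (values.T @ Q), mode="economic", pivoting=True)
    return Q


def rsvd_denoise(
    S: CasoratiMatrix,
    k: int,
    oversample: int = 8,
    power_iterations: int = 2,
    seed: int | None = None,
) -> CasoratiMatrix:
    """Denoised data P: projection of S onto its leading k singular components.

    The oversampled sketch basis Q estimates the leading subspace
    (P = Q Q^T S on that basis); the small matrix Q^T S is then decomposed and
    only the top k components are retained, so the output has rank at most k —
    the oversampling columns sharpen the subspace estimate but the retained
    component count is exactly the requested one.
    """
    Q = randomized_range_finder(S, k, oversample, power_iterations, seed)
    values = np.asarray(S.values, dtype=float)
    B = Q.T @ values
    Ub, s, Vh = np.linalg.svd(B, full_matrices=False)
    P = (Q @ (Ub[:, :k] * s[:k])) @ Vh[:k]
    return CasoratiMatrix(values=P, n_x=S.n_x, n_z=S.n_z)


def truncated_factors(
    S: CasoratiMatrix,
    k: int,
    oversample: int = 8,
    power_iterations: int = 2,
    seed: int | None = None,
) -> SVDFactors:
    """Top-k SVD factors via the randomized sketch (SVD of Q^T S lifted by Q)."""
    Q = randomized_range_finder(S, k, oversample, power_iterations, seed)
    values = np.asarray(S.values, dtype=float)
    B = Q.T @ values
    Ub, s, Vh = np.linalg.svd(B, full_matrices=False)
    U = Q @ Ub[:, :k]
    U, V = _fix_signs(U, Vh[:k].T)
    return SVDFactors(
        spatial_vectors=U, singular_values=s[:k], temporal_vectors=V
    )
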