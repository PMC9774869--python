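import numpy as np
import pytest

from pastsvd.data_io import CasoratiMatrix
from pastsvd.rsvd import (
    FilterMask,
    SVDFactors,
    full_svd,
    randomized_range_finder,
    rsvd_denoise,
    svd_filter,
    truncated_factors,
)


def _gapped_matrix(rng, m, n, r):
    """Random matrix with a strong spectral gap after component r."""
    U, _ = np.linalg.qr(rng.standard_normal((m, r)))
    V, _ = np.linalg.qr(rng.standard_normal((n, r)))
    s = np.linspace(50.0, 20.0, r)
    return (U * s) @ V.T + 0.01 * rng.standard_normal((m, n))


def _cas(values):
    return CasoratiMatrix(values=values, n_x=1, n_z=values.shape[0])


def test_full_svd_reconstructs_and_orders(rng):
    A = rng.standard_normal((30, 12))
    f = full_svd(_cas(A))
    assert np.all(np.diff(f.singular_values) <= 1e-12)
    recon = (f.spatial_vectors * f.singular_values) @ f.temporal_vectors.T
    assert np.allclose(recon, A)
    # Orthonormality of both factor sets.
    assert np.allclose(f.spatial_vectors.T @ f.spatial_vectors, np.eye(12), atol=1e-10)
    assert np.allclose(f.temporal_vectors.T @ f.temporal_vectors, np.eye(12), atol=1e-10)


def test_full_svd_sign_convention(rng):
    f = full_svd(_cas(rng.standard_normal((30, 8))))
    U = f.spatial_vectors
    peaks = U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])]
    assert np.all(peaks > 0)


def test_svd_filter_masks(rng):
    A = rng.standard_normal((40, 10))
    cas = _cas(A)
    f = full_svd(cas)
    assert np.allclose(svd_filter(f, FilterMask(10), cas).values, A)
    assert np.allclose(svd_filter(f, FilterMask(0), cas).values, 0.0)
    keep = np.zeros(10, dtype=bool)
    keep[1] = True
    one = svd_filter(f, FilterMask(keep), cas).values
    expected = f.singular_values[1] * np.outer(
        f.spatial_vectors[:, 1], f.temporal_vectors[:, 1]
    )
    assert np.allclose(one, expected)
    with pytest.raises(ValueError):
        FilterMask(11).as_bool(10)


def test_rsvd_rank1_identity(rng):
    u = rng.standard_normal(200)
    v = rng.standard_normal(20)
    A = np.outer(u, v)
    P = rsvd_denoise(_cas(A), k=1, seed=0).values
    assert np.allclose(P, A, atol=1e-10 * np.abs(A).max())


def test_rsvd_matches_eckart_young_on_gapped_spectra(rng):
    for trial in range(20):
        m = int(rng.integers(60, 201))
        n = int(rng.integers(20, 51))
        r = int(rng.integers(2, 7))
        A = _gapped_matrix(rng, m, n, r)
        cas = _cas(A)
        best = svd_filter(full_svd(cas), FilterMask(r), cas).values
        approx = rsvd_denoise(cas, k=r, seed=trial).values
        rel = np.linalg.norm(approx - best) / np.linalg.norm(best)
        assert rel < 1e-3


def test_rsvd_output_rank_is_exactly_k(rng):
    A = rng.standard_normal((300, 30))
    P = rsvd_denoise(_cas(A), k=4, seed=0).values
    s = np.linalg.svd(P, compute_uv=False)
    assert s[4] / s[0] < 1e-10


def test_rsvd_idempotent_and_energy_monotone(rng):
    A = _gapped_matrix(rng, 150, 30, 5)
    cas = _cas(A)
    P1 = rsvd_denoise(cas, k=5, seed=1).values
    P2 = rsvd_denoise(_cas(P1), k=5, seed=2).values
    assert np.allclose(P1, P2, atol=1e-8 * np.abs(P1).max())
    energies = [
        np.linalg.norm(rsvd_denoise(cas, k=k, seed=0).values) for k in range(1, 8)
    ]
    assert np.all(np.diff(energies) >= -1e-9)


def test_rsvd_deterministic_given_seed(rng):
    A = rng.standard_normal((100, 20))
    cas = _cas(A)
    assert np.array_equal(
        rsvd_denoise(cas, k=3, seed=7).values, rsvd_denoise(cas, k=3, seed=7).values
    )


def test_range_finder_orthonormal_and_validates(rng):
    A = _gapped_matrix(rng, 120, 30, 4)
    Q = randomized_range_finder(_cas(A), k=4, seed=0)
    assert np.allclose(Q.T @ Q, np.eye(Q.shape[1]), atol=1e-10)
    with pytest.raises(ValueError, match="exceeds n_t"):
        randomized_range_finder(_cas(A), k=25, oversample=8)
    with pytest.raises(ValueError):
        randomized_range_finder(_cas(A), k=0)


def test_truncated_factors_match_full_svd_on_gapped_spectrum(rng):
    A = _gapped_matrix(rng, 200, 40, 4)
    exact = full_svd(_cas(A))
    approx = truncated_factors(_cas(A), k=4, seed=0)
    assert np.allclose(approx.singular_values, exact.singular_values[:4], rtol=1e-6)
    # Subspace agreement (sign-fixed columns align up to tiny angles).
    overlap = np.abs(np.sum(approx.spatial_vectors * exact.spatial_vectors[:, :4], axis=0))
    assert np.all(overlap > 1 - 1e-6)


def test_svdfactors_rejects_unsorted_values():
    with pytest.raises(ValueError):
        SVDFactors(
            spatial_vectors=np.eye(3),
            singular_values=np.array([1.0, 2.0, 0.5]),
            temporal_vectors=np.eye(3),
        )
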