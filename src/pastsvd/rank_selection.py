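"""Tissue-subspace rank estimation from singular-vector statistics.

Two complementary, non-parametric estimators locate the boundary between the
coherent tissue subspace and the noise subspace of a Casorati SVD:

* **Temporal**: tissue temporal singular vectors are narrowband (quasi-static
  signal varies slowly across frames) while noise vectors are broadband. For
  each temporal vector we compute a double-sided power spectral density and
  the one-sided bandwidth containing 99% of each side's energy; the rank is
  the last order before that bandwidth expands towards the full band.
* **Spatial**: magnitude images |u_k| of tissue spatial singular vectors are
  mutually correlated (they share the vascular support) whereas noise vectors
  are spatially random. A Pearson correlation matrix of the |u_k| shows a
  leading coherent block whose boundary is the rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rsvd import SVDFactors

__all__ = [
    "BandwidthCurve",
    "SimilarityMatrix",
    "RankEstimate",
    "temporal_psd",
    "bandwidth99",
    "estimate_rank_temporal",
    "spatial_similarity_matrix",
    "estimate_rank_spatial",
    "estimate_rank",
    "plot_rank_diagnostics",
]

DEFAULT_MAX_ORDERS = 75


@dataclass
class BandwidthCurve:
    """One-sided 99%-energy bandwidth per singular-vector order, in [0, 1]."""

    values: np.ndarray
    fraction: float = 0.99

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("bandwidth fractions must lie in [0, 1]")
        self.values = v


@dataclass
class SimilarityMatrix:
    """Symmetric Pearson-correlation matrix of spatial magnitude images."""

    values: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.values, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-8):
            raise ValueError("similarity matrix must have unit diagonal")
        if C.min() < -1 - 1e-10 or C.max() > 1 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = C

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class RankEstimate:
    """Ranks from both estimators plus the diagnostics that justify them."""

    k_temporal: int
    k_spatial: int
    bandwidth_curve: BandwidthCurve
    similarity: SimilarityMatrix

    @property
    def k_min(self) -> int:
        """Conservative combination used by the denoising pipeline."""
        return min(self.k_temporal, self.k_spatial)


def temporal_psd(V: np.ndarray) -> np.ndarray:
    """Per-order double-sided PSD of temporal singular vectors.

    Row k is |FFT(v_k)|^2 / n_t, frequency-shifted so DC sits at the center
    bin. Each row sums to the column's energy (Parseval).
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be 2-D (n_t, orders)")
    n_t = V.shape[0]
    if n_t < 8:
        raise ValueError("need n_t >= 8 for a meaningful bandwidth")
    spectra = np.fft.fft(V, axis=0)
    psd = np.abs(spectra) ** 2 / n_t
    return np.fft.fftshift(psd, axes=0).T


def bandwidth99(psd_row: np.ndarray, fraction: float = 0.99) -> float:
    """One-sided bandwidth containing *fraction* of each side's energy.

    The PSD row is DC-centered. Each side (negative / positive frequencies,
    each taking half the DC bin) is scanned outward from DC: the bandwidth is
    the smallest cutoff frequency B such that bins with |f| <= B hold at
    least *fraction* of that side's energy, expressed as B / (side's maximum
    frequency). The two sides are averaged.
    """
    psd_row = np.asarray(psd_row, dtype=float)
    n = psd_row.size
    if psd_row.sum() <= 0:
        raise ValueError("zero-energy PSD")
    freqs = np.fft.fftshift(np.fft.fftfreq(n))
    dc = int(np.argmin(np.abs(freqs)))
    sides = []
    for side in (freqs <= 0, freqs >= 0):
        idx = np.flatnonzero(side)
        weights = psd_row[idx].copy()
        weights[idx == dc] *= 0.5
        absf = np.abs(freqs[idx])
        order = np.argsort(absf, kind="stable")
        absf, weights = absf[order], weights[order]
        total = weights.sum()
        if total <= 0:
            sides.append(0.0)
            continue
        cum = np.cumsum(weights)
        stop = int(np.searchsorted(cum, fraction * total - 1e-15))
        sides.append(absf[min(stop, len(absf) - 1)] / absf[-1])
    return float(np.mean(sides))


def _bandwidth_curve(V: np.ndarray, fraction: float) -> BandwidthCurve:
    psd = temporal_psd(V)
    values = np.array([bandwidth99(row, fraction) for row in psd])
    return BandwidthCurve(values=values, fraction=fraction)


def estimate_rank_temporal(
    V: np.ndarray,
    fraction: float = 0.99,
    expansion_threshold: float = 0.85,
) -> tuple[int, BandwidthCurve]:
    """Rank = last order before the 99% bandwidth expands past the threshold.

    Returns the rank and the diagnostic bandwidth curve. If no order exceeds
    the threshold, the rank equals the number of analyzed orders; the rank is
    clamped to at least 1.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[1] < 4:
        raise ValueError("need at least 4 singular-vector orders")
    curve = _bandwidth_curve(V, fraction)
    above = np.flatnonzero(curve.values > expansion_threshold)
    if above.size == 0:
        k = curve.values.size
    else:
        k = max(int(above[0]), 1)
    return k, curve


def spatial_similarity_matrix(U: np.ndarray, orders: int | None = None) -> SimilarityMatrix:
    """Pearson correlations between spatial magnitude images |u_n|, |u_m|."""
    U = np.asarray(U, dtype=float)
    if U.ndim != 2:
        raise ValueError("U must be 2-D (n_x*n_z, orders)")
    if orders is None:
        orders = U.shape[1]
    if orders > U.shape[1]:
        raise ValueError("orders exceeds available columns")
    A = np.abs(U[:, :orders])
    stds = A.std(axis=0)
    bad = np.flatnonzero(stds == 0)
    if bad.size:
        raise ValueError(f"zero-variance magnitude image at order {bad[0] + 1}")
    C = np.corrcoef(A.T)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return SimilarityMatrix(values=C)


def estimate_rank_spatial(C: SimilarityMatrix, threshold: float = 0.2) -> int:
    """Rank = size of the largest leading coherently-correlated block.

    A block of size k qualifies when every column j <= k has mean off-diagonal
    correlation with the rest of the block >= *threshold*. Returns 1 if no
    block of size >= 2 qualifies.
    """
    M = C.values
    n = M.shape[0]
    best = 1
    for k in range(2, n + 1):
        block = M[:k, :k]
        col_means = (block.sum(axis=0) - 1.0) / (k - 1)
        if np.all(col_means >= threshold):
            best = k
    return best


def estimate_rank(
    factors: SVDFactors,
    orders: int | None = None,
    fraction: float = 0.99,
    expansion_threshold: float = 0.85,
    spatial_threshold: float = 0.2,
) -> RankEstimate:
    """Run both estimators on SVD factors and bundle the diagnostics."""
    available = factors.rank
    if orders is None:
        orders = min(available, DEFAULT_MAX_ORDERS)
    orders = min(orders, available)
    V = factors.temporal_vectors[:, :orders]
    U = factors.spatial_vectors[:, :orders]
    k_t, curve = estimate_rank_temporal(V, fraction, expansion_threshold)
    C = spatial_similarity_matrix(U)
    k_s = estimate_rank_spatial(C, spatial_threshold)
    return RankEstimate(
        k_temporal=k_t, k_spatial=k_s, bandwidth_curve=curve, similarity=C
    )


def plot_rank_diagnostics(
    factors: SVDFactors,
    estimate: RankEstimate,
    psd_path: str,
    similarity_path: str,
) -> None:
    """Write PSD/bandwidth and similarity-matrix diagnostic figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    orders = estimate.bandwidth_curve.values.size
    psd = temporal_psd(factors.temporal_vectors[:, :orders])

    fig, ax = plt.subplots(figsize=(6, 4))
    db = 10 * np.log10(psd.T + 1e-20)
    im = ax.imshow(db, aspect="auto", origin="lower",
                   extent=(1, orders, -0.5, 0.5), cmap="viridis")
    ax.plot(np.arange(1, orders + 1), estimate.bandwidth_curve.values / 2,
            color="w", lw=1.5, label="99% bandwidth")
    ax.axvline(estimate.k_temporal + 0.5, color="r", ls="--",
               label=f"k_temporal = {estimate.k_temporal}")
    ax.set_xlabel("singular-vector order")
    ax.set_ylabel("normalized frequency")
    ax.legend(loc="upper right", fontsize=8)
    fig.colorbar(im, ax=ax, label="PSD (dB)")
    fig.tight_layout()
    fig.savefig(psd_path, dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(estimate.similarity.values, vmin=0, vmax=1, cmap="magma",
                   extent=(0.5, orders + 0.5, orders + 0.5, 0.5))
    k = estimate.k_spatial
    ax.add_patch(plt.Rectangle((0.5, 0.5), k, k, fill=False, ec="r", ls="--"))
    ax.set_xlabel("order m")
    ax.set_ylabel("order n")
    fig.colorbar(im, ax=ax, label="correlation")
    fig.tight_layout()
    fig.savefig(similarity_path, dpi=120)
    plt.close(fig)
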