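"""End-to-end spatiotemporal SVD denoising pipeline and baselines.

The spatiotemporal SVD (STSVD) denoiser slides a window over the frame axis,
builds the window's Casorati matrix, resolves the tissue-subspace rank
(explicitly or via the rank estimators), projects onto the leading subspace
with the randomized SVD, and emits the denoised newest frame of each window —
a causal scheme compatible with real-time batch processing. Two baselines are
provided: a trailing-window frame average and a per-A-line wavelet denoiser
(Daubechies-4, soft universal thresholding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt

from .data_io import CasoratiMatrix, RFStack, from_casorati, to_casorati
from .rank_selection import estimate_rank
from .rsvd import rsvd_denoise, truncated_factors

__all__ = ["DenoiseConfig", "stsvd_denoise", "frame_average", "dwt_denoise"]

logger = logging.getLogger(__name__)

RANK_MODES = ("auto-temporal", "auto-spatial", "auto-min")


@dataclass
class DenoiseConfig:
    """STSVD pipeline configuration.

    ``rank`` is an explicit component count or one of the auto modes
    ("auto-temporal", "auto-spatial", "auto-min"); auto modes run the rank
    estimators per window on ``auto_orders`` leading components obtained from
    the randomized sketch. Per-window seeds derive deterministically from
    ``seed`` plus the window index.
    """

    rank: int | str = "auto-min"
    window_frames: int = 75
    stride: int = 1
    oversample: int = 8
    power_iterations: int = 2
    seed: int = 0
    auto_orders: int = 16

    def __post_init__(self) -> None:
        if isinstance(self.rank, str):
            if self.rank not in RANK_MODES:
                raise ValueError(f"unknown rank mode {self.rank!r}")
        elif self.rank < 1:
            raise ValueError("explicit rank must be >= 1")
        if self.window_frames < 1 or self.stride < 1:
            raise ValueError("window_frames and stride must be >= 1")


def _resolve_rank(S: CasoratiMatrix, cfg: DenoiseConfig, seed: int) -> int:
    if not isinstance(cfg.rank, str):
        return int(cfg.rank)
    orders = min(cfg.auto_orders, S.n_t - cfg.oversample)
    factors = truncated_factors(
        S, orders, cfg.oversample, cfg.power_iterations, seed=seed
    )
    est = estimate_rank(factors, orders=orders)
    if cfg.rank == "auto-temporal":
        return est.k_temporal
    if cfg.rank == "auto-spatial":
        return est.k_spatial
    return est.k_min


def stsvd_denoise(stack: RFStack, cfg: DenoiseConfig) -> RFStack:
    """Sliding-window STSVD denoising; output has the input's shape.

    Each window position denoises the window's Casorati matrix and emits the
    newest ``stride`` frames; frames before the first full window reuse the
    first window's projection. Deterministic given ``cfg.seed``.
    """
    n_t = stack.n_t
    w = cfg.window_frames
    if w > n_t:
        raise ValueError(f"window_frames ({w}) exceeds n_t ({n_t})")
    if isinstance(cfg.rank, str) and w < 8:
        raise ValueError("auto rank needs window_frames >= 8")
    cas = to_casorati(stack)
    values = np.asarray(cas.values, dtype=float)
    out = np.empty_like(values)

    ends = list(range(w - 1, n_t, cfg.stride))
    if ends[-1] != n_t - 1:
        ends.append(n_t - 1)
    for widx, end in enumerate(ends):
        window = CasoratiMatrix(
            values=values[:, end - w + 1 : end + 1], n_x=cas.n_x, n_z=cas.n_z
        )
        seed = cfg.seed + widx
        k = _resolve_rank(window, cfg, seed)
        logger.info("window ending at frame %d: rank %d", end, k)
        denoised = rsvd_denoise(
            window, k, cfg.oversample, cfg.power_iterations, seed=seed
        ).values
        if widx == 0:
            out[:, : end + 1] = denoised
        else:
            n_new = min(cfg.stride, end - ends[widx - 1])
            out[:, end - n_new + 1 : end + 1] = denoised[:, -n_new:]
    return from_casorati(
        CasoratiMatrix(values=out, n_x=cas.n_x, n_z=cas.n_z), stack
    )


def frame_average(stack: RFStack, batch: int) -> RFStack:
    """Running mean over the trailing ``batch`` frames (shorter at the start)."""
    if batch < 1:
        raise ValueError("batch must be >= 1")
    samples = np.asarray(stack.samples, dtype=float)
    n_t = samples.shape[2]
    csum = np.concatenate(
        [np.zeros(samples.shape[:2] + (1,)), np.cumsum(samples, axis=2)], axis=2
    )
    t = np.arange(n_t)
    start = np.maximum(0, t - batch + 1)
    counts = t - start + 1
    out = (csum[:, :, t + 1] - csum[:, :, start]) / counts
    return stack.with_samples(out)


def dwt_denoise(frame: np.ndarray, wavelet: str = "db4", mode_2d: bool = False) -> np.ndarray:
    """Wavelet denoising of one RF frame (soft universal thresholding).

    Default operates per A-line (each element's depth series): multilevel db4
    decomposition (level = min(4, maximum allowed)), noise sigma estimated
    from the finest detail coefficients via MAD/0.6745, and the universal
    threshold ``sigma * sqrt(2 ln n_z)`` applied softly to all detail levels;
    approximation coefficients are untouched. ``mode_2d=True`` runs the same
    scheme on the 2-D transform of the whole frame instead.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D (n_x, n_z)")
    n_z = frame.shape[1]
    if n_z < 16:
        raise ValueError("need n_z >= 16")

    if mode_2d:
        level = min(4, pywt.dwtn_max_level(frame.shape, wavelet))
        coeffs = pywt.wavedec2(frame, wavelet, level=level)
        finest = np.concatenate([c.ravel() for c in coeffs[-1]])
        sigma = np.median(np.abs(finest)) / 0.6745
        lam = sigma * np.sqrt(2 * np.log(frame.size))
        out = [coeffs[0]] + [
            tuple(pywt.threshold(c, lam, mode="soft") for c in detail)
            for detail in coeffs[1:]
        ]
        return pywt.waverec2(out, wavelet)[: frame.shape[0], :n_z]

    level = min(4, pywt.dwt_max_level(n_z, wavelet))
    result = np.empty_like(frame)
    for i, line in enumerate(frame):
        coeffs = pywt.wavedec(line, wavelet, level=level)
        sigma = np.median(np.abs(coeffs[-1])) / 0.6745
        lam = sigma * np.sqrt(2 * np.log(n_z))
        coeffs = [coeffs[0]] + [
            pywt.threshold(c, lam, mode="soft") for c in coeffs[1:]
        ]
        result[i] = pywt.waverec(coeffs, wavelet)[:n_z]
    return result
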