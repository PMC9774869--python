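import numpy as np
import pytest

from pastsvd.data_io import to_casorati
from pastsvd.denoising import DenoiseConfig, dwt_denoise, frame_average, stsvd_denoise
from pastsvd.synthetic import NoiseSpec, add_noise_db


def test_config_validation():
    with pytest.raises(ValueError, match="rank mode"):
        DenoiseConfig(rank="auto")
    with pytest.raises(ValueError, match=">= 1"):
        DenoiseConfig(rank=0)
    with pytest.raises(ValueError):
        DenoiseConfig(window_frames=0)


def test_stsvd_full_batch_output_rank(lowrank_stack):
    noisy = add_noise_db(lowrank_stack, NoiseSpec(snr_db=0.0, seed=0))
    cfg = DenoiseConfig(rank=3, window_frames=noisy.n_t, seed=0)
    out = stsvd_denoise(noisy, cfg)
    s = np.linalg.svd(to_casorati(out).values, compute_uv=False)
    assert s[3] / s[0] < 1e-10
    assert out.samples.shape == noisy.samples.shape


def test_stsvd_recovers_lowrank_signal(lowrank_stack):
    noisy = add_noise_db(lowrank_stack, NoiseSpec(snr_db=10.0, seed=1))
    out = stsvd_denoise(noisy, DenoiseConfig(rank=3, window_frames=16, seed=0))
    err_before = np.linalg.norm(noisy.samples - lowrank_stack.samples)
    err_after = np.linalg.norm(out.samples - lowrank_stack.samples)
    assert err_after < 0.5 * err_before


def test_stsvd_auto_rank_improves_noisy_lowrank(lowrank_stack):
    noisy = add_noise_db(lowrank_stack, NoiseSpec(snr_db=0.0, seed=2))
    cfg = DenoiseConfig(rank="auto-min", window_frames=24, seed=0, auto_orders=12)
    out = stsvd_denoise(noisy, cfg)
    err_before = np.linalg.norm(noisy.samples - lowrank_stack.samples)
    err_after = np.linalg.norm(out.samples - lowrank_stack.samples)
    assert err_after < err_before


def test_stsvd_deterministic_and_causal_emission(lowrank_stack):
    noisy = add_noise_db(lowrank_stack, NoiseSpec(snr_db=0.0, seed=3))
    cfg = DenoiseConfig(rank=3, window_frames=16, stride=4, seed=9)
    a = stsvd_denoise(noisy, cfg)
    b = stsvd_denoise(noisy, cfg)
    assert np.array_equal(a.samples, b.samples)
    # Frame t >= window-1 depends only on frames <= t (causality): truncating
    # the input after a window boundary leaves earlier outputs unchanged.
    truncated = stsvd_denoise(noisy.with_samples(noisy.samples[:, :, :20]), cfg)
    assert np.allclose(a.samples[:, :, :16], truncated.samples[:, :, :16])


def test_stsvd_window_validation(lowrank_stack):
    with pytest.raises(ValueError, match="exceeds n_t"):
        stsvd_denoise(lowrank_stack, DenoiseConfig(rank=1, window_frames=999))
    with pytest.raises(ValueError, match=">= 8"):
        stsvd_denoise(lowrank_stack, DenoiseConfig(rank="auto-min", window_frames=4))


def test_frame_average_matches_naive_oracle(random_stack):
    batch = 5
    out = frame_average(random_stack, batch)
    x = random_stack.samples
    for t in range(random_stack.n_t):
        start = max(0, t - batch + 1)
        assert np.allclose(out.samples[:, :, t], x[:, :, start : t + 1].mean(axis=2))
    const = random_stack.with_samples(np.ones_like(x))
    assert np.allclose(frame_average(const, 7).samples, 1.0)
    with pytest.raises(ValueError):
        frame_average(random_stack, 0)


def test_dwt_reduces_noise_on_smooth_signal(rng):
    z = np.arange(512)
    clean = np.stack(
        [np.exp(-0.5 * ((z - 200 - 10 * i) / 15.0) ** 2) for i in range(8)]
    )
    noisy = clean + 0.1 * rng.standard_normal(clean.shape)
    den = dwt_denoise(noisy)
    assert den.shape == noisy.shape
    assert np.linalg.norm(den - clean) < 0.6 * np.linalg.norm(noisy - clean)


def test_dwt_2d_mode_and_validation(rng):
    noisy = rng.standard_normal((16, 64))
    out = dwt_denoise(noisy, mode_2d=True)
    assert out.shape == noisy.shape
    # Soft universal thresholding shrinks the noise energy.
    assert np.linalg.norm(out) < np.linalg.norm(noisy)
    with pytest.raises(ValueError, match="2-D"):
        dwt_denoise(np.zeros(32))
    with pytest.raises(ValueError, match="n_z"):
        dwt_denoise(np.zeros((4, 8)))
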