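import numpy as np
import pytest

from pastsvd.data_io import ArrayGeometry, to_casorati
from pastsvd.synthetic import (
    MotionSchedule,
    NoiseSpec,
    add_noise_db,
    coherent_lowrank_matrix,
    forward_project,
    make_sequence,
    make_vessel_phantom,
    realized_snr_db,
)


def test_phantom_respects_depth_band_and_decay(tiny_phantom):
    p = tiny_phantom
    assert np.all(p.pressure_map >= 0)
    assert p.vessel_mask.any()
    z = p.z_coords_mm()
    occupied = np.flatnonzero(p.vessel_mask.any(axis=0))
    assert z[occupied[0]] >= p.depth_extent_mm[0] - p.spacing_mm
    assert z[occupied[-1]] <= p.depth_extent_mm[1] + p.spacing_mm
    # Depth decay: amplitudes never exceed the fluence envelope.
    assert np.all(p.pressure_map <= np.exp(-0.15 * z)[None, :] + 1e-12)


def test_phantom_is_seeded():
    a = make_vessel_phantom(seed=5, extent_mm=10, depth_extent_mm=(3, 7))
    b = make_vessel_phantom(seed=5, extent_mm=10, depth_extent_mm=(3, 7))
    c = make_vessel_phantom(seed=6, extent_mm=10, depth_extent_mm=(3, 7))
    assert np.array_equal(a.pressure_map, b.pressure_map)
    assert not np.array_equal(a.pressure_map, c.pressure_map)


def test_forward_project_point_source_delay(tiny_phantom):
    geometry = ArrayGeometry(n_elements=16)
    pmap = np.zeros_like(tiny_phantom.pressure_map)
    xs = tiny_phantom.x_coords_mm()
    zs = tiny_phantom.z_coords_mm()
    ix, iz = 60, 50  # x = xs[60], z = zs[50] ~ 5 mm
    pmap[ix, iz] = 1.0
    frame = forward_project(tiny_phantom, geometry, n_z=256, pressure_map=pmap)
    # Envelope peak on the nearest element sits at the one-way time of flight.
    from pastsvd.data_io import element_positions_mm
    from pastsvd.reconstruction import envelope

    elem_x = element_positions_mm(geometry)
    e = int(np.argmin(np.abs(elem_x - xs[ix])))
    dist = np.hypot(xs[ix] - elem_x[e], zs[iz])
    expected = dist / (geometry.sound_speed_m_s / 1000.0) * geometry.sampling_rate_mhz
    peak = int(np.argmax(envelope(frame[e])))
    assert abs(peak - expected) <= 2


def test_static_sequence_is_rank_one(tiny_sequence):
    s = np.linalg.svd(to_casorati(tiny_sequence).values, compute_uv=False)
    assert s[1] / s[0] < 1e-12


def test_motion_sequence_rank_matches_state_count(tiny_phantom):
    geometry = ArrayGeometry(n_elements=16)
    schedule = MotionSchedule(groups=[(3, 0.0), (3, 1.0), (3, 2.0), (3, -1.0)])
    stack = make_sequence(tiny_phantom, geometry, schedule, n_t=12, n_z=256)
    s = np.linalg.svd(to_casorati(stack).values, compute_uv=False)
    assert s[3] / s[0] > 1e-6  # four genuinely distinct states
    assert s[4] / s[0] < 1e-12


def test_sequence_shift_off_grid_raises(tiny_phantom):
    geometry = ArrayGeometry(n_elements=16)
    schedule = MotionSchedule(groups=[(2, 0.0), (2, 30.0)])
    with pytest.raises(ValueError, match="out of the grid"):
        make_sequence(tiny_phantom, geometry, schedule, n_t=4, n_z=256)


def test_schedule_frame_count_must_match(tiny_phantom):
    geometry = ArrayGeometry(n_elements=16)
    with pytest.raises(ValueError, match="n_t"):
        make_sequence(tiny_phantom, geometry, MotionSchedule.static(9), n_t=8)


def test_noise_calibration(tiny_sequence):
    for snr in (-5.0, -10.0, -15.0):
        noisy = add_noise_db(tiny_sequence, NoiseSpec(snr_db=snr, seed=2))
        assert realized_snr_db(tiny_sequence, noisy) == pytest.approx(snr, abs=0.1)


def test_noise_is_seeded(tiny_sequence):
    a = add_noise_db(tiny_sequence, NoiseSpec(snr_db=-10, seed=4))
    b = add_noise_db(tiny_sequence, NoiseSpec(snr_db=-10, seed=4))
    c = add_noise_db(tiny_sequence, NoiseSpec(snr_db=-10, seed=5))
    assert np.array_equal(a.samples, b.samples)
    assert not np.array_equal(a.samples, c.samples)


def test_coherent_lowrank_matrix_structure():
    cas = coherent_lowrank_matrix(rank=4, seed=0)
    assert cas.values.shape == (2000, 100)
    s = np.linalg.svd(cas.values, compute_uv=False)
    noise_top = np.sqrt(2000) + np.sqrt(100)
    # Four signal components clear of the noise plateau.
    assert s[3] > 3 * noise_top
    assert s[4] < 1.2 * noise_top
    with pytest.raises(ValueError):
        coherent_lowrank_matrix(rank=0)
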