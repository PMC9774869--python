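"""Synthetic photoacoustic RF sequences with controlled rank and noise.

The generator emulates a 128-element, 7 MHz linear-array acquisition of a
quasi-static vascular phantom over ~100 frames. A procedural random-walk
vessel generator rasterizes tubular absorbers into a 40 x 40 mm grid
(0.1 mm spacing) between 10 and 20 mm depth, with amplitude decaying
exponentially with depth as a surrogate for optical fluence. Each frame is
produced by an analytic forward model: every absorber pixel contributes a
band-limited bipolar pulse to every element, delayed by the one-way
time of flight and attenuated as 1/distance. Slow motion is modelled as
whole-pixel axial shifts of the vessel region (default schedule: four
25-frame groups shifted by 0, 1, 2 and -1 mm), and Gaussian noise is added
directly to the Casorati matrix at a prescribed SNR (-5, -10 or -15 dB are
the standard study levels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.signal

from .data_io import ArrayGeometry, CasoratiMatrix, RFStack, element_positions_mm, to_casorati

__all__ = [
    "VesselPhantom",
    "MotionSchedule",
    "NoiseSpec",
    "make_vessel_phantom",
    "forward_project",
    "make_sequence",
    "add_noise_db",
    "coherent_lowrank_matrix",
    "realized_snr_db",
]

GRID_EXTENT_MM = 40.0
GRID_SPACING_MM = 0.1
DEFAULT_DEPTH_EXTENT_MM = (10.0, 20.0)
DEFAULT_FLUENCE_DECAY_PER_MM = 0.15
DEFAULT_N_Z = 700
DEFAULT_MOTION_SHIFTS_MM = (0.0, 1.0, 2.0, -1.0)


@dataclass
class VesselPhantom:
    """Absorber map on a regular grid, indexed ``pressure_map[x, z]``.

    ``x`` spans ``[-extent/2, extent/2]`` (centered on the array midline),
    ``z`` spans ``[0, extent]`` in depth.
    """

    pressure_map: np.ndarray
    vessel_mask: np.ndarray
    spacing_mm: float = GRID_SPACING_MM
    depth_extent_mm: tuple[float, float] = DEFAULT_DEPTH_EXTENT_MM

    def __post_init__(self) -> None:
        self.pressure_map = np.asarray(self.pressure_map, dtype=float)
        self.vessel_mask = np.asarray(self.vessel_mask, dtype=bool)
        if self.pressure_map.shape != self.vessel_mask.shape:
            raise ValueError("pressure_map and vessel_mask shapes differ")
        if np.any(self.pressure_map < 0):
            raise ValueError("pressures must be nonnegative")
        if np.any(self.vessel_mask & (self.pressure_map <= 0)) and self.vessel_mask.any():
            raise ValueError("vessel_mask must lie within nonzero pressures")

    @property
    def extent_mm(self) -> float:
        return self.pressure_map.shape[0] * self.spacing_mm

    def x_coords_mm(self) -> np.ndarray:
        n = self.pressure_map.shape[0]
        return (np.arange(n) + 0.5) * self.spacing_mm - self.extent_mm / 2

    def z_coords_mm(self) -> np.ndarray:
        n = self.pressure_map.shape[1]
        return (np.arange(n) + 0.5) * self.spacing_mm


@dataclass
class MotionSchedule:
    """Per-group axial motion: list of ``(frame_count, z_shift_mm)``."""

    groups: list[tuple[int, float]] = field(
        default_factory=lambda: [(25, s) for s in DEFAULT_MOTION_SHIFTS_MM]
    )

    @property
    def n_t(self) -> int:
        return sum(c for c, _ in self.groups)

    @staticmethod
    def static(n_t: int = 100) -> "MotionSchedule":
        return MotionSchedule(groups=[(n_t, 0.0)])

    @staticmethod
    def four_state(frames_per_group: int = 25) -> "MotionSchedule":
        return MotionSchedule(
            groups=[(frames_per_group, s) for s in DEFAULT_MOTION_SHIFTS_MM]
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Casorati-domain Gaussian noise at a given SNR (dB), seeded."""

    snr_db: float = -10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


def make_vessel_phantom(
    seed: int,
    n_vessels: int = 8,
    radius_range_mm: tuple[float, float] = (0.1, 0.35),
    tortuosity: float = 0.08,
    extent_mm: float = GRID_EXTENT_MM,
    spacing_mm: float = GRID_SPACING_MM,
    depth_extent_mm: tuple[float, float] = DEFAULT_DEPTH_EXTENT_MM,
    fluence_decay_per_mm: float = DEFAULT_FLUENCE_DECAY_PER_MM,
) -> VesselPhantom:
    """Procedural vascular phantom: random-walk tubes with depth-decaying amplitude.

    Each vessel is a quasi-horizontal random walk across the grid, rasterized
    with a per-vessel radius; amplitudes are scaled by a per-vessel factor and
    by ``exp(-decay * z)`` so deeper vessels are weaker (a fluence surrogate).
    """
    if radius_range_mm[0] <= 0 or radius_range_mm[1] < radius_range_mm[0]:
        raise ValueError("invalid radius range")
    z_min, z_max = depth_extent_mm
    if z_max - z_min <= 2 * radius_range_mm[1]:
        raise ValueError("vessel radius too large for the depth extent")
    n_grid = int(round(extent_mm / spacing_mm))
    rng = np.random.default_rng(seed)
    pressure = np.zeros((n_grid, n_grid))
    mask = np.zeros((n_grid, n_grid), dtype=bool)
    z_coords = (np.arange(n_grid) + 0.5) * spacing_mm

    for _ in range(n_vessels):
        radius_mm = rng.uniform(*radius_range_mm)
        r_px = max(1, int(round(radius_mm / spacing_mm)))
        amp = rng.uniform(0.5, 1.0)
        length_px = int(rng.uniform(0.5, 1.0) * n_grid)
        x = rng.uniform(0, n_grid - 1)
        z_lo = (z_min + radius_mm) / spacing_mm
        z_hi = (z_max - radius_mm) / spacing_mm
        z = rng.uniform(z_lo, z_hi)
        heading = rng.choice([-1.0, 1.0]) * rng.uniform(-0.3, 0.3)
        direction = rng.choice([-1.0, 1.0])
        centers = np.zeros((n_grid, n_grid), dtype=bool)
        for _ in range(length_px):
            xi, zi = int(round(x)), int(round(z))
            if 0 <= xi < n_grid and 0 <= zi < n_grid:
                centers[xi, zi] = True
            heading += rng.normal(0.0, tortuosity)
            heading = float(np.clip(heading, -0.8, 0.8))
            x += direction * np.cos(heading)
            z += np.sin(heading)
            if z < z_lo or z > z_hi:  # reflect off the depth band
                z = float(np.clip(z, z_lo, z_hi))
                heading = -heading
            if x < 0 or x > n_grid - 1:
                break
        offsets = np.arange(-r_px, r_px + 1)
        ox, oz = np.meshgrid(offsets, offsets, indexing="ij")
        disk = (ox**2 + oz**2) <= r_px**2
        tube = scipy.ndimage.binary_dilation(centers, structure=disk)
        mask |= tube
        pressure = np.maximum(pressure, tube * amp)

    pressure *= np.exp(-fluence_decay_per_mm * z_coords)[None, :]
    return VesselPhantom(
        pressure_map=pressure,
        vessel_mask=mask,
        spacing_mm=spacing_mm,
        depth_extent_mm=depth_extent_mm,
    )


def _pulse(geometry: ArrayGeometry) -> np.ndarray:
    """Band-limited bipolar pulse sampled at the acquisition rate (odd length)."""
    fc = geometry.center_frequency_mhz * 1e6
    bw = geometry.fractional_bandwidth_percent / 100.0
    fs = geometry.sampling_rate_mhz * 1e6
    t_cut = scipy.signal.gausspulse("cutoff", fc=fc, bw=bw, bwr=-6, tpr=-60)
    n_half = int(np.ceil(t_cut * fs))
    t = np.arange(-n_half, n_half + 1) / fs
    return scipy.signal.gausspulse(t, fc=fc, bw=bw, bwr=-6)


def forward_project(
    phantom: VesselPhantom,
    geometry: ArrayGeometry,
    n_z: int = DEFAULT_N_Z,
    pressure_map: np.ndarray | None = None,
) -> np.ndarray:
    """Analytic one-way forward model: one RF frame of shape ``(n_x, n_z)``.

    Every nonzero pixel contributes, to every element, a Gaussian-modulated
    pulse at the array's center frequency delayed by distance/sound_speed and
    scaled by amplitude/distance; contributions superpose linearly.
    """
    pmap = phantom.pressure_map if pressure_map is None else pressure_map
    xs_grid = phantom.x_coords_mm()
    zs_grid = phantom.z_coords_mm()
    elem_x = element_positions_mm(geometry)
    if elem_x.min() < xs_grid[0] - phantom.spacing_mm or elem_x.max() > xs_grid[-1] + phantom.spacing_mm:
        raise ValueError("array elements lie outside the phantom grid span")

    ix, iz = np.nonzero(pmap)
    n_x = geometry.n_elements
    fs_mhz = geometry.sampling_rate_mhz
    c_mm_per_us = geometry.sound_speed_m_s / 1000.0
    traces = np.zeros((n_x, n_z))
    if ix.size:
        px = xs_grid[ix]
        pz = zs_grid[iz]
        amps = pmap[ix, iz]
        for e in range(n_x):
            dist = np.hypot(px - elem_x[e], pz)
            delay = dist / c_mm_per_us * fs_mhz  # fractional sample index
            a = amps / np.maximum(dist, phantom.spacing_mm)
            i0 = np.floor(delay).astype(np.intp)
            w = delay - i0
            ok0 = (i0 >= 0) & (i0 < n_z)
            ok1 = (i0 + 1 >= 0) & (i0 + 1 < n_z)
            np.add.at(traces[e], i0[ok0], a[ok0] * (1 - w[ok0]))
            np.add.at(traces[e], i0[ok1] + 1, a[ok1] * w[ok1])
        pulse = _pulse(geometry)
        traces = scipy.signal.fftconvolve(traces, pulse[None, :], mode="same", axes=1)
    return traces


def _shift_axial(pmap: np.ndarray, shift_px: int) -> np.ndarray:
    """Whole-pixel axial (z) shift; raises if nonzero content would leave the grid."""
    if shift_px == 0:
        return pmap
    out = np.zeros_like(pmap)
    if shift_px > 0:
        if np.any(pmap[:, -shift_px:] != 0):
            raise ValueError("axial shift moves vessels out of the grid")
        out[:, shift_px:] = pmap[:, :-shift_px]
    else:
        if np.any(pmap[:, :-shift_px] != 0):
            raise ValueError("axial shift moves vessels out of the grid")
        out[:, :shift_px] = pmap[:, -shift_px:]
    return out


def make_sequence(
    phantom: VesselPhantom,
    geometry: ArrayGeometry,
    schedule: MotionSchedule,
    n_t: int = 100,
    n_z: int = DEFAULT_N_Z,
    frame_interval_s: float = 0.1,
) -> RFStack:
    """Clean RF sequence driven by a motion schedule.

    Per motion state the vessel map is shifted axially by a whole number of
    grid pixels (1 mm = 10 pixels at the default spacing), projected once and
    replicated across the group's frames; the clean Casorati matrix therefore
    has rank at most the number of distinct states.
    """
    if schedule.n_t != n_t:
        raise ValueError(f"schedule frames ({schedule.n_t}) != n_t ({n_t})")
    samples = np.zeros((geometry.n_elements, n_z, n_t))
    frame_cache: dict[int, np.ndarray] = {}
    t = 0
    for count, shift_mm in schedule.groups:
        shift_px = int(round(shift_mm / phantom.spacing_mm))
        if shift_px not in frame_cache:
            shifted = _shift_axial(phantom.pressure_map, shift_px)
            frame_cache[shift_px] = forward_project(
                phantom, geometry, n_z=n_z, pressure_map=shifted
            )
        samples[:, :, t : t + count] = frame_cache[shift_px][:, :, None]
        t += count
    return RFStack(
        samples=samples,
        geometry=geometry,
        frame_interval_s=frame_interval_s,
        provenance="synthetic",
    )


def add_noise_db(stack: RFStack, spec: NoiseSpec) -> RFStack:
    """Add i.i.d. Gaussian noise to every Casorati entry at the requested SNR.

    Noise variance is ``P_signal * 10**(-snr_db/10)`` with ``P_signal`` the
    mean squared value over the entire clean Casorati matrix.
    """
    clean = np.asarray(stack.samples, dtype=float)
    p_signal = float(np.mean(clean**2))
    if p_signal <= 0:
        raise ValueError("clean stack has zero energy")
    sigma = np.sqrt(p_signal * 10.0 ** (-spec.snr_db / 10.0))
    rng = np.random.default_rng(spec.seed)
    noisy = clean + sigma * rng.standard_normal(clean.shape)
    return stack.with_samples(noisy)


def coherent_lowrank_matrix(
    rank: int,
    n_space: int = 2000,
    n_t: int = 100,
    component_snr: float = 5.0,
    seed: int = 0,
) -> CasoratiMatrix:
    """Rank-r coherent signal plus unit-variance Gaussian noise.

    Signal spatial vectors share a smooth support envelope (so their magnitude
    images are mutually correlated, like vessels across singular orders) and
    temporal vectors are band-limited to the first 8 Fourier modes (so their
    99% bandwidth is far below the noise plateau). Component singular values
    are set to ``component_snr`` (and up to 1.6x that) times the top noise
    singular value ``sqrt(m) + sqrt(n)``.
    """
    if rank < 1 or rank > min(n_space, n_t) // 2:
        raise ValueError("rank out of range")
    rng = np.random.default_rng(seed)

    idx = np.arange(n_space)
    envelope = np.exp(-0.5 * ((idx - n_space / 2) / (n_space / 8.0)) ** 2)
    fields = rng.standard_normal((n_space, rank))
    fields = scipy.ndimage.gaussian_filter1d(fields, sigma=n_space / 100.0, axis=0)
    U, _ = np.linalg.qr(envelope[:, None] * fields)

    n_modes = 8
    coeffs = np.zeros((n_t // 2 + 1, rank), dtype=complex)
    re = rng.standard_normal((n_modes, rank))
    im = rng.standard_normal((n_modes, rank))
    coeffs[1 : n_modes + 1] = re + 1j * im
    V, _ = np.linalg.qr(np.fft.irfft(coeffs, n=n_t, axis=0))

    noise_top = np.sqrt(n_space) + np.sqrt(n_t)
    s = component_snr * noise_top * np.linspace(1.6, 1.0, rank)
    S = (U * s) @ V.T + rng.standard_normal((n_space, n_t))
    return CasoratiMatrix(values=S, n_x=1, n_z=n_space)


def realized_snr_db(clean: RFStack, noisy: RFStack) -> float:
    """10*log10 of clean power over added-noise power (diagnostic)."""
    diff = np.asarray(noisy.samples, dtype=float) - np.asarray(clean.samples, dtype=float)
    p_noise = float(np.mean(diff**2))
    p_signal = float(np.mean(np.asarray(clean.samples, dtype=float) ** 2))
    if p_noise <= 0:
        raise ValueError("no noise present")
    return 10.0 * np.log10(p_signal / p_noise)
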