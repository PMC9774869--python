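"""Delay-and-sum reconstruction of photoacoustic images from RF frames.

Photoacoustic sources emit once and are only received, so delays are one-way:
pixel (x, z) accumulates, over all elements, the RF sample at time
distance((x, z), element) / c, with linear interpolation between samples.
The same reconstruction is applied to every denoiser's output, so
image-domain comparisons are internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .data_io import ArrayGeometry, PAImage, RFStack, element_positions_mm

__all__ = ["ImageGrid", "das_reconstruct", "das_reconstruct_stack", "envelope"]


@dataclass(frozen=True)
class ImageGrid:
    """Regular reconstruction grid in array-centered coordinates (mm)."""

    x0_mm: float
    z0_mm: float
    dx_mm: float
    dz_mm: float
    n_x: int
    n_z: int

    def __post_init__(self) -> None:
        if self.dx_mm <= 0 or self.dz_mm <= 0:
            raise ValueError("pixel spacing must be > 0")
        if self.z0_mm < 0:
            raise ValueError("depth must be >= 0")

    @staticmethod
    def default_for(geometry: ArrayGeometry,
                    z_range_mm: tuple[float, float] = (5.0, 25.0),
                    dz_mm: float = 0.1) -> "ImageGrid":
        """One pixel column per element, depth 5-25 mm by default."""
        elem_x = element_positions_mm(geometry)
        n_z = int(round((z_range_mm[1] - z_range_mm[0]) / dz_mm))
        return ImageGrid(
            x0_mm=float(elem_x[0]),
            z0_mm=z_range_mm[0],
            dx_mm=geometry.pitch_mm,
            dz_mm=dz_mm,
            n_x=geometry.n_elements,
            n_z=n_z,
        )

    def x_coords_mm(self) -> np.ndarray:
        return self.x0_mm + np.arange(self.n_x) * self.dx_mm

    def z_coords_mm(self) -> np.ndarray:
        return self.z0_mm + np.arange(self.n_z) * self.dz_mm


_delay_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _delays(geometry: ArrayGeometry, grid: ImageGrid) -> tuple[np.ndarray, np.ndarray]:
    """Fractional sample delays (n_elements, n_pixels) split into floor + weight."""
    key = (geometry, grid)
    if key not in _delay_cache:
        elem_x = element_positions_mm(geometry)
        px, pz = np.meshgrid(grid.x_coords_mm(), grid.z_coords_mm(), indexing="ij")
        dist = np.hypot(px.ravel()[None, :] - elem_x[:, None], pz.ravel()[None, :])
        c_mm_per_us = geometry.sound_speed_m_s / 1000.0
        delay = dist / c_mm_per_us * geometry.sampling_rate_mhz
        i0 = np.floor(delay).astype(np.intp)
        w = delay - i0
        if len(_delay_cache) > 8:
            _delay_cache.clear()
        _delay_cache[key] = (i0, w)
    return _delay_cache[key]


def das_reconstruct(
    frame: np.ndarray, geometry: ArrayGeometry, grid: ImageGrid | None = None
) -> PAImage:
    """Delay-and-sum one RF frame ``(n_x, n_z)`` onto an image grid."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[0] != geometry.n_elements:
        raise ValueError("frame must be (n_elements, n_samples)")
    if grid is None:
        grid = ImageGrid.default_for(geometry)
    n_samples = frame.shape[1]
    max_depth_mm = grid.z_coords_mm()[-1]
    max_delay = max_depth_mm / (geometry.sound_speed_m_s / 1000.0) * geometry.sampling_rate_mhz
    if max_delay >= n_samples:
        raise ValueError("image grid extends beyond the recorded depth window")
    i0, w = _delays(geometry, grid)
    # Clip indices for off-window lateral pixels; their weight is zeroed.
    valid = (i0 >= 0) & (i0 + 1 < n_samples)
    i0c = np.clip(i0, 0, n_samples - 2)
    rows = np.arange(geometry.n_elements)[:, None]
    vals = frame[rows, i0c] * (1 - w) + frame[rows, i0c + 1] * w
    vals[~valid] = 0.0
    pixels = vals.sum(axis=0).reshape(grid.n_x, grid.n_z)
    return PAImage(
        pixels=pixels,
        pixel_spacing_mm=(grid.dx_mm, grid.dz_mm),
        origin_mm=(grid.x0_mm, grid.z0_mm),
    )


def das_reconstruct_stack(
    stack: RFStack, grid: ImageGrid | None = None, frames: np.ndarray | None = None
) -> list[PAImage]:
    """Reconstruct every (or selected) frame of an RF stack."""
    if grid is None:
        grid = ImageGrid.default_for(stack.geometry)
    if frames is None:
        frames = np.arange(stack.n_t)
    return [das_reconstruct(stack.samples[:, :, t], stack.geometry, grid) for t in frames]


def envelope(data: np.ndarray, axis: int = -1) -> np.ndarray:
    """Analytic-signal magnitude along the depth axis."""
    data = np.asarray(data, dtype=float)
    if data.shape[axis] < 8:
        raise ValueError("need at least 8 samples along the depth axis")
    return np.abs(scipy.signal.hilbert(data, axis=axis))
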