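"""RF data model and HDF5 container I/O.

The universal interchange object is the :class:`RFStack`: a 3-D array of
radiofrequency samples indexed ``(element x, depth-sample z, frame t)``
together with the acquisition geometry. Spatiotemporal filtering operates on
its 2-D Casorati view, in which each column is one frame flattened
element-major (row index = ``x * n_z + z``). That flattening order is a fixed
convention used everywhere in this package, in particular when spatial
singular vectors are reshaped back into images for rank diagnostics.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "ArrayGeometry",
    "RFStack",
    "CasoratiMatrix",
    "PAImage",
    "FormatError",
    "load_rf",
    "save_rf",
    "to_casorati",
    "from_casorati",
    "element_positions_mm",
    "save_image_tiff",
]


class FormatError(ValueError):
    """Raised when an RF container is structurally invalid."""


@dataclass(frozen=True)
class ArrayGeometry:
    """Linear-array transducer geometry and sampling parameters.

    Defaults describe a 128-element, 0.3 mm pitch (38.4 mm aperture) array
    with 7 MHz center frequency and 80.9% -6 dB fractional bandwidth,
    sampled at 40 MHz in a 1500 m/s medium.
    """

    n_elements: int = 128
    pitch_mm: float = 0.3
    center_frequency_mhz: float = 7.0
    fractional_bandwidth_percent: float = 80.9
    sampling_rate_mhz: float = 40.0
    sound_speed_m_s: float = 1500.0

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise ValueError("n_elements must be >= 1")
        if self.pitch_mm <= 0:
            raise ValueError("pitch_mm must be > 0")
        if self.sampling_rate_mhz <= 2 * self.center_frequency_mhz:
            raise ValueError(
                "sampling_rate_mhz must exceed 2 x center_frequency_mhz (Nyquist)"
            )
        if self.sound_speed_m_s <= 0:
            raise ValueError("sound_speed_m_s must be > 0")

    @property
    def aperture_mm(self) -> float:
        return self.n_elements * self.pitch_mm

    @property
    def dz_mm(self) -> float:
        """Depth increment per sample at one-way delays (mm)."""
        return self.sound_speed_m_s * 1e3 / (self.sampling_rate_mhz * 1e6)


def element_positions_mm(geometry: ArrayGeometry) -> np.ndarray:
    """Lateral element-center positions, centered on the array midpoint."""
    n = geometry.n_elements
    return (np.arange(n) - (n - 1) / 2.0) * geometry.pitch_mm


@dataclass
class RFStack:
    """A stack of RF frames: ``samples[x, z, t]`` plus acquisition metadata."""

    samples: np.ndarray
    geometry: ArrayGeometry
    frame_interval_s: float = 0.1
    provenance: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 3:
            raise ValueError("samples must be 3-D (n_x, n_z, n_t)")
        if self.samples.shape[0] != self.geometry.n_elements:
            raise ValueError(
                f"samples first axis ({self.samples.shape[0]}) must equal "
                f"geometry.n_elements ({self.geometry.n_elements})"
            )
        if self.samples.shape[2] < 1:
            raise ValueError("need at least one frame")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_x(self) -> int:
        return self.samples.shape[0]

    @property
    def n_z(self) -> int:
        return self.samples.shape[1]

    @property
    def n_t(self) -> int:
        return self.samples.shape[2]

    def with_samples(self, samples: np.ndarray) -> "RFStack":
        return replace(self, samples=samples)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RFStack):
            return NotImplemented
        return (
            self.geometry == other.geometry
            and self.frame_interval_s == other.frame_interval_s
            and self.provenance == other.provenance
            and self.samples.shape == other.samples.shape
            and self.samples.dtype == other.samples.dtype
            and np.array_equal(self.samples, other.samples)
        )


@dataclass
class CasoratiMatrix:
    """2-D spatiotemporal view of an RF stack: shape ``(n_x * n_z, n_t)``.

    Column ``t`` is frame ``t`` flattened element-major (row = ``x*n_z + z``).
    """

    values: np.ndarray
    n_x: int
    n_z: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[0] != self.n_x * self.n_z:
            raise ValueError(
                f"row count {self.values.shape[0]} != n_x*n_z = {self.n_x * self.n_z}"
            )

    @property
    def n_t(self) -> int:
        return self.values.shape[1]


@dataclass
class PAImage:
    """Reconstructed photoacoustic image: ``pixels[x, z]`` on a regular grid."""

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (0.3, 0.1)  # (dx, dz)
    origin_mm: tuple[float, float] = (0.0, 0.0)  # (x0, z0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if min(self.pixel_spacing_mm) <= 0:
            raise ValueError("pixel spacing must be > 0")


_GEOMETRY_ATTRS = (
    "n_elements",
    "pitch_mm",
    "center_frequency_mhz",
    "fractional_bandwidth_percent",
    "sampling_rate_mhz",
    "sound_speed_m_s",
)


def save_rf(stack: RFStack, path: str | os.PathLike) -> None:
    """Write an RF stack to an HDF5 container (atomically: temp file + rename).

    The `samples` dataset is stored as float32; a round trip through
    :func:`load_rf` is therefore bit-exact for float32 stacks.
    """
    path = os.fspath(path)
    directory = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(suffix=".h5", dir=directory)
    os.close(fd)
    try:
        with h5py.File(tmp, "w") as f:
            f.create_dataset("samples", data=stack.samples.astype(np.float32))
            for name in _GEOMETRY_ATTRS:
                f.attrs[name] = getattr(stack.geometry, name)
            f.attrs["frame_interval_s"] = stack.frame_interval_s
            f.attrs["provenance"] = stack.provenance
        os.replace(tmp, path)
    except OSError:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_rf(path: str | os.PathLike) -> RFStack:
    """Read an RF stack written by :func:`save_rf`.

    Raises
    ------
    OSError
        If the file is missing or unreadable.
    FormatError
        If a dataset or attribute is absent, naming the offending field.
    """
    with h5py.File(os.fspath(path), "r") as f:
        if "samples" not in f:
            raise FormatError("missing dataset 'samples'")
        for name in _GEOMETRY_ATTRS + ("frame_interval_s",):
            if name not in f.attrs:
                raise FormatError(f"missing attribute '{name}'")
        samples = f["samples"][()]
        if samples.ndim != 3:
            raise FormatError("'samples' must be 3-D (n_x, n_z, n_t)")
        geometry = ArrayGeometry(
            n_elements=int(f.attrs["n_elements"]),
            pitch_mm=float(f.attrs["pitch_mm"]),
            center_frequency_mhz=float(f.attrs["center_frequency_mhz"]),
            fractional_bandwidth_percent=float(
                f.attrs["fractional_bandwidth_percent"]
            ),
            sampling_rate_mhz=float(f.attrs["sampling_rate_mhz"]),
            sound_speed_m_s=float(f.attrs["sound_speed_m_s"]),
        )
        if samples.shape[0] != geometry.n_elements:
            raise FormatError(
                "samples first axis does not match attribute 'n_elements'"
            )
        return RFStack(
            samples=samples,
            geometry=geometry,
            frame_interval_s=float(f.attrs["frame_interval_s"]),
            provenance=str(f.attrs.get("provenance", "")),
        )


def to_casorati(stack: RFStack) -> CasoratiMatrix:
    """Reshape a stack to its Casorati matrix (columns = flattened frames)."""
    n_x, n_z, n_t = stack.samples.shape
    values = stack.samples.reshape(n_x * n_z, n_t)
    return CasoratiMatrix(values=values, n_x=n_x, n_z=n_z)


def from_casorati(mat: CasoratiMatrix, template: RFStack) -> RFStack:
    """Inverse of :func:`to_casorati`; metadata copied from *template*."""
    n_x, n_z = template.n_x, template.n_z
    if mat.values.shape[0] != n_x * n_z:
        raise ValueError(
            f"Casorati row count {mat.values.shape[0]} does not match "
            f"template n_x*n_z = {n_x * n_z}"
        )
    samples = mat.values.reshape(n_x, n_z, mat.values.shape[1])
    return template.with_samples(samples)


def save_image_tiff(image: PAImage, path: str | os.PathLike) -> None:
    """Export a PA image as 32-bit float TIFF (depth along rows for display)."""
    import tifffile

    tifffile.imwrite(os.fspath(path), image.pixels.T.astype(np.float32))
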