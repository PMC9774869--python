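"""Image-quality metrics for denoising evaluation.

Reference metrics (PSNR, global SSIM, EPI) compare a denoised image X against
a noise-free reference Y; non-reference metrics (SNR, CNR) compare signal and
background regions of interest of a single image; axial FWHM measures
resolution on a depth profile.

Two conventions here deliberately follow the source formulas rather than
common practice, with switches for the conventional forms:

* PSNR uses ``10*log10(max(X) / MSE)`` — the peak enters unsquared
  (``compat="standard"`` squares it).
* SNR uses ``10*log10`` on an amplitude ratio (not ``20*log10``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage

__all__ = [
    "Rect",
    "ROISet",
    "MetricReport",
    "psnr",
    "ssim",
    "epi",
    "image_snr",
    "image_cnr",
    "axial_fwhm",
    "to_uint8_range",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned pixel rectangle: ``pixels[x0:x0+width, z0:z0+height]``."""

    x0: int
    z0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("rectangle must be non-empty")
        if self.x0 < 0 or self.z0 < 0:
            raise ValueError("rectangle origin must be nonnegative")

    @property
    def n_pixels(self) -> int:
        return self.width * self.height

    def extract(self, img: np.ndarray) -> np.ndarray:
        if self.x0 + self.width > img.shape[0] or self.z0 + self.height > img.shape[1]:
            raise ValueError("rectangle exceeds image bounds")
        return img[self.x0 : self.x0 + self.width, self.z0 : self.z0 + self.height]

    def _cells(self) -> set[tuple[int, int]]:
        return {
            (x, z)
            for x in range(self.x0, self.x0 + self.width)
            for z in range(self.z0, self.z0 + self.height)
        }


@dataclass
class ROISet:
    """Signal and background-noise regions of equal pixel counts."""

    signal_regions: list[Rect]
    noise_regions: list[Rect]

    def __post_init__(self) -> None:
        if not self.signal_regions or not self.noise_regions:
            raise ValueError("need at least one signal and one noise region")
        counts = {r.n_pixels for r in self.signal_regions + self.noise_regions}
        if len(counts) != 1:
            raise ValueError("all regions must have equal pixel counts")
        sig = set().union(*(r._cells() for r in self.signal_regions))
        noi = set().union(*(r._cells() for r in self.noise_regions))
        if sig & noi:
            raise ValueError("signal and noise regions must be disjoint")


@dataclass
class MetricReport:
    """Bundle of metric values; any entry may be absent."""

    psnr_db: float | None = None
    ssim: float | None = None
    epi: float | None = None
    snr_db: float | None = None
    cnr: float | None = None
    axial_fwhm_mm: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "psnr_db": self.psnr_db,
            "ssim": self.ssim,
            "epi": self.epi,
            "snr_db": self.snr_db,
            "cnr": self.cnr,
            "axial_fwhm_mm": self.axial_fwhm_mm,
        }


def _check_shapes(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    return X, Y


def psnr(X: np.ndarray, Y: np.ndarray, compat: str = "unsquared") -> float:
    """Peak signal-to-noise ratio of denoised X against reference Y, in dB.

    ``compat="unsquared"`` uses the unsquared peak ``10*log10(max(X)/MSE)``;
    ``compat="standard"`` uses the conventional ``10*log10(max(X)**2/MSE)``.
    Identical images return ``inf``.
    """
    X, Y = _check_shapes(X, Y)
    mse = float(np.mean((X - Y) ** 2))
    if mse == 0:
        return float("inf")
    peak = float(np.max(X))
    if compat == "unsquared":
        return 10.0 * np.log10(peak / mse)
    if compat == "standard":
        return 10.0 * np.log10(peak**2 / mse)
    raise ValueError(f"unknown compat mode {compat!r}")


def to_uint8_range(img: np.ndarray, lo: float | None = None, hi: float | None = None) -> np.ndarray:
    """Rescale an image to [0, 255] (shared bounds allow consistent pairs)."""
    img = np.asarray(img, dtype=float)
    lo = float(img.min()) if lo is None else lo
    hi = float(img.max()) if hi is None else hi
    if hi <= lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo) * 255.0


def ssim(X: np.ndarray, Y: np.ndarray, L: float = 255.0) -> float:
    """Global single-window SSIM with C1=(0.01*L)^2, C2=(0.03*L)^2.

    Inputs are expected on the [0, L] dynamic range (see
    :func:`to_uint8_range`). Symmetric in X and Y.
    """
    X, Y = _check_shapes(X, Y)
    c1 = (0.01 * L) ** 2
    c2 = (0.03 * L) ** 2
    mx, my = X.mean(), Y.mean()
    vx, vy = X.var(), Y.var()
    cov = float(np.mean((X - mx) * (Y - my)))
    return float(
        (2 * mx * my + c1) * (2 * cov + c2) / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    )


_LAPLACIAN = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


def epi(X: np.ndarray, Y: np.ndarray) -> float:
    """Edge preservation index: correlation of Laplacian-filtered images.

    Both images are high-pass filtered with the 3x3 Laplacian (reflective
    borders); the EPI is the normalized correlation of the mean-subtracted
    filtered images over the whole image.
    """
    X, Y = _check_shapes(X, Y)
    if min(X.shape) < 3:
        raise ValueError("images must be at least 3x3")
    dx = scipy.ndimage.convolve(X, _LAPLACIAN, mode="reflect")
    dy = scipy.ndimage.convolve(Y, _LAPLACIAN, mode="reflect")
    dx -= dx.mean()
    dy -= dy.mean()
    nx = float(np.sum(dx * dx))
    ny = float(np.sum(dy * dy))
    if nx == 0 or ny == 0:
        raise ValueError("Laplacian-filtered image has zero variance")
    return float(np.sum(dx * dy) / np.sqrt(nx * ny))


def image_snr(img: np.ndarray, rois: ROISet) -> float:
    """SNR: 10*log10(mean signal-region amplitude / mean noise-region std)."""
    img = np.asarray(img, dtype=float)
    mu = np.mean([r.extract(img).mean() for r in rois.signal_regions])
    sigma = np.mean([r.extract(img).std() for r in rois.noise_regions])
    if sigma <= 0:
        raise ValueError("noise regions have zero standard deviation")
    return float(10.0 * np.log10(mu / sigma))


def image_cnr(img: np.ndarray, rois: ROISet) -> float:
    """CNR: |mean signal mean - mean noise mean| / mean noise std."""
    img = np.asarray(img, dtype=float)
    mu_s = np.mean([r.extract(img).mean() for r in rois.signal_regions])
    mu_n = np.mean([r.extract(img).mean() for r in rois.noise_regions])
    sigma = np.mean([r.extract(img).std() for r in rois.noise_regions])
    if sigma <= 0:
        raise ValueError("noise regions have zero standard deviation")
    return float(abs(mu_s - mu_n) / sigma)


def axial_fwhm(profile: np.ndarray, spacing_mm: float) -> float:
    """Full width at half maximum of a depth profile's global peak, in mm.

    Crossings of the half-maximum level on each side of the peak are located
    by linear interpolation between the bracketing samples.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.size < 3:
        raise ValueError("profile must be 1-D with at least 3 samples")
    peak = int(np.argmax(profile))
    if peak == 0 or peak == profile.size - 1:
        raise ValueError("global maximum must not lie on a boundary")
    half = profile[peak] / 2.0

    def cross(indices: np.ndarray) -> float:
        for i in indices:
            if profile[i] < half:
                # linear interpolation between i and the sample nearer the peak
                j = i + 1 if i < peak else i - 1
                frac = (half - profile[i]) / (profile[j] - profile[i])
                return i + frac * (j - i)
        raise ValueError("no half-maximum crossing on one side of the peak")

    left = cross(np.arange(peak - 1, -1, -1))
    right = cross(np.arange(peak + 1, profile.size))
    return float((right - left) * spacing_mm)
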