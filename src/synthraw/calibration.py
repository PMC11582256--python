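"""Map estimation from fully sampled raw data.

Decomposes a multi-coil slice into the factors the synthesis model works
with: a magnitude image ``M``, a complex phase map ``P``, complex coil
sensitivity maps ``CSM`` and a coil noise covariance ``phi``.

The sensitivity estimator is a phase-sensitive calibration-region method:
coil images are low-pass filtered through an apodized central calibration
block, divided by their root-sum-of-squares, and phase-anchored to the
first coil so that the combined image retains the object phase. The
decomposition of a product ``M * P * CSM`` into its factors is not unique;
this anchoring fixes the convention (smooth receive phase that is common to
all coils is attributed to the object phase rather than the maps).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_data import MagnitudeImage, MultiCoilKSpace, ScanRecord, ifft2c

__all__ = [
    "CoilSensitivityMaps",
    "PhaseMap",
    "NoiseCovariance",
    "MapTriplet",
    "estimate_csm",
    "phase_sensitive_combine",
    "normalize_csm_phase",
    "estimate_noise_cov",
    "find_background_region",
    "decompose_scan",
]

SUPPORT_THRESHOLD = 0.05  # fraction of peak low-pass RSS counted as object
DEFAULT_NOISE_REGION = 20  # edge length of the background patch


@dataclass
class CoilSensitivityMaps:
    """Complex sensitivity profiles, coils x ky x kx, unit RSS inside support."""

    data: np.ndarray
    support_mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        self.support_mask = np.asarray(self.support_mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("CSM data must be (coils, ky, kx)")
        if self.support_mask.shape != self.data.shape[1:]:
            raise ValueError("support mask shape must match the spatial grid")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]


@dataclass
class PhaseMap:
    """Complex map carrying the coil-combined image phase.

    The magnitude is retained until explicit unit-normalization (which
    happens inside the synthesis equation, ``P / |P|``).
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 2:
            raise ValueError("PhaseMap data must be 2D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("PhaseMap contains non-finite entries")

    def unit(self) -> np.ndarray:
        """``P / |P|`` with the convention that zero magnitude maps to 1."""
        mag = np.abs(self.data)
        out = np.ones_like(self.data)
        nz = mag > 1e-12
        out[nz] = self.data[nz] / mag[nz]
        return out


@dataclass
class NoiseCovariance:
    """Hermitian PSD coils x coils covariance of receiver noise (phi)."""

    matrix: np.ndarray
    source_region: Optional[tuple[int, int, int, int]] = None  # (y0, x0, h, w)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.complex128)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("noise covariance must be square")
        if not np.allclose(self.matrix, self.matrix.conj().T, atol=1e-10):
            raise ValueError("noise covariance must be Hermitian")
        eigvals = np.linalg.eigvalsh(self.matrix)
        if np.any(eigvals < -1e-10):
            raise ValueError("noise covariance must be positive semi-definite")

    @property
    def n_coils(self) -> int:
        return self.matrix.shape[0]


@dataclass
class MapTriplet:
    """All right-hand-side factors of the raw-data synthesis equation."""

    magnitude: MagnitudeImage
    phase: PhaseMap
    csm: CoilSensitivityMaps
    noise_cov: NoiseCovariance

    def __post_init__(self) -> None:
        shape = self.magnitude.data.shape
        if self.phase.data.shape != shape or self.csm.data.shape[1:] != shape:
            raise ValueError("magnitude, phase and CSM grids must share shape")
        if self.csm.n_coils != self.noise_cov.n_coils:
            raise ValueError("CSM coil count must equal noise covariance dimension")


def _calibration_lowpass(kspace: np.ndarray, calib_lines: int) -> np.ndarray:
    """Low-pass coil images from an apodized central calibration block.

    A Hann window over a ``calib_lines``-wide block is applied on both
    k-space axes (the block is what a regular undersampling scheme keeps
    fully sampled in ky; using the same width in kx gives isotropically
    smooth maps and suppresses ringing).
    """
    n_ky, n_kx = kspace.shape[-2:]
    window = np.zeros(n_ky)
    c = n_ky // 2
    lo = c - calib_lines // 2
    hann = np.hanning(calib_lines + 2)[1:-1]
    window[lo : lo + calib_lines] = hann

    window_x = np.zeros(n_kx)
    cx = n_kx // 2
    w = min(calib_lines, n_kx)
    lox = cx - w // 2
    hann_x = np.hanning(w + 2)[1:-1]
    window_x[lox : lox + w] = hann_x

    filtered = kspace * window[:, None] * window_x[None, :]
    return ifft2c(filtered)


def estimate_csm(kspace: MultiCoilKSpace, calib_lines: int = 26) -> CoilSensitivityMaps:
    """Estimate coil sensitivity maps from the central calibration region.

    Low-pass coil images are divided by their RSS, phase-anchored per pixel
    to coil 0 so the combined image keeps the object phase, RSS-normalized
    inside the support (low-pass RSS above 5% of its peak) and zeroed
    outside. The global phase is then normalized so the mean phase of coil 0
    over the support is zero.
    """
    data = kspace.data if isinstance(kspace, MultiCoilKSpace) else np.asarray(kspace)
    n_ky = data.shape[-2]
    if calib_lines < 8 or calib_lines > n_ky:
        raise ValueError("calib_lines must be >= 8 and <= the ky extent")
    if not np.any(data):
        raise ValueError("degenerate input: all-zero k-space")

    lowpass = _calibration_lowpass(data, calib_lines)
    rss = np.sqrt(np.sum(np.abs(lowpass) ** 2, axis=0))
    support = rss >= SUPPORT_THRESHOLD * rss.max()

    maps = np.zeros_like(lowpass)
    maps[:, support] = lowpass[:, support] / rss[support]

    # Anchor per-pixel phase to coil 0: attributes the common (object) phase
    # to the combined image rather than the maps.
    ref = maps[0]
    ref_phase = np.ones_like(ref)
    nz = np.abs(ref) > 1e-12
    ref_phase[nz] = ref[nz] / np.abs(ref[nz])
    maps = maps * ref_phase.conj()[None]

    return normalize_csm_phase(CoilSensitivityMaps(maps, support))


def phase_sensitive_combine(coil_images: np.ndarray, csm: CoilSensitivityMaps) -> np.ndarray:
    """Combine coil images as ``sum_j conj(CSM_j) * image_j``.

    With exact unit-RSS maps the magnitude equals the RSS combination and
    the phase is the object phase.
    """
    coil_images = np.asarray(coil_images)
    if coil_images.shape != csm.data.shape:
        raise ValueError(
            f"shape mismatch: coil images {coil_images.shape} vs CSM {csm.data.shape}"
        )
    return np.sum(csm.data.conj() * coil_images, axis=0)


def normalize_csm_phase(csm: CoilSensitivityMaps) -> CoilSensitivityMaps:
    """Remove the global phase: divide all coils by the mean phase of coil 0.

    The mean phase is the argument of the support-masked mean of the
    unit-normalized coil-0 map (a circular mean, robust to wrapping).
    Idempotent; magnitudes are unchanged exactly.
    """
    support = csm.support_mask
    coil0 = csm.data[0][support]
    coil0 = coil0[np.abs(coil0) > 1e-12]
    if coil0.size == 0:
        raise ValueError("coil 0 has empty support")
    mean_dir = np.mean(coil0 / np.abs(coil0))
    theta = np.angle(mean_dir)
    return CoilSensitivityMaps(csm.data * np.exp(-1j * theta), support)


def find_background_region(
    coil_images: np.ndarray, size: int = DEFAULT_NOISE_REGION
) -> tuple[int, int, int, int]:
    """Pick the corner ``size x size`` patch with minimal mean RSS.

    A deterministic stand-in for manual background selection.
    """
    coil_images = np.asarray(coil_images)
    n_y, n_x = coil_images.shape[-2:]
    if size > n_y or size > n_x:
        raise ValueError("background region larger than the image")
    rss = np.sqrt(np.sum(np.abs(coil_images) ** 2, axis=0))
    corners = [
        (0, 0),
        (0, n_x - size),
        (n_y - size, 0),
        (n_y - size, n_x - size),
    ]
    means = [rss[y0 : y0 + size, x0 : x0 + size].mean() for y0, x0 in corners]
    y0, x0 = corners[int(np.argmin(means))]
    return (y0, x0, size, size)


def estimate_noise_cov(
    coil_images: np.ndarray,
    region: Optional[tuple[int, int, int, int]] = None,
) -> NoiseCovariance:
    """Sample covariance across coils of complex samples in a background patch.

    ``region`` is ``(y0, x0, height, width)``; when omitted the lowest-RSS
    corner 20 x 20 patch is used. The estimate is mean-subtracted and
    Hermitian PSD by construction.
    """
    coil_images = np.asarray(coil_images)
    n_coils = coil_images.shape[0]
    if region is None:
        region = find_background_region(coil_images)
    y0, x0, h, w = region
    n_y, n_x = coil_images.shape[-2:]
    if y0 < 0 or x0 < 0 or y0 + h > n_y or x0 + w > n_x:
        raise ValueError("noise region out of bounds")
    if h * w < 2 * n_coils:
        raise ValueError("noise region must contain at least 2x coils samples")
    samples = coil_images[:, y0 : y0 + h, x0 : x0 + w].reshape(n_coils, -1)
    if not np.any(samples):
        return NoiseCovariance(np.zeros((n_coils, n_coils), dtype=complex), region)
    samples = samples - samples.mean(axis=1, keepdims=True)
    n = samples.shape[1]
    cov = samples @ samples.conj().T / (n - 1)
    cov = (cov + cov.conj().T) / 2  # exact Hermitian symmetry
    return NoiseCovariance(cov, region)


def decompose_scan(scan: ScanRecord, calib_lines: int = 26) -> list[MapTriplet]:
    """Split each fully sampled slice into its (M, P, CSM, phi) factors.

    ``M`` is the magnitude of the phase-sensitive combination, ``P`` the
    combined image itself (magnitude carried; unit-normalized on use),
    ``CSM`` the phase-normalized sensitivity estimate, ``phi`` the noise
    covariance of a background patch of the coil images (identical to the
    k-space noise statistics under the orthonormal FFT convention).
    Deterministic: repeated calls give identical triplets.
    """
    triplets = []
    for ks in scan.kspace:
        coil_images = ifft2c(ks.data)
        csm = estimate_csm(ks, calib_lines=calib_lines)
        combined = phase_sensitive_combine(coil_images, csm)
        magnitude = MagnitudeImage(np.abs(combined))
        phase = PhaseMap(combined)
        noise_cov = estimate_noise_cov(coil_images)
        triplets.append(MapTriplet(magnitude, phase, csm, noise_cov))
    return triplets
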