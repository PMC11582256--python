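"""Synthetic raw-data synthesis.

The central operation combines a magnitude image ``M``, a unit-normalized
complex phase map ``P / |P|``, coil sensitivity maps ``CSM`` and
coil-correlated complex Gaussian noise with covariance ``phi``::

    raw = FFT( M * (P / |P|) * CSM ) + N(0, phi)

Noise is added in k-space, i.i.d. across k-space samples and correlated
across coils through the Cholesky factor of ``phi``; with the package's
orthonormal centered FFT this is statistically identical to image-domain
noise. Real and imaginary parts each carry half the variance, so the total
complex variance per coil equals ``diag(phi)``.

Also provided here: the sinusoidal-phase ablation baseline and the
on-the-fly synthetic/real training-pool sampler (default 75% synthetic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core_data import MagnitudeImage, MultiCoilKSpace, fft2c, rss_combine
from .calibration import (
    CoilSensitivityMaps,
    MapTriplet,
    NoiseCovariance,
    PhaseMap,
)

__all__ = [
    "SyntheticPool",
    "RealPool",
    "SinusoidalPhaseParams",
    "synthesize_raw",
    "sinusoidal_phase",
    "sample_noise_cov",
    "draw_training_sample",
]


def _unit_phase(phase: np.ndarray) -> np.ndarray:
    mag = np.abs(phase)
    out = np.ones_like(phase, dtype=np.complex128)
    nz = mag > 1e-12
    out[nz] = phase[nz] / mag[nz]
    return out


def synthesize_raw(
    magnitude: MagnitudeImage,
    phase: PhaseMap,
    csm: CoilSensitivityMaps,
    noise_cov: NoiseCovariance,
    rng: np.random.Generator | int,
) -> MultiCoilKSpace:
    """Synthesize multi-coil k-space from magnitude, phase, CSMs and noise.

    Coil images ``M * (P/|P|) * CSM_j`` are transformed to k-space and
    complex Gaussian noise with coil covariance ``phi`` (independent across
    k-space samples) is added. ``P/|P|`` is taken as 1 where ``|P|`` is
    numerically zero.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    m = magnitude.data if isinstance(magnitude, MagnitudeImage) else np.asarray(magnitude)
    p = phase if isinstance(phase, PhaseMap) else PhaseMap(np.asarray(phase))
    csm_data = csm.data if isinstance(csm, CoilSensitivityMaps) else np.asarray(csm)
    phi = (
        noise_cov.matrix
        if isinstance(noise_cov, NoiseCovariance)
        else NoiseCovariance(np.asarray(noise_cov)).matrix
    )
    if csm_data.shape[1:] != m.shape or p.data.shape != m.shape:
        raise ValueError("magnitude, phase and CSM grids must share shape")
    n_coils = csm_data.shape[0]
    if phi.shape != (n_coils, n_coils):
        raise ValueError("noise covariance dimension must equal the coil count")

    coil_images = m[None] * _unit_phase(p.data)[None] * csm_data
    kspace = fft2c(coil_images)

    if np.any(np.abs(phi) > 0):
        # phi is PSD (validated); a tiny jitter keeps Cholesky stable when
        # it is singular.
        jitter = 1e-12 * max(np.abs(np.diag(phi)).max(), 1.0)
        chol = np.linalg.cholesky(phi + jitter * np.eye(n_coils))
        shape = (n_coils,) + m.shape
        z = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2.0)
        noise = np.einsum("ij,j...->i...", chol, z)
        kspace = kspace + noise
    return MultiCoilKSpace(kspace)


@dataclass
class SinusoidalPhaseParams:
    """Parameter ranges for the sinusoidal-phase ablation baseline.

    Phase is ``A * sin(2*pi*(fx*x + fy*y) + psi)`` with ``A`` in radians and
    spatial frequencies in cycles per field of view, drawn uniformly.
    """

    amplitude_range: tuple[float, float] = (0.0, 2 * np.pi)
    frequency_range: tuple[float, float] = (0.0, 2.0)
    fixed_amplitude: Optional[float] = None


def sinusoidal_phase(
    shape: tuple[int, int],
    params: SinusoidalPhaseParams | None = None,
    rng: np.random.Generator | int = 0,
) -> PhaseMap:
    """Unit-magnitude phase map with a random planar sinusoidal phase."""
    params = params or SinusoidalPhaseParams()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    amp = (
        params.fixed_amplitude
        if params.fixed_amplitude is not None
        else rng.uniform(*params.amplitude_range)
    )
    fx = rng.uniform(*params.frequency_range)
    fy = rng.uniform(*params.frequency_range)
    psi = rng.uniform(0, 2 * np.pi)
    ny, nx = shape
    y, x = np.meshgrid(np.arange(ny) / ny, np.arange(nx) / nx, indexing="ij")
    angle = amp * np.sin(2 * np.pi * (fx * x + fy * y) + psi)
    return PhaseMap(np.exp(1j * angle))


def sample_noise_cov(
    pool: list[NoiseCovariance], rng: np.random.Generator | int
) -> NoiseCovariance:
    """Uniform random covariance from a pool of real-scan estimates."""
    if not pool:
        raise ValueError("noise covariance pool is empty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return pool[int(rng.integers(len(pool)))]


@dataclass
class SyntheticPool:
    """On-the-fly synthetic raw data: magnitude sources + trained map models.

    ``phase_model``/``csm_model`` are (AAEModel, SuperResModel) bundles from
    the generative module. For ablation modes the matching ground-truth
    triplets of the magnitude sources can be attached so real maps can be
    substituted for generated ones.
    """

    magnitude_source: list[MagnitudeImage]
    phase_model: tuple = None
    csm_model: tuple = None
    noise_cov_pool: list[NoiseCovariance] = field(default_factory=list)
    triplets: Optional[list[MapTriplet]] = None
    phase_source: str = "synthetic"  # synthetic | real | sinusoidal
    csm_source: str = "synthetic"  # synthetic | real
    sinusoidal_params: SinusoidalPhaseParams = field(default_factory=SinusoidalPhaseParams)

    def __post_init__(self) -> None:
        if not self.magnitude_source:
            raise ValueError("synthetic pool needs at least one magnitude image")
        if not self.noise_cov_pool:
            raise ValueError("synthetic pool needs a noise covariance pool")


@dataclass
class RealPool:
    """Stored raw slices (with their decompositions) from real scans."""

    slices: list[tuple[MultiCoilKSpace, MagnitudeImage]]

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("real pool is empty")


def _synthesize_from_pool(
    pool: SyntheticPool, rng: np.random.Generator
) -> tuple[MultiCoilKSpace, MagnitudeImage]:
    from .generative import sample_map  # deferred: generative trains lazily

    idx = int(rng.integers(len(pool.magnitude_source)))
    magnitude = pool.magnitude_source[idx]
    shape = magnitude.data.shape

    if pool.phase_source == "synthetic":
        aae, sr = pool.phase_model
        phase = PhaseMap(sample_map(aae, sr, magnitude, rng)[0])
    elif pool.phase_source == "sinusoidal":
        phase = sinusoidal_phase(shape, pool.sinusoidal_params, rng)
    elif pool.phase_source == "real":
        phase = pool.triplets[idx].phase
    else:
        raise ValueError(f"unknown phase source {pool.phase_source!r}")

    if pool.csm_source == "synthetic":
        aae, sr = pool.csm_model
        csm_maps = sample_map(aae, sr, magnitude, rng)
        # RSS-normalize generated maps so the magnitude image is exactly the
        # RSS ground truth of the noiseless synthetic slice
        rss = np.sqrt(np.sum(np.abs(csm_maps) ** 2, axis=0))
        csm_maps = csm_maps / np.maximum(rss, 1e-3)
        support = magnitude.data > 0
        csm = CoilSensitivityMaps(csm_maps, support)
    elif pool.csm_source == "real":
        csm = pool.triplets[idx].csm
    else:
        raise ValueError(f"unknown CSM source {pool.csm_source!r}")

    phi = sample_noise_cov(pool.noise_cov_pool, rng)
    raw = synthesize_raw(magnitude, phase, csm, phi, rng)
    from .core_data import ifft2c

    gt = MagnitudeImage(rss_combine(ifft2c(raw.data)))
    return raw, gt


def draw_training_sample(
    synth: Optional[SyntheticPool],
    real: Optional[RealPool],
    rng: np.random.Generator | int,
    mix_fraction: float = 0.75,
) -> tuple[MultiCoilKSpace, MagnitudeImage, str]:
    """Draw one fully sampled training slice and its RSS ground truth.

    With probability ``mix_fraction`` a slice is synthesized on the fly from
    the synthetic pool (magnitude image + generated/substituted maps +
    sampled noise covariance); otherwise a stored real slice is returned.
    The third element of the return tuple records which pool was used
    (``"synthetic"`` or ``"real"``).
    """
    if not 0.0 <= mix_fraction <= 1.0:
        raise ValueError("mix_fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    use_synth = rng.random() < mix_fraction
    if use_synth:
        if synth is None:
            raise ValueError("synthetic pool required for mix_fraction > 0")
        raw, gt = _synthesize_from_pool(synth, rng)
        return raw, gt, "synthetic"
    if real is None:
        raise ValueError("real pool required for mix_fraction < 1")
    ks, gt = real.slices[int(rng.integers(len(real.slices)))]
    return ks, gt, "real"
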