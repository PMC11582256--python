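"""Phantom ground-truth generator.

Produces multi-coil raw datasets with *known* magnitude, phase, coil
sensitivity maps and noise covariance, standing in for brain scans so the
calibration, generative, synthesis and reconstruction modules can be tested
end to end without external data.

What the phantoms emulate:

* piecewise-smooth magnitude: overlapping random ellipses on a zero
  background, confined to a central disc so that the 20 x 20 image corners
  are exactly signal-free (the background-noise-region contract);
* smooth object phase: a low-order 2D polynomial plus one low-frequency
  sinusoid, with a configurable bound on the per-pixel phase step;
* smooth coil sensitivities: Gaussian lobes centred around the object
  perimeter with mild per-coil linear phase ramps, RSS-normalized to 1
  everywhere. Coil 0 is kept real-positive, which pins down the otherwise
  ambiguous split of smooth phase between object and maps and makes
  estimated maps directly comparable to the ground truth;
* receiver noise: complex Gaussian, coil-correlated with a known
  covariance (uniform diagonal scale, constant off-diagonal correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import MagnitudeImage, ScanRecord
from .calibration import (
    CoilSensitivityMaps,
    MapTriplet,
    NoiseCovariance,
    PhaseMap,
)
from .synthesis import synthesize_raw

__all__ = [
    "PhantomSpec",
    "make_magnitude",
    "make_phase",
    "make_csms",
    "make_scan",
    "make_dataset",
]


@dataclass
class PhantomSpec:
    """Parameters of the phantom family.

    Defaults target the desk-test scale (64 x 64 grid, 4 coils); set
    ``grid_size=320, n_coils=16`` to mirror the full-scale acquisition.
    """

    grid_size: int = 64
    n_coils: int = 4
    n_ellipses: tuple[int, int] = (3, 6)
    intensity_range: tuple[float, float] = (0.3, 1.0)
    object_radius_fraction: float = 0.27  # keeps 20x20 corners signal-free at 64+
    phase_poly_order: int = 2
    phase_poly_scale: float = 1.5  # radians across the object
    phase_sin_amplitude: float = 0.6  # radians
    phase_sin_cycles: float = 1.0  # cycles per field of view
    max_phase_step: float = 0.5  # radians between neighbouring pixels
    csm_lobe_sigma: float = 0.6  # fraction of grid size
    csm_phase_ramp: float = 2.0  # max radians across the grid per coil
    noise_sigma: float = 0.02
    noise_correlation: float = 0.3

    def __post_init__(self) -> None:
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        if self.n_coils < 1:
            raise ValueError("n_coils must be >= 1")

    def noise_covariance(self) -> NoiseCovariance:
        c = self.n_coils
        phi = np.full((c, c), self.noise_correlation, dtype=complex)
        np.fill_diagonal(phi, 1.0)
        phi *= self.noise_sigma**2
        return NoiseCovariance(phi)


def _coords(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized coordinates in [-0.5, 0.5)."""
    ax = (np.arange(n) - n // 2) / n
    return np.meshgrid(ax, ax, indexing="ij")


def make_magnitude(spec: PhantomSpec, seed: int | np.random.Generator) -> MagnitudeImage:
    """Piecewise-smooth overlapping-ellipse object on a zero background."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = spec.grid_size
    yy, xx = _coords(n)
    image = np.zeros((n, n))
    r_max = spec.object_radius_fraction
    n_ell = int(rng.integers(spec.n_ellipses[0], spec.n_ellipses[1] + 1))
    for _ in range(n_ell):
        cy, cx = rng.uniform(-0.45 * r_max, 0.45 * r_max, size=2)
        a = rng.uniform(0.25 * r_max, 0.55 * r_max)
        b = rng.uniform(0.25 * r_max, 0.55 * r_max)
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(*spec.intensity_range)
        yr = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
        xr = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
        image += amp * ((yr / a) ** 2 + (xr / b) ** 2 <= 1.0)
    # hard confinement to the central disc keeps corners exactly zero
    image[yy**2 + xx**2 > r_max**2] = 0.0
    peak = image.max()
    if peak > 0:
        image /= peak
    return MagnitudeImage(image)


def make_phase(spec: PhantomSpec, seed: int | np.random.Generator) -> PhaseMap:
    """Unit-magnitude map: low-order polynomial + low-frequency sinusoid."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = spec.grid_size
    yy, xx = _coords(n)
    angle = np.zeros((n, n))
    order = spec.phase_poly_order
    for i in range(order + 1):
        for j in range(order + 1 - i):
            if i == j == 0:
                coeff = rng.uniform(-np.pi, np.pi)  # constant offset
            else:
                coeff = rng.uniform(-1, 1) * spec.phase_poly_scale
            angle += coeff * (yy**i) * (xx**j)
    if spec.phase_sin_amplitude > 0:
        fy, fx = rng.uniform(-spec.phase_sin_cycles, spec.phase_sin_cycles, size=2)
        psi = rng.uniform(0, 2 * np.pi)
        angle += spec.phase_sin_amplitude * np.sin(2 * np.pi * (fy * yy + fx * xx) + psi)
    # enforce the configured smoothness bound
    step = max(
        np.abs(np.diff(angle, axis=0)).max(initial=0.0),
        np.abs(np.diff(angle, axis=1)).max(initial=0.0),
    )
    if step > spec.max_phase_step:
        angle *= spec.max_phase_step / step
    return PhaseMap(np.exp(1j * angle))


def make_csms(spec: PhantomSpec, seed: int | np.random.Generator) -> CoilSensitivityMaps:
    """Smooth Gaussian sensitivity lobes around the perimeter, unit RSS.

    Coil 0 is real-positive; other coils carry mild linear phase ramps.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n, c = spec.grid_size, spec.n_coils
    yy, xx = _coords(n)
    maps = np.zeros((c, n, n), dtype=complex)
    angles = 2 * np.pi * np.arange(c) / c + rng.uniform(0, 2 * np.pi)
    sigma = spec.csm_lobe_sigma
    for j in range(c):
        cy, cx = 0.45 * np.sin(angles[j]), 0.45 * np.cos(angles[j])
        lobe = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2)) / (2 * sigma**2))
        lobe = 0.15 + lobe  # keep a floor so RSS never vanishes
        if j == 0:
            maps[j] = lobe
        else:
            gy, gx = rng.uniform(-spec.csm_phase_ramp, spec.csm_phase_ramp, size=2)
            maps[j] = lobe * np.exp(1j * (gy * yy + gx * xx))
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= rss[None]
    return CoilSensitivityMaps(maps, np.ones((n, n), dtype=bool))


def make_scan(
    spec: PhantomSpec,
    n_slices: int,
    seed: int | np.random.Generator,
    noiseless: bool = False,
    split: str = "train",
) -> tuple[ScanRecord, list[MapTriplet]]:
    """Build one phantom scan plus its ground-truth decomposition.

    Each slice is ``M * (P/|P|) * CSM`` transformed to k-space with complex
    Gaussian noise of known covariance added (unless ``noiseless``). The
    true :class:`MapTriplet` per slice is returned for oracle comparisons.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    phi = spec.noise_covariance()
    zero_phi = NoiseCovariance(np.zeros_like(phi.matrix))
    kspace, magnitudes, triplets = [], [], []
    for _ in range(n_slices):
        m = make_magnitude(spec, rng)
        p = make_phase(spec, rng)
        csm = make_csms(spec, rng)
        used_phi = zero_phi if noiseless else phi
        raw = synthesize_raw(m, p, csm, used_phi, rng)
        kspace.append(raw)
        magnitudes.append(m)
        triplets.append(MapTriplet(m, p, csm, used_phi))
    record = ScanRecord(
        kspace=kspace,
        magnitude=magnitudes,
        metadata={"scanner": "phantom", "scale_factor": 1.0, "n_coils": spec.n_coils},
        split=split,
    )
    return record, triplets


def make_dataset(
    spec: PhantomSpec,
    n_scans: int,
    split_fractions: tuple[float, float, float] = (0.8, 0.05, 0.15),
    seed: int = 0,
    n_slices: int = 2,
    noiseless: bool = False,
) -> list[ScanRecord]:
    """Deterministically split phantom scans into train/validation/test.

    Rounding rule: validation and test counts are floored, the remainder
    goes to train. Per-scan seeds are spawned from the master seed, so any
    scan is reproducible independently of the others.
    """
    f_train, f_val, f_test = split_fractions
    if not np.isclose(f_train + f_val + f_test, 1.0):
        raise ValueError("split fractions must sum to 1")
    n_val = int(np.floor(f_val * n_scans))
    n_test = int(np.floor(f_test * n_scans))
    n_train = n_scans - n_val - n_test
    splits = ["train"] * n_train + ["validation"] * n_val + ["test"] * n_test
    child_seeds = np.random.SeedSequence(seed).spawn(n_scans)
    records = []
    for split, child in zip(splits, child_seeds):
        record, _ = make_scan(
            spec, n_slices, np.random.default_rng(child), noiseless=noiseless, split=split
        )
        records.append(record)
    return records
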