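"""Core containers and k-space plumbing.

Conventions used throughout the package:

* Arrays are ordered ``(slice, coil, ky, kx)``; ``ky`` is the phase-encoding
  axis that gets undersampled.
* Fourier transforms are centered (DC at the grid centre) and orthonormal,
  so white Gaussian noise has identical statistics in image space and
  k-space, and Parseval's identity holds exactly.
* The centre of an even axis of length ``n`` is index ``n // 2`` (0-based).
* Calibration and synthesis math runs in double (complex128); single
  precision is only used inside network training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import yaml

__all__ = [
    "ComplexImage",
    "MultiCoilKSpace",
    "MagnitudeImage",
    "ScanRecord",
    "ExperimentConfig",
    "FormatError",
    "fft2c",
    "ifft2c",
    "rss_combine",
    "scale_raw",
    "read_scan",
    "write_scan",
    "load_config",
    "save_config",
]

DEFAULT_SCALE_FACTOR = 1e6

VALID_SPLITS = ("train", "validation", "test")


class FormatError(ValueError):
    """Raised when an on-disk container violates the expected layout."""


def _check_finite(data: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{name} contains non-finite entries")


@dataclass
class ComplexImage:
    """A complex-valued 2D image (or k-space plane), height x width."""

    data: np.ndarray
    spacing: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 2:
            raise ValueError("ComplexImage requires a 2D array")
        if min(self.data.shape) < 8:
            raise ValueError("ComplexImage axes must be >= 8")
        _check_finite(self.data, "ComplexImage")


@dataclass
class MultiCoilKSpace:
    """Complex k-space for one slice: coils x ky x kx."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.complexfloating):
            self.data = self.data.astype(np.complex128)
        if self.data.ndim != 3:
            raise ValueError("MultiCoilKSpace requires a 3D array (coils, ky, kx)")
        if self.data.shape[0] < 1:
            raise ValueError("MultiCoilKSpace requires >= 1 coil")
        _check_finite(self.data, "MultiCoilKSpace")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class MagnitudeImage:
    """Non-negative real image (symbol M)."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("MagnitudeImage requires a 2D array")
        if np.any(self.data < 0):
            raise ValueError("MagnitudeImage entries must be >= 0")
        _check_finite(self.data, "MagnitudeImage")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class ScanRecord:
    """One scan: per-slice multi-coil k-space plus magnitude reconstructions."""

    kspace: list[MultiCoilKSpace]
    magnitude: list[MagnitudeImage]
    metadata: dict
    split: str = "train"

    def __post_init__(self) -> None:
        if self.split not in VALID_SPLITS:
            raise ValueError(f"split must be one of {VALID_SPLITS}, got {self.split!r}")
        shapes = {ks.data.shape for ks in self.kspace}
        if len(shapes) > 1:
            raise ValueError("all slices must share coil count and matrix size")

    @property
    def n_slices(self) -> int:
        return len(self.kspace)

    @property
    def n_coils(self) -> int:
        return self.kspace[0].n_coils


@dataclass
class ExperimentConfig:
    """Settings for one reconstruction-training experiment."""

    training_scans: int = 20
    use_augmentation: bool = False
    data_mode: str = "real"  # real | synthetic | ablation variants
    synthetic_fraction: float = 0.75
    epochs: int = 1000
    batches_per_epoch: int = 200
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.synthetic_fraction <= 1.0:
            raise ValueError("synthetic_fraction must lie in [0, 1]")
        for name in ("training_scans", "epochs", "batches_per_epoch", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return ExperimentConfig(**payload)


def save_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Centered orthonormal Fourier transforms
# ---------------------------------------------------------------------------

def fft2c(x: np.ndarray) -> np.ndarray:
    """Centered, orthonormal 2D FFT over the last two axes.

    Energy-preserving (Parseval) and unitary; the DC component lands at
    index ``n // 2`` on each axis.
    """
    x = np.asarray(x)
    if not np.all(np.isfinite(x)):
        raise ValueError("fft2c input contains non-finite entries")
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def ifft2c(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c` (same centering and normalization)."""
    x = np.asarray(x)
    if not np.all(np.isfinite(x)):
        raise ValueError("ifft2c input contains non-finite entries")
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def rss_combine(coil_images: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares combination across the leading coil axis."""
    coil_images = np.asarray(coil_images)
    if coil_images.ndim < 3 or coil_images.shape[0] < 1:
        raise ValueError("rss_combine requires a non-empty (coils, ..., ky, kx) stack")
    return np.sqrt(np.sum(np.abs(coil_images) ** 2, axis=0))


def scale_raw(kspace: np.ndarray, factor: float = DEFAULT_SCALE_FACTOR) -> np.ndarray:
    """Scale raw k-space by a constant so image intensities sit near unity.

    FastMRI-style raw data comes in at ~1e-6 intensity units; the default
    factor of 1e6 brings reconstructions to unit scale.
    """
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return np.asarray(kspace) * factor


# ---------------------------------------------------------------------------
# HDF5 container (FastMRI dialect)
# ---------------------------------------------------------------------------

def write_scan(record: ScanRecord, path) -> None:
    """Write a :class:`ScanRecord` to the HDF5 dialect.

    Layout: dataset ``kspace`` (complex, slices x coils x ky x kx), optional
    ``reconstruction_rss`` (real, slices x ky x kx), attributes ``scanner``,
    ``split``, ``scale_factor``.
    """
    kspace = np.stack([ks.data for ks in record.kspace])
    with h5py.File(path, "w") as fh:
        fh.create_dataset("kspace", data=kspace)
        if record.magnitude:
            rss = np.stack([m.data for m in record.magnitude])
            fh.create_dataset("reconstruction_rss", data=rss)
        fh.attrs["split"] = record.split
        for key, value in record.metadata.items():
            fh.attrs[key] = value


def read_scan(path) -> ScanRecord:
    """Read a scan written by :func:`write_scan` (or any FastMRI-style file)."""
    path = Path(path)
    with h5py.File(path, "r") as fh:
        if "kspace" not in fh:
            raise FormatError(f"{path.name}: missing dataset 'kspace'")
        ds = fh["kspace"]
        if ds.ndim != 4:
            raise FormatError(
                f"{path.name}: 'kspace' must have 4 axes (slices, coils, ky, kx), got {ds.ndim}"
            )
        if not np.issubdtype(ds.dtype, np.complexfloating):
            raise FormatError(f"{path.name}: 'kspace' must be stored as complex, got {ds.dtype}")
        kspace = ds[...]
        magnitude = []
        if "reconstruction_rss" in fh:
            magnitude = [MagnitudeImage(m) for m in fh["reconstruction_rss"][...]]
        metadata = {k: v for k, v in fh.attrs.items() if k != "split"}
        split = str(fh.attrs.get("split", "train"))
    return ScanRecord(
        kspace=[MultiCoilKSpace(s) for s in kspace],
        magnitude=magnitude,
        metadata=metadata,
        split=split,
    )
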