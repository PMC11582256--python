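"""Undersampled Cartesian reconstruction: masks, augmentation, variational net.

The acceleration scheme is the regular fourfold pattern with an
autocalibration block: every ``stride``-th phase-encode line plus
``calib_width`` contiguous central lines (defaults 4 and 26, giving an
effective acceleration just under 4 at 320 lines).

The reconstruction model is a size-parameterized end-to-end variational
network: an unrolled sequence of cascades alternating a learned image-space
regularizer (applied to the sensitivity-combined image) with soft data
consistency against the sampled lines, plus a sensitivity-estimation
submodule that refines calibration-region sensitivity maps with a small
CNN. It is trained to maximize mean SSIM against the RSS reconstruction of
the fully sampled data. The default instance is deliberately small
(4 cascades, 16 channels) — structural fidelity, not benchmark capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import ndimage

from .core_data import MagnitudeImage, MultiCoilKSpace, fft2c, ifft2c, rss_combine
from .calibration import estimate_csm
from . import nn
from .nn import functional as F
from .nn.autograd import Tensor

__all__ = [
    "UndersamplingMask",
    "AugmentationConfig",
    "AugmentationParams",
    "ReconTrainConfig",
    "ReconModel",
    "make_mask",
    "apply_undersampling",
    "sample_augmentation",
    "apply_augmentation_params",
    "augment",
    "build_recon_model",
    "train_recon",
    "reconstruct",
    "zero_filled",
]


# ---------------------------------------------------------------------------
# Undersampling
# ---------------------------------------------------------------------------


@dataclass
class UndersamplingMask:
    """Boolean selector over the phase-encoding (ky) axis."""

    lines: np.ndarray
    stride: int = 4
    calib_width: int = 26

    def __post_init__(self) -> None:
        self.lines = np.asarray(self.lines, dtype=bool)

    @property
    def ky_extent(self) -> int:
        return self.lines.size

    @property
    def acceleration(self) -> float:
        return self.lines.size / max(int(self.lines.sum()), 1)


def make_mask(ky_extent: int, stride: int = 4, calib_width: int = 26) -> UndersamplingMask:
    """Regular-stride lines (offset 0) plus a centred calibration block.

    For an even extent ``n`` the block occupies ``[n//2 - calib_width//2,
    n//2 + calib_width - calib_width//2)``, consistent with the centered-FFT
    convention. Deterministic.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if calib_width > ky_extent:
        raise ValueError("calib_width exceeds the ky extent")
    lines = np.zeros(ky_extent, dtype=bool)
    lines[::stride] = True
    centre = ky_extent // 2
    lo = centre - calib_width // 2
    lines[lo : lo + calib_width] = True
    return UndersamplingMask(lines, stride, calib_width)


def apply_undersampling(kspace, mask: UndersamplingMask) -> MultiCoilKSpace:
    """Zero all unsampled ky lines; sampled lines are copied verbatim."""
    data = kspace.data if isinstance(kspace, MultiCoilKSpace) else np.asarray(kspace)
    if data.shape[-2] != mask.ky_extent:
        raise ValueError(
            f"mask length {mask.ky_extent} != ky extent {data.shape[-2]}"
        )
    return MultiCoilKSpace(data * mask.lines[:, None])


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


@dataclass
class AugmentationConfig:
    """Per-augmentation enable probability and parameter ranges."""

    probability: float = 0.5
    integer_translation: int = 8  # +/- pixels
    use_rot90: bool = True  # 0/90/180/270 degrees
    use_mirror: bool = True  # x, y, or both
    rotation_degrees: float = 10.0  # +/- continuous rotation
    zoom_range: tuple[float, float] = (0.9, 1.1)
    subpixel_translation: float = 16.0  # +/- pixels

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")


@dataclass
class AugmentationParams:
    """A concrete draw of augmentations; ``None`` fields are skipped."""

    integer_shift: Optional[tuple[int, int]] = None
    rot90_quarters: Optional[int] = None
    mirror: Optional[str] = None  # "x" | "y" | "both"
    rotation_deg: Optional[float] = None
    zoom: Optional[float] = None
    subpixel_shift: Optional[tuple[float, float]] = None


def sample_augmentation(
    config: AugmentationConfig, rng: np.random.Generator | int
) -> AugmentationParams:
    """Independently enable each augmentation with the configured probability."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = config.probability
    params = AugmentationParams()
    if rng.random() < p:
        t = config.integer_translation
        params.integer_shift = (int(rng.integers(-t, t + 1)), int(rng.integers(-t, t + 1)))
    if config.use_rot90 and rng.random() < p:
        params.rot90_quarters = int(rng.integers(0, 4))
    if config.use_mirror and rng.random() < p:
        params.mirror = ("x", "y", "both")[int(rng.integers(0, 3))]
    if rng.random() < p:
        params.rotation_deg = float(rng.uniform(-config.rotation_degrees,
                                                config.rotation_degrees))
    if rng.random() < p:
        params.zoom = float(rng.uniform(*config.zoom_range))
    if rng.random() < p:
        s = config.subpixel_translation
        params.subpixel_shift = (float(rng.uniform(-s, s)), float(rng.uniform(-s, s)))
    return params


def _transform_real(image: np.ndarray, params: AugmentationParams) -> np.ndarray:
    """Apply the augmentation chain to one real 2D image.

    Discrete operations are exact; continuous ones use bilinear
    interpolation with zero padding.
    """
    out = image
    if params.integer_shift is not None:
        out = np.roll(out, params.integer_shift, axis=(0, 1))
    if params.rot90_quarters:
        out = np.rot90(out, params.rot90_quarters)
    if params.mirror is not None:
        if params.mirror in ("y", "both"):
            out = out[::-1, :]
        if params.mirror in ("x", "both"):
            out = out[:, ::-1]
    if params.rotation_deg:
        out = ndimage.rotate(out, params.rotation_deg, reshape=False, order=1,
                             mode="constant", cval=0.0)
    if params.zoom is not None and params.zoom != 1.0:
        n = out.shape[0]
        centre = (np.array(out.shape) - 1) / 2
        matrix = np.eye(2) / params.zoom
        offset = centre - matrix @ centre
        out = ndimage.affine_transform(out, matrix, offset=offset, order=1,
                                       mode="constant", cval=0.0)
    if params.subpixel_shift is not None:
        out = ndimage.shift(out, params.subpixel_shift, order=1, mode="constant", cval=0.0)
    return np.ascontiguousarray(out)


def apply_augmentation_params(
    kspace, ground_truth, params: AugmentationParams
) -> tuple[MultiCoilKSpace, MagnitudeImage]:
    """Apply one augmentation draw to every coil image and the ground truth.

    The identical spatial transform acts in the image domain on the real
    and imaginary parts of each coil image; k-space is regenerated from the
    transformed coil images.
    """
    data = kspace.data if isinstance(kspace, MultiCoilKSpace) else np.asarray(kspace)
    gt = ground_truth.data if isinstance(ground_truth, MagnitudeImage) else np.asarray(ground_truth)
    coil_images = ifft2c(data)
    transformed = np.stack([
        _transform_real(c.real, params) + 1j * _transform_real(c.imag, params)
        for c in coil_images
    ])
    new_gt = np.clip(_transform_real(gt, params), 0.0, None)
    return MultiCoilKSpace(fft2c(transformed)), MagnitudeImage(new_gt)


def augment(
    kspace, ground_truth, config: AugmentationConfig, rng: np.random.Generator | int
) -> tuple[MultiCoilKSpace, MagnitudeImage]:
    """Randomly augment a fully sampled slice and its RSS ground truth."""
    params = sample_augmentation(config, rng)
    return apply_augmentation_params(kspace, ground_truth, params)


# ---------------------------------------------------------------------------
# Variational network
# ---------------------------------------------------------------------------


def _to_channels(x: np.ndarray) -> np.ndarray:
    """(N, H, W) complex -> (N, 2, H, W) float32."""
    return np.stack([x.real, x.imag], axis=1).astype(np.float32)


def _fft_op(t: Tensor) -> Tensor:
    """Differentiable centered orthonormal FFT on (N, 2, H, W) tensors.

    The transform is unitary, so the backward pass is the inverse
    transform applied to the gradient.
    """
    comp = t.data[:, 0].astype(np.complex64) + 1j * t.data[:, 1]
    out = _to_channels(fft2c(comp))

    def backward(grad):
        g = grad[:, 0].astype(np.complex64) + 1j * grad[:, 1]
        t._accumulate(_to_channels(ifft2c(g)))

    return Tensor._make(out, (t,), backward)


def _ifft_op(t: Tensor) -> Tensor:
    comp = t.data[:, 0].astype(np.complex64) + 1j * t.data[:, 1]
    out = _to_channels(ifft2c(comp))

    def backward(grad):
        g = grad[:, 0].astype(np.complex64) + 1j * grad[:, 1]
        t._accumulate(_to_channels(fft2c(g)))

    return Tensor._make(out, (t,), backward)


def _cmul(a: Tensor, b: Tensor) -> Tensor:
    ar, ai = a[:, 0:1], a[:, 1:2]
    br, bi = b[:, 0:1], b[:, 1:2]
    return nn.concat([ar * br - ai * bi, ar * bi + ai * br], axis=1)


def _cconj(a: Tensor) -> Tensor:
    return nn.concat([a[:, 0:1], (-1.0) * a[:, 1:2]], axis=1)


class _Regularizer(nn.Module):
    """Image-space CNN on the sensitivity-combined complex image.

    Zero-initialized output layer: an untrained cascade reduces to pure
    data consistency.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        c = channels
        self.body = nn.Sequential(
            nn.Conv2d(2, c, 3, rng, padding=1), nn.LeakyReLU(),
            nn.Conv2d(c, c, 3, rng, padding=1), nn.LeakyReLU(),
            nn.Conv2d(c, 2, 3, rng, padding=1, zero_init=True),
        )

    def forward(self, x):
        return self.body(x)


class _SensRefiner(nn.Module):
    """Refines classical calibration-region maps, one coil per batch row."""

    def __init__(self, channels: int, rng: np.random.Generator):
        c = channels
        self.body = nn.Sequential(
            nn.Conv2d(2, c, 3, rng, padding=1), nn.LeakyReLU(),
            nn.Conv2d(c, 2, 3, rng, padding=1, zero_init=True),
        )

    def forward(self, s):
        return s + self.body(s)


@dataclass
class ReconTrainConfig:
    cascades: int = 4
    channels: int = 16
    sens_channels: int = 8
    learning_rate: float = 1e-3
    epochs: int = 1000
    batches_per_epoch: int = 200
    seed: int = 0
    augmentation: Optional[AugmentationConfig] = None


@dataclass
class ReconModel:
    regularizers: list
    sens_refiner: nn.Module
    dc_weights: list
    calib_width: int = 26
    trained: bool = False
    loss_history: list = field(default_factory=list)

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for reg in self.regularizers:
            params.extend(reg.parameters())
        params.extend(self.sens_refiner.parameters())
        params.extend(self.dc_weights)
        return params


def build_recon_model(config: ReconTrainConfig | None = None,
                      calib_width: int = 26) -> ReconModel:
    config = config or ReconTrainConfig()
    seeds = np.random.SeedSequence(config.seed).spawn(config.cascades + 1)
    regs = [_Regularizer(config.channels, np.random.default_rng(s)) for s in seeds[:-1]]
    sens = _SensRefiner(config.sens_channels, np.random.default_rng(seeds[-1]))
    dc = [Tensor(np.ones(1), requires_grad=True) for _ in range(config.cascades)]
    return ReconModel(regs, sens, dc, calib_width=calib_width)


def _forward(model: ReconModel, masked_kspace: np.ndarray,
             mask: UndersamplingMask) -> Tensor:
    """Unrolled reconstruction of one slice; returns the magnitude Tensor."""
    n_coils, n_ky, n_kx = masked_kspace.shape
    calib = min(model.calib_width, n_ky)
    csm0 = estimate_csm(MultiCoilKSpace(masked_kspace), calib_lines=max(calib, 8))
    sens = model.sens_refiner(Tensor(_to_channels(csm0.data)))
    # RSS-normalize the refined maps so coil combination stays well-scaled
    norm = (sens * sens).sum(axis=(0, 1), keepdims=True).sqrt() + 1e-6
    sens = sens / norm

    mask_t = Tensor(mask.lines.astype(np.float32)[None, None, :, None])
    k0 = Tensor(_to_channels(masked_kspace))
    k = k0
    for reg, w in zip(model.regularizers, model.dc_weights):
        images = _ifft_op(k)
        combined = _cmul(_cconj(sens), images).sum(axis=0, keepdims=True)
        correction = reg(combined)
        expanded = _cmul(sens, correction)
        k_reg = _fft_op(expanded)
        dc = mask_t * (k - k0) * w.reshape(1, 1, 1, 1)
        k = k - dc - k_reg
    images = _ifft_op(k)
    return ((images * images).sum(axis=(0, 1)) + 1e-12).sqrt()


def reconstruct(model: ReconModel, undersampled, mask: UndersamplingMask) -> MagnitudeImage:
    """Deterministic magnitude reconstruction of one undersampled slice."""
    data = undersampled.data if isinstance(undersampled, MultiCoilKSpace) else np.asarray(undersampled)
    out = _forward(model, data, mask)
    return MagnitudeImage(np.maximum(out.data.astype(np.float64), 0.0))


def zero_filled(undersampled, mask: Optional[UndersamplingMask] = None) -> MagnitudeImage:
    """RSS of the inverse transform with unsampled lines left at zero."""
    data = undersampled.data if isinstance(undersampled, MultiCoilKSpace) else np.asarray(undersampled)
    if mask is not None:
        data = data * mask.lines[:, None]
    return MagnitudeImage(rss_combine(ifft2c(data)))


def train_recon(
    sampler: Callable[[np.random.Generator], tuple],
    mask: UndersamplingMask,
    config: ReconTrainConfig | None = None,
    model: ReconModel | None = None,
) -> ReconModel:
    """Train the variational network on fully sampled slices from ``sampler``.

    Per step: draw a (raw k-space, RSS ground truth) sample, optionally
    augment it, retrospectively undersample with ``mask``, run the unrolled
    network and minimize ``1 - mSSIM`` against the ground truth. A schedule
    of 0 epochs returns the initialized model untouched.
    """
    config = config or ReconTrainConfig()
    if model is None:
        model = build_recon_model(config, calib_width=mask.calib_width)
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    data_rng = np.random.default_rng(seeds[0])
    aug_rng = np.random.default_rng(seeds[1])
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)

    total_steps = config.epochs * config.batches_per_epoch
    for step in range(total_steps):
        sample = sampler(data_rng)
        kspace, gt = sample[0], sample[1]
        if config.augmentation is not None:
            kspace, gt = augment(kspace, gt, config.augmentation, aug_rng)
        masked = apply_undersampling(kspace, mask)
        gt_data = gt.data if isinstance(gt, MagnitudeImage) else np.asarray(gt)
        out = _forward(model, masked.data, mask)
        loss = 1.0 - F.ssim(out, Tensor(gt_data.astype(np.float32)),
                            data_range=float(gt_data.max()))
        if not np.isfinite(loss.data):
            raise RuntimeError(f"NaN/Inf reconstruction loss at step {step}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        model.loss_history.append(float(loss.data))
    if total_steps > 0:
        model.trained = True
    return model
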