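"""Loss functions and differentiable image operations."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "l1_loss",
    "mse_loss",
    "gan_discriminator_loss",
    "gan_generator_loss",
    "ssim",
    "gaussian_kernel_2d",
]


def l1_loss(pred: Tensor, target: Tensor) -> Tensor:
    return (pred - target).abs().mean()


def mse_loss(pred: Tensor, target: Tensor) -> Tensor:
    return (pred - target).pow(2).mean()


def gan_discriminator_loss(real_logits: Tensor, fake_logits: Tensor) -> Tensor:
    """Non-saturating GAN: -log sigmoid(real) - log(1 - sigmoid(fake))."""
    return (-real_logits).softplus().mean() + fake_logits.softplus().mean()


def gan_generator_loss(fake_logits: Tensor) -> Tensor:
    """Generator side of the non-saturating loss: -log sigmoid(fake)."""
    return (-fake_logits).softplus().mean()


def gaussian_kernel_2d(win_size: int = 11, sigma: float = 1.5) -> np.ndarray:
    """Normalized truncated Gaussian window (the standard SSIM window)."""
    r = win_size // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2 * sigma**2))
    g /= g.sum()
    return np.outer(g, g)


def ssim(x: Tensor, y: Tensor, data_range: float, win_size: int = 11,
         sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03) -> Tensor:
    """Differentiable mean SSIM between two 2D images (Tensors, H x W).

    Gaussian-weighted local statistics on valid windows only, matching the
    standard SSIM definition used by the evaluation module.
    """
    h, w = x.shape
    if win_size > h or win_size > w:
        raise ValueError("SSIM window larger than the image")
    kernel = Tensor(gaussian_kernel_2d(win_size, sigma)[None, None])
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2

    def filt(t: Tensor) -> Tensor:
        return t.reshape(1, 1, h, w).conv2d(kernel)

    ux = filt(x)
    uy = filt(y)
    uxx = filt(x * x)
    uyy = filt(y * y)
    uxy = filt(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    num = (2.0 * ux * uy + c1) * (2.0 * vxy + c2)
    den = (ux * ux + uy * uy + c1) * (vx + vy + c2)
    return (num / den).mean()
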