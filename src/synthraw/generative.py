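"""Bi-directional conditional adversarial auto-encoders for map synthesis.

One AAE learns to represent complex phase maps, another coil sensitivity
maps, conditioned on the magnitude image. The encoder compresses a
(magnitude, map) pair into a short Gaussian latent code (default length 4);
the decoder reconstructs the map from (magnitude, latent). A discriminator
acting on the latent space pushes encoded codes toward N(0, I) — its
gradient reaches only the encoder, never the decoder output, so no
image-space adversarial artifacts can arise. A reverse path decodes random
latents and penalizes the re-encoding error, enforcing a one-to-one
latent <-> map relationship that keeps sampled maps diverse.

The AAE operates at a reduced resolution (default: fourfold downsampling,
320 -> 80 at full scale); a conditional super-resolution network restores
the native grid using the high-resolution magnitude image as guidance.

Complex maps are handled as stacked (Re, Im) channel pairs: a phase map is
2 real channels, a 16-coil sensitivity map 32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_data import MagnitudeImage
from . import nn
from .nn import functional as F

__all__ = [
    "LatentVector",
    "AAEModel",
    "SuperResModel",
    "AAETrainConfig",
    "downsample_map",
    "encode",
    "decode",
    "regenerate",
    "train_aae",
    "sample_map",
    "train_superres",
    "complex_to_channels",
    "channels_to_complex",
]

DEFAULT_LATENT_DIM = 4
DEFAULT_DOWNSAMPLE = 4
DEFAULT_LOWRES = 80  # 320 / 4 at full acquisition scale


@dataclass
class LatentVector:
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("latent vector must be finite")

    def __len__(self) -> int:
        return self.values.size


def complex_to_channels(maps: np.ndarray) -> np.ndarray:
    """(C, H, W) complex -> (2C, H, W) float32 as interleaved (Re, Im)."""
    maps = np.asarray(maps)
    if maps.ndim == 2:
        maps = maps[None]
    out = np.empty((2 * maps.shape[0],) + maps.shape[1:], dtype=np.float32)
    out[0::2] = maps.real
    out[1::2] = maps.imag
    return out


def channels_to_complex(channels: np.ndarray) -> np.ndarray:
    """(2C, H, W) float -> (C, H, W) complex128."""
    channels = np.asarray(channels)
    if channels.shape[0] % 2:
        raise ValueError("channel count must be even (Re, Im pairs)")
    return channels[0::2].astype(np.float64) + 1j * channels[1::2].astype(np.float64)


def downsample_map(maps: np.ndarray, factor: int = DEFAULT_DOWNSAMPLE) -> np.ndarray:
    """Anti-aliased reduction by block-averaging (real and imaginary parts).

    A 320 grid becomes 80 at the default factor. Works on (H, W) or
    (C, H, W) arrays, real or complex.
    """
    maps = np.asarray(maps)
    h, w = maps.shape[-2:]
    if h % factor or w % factor:
        raise ValueError(f"grid {h}x{w} not divisible by factor {factor}")
    shape = maps.shape[:-2] + (h // factor, factor, w // factor, factor)
    return maps.reshape(shape).mean(axis=(-3, -1))


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


class _Encoder(nn.Module):
    def __init__(self, in_channels: int, latent_dim: int, resolution: int,
                 base: int, rng: np.random.Generator):
        c = base
        self.body = nn.Sequential(
            nn.Conv2d(in_channels, c, 3, rng, stride=2, padding=1), nn.LeakyReLU(),
            nn.Conv2d(c, 2 * c, 3, rng, stride=2, padding=1), nn.LeakyReLU(),
            nn.Conv2d(2 * c, 2 * c, 3, rng, stride=2, padding=1), nn.LeakyReLU(),
            nn.Flatten(),
        )
        feat = 2 * c * (resolution // 8) ** 2
        self.head = nn.Linear(feat, latent_dim, rng)

    def forward(self, x):
        return self.head(self.body(x))


class _Decoder(nn.Module):
    """Magnitude-conditioned decoder; the latent is broadcast-concatenated
    at the bottleneck."""

    def __init__(self, out_channels: int, latent_dim: int, resolution: int,
                 base: int, rng: np.random.Generator):
        c = base
        self.latent_dim = latent_dim
        self.bottleneck_hw = resolution // 8
        self.mag_branch = nn.Sequential(
            nn.Conv2d(1, c, 3, rng, stride=2, padding=1), nn.LeakyReLU(),
            nn.Conv2d(c, 2 * c, 3, rng, stride=2, padding=1), nn.LeakyReLU(),
            nn.Conv2d(2 * c, 2 * c, 3, rng, stride=2, padding=1), nn.LeakyReLU(),
        )
        self.fuse = nn.Sequential(
            nn.Conv2d(2 * c + latent_dim, 2 * c, 3, rng, padding=1), nn.LeakyReLU(),
        )
        self.up = nn.Sequential(
            nn.UpsampleNearest(2), nn.Conv2d(2 * c, 2 * c, 3, rng, padding=1), nn.LeakyReLU(),
            nn.UpsampleNearest(2), nn.Conv2d(2 * c, c, 3, rng, padding=1), nn.LeakyReLU(),
            nn.UpsampleNearest(2), nn.Conv2d(c, c, 3, rng, padding=1), nn.LeakyReLU(),
        )
        self.head = nn.Conv2d(c, out_channels, 3, rng, padding=1)

    def forward(self, magnitude, z):
        feat = self.mag_branch(magnitude)
        n = feat.shape[0]
        hw = self.bottleneck_hw
        z_map = z.reshape(n, self.latent_dim, 1, 1) * nn.Tensor(
            np.ones((1, 1, hw, hw), dtype=np.float32)
        )
        fused = self.fuse(nn.concat([feat, z_map], axis=1))
        return self.head(self.up(fused))


class _LatentDiscriminator(nn.Module):
    def __init__(self, latent_dim: int, rng: np.random.Generator, width: int = 64):
        self.body = nn.Sequential(
            nn.Linear(latent_dim, width, rng), nn.LeakyReLU(),
            nn.Linear(width, width, rng), nn.LeakyReLU(),
            nn.Linear(width, 1, rng),
        )

    def forward(self, z):
        return self.body(z)


@dataclass
class AAETrainConfig:
    """Training settings for one adversarial auto-encoder.

    Loss weights: map reconstruction (L1), adversarial push of the latent
    marginals toward N(0,1) (non-saturating GAN on the latent only), and
    reverse latent consistency (L2 on re-encoded random latents).
    """

    latent_dim: int = DEFAULT_LATENT_DIM
    base_channels: int = 16
    w_reconstruction: float = 1.0
    w_adversarial: float = 0.05
    w_reverse: float = 0.5
    learning_rate: float = 1e-3
    steps: int = 500
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        for w in (self.w_reconstruction, self.w_adversarial, self.w_reverse):
            if w < 0:
                raise ValueError("loss weights must be >= 0")


@dataclass
class AAEModel:
    """Trained (or initialized) conditional AAE for one map type."""

    encoder: nn.Module
    decoder: nn.Module
    latent_discriminator: nn.Module
    target: str  # "phase" | "csm"
    map_channels: int  # complex channels: 1 for phase, coil count for csm
    latent_dim: int = DEFAULT_LATENT_DIM
    operating_resolution: int = DEFAULT_LOWRES
    trained: bool = False
    loss_history: dict = field(default_factory=dict)

    @property
    def output_channels(self) -> int:
        """Real network channels: 2 per complex map channel (Re + Im)."""
        return 2 * self.map_channels


def build_aae(
    target: str,
    map_channels: int,
    config: AAETrainConfig | None = None,
    operating_resolution: int = DEFAULT_LOWRES,
) -> AAEModel:
    """Construct an initialized AAE; weights are seeded from the config."""
    config = config or AAETrainConfig()
    if operating_resolution % 8:
        raise ValueError("operating resolution must be divisible by 8")
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    out_ch = 2 * map_channels
    encoder = _Encoder(1 + out_ch, config.latent_dim, operating_resolution,
                       config.base_channels, np.random.default_rng(seeds[0]))
    decoder = _Decoder(out_ch, config.latent_dim, operating_resolution,
                       config.base_channels, np.random.default_rng(seeds[1]))
    disc = _LatentDiscriminator(config.latent_dim, np.random.default_rng(seeds[2]))
    return AAEModel(encoder, decoder, disc, target, map_channels,
                    config.latent_dim, operating_resolution)


def _as_lowres_batch(model: AAEModel, magnitude, maps=None):
    mag = magnitude.data if isinstance(magnitude, MagnitudeImage) else np.asarray(magnitude)
    r = model.operating_resolution
    if mag.shape != (r, r):
        raise ValueError(
            f"magnitude must be at the operating resolution {r}x{r}, got {mag.shape}"
        )
    mag_t = nn.Tensor(mag[None, None])
    if maps is None:
        return mag_t
    ch = complex_to_channels(maps) if np.iscomplexobj(maps) else np.asarray(maps, np.float32)
    if ch.shape != (model.output_channels, r, r):
        raise ValueError(
            f"map must have {model.output_channels} real channels at {r}x{r}, got {ch.shape}"
        )
    return mag_t, nn.Tensor(ch[None])


def encode(model: AAEModel, magnitude, maps) -> LatentVector:
    """Encode a (magnitude, map) pair at operating resolution into a latent."""
    mag_t, map_t = _as_lowres_batch(model, magnitude, maps)
    z = model.encoder(nn.concat([mag_t, map_t], axis=1))
    return LatentVector(z.data[0])


def decode(model: AAEModel, magnitude, z) -> np.ndarray:
    """Decode (magnitude, latent) into a complex map stack (C, H, W)."""
    values = z.values if isinstance(z, LatentVector) else np.asarray(z, dtype=np.float64)
    if values.size != model.latent_dim:
        raise ValueError(f"latent length {values.size} != latent_dim {model.latent_dim}")
    mag_t = _as_lowres_batch(model, magnitude)
    z_t = nn.Tensor(values.astype(np.float32)[None])
    out = model.decoder(mag_t, z_t)
    return channels_to_complex(out.data[0])


def regenerate(model: AAEModel, magnitude, ground_truth_map) -> tuple[np.ndarray, float]:
    """Full auto-encode of a ground-truth map; returns (map, relative L2)."""
    if not model.trained:
        raise ValueError("regenerate requires a trained model")
    z = encode(model, magnitude, ground_truth_map)
    out = decode(model, magnitude, z)
    gt = np.asarray(ground_truth_map)
    if gt.ndim == 2:
        gt = gt[None]
    rel_l2 = float(np.linalg.norm(out - gt) / max(np.linalg.norm(gt), 1e-12))
    return out, rel_l2


def train_aae(
    dataset: list[tuple],
    config: AAETrainConfig | None = None,
    model: AAEModel | None = None,
    target: str = "phase",
) -> AAEModel:
    """Train the bi-directional conditional AAE.

    ``dataset`` holds (magnitude, complex map) pairs already at the
    operating resolution. Three losses are optimized jointly: L1 map
    reconstruction, the latent-space adversarial loss (discriminator
    gradients reach the encoder only), and the reverse-path latent
    consistency ``encode(decode(z)) ~ z`` for z ~ N(0, I).
    """
    if len(dataset) < 2:
        raise ValueError("train_aae needs at least 2 training pairs")
    config = config or AAETrainConfig()

    first_map = np.asarray(dataset[0][1])
    map_channels = 1 if first_map.ndim == 2 else first_map.shape[0]
    mag0 = dataset[0][0]
    mag0 = mag0.data if isinstance(mag0, MagnitudeImage) else np.asarray(mag0)
    resolution = mag0.shape[0]
    if model is None:
        model = build_aae(target, map_channels, config, operating_resolution=resolution)

    mags = np.stack([
        (m.data if isinstance(m, MagnitudeImage) else np.asarray(m)).astype(np.float32)
        for m, _ in dataset
    ])[:, None]
    maps = np.stack([complex_to_channels(x) for _, x in dataset])

    history = {"reconstruction": [], "adversarial": [], "reverse": [], "discriminator": []}
    model.loss_history = history

    if config.w_reconstruction == config.w_adversarial == config.w_reverse == 0:
        model.trained = True  # vacuous training: nothing to optimize
        return model

    seeds = np.random.SeedSequence(config.seed).spawn(2)
    order_rng = np.random.default_rng(seeds[0])
    latent_rng = np.random.default_rng(seeds[1])

    gen_params = model.encoder.parameters() + model.decoder.parameters()
    disc_params = model.latent_discriminator.parameters()
    opt_gen = nn.Adam(gen_params, lr=config.learning_rate)
    opt_disc = nn.Adam(disc_params, lr=config.learning_rate)

    n = len(dataset)
    for step in range(config.steps):
        idx = order_rng.integers(n, size=config.batch_size)
        mag_t = nn.Tensor(mags[idx])
        map_t = nn.Tensor(maps[idx])

        # forward path
        z = model.encoder(nn.concat([mag_t, map_t], axis=1))
        recon = model.decoder(mag_t, z)
        loss_rec = F.l1_loss(recon, map_t)

        # adversarial path (generator side): gradient reaches the encoder only
        loss_adv = F.gan_generator_loss(model.latent_discriminator(z))

        # reverse path: decode a random latent, re-encode, match
        z_rand = nn.Tensor(
            latent_rng.standard_normal((config.batch_size, config.latent_dim)).astype(np.float32)
        )
        decoded = model.decoder(mag_t, z_rand)
        z_back = model.encoder(nn.concat([mag_t, decoded], axis=1))
        loss_rev = F.mse_loss(z_back, z_rand)

        total = (
            config.w_reconstruction * loss_rec
            + config.w_adversarial * loss_adv
            + config.w_reverse * loss_rev
        )
        if not np.isfinite(total.data):
            raise RuntimeError(
                f"NaN/Inf loss at step {step}: rec={loss_rec.data}, "
                f"adv={loss_adv.data}, rev={loss_rev.data}"
            )
        opt_gen.zero_grad()
        opt_disc.zero_grad()
        total.backward()
        opt_gen.step()

        # discriminator update on detached latents
        if config.w_adversarial > 0:
            z_detached = nn.Tensor(z.data)
            z_prior = nn.Tensor(
                latent_rng.standard_normal((config.batch_size, config.latent_dim)).astype(
                    np.float32
                )
            )
            d_loss = F.gan_discriminator_loss(
                model.latent_discriminator(z_prior), model.latent_discriminator(z_detached)
            )
            opt_disc.zero_grad()
            d_loss.backward()
            opt_disc.step()
            history["discriminator"].append(float(d_loss.data))

        history["reconstruction"].append(float(loss_rec.data))
        history["adversarial"].append(float(loss_adv.data))
        history["reverse"].append(float(loss_rev.data))

    model.trained = True
    return model


# ---------------------------------------------------------------------------
# Super-resolution
# ---------------------------------------------------------------------------


class _SRNet(nn.Module):
    """Residual refinement of a bilinearly upsampled map, guided by the
    high-resolution magnitude. The final layer is zero-initialized so the
    untrained network reproduces plain bilinear upsampling."""

    def __init__(self, map_channels_real: int, base: int, rng: np.random.Generator):
        c = base
        self.body = nn.Sequential(
            nn.Conv2d(map_channels_real + 1, c, 3, rng, padding=1), nn.LeakyReLU(),
            nn.Conv2d(c, c, 3, rng, padding=1), nn.LeakyReLU(),
            nn.Conv2d(c, map_channels_real, 3, rng, padding=1, zero_init=True),
        )

    def forward(self, upsampled, magnitude):
        return upsampled + self.body(nn.concat([upsampled, magnitude], axis=1))


@dataclass
class SuperResModel:
    """Conditional upsampler restoring the native grid from the low-res map."""

    net: nn.Module
    map_channels: int
    scale_factor: int = DEFAULT_DOWNSAMPLE
    trained: bool = False
    loss_history: list = field(default_factory=list)


def build_superres(map_channels: int, scale_factor: int = DEFAULT_DOWNSAMPLE,
                   base_channels: int = 16, seed: int = 0) -> SuperResModel:
    rng = np.random.default_rng(seed)
    return SuperResModel(_SRNet(2 * map_channels, base_channels, rng),
                         map_channels, scale_factor)


def _bilinear_upsample(channels: np.ndarray, factor: int) -> np.ndarray:
    """Order-1 interpolation of each channel (the non-learned baseline)."""
    return np.stack([
        ndimage.zoom(ch, factor, order=1, mode="nearest", grid_mode=True)
        for ch in channels
    ]).astype(np.float32)


def apply_superres(sr: SuperResModel, lowres_map: np.ndarray, magnitude) -> np.ndarray:
    """Upsample a low-res complex map to the magnitude's grid."""
    mag = magnitude.data if isinstance(magnitude, MagnitudeImage) else np.asarray(magnitude)
    ch = complex_to_channels(lowres_map)
    up = _bilinear_upsample(ch, sr.scale_factor)
    if up.shape[1:] != mag.shape:
        raise ValueError(
            f"scale mismatch: upsampled grid {up.shape[1:]} vs magnitude {mag.shape}"
        )
    out = sr.net(nn.Tensor(up[None]), nn.Tensor(mag.astype(np.float32)[None, None]))
    return channels_to_complex(out.data[0])


def train_superres(
    triples: list[tuple],
    scale_factor: int = DEFAULT_DOWNSAMPLE,
    steps: int = 300,
    batch_size: int = 4,
    learning_rate: float = 5e-4,
    base_channels: int = 16,
    seed: int = 0,
    model: SuperResModel | None = None,
) -> SuperResModel:
    """Train the super-resolution net on (low-res map, magnitude, high-res map).

    Minimizes the L1 distance between the refined upsampled map and the
    ground-truth high-resolution map.
    """
    if not triples:
        raise ValueError("train_superres needs training triples")
    first_low = np.asarray(triples[0][0])
    map_channels = 1 if first_low.ndim == 2 else first_low.shape[0]
    lows, mags, highs = [], [], []
    for low, mag, high in triples:
        low = np.asarray(low)
        high = np.asarray(high)
        mag = mag.data if isinstance(mag, MagnitudeImage) else np.asarray(mag)
        if low.shape[-1] * scale_factor != high.shape[-1] or mag.shape != high.shape[-2:]:
            raise ValueError("scale factor inconsistent with the training pair grids")
        lows.append(_bilinear_upsample(complex_to_channels(low), scale_factor))
        mags.append(mag.astype(np.float32)[None])
        highs.append(complex_to_channels(high))
    lows = np.stack(lows)
    mags = np.stack(mags)
    highs = np.stack(highs)

    if model is None:
        model = build_superres(map_channels, scale_factor, base_channels, seed)
    opt = nn.Adam(model.net.parameters(), lr=learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n = len(triples)
    for step in range(steps):
        idx = rng.integers(n, size=min(batch_size, n))
        out = model.net(nn.Tensor(lows[idx]), nn.Tensor(mags[idx]))
        loss = F.l1_loss(out, nn.Tensor(highs[idx]))
        if not np.isfinite(loss.data):
            raise RuntimeError(f"NaN/Inf super-resolution loss at step {step}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        model.loss_history.append(float(loss.data))
    model.trained = True
    return model


def sample_map(
    model: AAEModel,
    sr: SuperResModel,
    magnitude,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Sample a full-resolution map for a magnitude image.

    Draws z ~ N(0, I), decodes at the operating resolution (conditioning on
    the block-averaged magnitude) and restores the native grid with the
    super-resolution net. Reproducible per seed.
    """
    if not model.trained or not sr.trained:
        raise ValueError("sample_map requires trained AAE and super-resolution models")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mag = magnitude.data if isinstance(magnitude, MagnitudeImage) else np.asarray(magnitude)
    mag_low = downsample_map(mag, sr.scale_factor)
    z = rng.standard_normal(model.latent_dim)
    low = decode(model, mag_low, z)
    return apply_superres(sr, low, mag)
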