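"""Conditional AAE and super-resolution behaviour."""

import numpy as np
import pytest
from scipy import stats

from synthraw import generative, phantoms
from synthraw.generative import (
    AAETrainConfig,
    apply_superres,
    build_aae,
    build_superres,
    channels_to_complex,
    complex_to_channels,
    decode,
    downsample_map,
    encode,
    regenerate,
    sample_map,
    train_aae,
    train_superres,
    _bilinear_upsample,
)


class TestDownsample:
    def test_constant_preserved(self):
        x = np.full((2, 16, 16), 3.0 + 1.0j)
        out = downsample_map(x, 4)
        assert out.shape == (2, 4, 4)
        assert np.allclose(out, 3.0 + 1.0j)

    def test_paper_scale_reduction(self):
        x = np.zeros((320, 320))
        assert downsample_map(x, 4).shape == (80, 80)

    def test_matches_block_loop(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        out = downsample_map(x, 4)
        for i in range(2):
            for j in range(2):
                block = x[4 * i : 4 * i + 4, 4 * j : 4 * j + 4]
                assert np.isclose(out[i, j], block.mean(), rtol=1e-14)

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            downsample_map(np.zeros((10, 10)), 4)


class TestChannelConversion:
    def test_round_trip(self):
        rng = np.random.default_rng(1)
        maps = rng.standard_normal((3, 8, 8)) + 1j * rng.standard_normal((3, 8, 8))
        assert np.allclose(channels_to_complex(complex_to_channels(maps)), maps,
                           rtol=1e-6)

    def test_csm_channel_width(self):
        # 16 complex coil maps <-> 32 real network channels
        maps = np.zeros((16, 8, 8), dtype=complex)
        assert complex_to_channels(maps).shape == (32, 8, 8)


class TestEncodeDecode:
    def test_latent_has_default_length_four(self, phase_aae):
        train_pair = np.zeros((16, 16)), np.ones((16, 16), dtype=complex)
        z = encode(phase_aae["trained"], *train_pair)
        assert len(z) == 4

    def test_encode_deterministic(self, phase_dataset, phase_aae):
        mag, pmap = phase_dataset[0][0]
        z1 = encode(phase_aae["trained"], mag, pmap)
        z2 = encode(phase_aae["trained"], mag, pmap)
        assert np.array_equal(z1.values, z2.values)

    def test_decode_deterministic_and_shaped(self, phase_dataset, phase_aae):
        mag, _ = phase_dataset[0][0]
        z = np.array([0.1, -0.2, 0.3, 0.4])
        a = decode(phase_aae["trained"], mag, z)
        b = decode(phase_aae["trained"], mag, z)
        assert np.array_equal(a, b)
        assert a.shape == (1, 16, 16)

    def test_decoded_maps_differ_for_distant_latents(self, phase_dataset, phase_aae):
        mag, _ = phase_dataset[0][0]
        a = decode(phase_aae["trained"], mag, np.array([1.0, 1.0, 1.0, 1.0]))
        b = decode(phase_aae["trained"], mag, np.array([-1.0, -1.0, -1.0, -1.0]))
        assert np.linalg.norm(a - b) / np.linalg.norm(a) > 1e-3

    def test_latent_length_mismatch_rejected(self, phase_dataset, phase_aae):
        mag, _ = phase_dataset[0][0]
        with pytest.raises(ValueError, match="latent"):
            decode(phase_aae["trained"], mag, np.zeros(7))

    def test_resolution_mismatch_rejected(self, phase_aae):
        with pytest.raises(ValueError, match="resolution"):
            encode(phase_aae["trained"], np.zeros((32, 32)),
                   np.ones((32, 32), dtype=complex))

    def test_csm_decoder_channels(self):
        # a 16-coil sensitivity decoder emits 16 complex maps = 32 channels
        model = build_aae("csm", 16, AAETrainConfig(seed=0), operating_resolution=16)
        assert model.output_channels == 32
        out = decode(model, np.zeros((16, 16)), np.zeros(4))
        assert out.shape == (16, 16, 16)


class TestTrainAAE:
    def test_reconstruction_loss_halves(self, phase_aae):
        h = phase_aae["trained"].loss_history["reconstruction"]
        assert np.mean(h[-10:]) < 0.5 * np.mean(h[:10])

    def test_reverse_consistency_improves(self, phase_aae):
        h = phase_aae["trained"].loss_history["reverse"]
        assert np.mean(h[-10:]) < np.mean(h[:10])

    def test_latents_move_toward_standard_normal(self, phase_dataset, phase_aae):
        train, _ = phase_dataset

        def ks_distance(model):
            zs = np.stack([encode(model, m, p).values for m, p in train])
            return np.mean([
                stats.ks_1samp(zs[:, d], stats.norm.cdf).statistic
                for d in range(zs.shape[1])
            ])

        assert ks_distance(phase_aae["trained"]) < ks_distance(phase_aae["untrained"])

    def test_latent_moments_near_prior(self, phase_dataset, phase_aae):
        train, _ = phase_dataset
        zs = np.stack([encode(phase_aae["trained"], m, p).values for m, p in train])
        assert np.all(np.abs(zs.mean(axis=0)) < 0.5)
        assert np.all((zs.var(axis=0) > 0.4) & (zs.var(axis=0) < 2.5))

    def test_zero_weights_leave_model_untouched(self, phase_dataset):
        train, _ = phase_dataset
        config = AAETrainConfig(steps=5, seed=3, w_reconstruction=0.0,
                                w_adversarial=0.0, w_reverse=0.0)
        model = build_aae("phase", 1, config, operating_resolution=16)
        before = model.encoder.state_vector()
        train_aae(train[:4], config, model=model)
        assert np.array_equal(model.encoder.state_vector(), before)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_aae([], AAETrainConfig())


class TestRegenerate:
    def test_training_set_regeneration_error(self, phase_dataset, phase_aae):
        train, _ = phase_dataset
        errors = [regenerate(phase_aae["trained"], m, p)[1] for m, p in train[:8]]
        assert np.mean(errors) < 0.25

    def test_held_out_regeneration_bounded(self, phase_dataset, phase_aae):
        _, held = phase_dataset
        errors = [regenerate(phase_aae["trained"], m, p)[1] for m, p in held]
        assert np.mean(errors) < 0.6

    def test_training_reduces_regeneration_error(self, phase_dataset, phase_aae):
        _, held = phase_dataset
        untrained = phase_aae["untrained"]

        def raw_regen_error(model, m, p):
            out = decode(model, m, encode(model, m, p))
            gt = p[None] if np.asarray(p).ndim == 2 else p
            return np.linalg.norm(out - gt) / np.linalg.norm(gt)

        err_untrained = np.mean([raw_regen_error(untrained, m, p) for m, p in held])
        err_trained = np.mean([regenerate(phase_aae["trained"], m, p)[1]
                               for m, p in held])
        assert err_trained < err_untrained

    def test_untrained_model_rejected(self, phase_dataset):
        mag, pmap = phase_dataset[0][0]
        model = build_aae("phase", 1, AAETrainConfig(seed=1), operating_resolution=16)
        with pytest.raises(ValueError, match="trained"):
            regenerate(model, mag, pmap)

    def test_output_shape_matches_input(self, phase_dataset, phase_aae):
        mag, pmap = phase_dataset[0][0]
        out, _ = regenerate(phase_aae["trained"], mag, pmap)
        assert out.shape == (1,) + pmap.shape


class TestSampleMap:
    def test_seed_reproducibility_and_diversity(self, spec64, phase_aae, sr_bundle):
        mag = phantoms.make_magnitude(spec64, 21)
        a = sample_map(phase_aae["trained"], sr_bundle["model"], mag, seed=1)
        a2 = sample_map(phase_aae["trained"], sr_bundle["model"], mag, seed=1)
        b = sample_map(phase_aae["trained"], sr_bundle["model"], mag, seed=2)
        assert np.array_equal(a, a2)
        assert np.linalg.norm(a - b) / np.linalg.norm(a) > 1e-3
        assert a.shape == (1, 64, 64)  # full resolution restored

    def test_untrained_models_rejected(self, spec64, phase_aae):
        mag = phantoms.make_magnitude(spec64, 21)
        sr = build_superres(1)
        with pytest.raises(ValueError, match="trained"):
            sample_map(phase_aae["trained"], sr, mag, seed=0)


class TestSuperRes:
    def test_loss_decreases(self, sr_bundle):
        h = sr_bundle["model"].loss_history
        assert np.mean(h[-20:]) < np.mean(h[:20])

    def test_beats_bilinear_on_held_out(self, sr_bundle):
        model = sr_bundle["model"]
        errs, base = [], []
        for low, mag, high in sr_bundle["held"]:
            up = channels_to_complex(_bilinear_upsample(complex_to_channels(low), 4))
            base.append(np.linalg.norm(up - high) / np.linalg.norm(high))
            out = apply_superres(model, low, mag)
            errs.append(np.linalg.norm(out - high) / np.linalg.norm(high))
        assert np.mean(errs) < np.mean(base)

    def test_output_grid_is_scaled(self, sr_bundle):
        low, mag, _ = sr_bundle["train"][0]
        out = apply_superres(sr_bundle["model"], low, mag)
        assert out.shape[-1] == low.shape[-1] * 4

    def test_scale_mismatch_rejected(self, sr_bundle):
        low, _, high = sr_bundle["train"][0]
        with pytest.raises(ValueError, match="scale"):
            train_superres([(low, np.zeros((32, 32)), high)], scale_factor=4, steps=1)
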