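"""Masks, retrospective undersampling, augmentation, variational network."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synthraw import phantoms, reconstruction
from synthraw.core_data import MagnitudeImage, MultiCoilKSpace, ifft2c, rss_combine
from synthraw.evaluation import mae
from synthraw.reconstruction import (
    AugmentationConfig,
    AugmentationParams,
    ReconTrainConfig,
    apply_augmentation_params,
    apply_undersampling,
    augment,
    build_recon_model,
    make_mask,
    reconstruct,
    sample_augmentation,
    train_recon,
    zero_filled,
)


class TestMakeMask:
    def test_paper_scale_calibration_block(self):
        mask = make_mask(320, stride=4, calib_width=26)
        sampled = np.flatnonzero(mask.lines)
        # the central 26 lines form one contiguous fully sampled run
        centre_block = np.arange(160 - 13, 160 + 13)
        assert np.all(mask.lines[centre_block])
        runs = np.split(sampled, np.flatnonzero(np.diff(sampled) > 1) + 1)
        longest = max(runs, key=len)
        assert len(longest) == 26
        assert np.array_equal(longest, centre_block)

    def test_stride_pattern_outside_block(self):
        mask = make_mask(320, stride=4, calib_width=26)
        outside = np.flatnonzero(mask.lines[:140])
        assert np.all(np.diff(outside) == 4)
        assert np.all(outside % 4 == 0)

    def test_sampled_set_is_union_of_stride_and_block(self):
        mask = make_mask(320, stride=4, calib_width=26)
        expected = set(range(0, 320, 4)) | set(range(147, 173))
        assert set(np.flatnonzero(mask.lines)) == expected

    def test_acceleration_between_three_and_four(self):
        mask = make_mask(320, stride=4, calib_width=26)
        assert 3.0 < mask.acceleration < 4.0

    def test_stride_one_samples_everything(self):
        assert np.all(make_mask(64, stride=1, calib_width=16).lines)

    def test_calib_width_bound(self):
        with pytest.raises(ValueError):
            make_mask(20, stride=4, calib_width=26)


class TestApplyUndersampling:
    def test_full_mask_is_identity(self):
        rng = np.random.default_rng(0)
        ks = rng.standard_normal((2, 32, 32)) + 1j * rng.standard_normal((2, 32, 32))
        mask = make_mask(32, stride=1, calib_width=8)
        assert np.array_equal(apply_undersampling(ks, mask).data, ks)

    def test_sampled_lines_verbatim_others_zero(self):
        rng = np.random.default_rng(1)
        ks = rng.standard_normal((2, 32, 32)) + 1j * rng.standard_normal((2, 32, 32))
        mask = make_mask(32, stride=4, calib_width=8)
        out = apply_undersampling(ks, mask).data
        assert np.array_equal(out[:, mask.lines], ks[:, mask.lines])
        assert np.all(out[:, ~mask.lines] == 0)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000), stride=st.integers(1, 6))
    def test_energy_never_increases(self, seed, stride):
        rng = np.random.default_rng(seed)
        ks = rng.standard_normal((2, 32, 32)) + 1j * rng.standard_normal((2, 32, 32))
        mask = make_mask(32, stride=stride, calib_width=8)
        out = apply_undersampling(ks, mask).data
        e_in = np.sum(np.abs(ks) ** 2)
        e_out = np.sum(np.abs(out) ** 2)
        assert e_out <= e_in + 1e-9
        if np.all(mask.lines):
            assert np.isclose(e_out, e_in)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_undersampling(np.zeros((1, 32, 32), dtype=complex),
                                make_mask(64, 4, 8))


@pytest.fixture(scope="module")
def raw_slice(spec64):
    scan, _ = phantoms.make_scan(spec64, 1, seed=17)
    ks = scan.kspace[0]
    gt = MagnitudeImage(rss_combine(ifft2c(ks.data)))
    return ks, gt


class TestAugmentation:
    def test_zero_probability_is_identity(self, raw_slice):
        ks, gt = raw_slice
        config = AugmentationConfig(probability=0.0)
        out_ks, out_gt = augment(ks, gt, config, 0)
        assert np.allclose(out_ks.data, ks.data, atol=1e-12)
        assert np.allclose(out_gt.data, gt.data, atol=1e-12)

    def test_four_quarter_rotations_are_identity(self, raw_slice):
        ks, gt = raw_slice
        params = AugmentationParams(rot90_quarters=1)
        out_ks, out_gt = ks, gt
        for _ in range(4):
            out_ks, out_gt = apply_augmentation_params(out_ks, out_gt, params)
        assert np.allclose(out_ks.data, ks.data, atol=1e-9)
        assert np.allclose(out_gt.data, gt.data, atol=1e-9)

    def test_double_mirror_is_identity(self, raw_slice):
        ks, gt = raw_slice
        params = AugmentationParams(mirror="x")
        once_ks, once_gt = apply_augmentation_params(ks, gt, params)
        twice_ks, twice_gt = apply_augmentation_params(once_ks, once_gt, params)
        assert np.allclose(twice_ks.data, ks.data, atol=1e-9)
        assert np.allclose(twice_gt.data, gt.data, atol=1e-9)

    def test_seeded_draw_reproducible(self):
        config = AugmentationConfig()
        a = sample_augmentation(config, 7)
        b = sample_augmentation(config, 7)
        assert a == b

    def test_discrete_transforms_commute_with_rss(self, raw_slice):
        # RSS(transformed coils) == transform(RSS(coils)) for the exact ops
        ks, _ = raw_slice
        coil_images = ifft2c(ks.data)
        params = AugmentationParams(integer_shift=(3, -5), rot90_quarters=1,
                                    mirror="y")
        rss_before = rss_combine(coil_images)
        out_ks, _ = apply_augmentation_params(
            ks, MagnitudeImage(rss_before), params)
        rss_after = rss_combine(ifft2c(out_ks.data))
        from synthraw.reconstruction import _transform_real

        expected = _transform_real(rss_before, params)
        assert np.allclose(rss_after, expected, atol=1e-9)

    def test_continuous_transforms_preserve_shape(self, raw_slice):
        ks, gt = raw_slice
        params = AugmentationParams(rotation_deg=7.5, zoom=1.05,
                                    subpixel_shift=(2.3, -4.1))
        out_ks, out_gt = apply_augmentation_params(ks, gt, params)
        assert out_ks.data.shape == ks.data.shape
        assert out_gt.data.shape == gt.data.shape
        assert np.all(out_gt.data >= 0)


class TestVariationalNetwork:
    def test_training_loss_decreases(self, recon_bundle):
        h = recon_bundle["model"].loss_history
        assert np.mean(h[-20:]) < np.mean(h[:20])

    def test_beats_zero_filled_on_held_out(self, recon_bundle):
        model, mask = recon_bundle["model"], recon_bundle["mask"]
        mae_net, mae_zf = [], []
        for ks, gt in recon_bundle["held"]:
            masked = apply_undersampling(ks, mask)
            mae_net.append(mae(reconstruct(model, masked, mask), gt))
            mae_zf.append(mae(zero_filled(masked), gt))
        assert np.mean(mae_net) < np.mean(mae_zf)

    def test_zero_epochs_returns_untouched_model(self, recon_bundle):
        mask = recon_bundle["mask"]
        config = ReconTrainConfig(cascades=2, channels=8, epochs=0,
                                  batches_per_epoch=10, seed=0)
        model = build_recon_model(config, calib_width=mask.calib_width)
        before = np.concatenate([p.data.ravel().copy() for p in model.parameters()])

        def sampler(rng):  # pragma: no cover - never called with 0 epochs
            raise AssertionError("sampler must not be called")

        out = train_recon(sampler, mask, config, model=model)
        after = np.concatenate([p.data.ravel() for p in out.parameters()])
        assert np.array_equal(before, after)
        assert not out.trained

    def test_reconstruct_deterministic_nonnegative(self, recon_bundle):
        model, mask = recon_bundle["model"], recon_bundle["mask"]
        ks, _ = recon_bundle["held"][0]
        masked = apply_undersampling(ks, mask)
        a = reconstruct(model, masked, mask)
        b = reconstruct(model, masked, mask)
        assert np.array_equal(a.data, b.data)
        assert np.all(a.data >= 0)
        assert a.data.shape == (64, 64)

    def test_overfit_single_slice_with_full_mask(self):
        spec = phantoms.PhantomSpec(grid_size=32, n_coils=2)
        scan, _ = phantoms.make_scan(spec, 1, seed=2)
        ks = scan.kspace[0]
        gt = MagnitudeImage(rss_combine(ifft2c(ks.data)))
        mask = make_mask(32, stride=1, calib_width=8)
        config = ReconTrainConfig(cascades=2, channels=8, epochs=1,
                                  batches_per_epoch=30, seed=0)
        model = train_recon(lambda rng: (ks, gt), mask, config)
        out = reconstruct(model, ks, mask)
        assert mae(out, gt) < 0.05 * gt.data.mean()
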