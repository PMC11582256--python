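"""Shared fixtures: phantom data and the trained models reused across tests.

The heavier fixtures (AAE, super-resolution, variational-network training
runs) are session-scoped so each smoke training happens once per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

from synthraw import calibration, core_data, generative, phantoms, reconstruction


@pytest.fixture(scope="session")
def spec64():
    return phantoms.PhantomSpec()


@pytest.fixture(scope="session")
def noiseless_scan(spec64):
    """Two noiseless phantom slices with their ground-truth decompositions."""
    return phantoms.make_scan(spec64, 2, seed=1, noiseless=True)


@pytest.fixture(scope="session")
def phase_dataset(spec64):
    """48 low-resolution (magnitude, phase) pairs: 40 train, 8 held out."""
    rng = np.random.default_rng(0)
    pairs = []
    for _ in range(48):
        m = phantoms.make_magnitude(spec64, rng)
        p = phantoms.make_phase(spec64, rng)
        pairs.append(
            (generative.downsample_map(m.data, 4), generative.downsample_map(p.data, 4))
        )
    return pairs[:40], pairs[40:]


@pytest.fixture(scope="session")
def phase_aae(phase_dataset):
    """A 500-step fixed-seed AAE run on 40 phantom slices, with an
    identically initialized untrained copy for before/after comparisons."""
    train, _ = phase_dataset
    config = generative.AAETrainConfig(steps=500, seed=0)
    untrained = generative.build_aae("phase", 1, config, operating_resolution=16)
    trained = generative.build_aae("phase", 1, config, operating_resolution=16)
    trained = generative.train_aae(train, config, model=trained)
    return {"trained": trained, "untrained": untrained, "config": config}


@pytest.fixture(scope="session")
def sr_bundle(spec64):
    """Super-resolution training set from decomposed phantom scans
    (support-edge structure aligned with the magnitude): 20 train, 4 held."""
    rng = np.random.default_rng(0)
    triples = []
    for _ in range(24):
        scan, _ = phantoms.make_scan(spec64, 1, rng, noiseless=True)
        trip = calibration.decompose_scan(scan, calib_lines=26)[0]
        p_unit = trip.phase.unit()
        low = generative.downsample_map(p_unit, 4)
        triples.append((low, trip.magnitude.data, p_unit[None]))
    train, held = triples[:20], triples[20:]
    model = generative.train_superres(train, steps=300, seed=0)
    return {"model": model, "train": train, "held": held}


@pytest.fixture(scope="session")
def recon_bundle(spec64):
    """A 300-step fixed-seed variational-network run: 6 training slices,
    4 held-out slices, fourfold-undersampling mask with calibration block."""
    rng = np.random.default_rng(42)
    slices = []
    for _ in range(10):
        scan, _ = phantoms.make_scan(spec64, 1, rng)
        ks = scan.kspace[0]
        gt = core_data.MagnitudeImage(core_data.rss_combine(core_data.ifft2c(ks.data)))
        slices.append((ks, gt))
    train, held = slices[:6], slices[6:]
    mask = reconstruction.make_mask(64, stride=4, calib_width=16)

    def sampler(rng_, _train=train):
        return _train[int(rng_.integers(len(_train)))]

    config = reconstruction.ReconTrainConfig(
        cascades=4, channels=16, epochs=1, batches_per_epoch=300, seed=0
    )
    model = reconstruction.train_recon(sampler, mask, config)
    return {"model": model, "mask": mask, "train": train, "held": held}
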