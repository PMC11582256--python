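"""Reconstruction metrics, paired testing, model selection, experiment grid.

Metrics are computed per slice and averaged per subject; paired t-tests
pair subjects across experiments. mSSIM uses the standard 11 x 11 Gaussian
window (sigma 1.5), K1 = 0.01, K2 = 0.03, with the dynamic range taken from
the ground-truth volume. No multiple-testing correction is applied to the
significance markers (raw P values are reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, stats

from .core_data import MagnitudeImage

__all__ = [
    "ExperimentResult",
    "PairedTTestResult",
    "GridConfig",
    "mae",
    "rmse",
    "mssim",
    "paired_ttest",
    "select_best_run",
    "summarize_results",
    "run_experiment_grid",
]


def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, MagnitudeImage) else np.asarray(x, dtype=np.float64)


def _check_shapes(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")


def mae(x, y) -> float:
    """Mean absolute error."""
    x, y = _as_array(x), _as_array(y)
    _check_shapes(x, y)
    return float(np.mean(np.abs(x - y)))


def rmse(x, y) -> float:
    """Root mean squared error."""
    x, y = _as_array(x), _as_array(y)
    _check_shapes(x, y)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def mssim(
    x,
    y,
    data_range: Optional[float] = None,
    win_size: int = 11,
    sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Mean structural similarity index over Gaussian-weighted local windows.

    ``data_range`` defaults to the maximum of ``y`` (the reference image);
    pass the ground-truth volume maximum when evaluating volumes. Only
    windows fully inside the image contribute (edge crop of half a window).
    """
    x, y = _as_array(x), _as_array(y)
    _check_shapes(x, y)
    if win_size > min(x.shape):
        raise ValueError("SSIM window larger than the image")
    if data_range is None:
        data_range = float(y.max())

    truncate = (win_size // 2) / sigma  # radius win_size//2 after rounding

    def filt(img):
        return ndimage.gaussian_filter(img, sigma, truncate=truncate)

    ux, uy = filt(x), filt(y)
    uxx, uyy, uxy = filt(x * x), filt(y * y), filt(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    ssim_map = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux * ux + uy * uy + c1) * (vx + vy + c2)
    )
    pad = win_size // 2
    return float(ssim_map[pad:-pad, pad:-pad].mean())


@dataclass
class PairedTTestResult:
    statistic: float
    pvalue: float
    degenerate: bool = False  # zero-variance differences


def paired_ttest(metric_a, metric_b) -> PairedTTestResult:
    """Two-sided paired t-test on per-subject metric differences.

    Zero-variance differences are flagged ``degenerate``: identical vectors
    give statistic 0 / p 1; a constant nonzero shift gives an infinite
    statistic and p = 0 (the limit of the t statistic).
    """
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    # rounding-level variance around a common shift is still degenerate
    if d.std(ddof=1) <= 1e-12 * max(1.0, abs(d.mean())):
        d = np.full_like(d, d.mean())
    if np.all(d == d[0]):
        if d[0] == 0:
            return PairedTTestResult(0.0, 1.0, degenerate=True)
        return PairedTTestResult(float(np.sign(d[0]) * np.inf), 0.0, degenerate=True)
    res = stats.ttest_rel(a, b)
    return PairedTTestResult(float(res.statistic), float(res.pvalue))


@dataclass
class ExperimentResult:
    """Per-subject metrics for one training run of one experiment."""

    run_id: int
    mode: str
    training_scans: int
    use_augmentation: bool
    subject_metrics: dict  # subject id -> {"mae": ..., "rmse": ..., "mssim": ...}
    validation_mssim: float

    def metric_vector(self, name: str) -> np.ndarray:
        return np.array([m[name] for m in self.subject_metrics.values()])

    def mean(self, name: str) -> float:
        return float(self.metric_vector(name).mean())

    def std(self, name: str) -> float:
        return float(self.metric_vector(name).std(ddof=1))


def select_best_run(results: list[ExperimentResult]) -> ExperimentResult:
    """The run with the highest validation mSSIM; ties go to the lowest run id."""
    if not results:
        raise ValueError("no results to select from")
    return max(results, key=lambda r: (r.validation_mssim, -r.run_id))


def summarize_results(results: list[ExperimentResult]) -> dict:
    """Mean +/- sd per (mode, size, augmentation) cell, selected runs and
    paired-test annotations against the first mode listed."""
    cells: dict = {}
    for r in results:
        key = (r.mode, r.training_scans, r.use_augmentation)
        cells.setdefault(key, []).append(r)
    summary = {}
    for key, runs in cells.items():
        best = select_best_run(runs)
        entry = {
            "n_runs": len(runs),
            "selected_run": best.run_id,
            "note": "raw P values; no multiple-testing correction",
        }
        for metric in ("mae", "rmse", "mssim"):
            values = [r.mean(metric) for r in runs]
            entry[metric] = {
                "mean": float(np.mean(values)),
                "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
                "selected": best.mean(metric),
            }
        summary[key] = entry
    # paired tests of every mode against the first mode at matching size/aug
    modes = list(dict.fromkeys(k[0] for k in cells))
    if len(modes) > 1:
        baseline_mode = modes[0]
        for key, runs in cells.items():
            mode, size, aug = key
            base_key = (baseline_mode, size, aug)
            if mode == baseline_mode or base_key not in cells:
                continue
            best = select_best_run(runs)
            base_best = select_best_run(cells[base_key])
            if best.subject_metrics.keys() == base_best.subject_metrics.keys():
                test = paired_ttest(
                    best.metric_vector("mae"), base_best.metric_vector("mae")
                )
                summary[key]["mae_vs_baseline"] = {
                    "statistic": test.statistic,
                    "pvalue": test.pvalue,
                    "degenerate": test.degenerate,
                }
    return summary


# ---------------------------------------------------------------------------
# Experiment grid
# ---------------------------------------------------------------------------

_MODE_SOURCES = {
    "real": None,  # real raw data only, no synthetic pool
    "synthetic": ("synthetic", "synthetic"),
    "real-phase-real-csm": ("real", "real"),
    "real-phase-synth-csm": ("real", "synthetic"),
    "sinusoidal-phase-synth-csm": ("sinusoidal", "synthetic"),
    "synth-phase-real-csm": ("synthetic", "real"),
}


@dataclass
class GridConfig:
    """Desk-scaled experiment grid over data modes, sizes and repetitions.

    ``modes`` entries are a data-source name from: ``real``, ``synthetic``,
    ``real-phase-real-csm``, ``real-phase-synth-csm``,
    ``sinusoidal-phase-synth-csm``, ``synth-phase-real-csm`` — with an
    optional ``+aug`` suffix enabling augmentation. All sizes (scans,
    epochs, network widths, generative training steps) are configurable so
    the full protocol shape runs at any scale.
    """

    phantom_spec: object = None  # PhantomSpec; default built lazily
    modes: list = field(default_factory=lambda: ["real", "synthetic"])
    training_sizes: list = field(default_factory=lambda: [4])
    repetitions: int = 1
    n_val_scans: int = 1
    n_test_scans: int = 2
    slices_per_scan: int = 1
    aae_train_scans: int = 2  # scans whose raw data trains the AAEs
    epochs: int = 1
    batches_per_epoch: int = 20
    cascades: int = 2
    channels: int = 8
    learning_rate: float = 1e-3
    aae_steps: int = 40
    sr_steps: int = 30
    mix_fraction: float = 0.75
    stride: int = 4
    calib_width: Optional[int] = None
    seed: int = 0


def _evaluate_model(model, scans, mask, recon_module):
    """Per-subject slice-averaged MAE/RMSE/mSSIM for a list of scans."""
    metrics = {}
    for sid, scan in enumerate(scans):
        per_slice = {"mae": [], "rmse": [], "mssim": []}
        vol_max = max(float(m.data.max()) for m in scan.magnitude)
        for ks, gt in zip(scan.kspace, scan.magnitude):
            masked = recon_module.apply_undersampling(ks, mask)
            recon = recon_module.reconstruct(model, masked, mask)
            per_slice["mae"].append(mae(recon, gt))
            per_slice["rmse"].append(rmse(recon, gt))
            per_slice["mssim"].append(mssim(recon, gt, data_range=vol_max))
        metrics[sid] = {k: float(np.mean(v)) for k, v in per_slice.items()}
    return metrics


def run_experiment_grid(config: GridConfig) -> dict:
    """Run every (mode x training size x repetition) cell and summarize.

    For each cell a reconstruction network is trained on the configured
    data source, evaluated per test subject, and recorded as an
    :class:`ExperimentResult`. Fully deterministic given ``config.seed``.
    Returns ``{"results": [...], "summary": {...}}``.
    """
    from . import generative, phantoms, reconstruction, synthesis
    from .calibration import decompose_scan
    from .core_data import ifft2c, rss_combine, MagnitudeImage

    spec = config.phantom_spec or phantoms.PhantomSpec(grid_size=32, n_coils=2)
    n = spec.grid_size
    calib_width = config.calib_width or (26 if n >= 64 else 8)
    mask = reconstruction.make_mask(n, stride=config.stride, calib_width=calib_width)

    seeds = np.random.SeedSequence(config.seed).spawn(4)
    data_seed, aae_seed, run_seed_root, sample_seed = seeds

    max_size = max(config.training_sizes)
    train_scans = [
        phantoms.make_scan(spec, config.slices_per_scan,
                           np.random.default_rng(s), split="train")[0]
        for s in data_seed.spawn(max_size)
    ]
    val_scans = [
        phantoms.make_scan(spec, config.slices_per_scan,
                           np.random.default_rng(s), split="validation")[0]
        for s in data_seed.spawn(max_size + config.n_val_scans)[max_size:]
    ]
    test_seeds = data_seed.spawn(max_size + config.n_val_scans + config.n_test_scans)
    test_scans = [
        phantoms.make_scan(spec, config.slices_per_scan,
                           np.random.default_rng(s), split="test")[0]
        for s in test_seeds[max_size + config.n_val_scans:]
    ]

    needs_synth = any(m.split("+")[0] != "real" for m in config.modes)
    calib = min(calib_width, n)
    aae_scans = train_scans[: config.aae_train_scans]
    triplets = []
    for scan in aae_scans:
        triplets.extend(decompose_scan(scan, calib_lines=calib))
    noise_pool = [t.noise_cov for t in triplets]

    phase_bundle = csm_bundle = None
    if needs_synth:
        factor = generative.DEFAULT_DOWNSAMPLE
        lowres = n // factor
        aae_cfg = generative.AAETrainConfig(
            steps=config.aae_steps, seed=int(aae_seed.generate_state(1)[0] % 2**31)
        )
        phase_pairs, csm_pairs, sr_phase, sr_csm = [], [], [], []
        for t in triplets:
            mag_low = generative.downsample_map(t.magnitude.data, factor)
            p_unit = t.phase.unit()
            p_low = generative.downsample_map(p_unit, factor)
            c_low = generative.downsample_map(t.csm.data, factor)
            phase_pairs.append((mag_low, p_low))
            csm_pairs.append((mag_low, c_low))
            sr_phase.append((p_low, t.magnitude.data, p_unit[None]))
            sr_csm.append((c_low, t.magnitude.data, t.csm.data))
        phase_aae = generative.train_aae(phase_pairs, aae_cfg, target="phase")
        csm_aae = generative.train_aae(csm_pairs, aae_cfg, target="csm")
        sr_p = generative.train_superres(sr_phase, steps=config.sr_steps,
                                         seed=aae_cfg.seed)
        sr_c = generative.train_superres(sr_csm, steps=config.sr_steps,
                                         seed=aae_cfg.seed + 1)
        phase_bundle = (phase_aae, sr_p)
        csm_bundle = (csm_aae, sr_c)

    results = []
    run_counter = 0
    for mode in config.modes:
        base_mode, _, suffix = mode.partition("+")
        use_aug = suffix == "aug"
        if base_mode not in _MODE_SOURCES:
            raise ValueError(f"unknown mode {mode!r}")
        for size in config.training_sizes:
            scans = train_scans[:size]
            real_slices = [
                (ks, MagnitudeImage(rss_combine(ifft2c(ks.data))))
                for scan in scans[: config.aae_train_scans] or scans
                for ks in scan.kspace
            ]
            real_pool = synthesis.RealPool(real_slices)
            synth_pool = None
            if _MODE_SOURCES[base_mode] is not None:
                phase_src, csm_src = _MODE_SOURCES[base_mode]
                mags = [m for scan in scans for m in scan.magnitude]
                all_triplets = triplets if len(scans) <= config.aae_train_scans else None
                if phase_src == "real" or csm_src == "real":
                    # real-map ablations need the matching decompositions
                    pool_triplets = []
                    for scan in scans:
                        pool_triplets.extend(decompose_scan(scan, calib_lines=calib))
                    mags = [t.magnitude for t in pool_triplets]
                    all_triplets = pool_triplets
                synth_pool = synthesis.SyntheticPool(
                    magnitude_source=mags,
                    phase_model=phase_bundle,
                    csm_model=csm_bundle,
                    noise_cov_pool=noise_pool,
                    triplets=all_triplets,
                    phase_source=phase_src,
                    csm_source=csm_src,
                )
            mix = 0.0 if synth_pool is None else config.mix_fraction

            def sampler(rng, _synth=synth_pool, _real=real_pool, _mix=mix):
                ks, gt, _ = synthesis.draw_training_sample(_synth, _real, rng, _mix)
                return ks, gt

            for rep in range(config.repetitions):
                rep_seed = int(run_seed_root.generate_state(run_counter + 1)[-1] % 2**31)
                recon_cfg = reconstruction.ReconTrainConfig(
                    cascades=config.cascades,
                    channels=config.channels,
                    learning_rate=config.learning_rate,
                    epochs=config.epochs,
                    batches_per_epoch=config.batches_per_epoch,
                    seed=rep_seed,
                    augmentation=reconstruction.AugmentationConfig() if use_aug else None,
                )
                model = reconstruction.train_recon(sampler, mask, recon_cfg)
                val_metrics = _evaluate_model(model, val_scans, mask, reconstruction)
                val_mssim = float(np.mean([m["mssim"] for m in val_metrics.values()]))
                test_metrics = _evaluate_model(model, test_scans, mask, reconstruction)
                results.append(
                    ExperimentResult(
                        run_id=run_counter,
                        mode=mode,
                        training_scans=size,
                        use_augmentation=use_aug,
                        subject_metrics=test_metrics,
                        validation_mssim=val_mssim,
                    )
                )
                run_counter += 1
    return {"results": results, "summary": summarize_results(results)}
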