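"""Validation studies: the simulation experiments that qualify the pipeline.

These are the package's own benchmark procedures, run by the test suite and
the acceptance script:

* family-wise error control of the RFT voxel-level threshold under the null,
* recovery of the generating repetition model by group Bayesian comparison,
* recovery of the injected effect amplitude by the modulator beta,
* sensitivity: detection of every ground-truth region in a full analysis.

Problem sizes are scaled-down versions of the full design (see each
function): the null study runs at the volume level on a 16 x 16 x 64 grid,
and the recovery studies use 6 objects per block at 250 Hz with the trial
noise scaled by sqrt(6/60) so the per-condition-cell SNR equals the full
60-object design's.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage

from .glm import build_design, fit_glm
from .group import GroupSample, estimate_smoothness, fwe_threshold, one_sample_F
from .montage import Montage, make_default_montage
from .pipeline import StudyResult, analyze_dataset, subject_condition_matrix
from .preprocess import average_by_condition
from .simulate import (EffectSpec, SimulationConfig, default_effects, ground_truth_mask,
                       simulate_subject)
from .volume import FrameInterpolator, ScalpGrid, project_electrodes

FULL_OBJECTS = 60


def scaled_study_config(
    seed: int,
    dynamics: str = "exponential",
    n_objects_per_block: int = 6,
    sampling_rate_hz: float = 250.0,
) -> SimulationConfig:
    """Scaled-down study: fewer trials per cell, coarser sampling.

    Trial noise is scaled by sqrt(n_objects / 60) so each condition-cell mean
    carries the same noise SD as the full design; effects and between-subject
    variability keep their defaults.
    """
    base = SimulationConfig()
    effects = tuple(replace(e, dynamics=dynamics) for e in default_effects())
    return SimulationConfig(
        n_objects_per_block=n_objects_per_block,
        sampling_rate_hz=sampling_rate_hz,
        noise_sd_uv=base.noise_sd_uv * np.sqrt(n_objects_per_block / FULL_OBJECTS),
        effects=effects,
        # no distractor-target events: with few trials per cell, the 800 ms
        # exclusion could otherwise empty a condition cell entirely
        target_rate_range_s=None,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# family-wise error control under the null
# ---------------------------------------------------------------------------

def fwe_null_study(
    n_runs: int = 100,
    seed: int = 0,
    shape: tuple[int, int, int] = (16, 16, 64),
    n_subjects: int = 17,
    kernel_fwhm_vox: float = 3.0,
    alpha: float = 0.05,
) -> dict:
    """Monte-Carlo false-positive rate of the voxel-level RFT threshold.

    Each run draws ``n_subjects`` independent smooth Gaussian null volumes
    (white noise convolved with a Gaussian kernel, generated with padding so
    edges keep full variance), runs the group one-sample F test with
    smoothness estimated from the standardized residuals, and records whether
    any voxel exceeds the FWE threshold at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    sigma = kernel_fwhm_vox / np.sqrt(8.0 * np.log(2.0))
    pad = int(np.ceil(4 * sigma))
    mask = np.ones(shape, dtype=bool)
    hits = 0
    for _ in range(n_runs):
        big = rng.standard_normal((n_subjects,) + tuple(s + 2 * pad for s in shape))
        sm = ndimage.gaussian_filter(big, sigma=(0.0, sigma, sigma, sigma))
        vols = sm[:, pad:pad + shape[0], pad:pad + shape[1], pad:pad + shape[2]]
        x = vols.reshape(n_subjects, -1)
        sample = GroupSample(x, model="null")
        spm = one_sample_F(sample)
        resid = x - x.mean(axis=0, keepdims=True)
        fwhm = estimate_smoothness(resid.reshape((n_subjects,) + shape), mask)
        thr, _ = fwe_threshold(spm.df, fwhm, mask, alpha)
        if np.any(spm.F[np.isfinite(spm.F)] > thr):
            hits += 1
    return {
        "fwe_rate": hits / n_runs,
        "n_runs": n_runs,
        "alpha": alpha,
        "n_voxels": int(np.prod(shape)),
    }


# ---------------------------------------------------------------------------
# model recovery by group Bayesian comparison
# ---------------------------------------------------------------------------

def _effect_voxel_mask(config: SimulationConfig, result: StudyResult) -> np.ndarray:
    gt = ground_truth_mask(
        config, result.grid, result.montage,
        window_ms=(result.frame_times_ms[0], result.frame_times_ms[-1]),
    )
    return gt[result.mask3d]


def model_recovery_study(
    n_datasets: int = 20,
    seed: int = 0,
    dynamics: str = "exponential",
    montage: Montage | None = None,
) -> dict:
    """Fraction of ground-truth effect voxels where the generating model wins.

    Runs ``n_datasets`` independently seeded scaled studies with the given
    ground-truth dynamics and pools, over datasets and effect voxels, the sign
    of the group Delta-LME: exponential truth is scored against both rivals,
    categorical truth against the exponential model. Also records, for the
    exponential arm, the group-mean pooled modulator beta at each effect's
    center voxel (for amplitude-recovery checks).
    """
    montage = montage or make_default_montage()
    wins = {"exp_vs_lin": [], "exp_vs_cdt": [], "cdt_vs_exp": []}
    center_betas = []  # per dataset: list of group-mean betas, one per effect
    n_effect_voxels = 0
    for i in range(n_datasets):
        cfg = scaled_study_config(seed=seed + 1000 * (i + 1), dynamics=dynamics)
        res = analyze_dataset(cfg, montage=montage)
        gtf = _effect_voxel_mask(cfg, res)
        n_effect_voxels += int(gtf.sum())
        d_el = res.deltas[("exponential", "linear")].group_sum
        d_ec = res.deltas[("exponential", "chdet")].group_sum
        if dynamics == "exponential":
            wins["exp_vs_lin"].append(d_el[gtf] > 0)
            wins["exp_vs_cdt"].append(d_ec[gtf] > 0)
        elif dynamics == "categorical":
            wins["cdt_vs_exp"].append(-d_ec[gtf] > 0)
        center_betas.append(
            [res.pooled["exponential"][:, v].mean() for v in _center_voxels(cfg, res)]
        )
    out = {
        "n_datasets": n_datasets,
        "n_effect_voxels": n_effect_voxels,
        "center_betas": np.array(center_betas),
    }
    for key, chunks in wins.items():
        if chunks:
            out[key] = float(np.concatenate(chunks).mean())
    return out


def _center_voxels(config: SimulationConfig, result: StudyResult) -> list[int]:
    """Flat in-mask voxel index of each effect's center (mid-window, center pixel)."""
    xy = project_electrodes(result.montage, result.grid)
    centers = result.grid.pixel_centers_mm
    flat_index = np.full(result.mask3d.shape, -1, dtype=int)
    flat_index[result.mask3d] = np.arange(int(result.mask3d.sum()))
    out = []
    for eff in config.effects:
        cx, cy = xy[result.montage.index(eff.center_channel)]
        ix = int(np.argmin(np.abs(centers - cx)))
        iy = int(np.argmin(np.abs(centers - cy)))
        mid = 0.5 * (eff.window_ms[0] + eff.window_ms[1])
        it = int(np.argmin(np.abs(result.frame_times_ms - mid)))
        v = flat_index[ix, iy, it]
        if v < 0:  # center pixel outside scalp mask: take nearest in-mask pixel
            inmask = np.argwhere(result.mask3d[:, :, it])
            j = np.argmin((inmask[:, 0] - ix) ** 2 + (inmask[:, 1] - iy) ** 2)
            v = flat_index[inmask[j, 0], inmask[j, 1], it]
        out.append(int(v))
    return out


# ---------------------------------------------------------------------------
# amplitude recovery by the modulator beta
# ---------------------------------------------------------------------------

def measurement_chain_beta(
    config: SimulationConfig,
    montage: Montage | None = None,
    grid: ScalpGrid = ScalpGrid(),
    tau: float = 1.0,
) -> np.ndarray:
    """Pooled exponential-modulator betas of subject 0 through the
    averaging -> interpolation -> smoothing -> GLM chain (no filtering or
    re-referencing, so a spatially uniform effect passes through unchanged)."""
    montage = montage or make_default_montage()
    interp = FrameInterpolator(project_electrodes(montage, grid), grid)
    epochs = simulate_subject(config, 0, montage=montage, grid=grid)
    avg = average_by_condition(epochs)
    Y, mask3d, _ = subject_condition_matrix(avg, interp)
    design = build_design("exponential", config.n_blocks, config.n_presentations, tau)
    fit = fit_glm(Y, design, subject=0)
    return fit.betas[design.modulator_columns, :].mean(axis=0)


def broad_flat_effect(amplitude_uv: float = 1.5, tau: float = 1.0) -> EffectSpec:
    """A spatially uniform, temporally flat (20-550 ms) exponential effect.

    Within the analysis window the injected signal is constant over space and
    time, so linear interpolation and mask-normalized smoothing reproduce it
    exactly and the fitted modulator beta must equal the amplitude.
    """
    return EffectSpec(
        "Cz", 1e9, (20.0, 550.0), sign=-1, amplitude_uv=amplitude_uv,
        dynamics="exponential", tau=tau, ramp_ms=0.0,
    )


def amplitude_recovery_noise_free(amplitude_uv: float = 1.5) -> dict:
    """Exact recovery of a noise-free exponential effect by the modulator beta."""
    cfg = SimulationConfig(
        n_subjects=1, n_objects_per_block=2, sampling_rate_hz=250.0,
        noise_sd_uv=0.0, subject_sd_uv=0.0,
        effects=(broad_flat_effect(amplitude_uv),), seed=0,
    )
    betas = measurement_chain_beta(cfg)
    rel_err = float(np.max(np.abs(betas - amplitude_uv)) / amplitude_uv)
    return {"amplitude_uv": amplitude_uv, "max_rel_error": rel_err}


def amplitude_recovery_noisy(
    n_runs: int = 20, seed: int = 0, amplitude_uv: float = 1.5
) -> dict:
    """Group-mean beta under default noise vs. the injected amplitude.

    Each run simulates 17 subjects with the broad-flat effect and
    default-level cell noise (scaled design), averages the pooled beta at
    every in-mask voxel... the statistic reported is the group-and-voxel mean
    beta per run and its relative error against the amplitude.
    """
    base = SimulationConfig()
    means = []
    montage = make_default_montage()
    grid = ScalpGrid()
    interp = FrameInterpolator(project_electrodes(montage, grid), grid)
    design = build_design("exponential", 4, 6, 1.0)
    for i in range(n_runs):
        cfg = SimulationConfig(
            n_subjects=17, n_objects_per_block=2, sampling_rate_hz=250.0,
            noise_sd_uv=base.noise_sd_uv * np.sqrt(2 / FULL_OBJECTS),
            subject_sd_uv=0.0,
            effects=(broad_flat_effect(amplitude_uv),), seed=seed + 500 * (i + 1),
        )
        subj_betas = []
        for sid in range(cfg.n_subjects):
            epochs = simulate_subject(cfg, sid, montage=montage, grid=grid)
            avg = average_by_condition(epochs)
            Y, _, ft = subject_condition_matrix(avg, interp)
            fit = fit_glm(Y, design, subject=sid)
            pooled = fit.betas[design.modulator_columns, :].mean(axis=0)
            subj_betas.append(pooled.mean())
        means.append(np.mean(subj_betas))
    group_mean = float(np.mean(means))
    return {
        "amplitude_uv": amplitude_uv,
        "group_mean_beta": group_mean,
        "rel_error": float(abs(group_mean - amplitude_uv) / amplitude_uv),
        "per_run_rel_error_max": float(np.max(np.abs(np.array(means) - amplitude_uv))
                                       / amplitude_uv),
        "n_runs": n_runs,
    }


# ---------------------------------------------------------------------------
# sensitivity on one full-design dataset
# ---------------------------------------------------------------------------

def region_detection(result: StudyResult, config: SimulationConfig, model: str = "exponential") -> dict:
    """Per ground-truth region: overlap with the model's significant voxels."""
    sig = result.group[model].rft.significant_mask
    out = {}
    for eff in config.effects:
        single = replace(config, effects=(eff,))
        gtm = ground_truth_mask(
            single, result.grid, result.montage,
            window_ms=(result.frame_times_ms[0], result.frame_times_ms[-1]),
        )
        key = f"{eff.center_channel}_{int(eff.window_ms[0])}-{int(eff.window_ms[1])}ms"
        out[key] = bool((sig & gtm).any())
    return out
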