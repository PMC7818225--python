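"""Epoch preprocessing: filter, re-reference, baseline, reject, average.

The single entry point :func:`preprocess` enforces the stage order
(band-pass filter -> common-average re-reference -> baseline correction ->
amplitude-threshold artifact rejection -> per-condition averaging) and
returns the 24 mean ERPs (4 blocks x 6 presentation indices) per subject
that enter the first-level GLM.

The 24 dB/octave band-pass is a 4th-order Butterworth applied zero-phase
(forward-backward) so component latencies are not shifted; epochs are padded
by reflection before filtering. Rejection uses post-filter, post-baseline
values on all EEG *and* EOG channels (threshold +/-75 uV by default).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .simulate import EpochSet


@dataclass(frozen=True)
class PreprocConfig:
    band_hz: tuple[float, float] = (1.0, 30.0)
    filter_order: int = 4  # Butterworth order; 4 => 24 dB/octave single-pass roll-off
    baseline_window_ms: tuple[float, float] = (-100.0, 0.0)
    reject_threshold_uv: float = 75.0
    target_exclusion_ms: float = 800.0
    pad_s: float = 1.0

    def __post_init__(self) -> None:
        if self.band_hz[0] >= self.band_hz[1]:
            raise ValueError("band low edge must be below high edge")
        if self.reject_threshold_uv <= 0:
            raise ValueError("rejection threshold must be positive")


@dataclass
class AverageERPSet:
    """Per-subject mean ERPs: (n_blocks, n_presentations, channels, samples)."""

    means: np.ndarray
    counts: np.ndarray
    times_ms: np.ndarray
    montage: object
    subject: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nb, npres = self.counts.shape
        if self.means.shape[:2] != (nb, npres):
            raise ValueError("means and counts disagree on block/presentation layout")
        if np.any(self.counts < 1):
            raise ValueError("every (block, presentation) cell needs >= 1 trial")

    def cell(self, block: int, presentation: int) -> np.ndarray:
        """Mean ERP of one condition cell (1-based block and presentation)."""
        return self.means[block - 1, presentation - 1]


def _sampling_rate(epochs: EpochSet) -> float:
    return 1000.0 / float(epochs.times_ms[1] - epochs.times_ms[0])


def bandpass_filter(epochs: EpochSet, config: PreprocConfig = PreprocConfig()) -> EpochSet:
    """Zero-phase Butterworth band-pass with reflective padding.

    Raises if the upper band edge reaches the Nyquist frequency.
    """
    fs = _sampling_rate(epochs)
    lo, hi = config.band_hz
    if hi >= fs / 2.0:
        raise ValueError(f"band edge {hi} Hz is at or above Nyquist ({fs / 2.0} Hz)")
    sos = sps.butter(config.filter_order, (lo, hi), btype="bandpass", fs=fs, output="sos")
    pad = int(round(config.pad_s * fs))
    out = np.empty_like(epochs.data)
    chunk = max(1, int(2e7 // (epochs.data.shape[1] * (epochs.data.shape[2] + 2 * pad))))
    for start in range(0, epochs.n_trials, chunk):
        stop = min(start + chunk, epochs.n_trials)
        x = np.pad(
            np.asarray(epochs.data[start:stop], dtype=float),
            ((0, 0), (0, 0), (pad, pad)),
            mode="reflect",
        )
        y = sps.sosfiltfilt(sos, x, axis=-1, padlen=0)  # reflect-padded above
        out[start:stop] = y[:, :, pad:-pad] if pad else y
    return epochs.copy_with(data=out, filtered_band_hz=list(config.band_hz))


def filter_response_db(config: PreprocConfig, freq_hz: float, fs: float) -> float:
    """Analytic zero-phase magnitude response (dB) of the configured filter."""
    sos = sps.butter(config.filter_order, config.band_hz, btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[2.0 * np.pi * freq_hz / fs])
    return float(20.0 * np.log10(np.abs(h[0]) ** 2))  # squared: forward + backward pass


def rereference_common_average(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean over scalp channels from every scalp channel.

    EOG channels are excluded from the average and left untouched.
    """
    n_scalp = epochs.montage.n_scalp
    if n_scalp < 2:
        raise ValueError("common average reference needs >= 2 scalp channels")
    data = np.asarray(epochs.data, dtype=float).copy()
    data[:, :n_scalp, :] -= data[:, :n_scalp, :].mean(axis=1, keepdims=True)
    return epochs.copy_with(data=data, reference="common average (scalp channels)")


def baseline_correct(epochs: EpochSet, window_ms: tuple[float, float] = (-100.0, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    t = epochs.times_ms
    sel = (t >= window_ms[0] - 1e-9) & (t <= window_ms[1] + 1e-9)
    if not sel.any():
        raise ValueError(f"baseline window {window_ms} contains no samples")
    if window_ms[0] < t[0] - 1e-9 or window_ms[1] > t[-1] + 1e-9:
        raise ValueError(f"baseline window {window_ms} outside epoch [{t[0]}, {t[-1]}] ms")
    data = np.asarray(epochs.data, dtype=float).copy()
    data -= data[:, :, sel].mean(axis=2, keepdims=True)
    return epochs.copy_with(data=data, baseline_window_ms=list(window_ms))


def reject_artifacts(
    epochs: EpochSet, threshold_uv: float = 75.0
) -> tuple[EpochSet, np.ndarray]:
    """Drop trials whose absolute value exceeds the threshold on any channel.

    All channels count — EEG and EOG alike. Returns the retained epochs (in
    original order) and the indices of rejected trials.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    peak = np.abs(epochs.data).max(axis=(1, 2))
    rejected = np.flatnonzero(peak > threshold_uv)
    keep = peak <= threshold_uv
    out = epochs.copy_with(
        data=epochs.data[keep],
        trials=epochs.trials.loc[keep],
        rejected_trials=rejected.tolist(),
        reject_threshold_uv=threshold_uv,
        rejection_applied_to="post-filter, post-baseline values",
    )
    return out, rejected


def exclude_near_target(
    epochs: EpochSet, target_onsets_ms, horizon_ms: float = 800.0
) -> EpochSet:
    """Drop trials whose onset falls within (t_target, t_target + horizon].

    Emulates removing stimuli contaminated by the distractor-task response
    window; onsets must share the clock of ``trials.onset_ms``.
    """
    targets = np.asarray(list(target_onsets_ms), dtype=float)
    if targets.size == 0:
        return epochs.copy_with()
    onsets = epochs.trials["onset_ms"].to_numpy(dtype=float)
    diff = onsets[:, None] - targets[None, :]
    drop = ((diff > 0) & (diff <= horizon_ms)).any(axis=1)
    return epochs.copy_with(
        data=epochs.data[~drop],
        trials=epochs.trials.loc[~drop],
        n_excluded_near_target=int(drop.sum()),
    )


def average_by_condition(epochs: EpochSet) -> AverageERPSet:
    """Arithmetic mean per (block, presentation_index) cell.

    Raises, naming the cell, if any cell has no trials.
    """
    blocks = np.sort(epochs.trials["block"].unique())
    n_blocks = int(blocks.max())
    n_pres = int(epochs.trials["presentation"].max())
    n_ch, n_samp = epochs.data.shape[1:]
    means = np.zeros((n_blocks, n_pres, n_ch, n_samp))
    counts = np.zeros((n_blocks, n_pres), dtype=int)
    blk = epochs.trials["block"].to_numpy()
    pres = epochs.trials["presentation"].to_numpy()
    for b in range(1, n_blocks + 1):
        for r in range(1, n_pres + 1):
            sel = (blk == b) & (pres == r)
            if not sel.any():
                raise ValueError(f"no trials in cell (block={b}, presentation={r})")
            means[b - 1, r - 1] = epochs.data[sel].mean(axis=0)
            counts[b - 1, r - 1] = int(sel.sum())
    return AverageERPSet(
        means=means,
        counts=counts,
        times_ms=epochs.times_ms.copy(),
        montage=epochs.montage,
        subject=int(epochs.trials["subject"].iloc[0]),
        meta=dict(epochs.meta),
    )


def preprocess(
    epochs: EpochSet,
    config: PreprocConfig = PreprocConfig(),
    target_onsets_ms=None,
) -> AverageERPSet:
    """Full preprocessing chain for one subject.

    Order: target-window exclusion -> band-pass -> common average ->
    baseline -> amplitude rejection -> condition averaging. Counts of
    excluded and rejected trials are recorded in the output metadata.
    """
    if target_onsets_ms is None:
        target_onsets_ms = epochs.meta.get("target_onsets_ms", [])
    epochs = exclude_near_target(epochs, target_onsets_ms, config.target_exclusion_ms)
    epochs = bandpass_filter(epochs, config)
    epochs = rereference_common_average(epochs)
    epochs = baseline_correct(epochs, config.baseline_window_ms)
    epochs, rejected = reject_artifacts(epochs, config.reject_threshold_uv)
    avg = average_by_condition(epochs)
    avg.meta["n_rejected"] = int(rejected.size)
    avg.meta["preproc"] = {
        "band_hz": list(config.band_hz),
        "filter_order": config.filter_order,
        "baseline_window_ms": list(config.baseline_window_ms),
        "reject_threshold_uv": config.reject_threshold_uv,
        "rejection_applied_to": "post-filter, post-baseline values",
        "target_exclusion_ms": config.target_exclusion_ms,
    }
    return avg
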