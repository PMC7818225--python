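"""Fixed-effects Bayesian model comparison across the rival GLMs.

Per voxel, the difference in BIC log model evidence between two models is
summed over subjects; the sum is the log of the group Bayes factor. Because
all designs share the same parameter count, the group sum equals
sum_s (n/2) ln(RSS_B / RSS_A). Comparisons are summarized within a voxel set
(the conjunction of the per-model significant masks, or the whole volume)
by the distribution statistics of the group sums plus one-sample
Kolmogorov-Smirnov and Wilcoxon signed-rank tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glm import LMEMap


@dataclass
class DeltaLMEMap:
    """Per-subject and group-summed LME differences for an ordered model pair."""

    per_subject: np.ndarray  # (S, V)
    group_sum: np.ndarray  # (V,)
    pair: tuple[str, str]


def delta_lme(lme_a: list[LMEMap], lme_b: list[LMEMap]) -> DeltaLMEMap:
    """lme_A - lme_B per subject plus the group sum (log group Bayes factor)."""
    if len(lme_a) != len(lme_b) or not lme_a:
        raise ValueError("model A and B need the same nonempty subject list")
    for a, b in zip(lme_a, lme_b):
        if a.subject != b.subject:
            raise ValueError(f"subject mismatch: {a.subject} vs {b.subject}")
    per = np.stack([a.lme - b.lme for a, b in zip(lme_a, lme_b)])
    return DeltaLMEMap(
        per_subject=per,
        group_sum=per.sum(axis=0),
        pair=(lme_a[0].model, lme_b[0].model),
    )


def conjunction_mask(significant_masks: list[np.ndarray], mode: str = "all") -> np.ndarray:
    """Combine per-model significance masks: 'all' = intersection, 'any' = union."""
    if not significant_masks:
        raise ValueError("need at least one mask")
    stack = np.stack([np.asarray(m, dtype=bool) for m in significant_masks])
    if any(m.shape != stack[0].shape for m in stack):
        raise ValueError("masks must share one grid")
    if mode == "all":
        return stack.all(axis=0)
    if mode == "any":
        return stack.any(axis=0)
    raise ValueError(f"mode must be 'all' or 'any', got {mode!r}")


def wilcoxon_signed_rank(values) -> tuple[float, float]:
    """Wilcoxon signed-rank test of zero median, normal approximation.

    Zeros are dropped; W is the sum of positive signed ranks (average ranks
    for ties); Z = (W - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 - tie correction),
    with no continuity correction; two-tailed normal p.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v) & (v != 0)]
    if v.size == 0:
        raise ValueError("all values are zero; the signed-rank statistic is undefined")
    if v.size < 5:
        raise ValueError("need at least 5 nonzero values for the normal approximation")
    n = v.size
    ranks = stats.rankdata(np.abs(v))
    W = ranks[v > 0].sum()
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_corr = (counts ** 3 - counts).sum() / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr)
    z = (W - mu) / sigma
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def ks_statistic(values) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov statistic against the standard normal."""
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 values")
    res = stats.kstest(v, "norm")
    return float(res.statistic), float(res.pvalue)


def summarize_comparison(delta: DeltaLMEMap, voxel_set: np.ndarray, label: str = "") -> dict:
    """Distribution summary of the group-summed LME differences in a voxel set."""
    sel = np.asarray(voxel_set, dtype=bool)
    if sel.shape != delta.group_sum.shape:
        raise ValueError("voxel set must match the flat voxel axis")
    if not sel.any():
        raise ValueError("voxel set is empty")
    x = delta.group_sum[sel]
    wz, wp = wilcoxon_signed_rank(x)
    d, kp = ks_statistic(x)
    return {
        "comparison": f"{delta.pair[0].upper()} vs {delta.pair[1].upper()}",
        "voxel_set": label,
        "n_voxels": int(sel.sum()),
        "median": float(np.median(x)),
        "mean": float(np.mean(x)),
        "std": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "pct_gt0": float(100.0 * np.mean(x > 0)),
        "ks_D": d,
        "ks_p": kp,
        "wilcoxon_Z": wz,
        "wilcoxon_p": wp,
    }


def comparison_table(rows: list[dict]) -> pd.DataFrame:
    """Stack summary rows into a table mirroring the standard report layout."""
    cols = [
        "comparison", "voxel_set", "n_voxels", "median", "mean", "std",
        "pct_gt0", "ks_D", "ks_p", "wilcoxon_Z", "wilcoxon_p",
    ]
    return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class EvidenceLabel:
    strength: str
    favors: str  # 'A', 'B', or 'neither'

    def __str__(self) -> str:
        if self.favors == "neither":
            return "no preference"
        return f"{self.strength} evidence in favor of model {self.favors}"


def interpret_evidence(delta_value: float) -> EvidenceLabel:
    """Strength-of-evidence label for a log Bayes factor (natural log scale).

    |dLME| > 5 counts as very strong evidence; 3-5 strong, 1-3 positive,
    0-1 weak; the sign picks the favored model (positive favors A).
    """
    if not np.isfinite(delta_value):
        raise ValueError("delta LME must be finite")
    mag = abs(delta_value)
    if mag == 0:
        return EvidenceLabel("none", "neither")
    if mag > 5:
        strength = "very strong"
    elif mag > 3:
        strength = "strong"
    elif mag > 1:
        strength = "positive"
    else:
        strength = "weak"
    return EvidenceLabel(strength, "A" if delta_value > 0 else "B")
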