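"""First-level GLMs: design matrices with parametric repetition modulators.

For each subject the 24 condition-mean images (6 presentation indices x 4
blocks, block-major) are modeled by a 24 x 8 design: four block indicator
columns plus, for each block, one mean-centered parametric modulator encoding
a hypothesized amplitude trajectory over presentations. Three rival
trajectories are implemented:

  exponential  g(r) = exp(-(r-1)/tau)          (default tau = 1 presentation)
  linear       g(r) = unit-step decreasing ramp (the "null" trajectory)
  chdet        g(r) = 1{r == 1}                 ("change detection")

All three designs share k = 8 columns, so the BIC log-model-evidence
difference between models reduces to a residual-sum-of-squares ratio:
LME = -(n/2) ln(RSS/n) - (k/2) ln(n) with n = 24, k = 8, and the penalty
terms cancel in any between-model difference.

Sign convention: the modulators decrease over presentations, so suppression
of a positive component loads positively on the modulator.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODELS = ("exponential", "linear", "chdet")


@dataclass(frozen=True)
class RepetitionRegressor:
    """A repetition-trajectory regressor: raw g(1..n) and its centered form."""

    model: str
    raw: np.ndarray
    centered: np.ndarray
    tau: float | None = None


def build_modulator(model: str, n_presentations: int = 6, tau: float = 1.0) -> RepetitionRegressor:
    """Mean-centered parametric modulator for one block.

    ``exponential``: exp(-(r-1)/tau); ``linear``: decreasing unit-step ramp
    (n-1, n-2, ..., 0); ``chdet``: first-presentation indicator.
    """
    if n_presentations < 2:
        raise ValueError("need at least 2 presentations")
    r = np.arange(1, n_presentations + 1, dtype=float)
    if model == "exponential":
        if tau <= 0:
            raise ValueError("tau must be positive")
        raw = np.exp(-(r - 1.0) / tau)
    elif model == "linear":
        raw = (n_presentations - r).astype(float)
    elif model == "chdet":
        raw = (r == 1).astype(float)
    else:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    return RepetitionRegressor(
        model=model,
        raw=raw,
        centered=raw - raw.mean(),
        tau=tau if model == "exponential" else None,
    )


@dataclass(frozen=True)
class DesignMatrix:
    """First-level design: (n_blocks * n_presentations) rows x 2*n_blocks columns.

    Rows are block-major (block 1 presentations 1..6, block 2, ...); columns
    are the block indicators followed by the block-specific centered
    modulators (zero outside their block).
    """

    X: np.ndarray
    model: str
    n_blocks: int
    n_presentations: int
    tau: float | None

    @property
    def column_names(self) -> list[str]:
        return [f"block{b}" for b in range(1, self.n_blocks + 1)] + [
            f"mod_{self.model}_block{b}" for b in range(1, self.n_blocks + 1)
        ]

    @property
    def modulator_columns(self) -> slice:
        return slice(self.n_blocks, 2 * self.n_blocks)

    def row_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_product(
            [range(1, self.n_blocks + 1), range(1, self.n_presentations + 1)],
            names=["block", "presentation"],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.row_index(), columns=self.column_names)


def build_design(
    model: str, n_blocks: int = 4, n_presentations: int = 6, tau: float = 1.0
) -> DesignMatrix:
    """Assemble the full-rank first-level design matrix for one model."""
    reg = build_modulator(model, n_presentations, tau)
    n_rows = n_blocks * n_presentations
    X = np.zeros((n_rows, 2 * n_blocks))
    for b in range(n_blocks):
        rows = slice(b * n_presentations, (b + 1) * n_presentations)
        X[rows, b] = 1.0
        X[rows, n_blocks + b] = reg.centered
    if np.linalg.matrix_rank(X) != 2 * n_blocks:
        raise ValueError("design matrix is rank deficient")
    return DesignMatrix(
        X=X, model=model, n_blocks=n_blocks, n_presentations=n_presentations, tau=reg.tau
    )


@dataclass
class GLMFit:
    """Voxelwise OLS fit: betas (k, V), residual sum of squares (V,)."""

    betas: np.ndarray
    rss: np.ndarray
    n: int
    k: int
    model: str
    subject: int | None = None
    design: DesignMatrix | None = None


@dataclass
class LMEMap:
    """Per-voxel BIC-approximated log model evidence for one subject/model."""

    lme: np.ndarray
    model: str
    subject: int | None = None
    n_undefined: int = 0


def fit_glm(Y: np.ndarray, design: DesignMatrix, subject: int | None = None) -> GLMFit:
    """Ordinary least squares per voxel.

    ``Y`` is (n_images, V); rows must follow the design's block-major
    (block, presentation) order. Raises on NaNs in Y or a rank-deficient
    design.
    """
    X = design.X
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != X.shape[0]:
        raise ValueError(f"Y has {Y.shape[0]} rows, design expects {X.shape[0]}")
    if np.isnan(Y).any():
        raise ValueError("Y contains NaN; restrict to in-mask voxels first")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    betas = np.linalg.pinv(X) @ Y  # X is tiny and well-conditioned; V is large
    resid = Y - X @ betas
    rss = np.einsum("ij,ij->j", resid, resid)
    return GLMFit(
        betas=betas, rss=rss, n=X.shape[0], k=X.shape[1],
        model=design.model, subject=subject, design=design,
    )


def compute_lme(fit: GLMFit) -> LMEMap:
    """BIC log model evidence: -(n/2) ln(RSS/n) - (k/2) ln(n), natural log.

    Voxels with RSS = 0 (or numerically nonpositive) are undefined: flagged
    NaN, counted, and excluded from comparisons downstream.
    """
    rss = np.asarray(fit.rss, dtype=float)
    ok = rss > 0
    lme = np.full(rss.shape, np.nan)
    lme[ok] = -0.5 * fit.n * np.log(rss[ok] / fit.n) - 0.5 * fit.k * np.log(fit.n)
    return LMEMap(lme=lme, model=fit.model, subject=fit.subject, n_undefined=int((~ok).sum()))
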