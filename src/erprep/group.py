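"""Group-level inference on the scalp x time volume.

Two-stage summary statistics: per subject the four block-specific modulator
betas are pooled (averaged), the pooled maps enter a voxelwise one-sample
test (F = t^2 with df (1, S-1)), and the F map is thresholded at p < 0.05
family-wise error corrected at the voxel level using random field theory:
the threshold is the F value at which the expected Euler characteristic of
the excursion set, computed from the EC densities of an F field and the
resel counts of the masked search region, equals alpha. Field smoothness is
estimated from the standardized group-model residuals. Suprathreshold
voxels are reported as 26-connected clusters with up to three peaks each.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

FOUR_LN2 = 4.0 * np.log(2.0)


@dataclass
class GroupSample:
    """Per-subject pooled modulator beta maps: (S, V) over in-mask voxels."""

    subject_maps: np.ndarray
    model: str

    def __post_init__(self) -> None:
        self.subject_maps = np.asarray(self.subject_maps, dtype=float)
        if self.subject_maps.ndim != 2 or self.subject_maps.shape[0] < 2:
            raise ValueError("need an (S, V) array with S >= 2 subjects")
        if np.isnan(self.subject_maps).any():
            raise ValueError("NaN in subject maps; restrict to in-mask voxels")


@dataclass
class SPMMap:
    """Group F map with equivalent-Z values; df = (1, S-1)."""

    F: np.ndarray
    df: tuple[int, int]
    Z: np.ndarray
    model: str = ""
    n_infinite: int = 0


@dataclass
class RFTResult:
    fwhm_est: np.ndarray  # per-axis FWHM, voxel units
    resel_counts: np.ndarray  # R_0..R_3
    search_volume: int  # in-mask voxel count
    alpha: float
    f_threshold: float
    significant_mask: np.ndarray  # boolean, same shape as the search mask


def pool_blocks(fit) -> np.ndarray:
    """Average the block-specific modulator betas -> one map per subject."""
    return fit.betas[fit.design.modulator_columns, :].mean(axis=0)


def one_sample_F(sample: GroupSample) -> SPMMap:
    """Voxelwise one-sample test: F = (mean / (sd/sqrt(S)))^2, df (1, S-1).

    Zero-variance voxels get F = inf, are counted, and are excluded from
    thresholding by the caller.
    """
    x = sample.subject_maps
    S = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    F = np.full(mean.shape, np.inf)
    ok = sd > 0
    F[ok] = (mean[ok] / (sd[ok] / np.sqrt(S))) ** 2
    zero_var_nonzero = int((~ok & (mean != 0)).sum())
    F[~ok & (mean == 0)] = 0.0
    if zero_var_nonzero:
        warnings.warn(
            f"{zero_var_nonzero} zero-variance voxels with nonzero mean: "
            "F flagged infinite and excluded from thresholding",
            RuntimeWarning,
            stacklevel=2,
        )
    df = (1, S - 1)
    Z = f_to_z(F, df)
    return SPMMap(F=F, df=df, Z=Z, model=sample.model, n_infinite=zero_var_nonzero)


def f_to_z(F, df: tuple[int, int]):
    """Equivalent Z: the normal deviate with the same upper-tail probability.

    Computed through the regularized incomplete beta function, so extreme
    tails (p ~ 1e-7 and beyond) are accurate.
    """
    F = np.asarray(F, dtype=float)
    d1, d2 = df
    if np.any(F < -1e-12):
        raise ValueError("F statistics must be nonnegative")
    p = stats.f.sf(F, d1, d2)
    z = stats.norm.isf(p)
    return z if z.shape else float(z)


def estimate_smoothness(residuals: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-axis smoothness FWHM (voxels) from standardized residual maps.

    ``residuals`` is (S, nx, ny, nt); each map is standardized per voxel
    (unit sum of squares over subjects), then the variance of the forward
    difference along each axis — over voxel pairs fully inside the mask —
    gives FWHM_axis = sqrt(4 ln 2 / var(derivative)).
    """
    res = np.asarray(residuals, dtype=float)
    if res.ndim != 4:
        raise ValueError("residuals must be (S, nx, ny, nt)")
    mask = np.asarray(mask, dtype=bool)
    ss = np.sum(res ** 2, axis=0)
    u = np.zeros_like(res)
    np.divide(res, np.sqrt(ss)[None], out=u, where=(ss > 0)[None])
    fwhm = np.empty(3)
    for ax in range(3):
        d = np.diff(u, axis=ax + 1)
        valid = np.logical_and(
            np.take(mask, np.arange(mask.shape[ax] - 1), axis=ax),
            np.take(mask, np.arange(1, mask.shape[ax]), axis=ax),
        )
        if valid.sum() < 2:
            raise ValueError("mask too small to estimate smoothness derivatives")
        v = np.sum(d ** 2, axis=0)[valid].mean()
        fwhm[ax] = np.sqrt(FOUR_LN2 / v) if v > 0 else np.inf
    return fwhm


def resel_counts(mask: np.ndarray, fwhm: np.ndarray) -> np.ndarray:
    """Resolution-element counts R_0..R_3 of a masked 3-D lattice.

    Counts points, edges, faces, and cubes of the mask lattice and converts
    them to resel counts with the per-axis smoothness, so edge and face
    resels of the search region are included, not just its volume.
    """
    m = np.asarray(mask, dtype=bool)
    rx, ry, rt = 1.0 / np.asarray(fwhm, dtype=float)
    P = m.sum()
    Ex = (m[:-1, :, :] & m[1:, :, :]).sum()
    Ey = (m[:, :-1, :] & m[:, 1:, :]).sum()
    Et = (m[:, :, :-1] & m[:, :, 1:]).sum()
    Fxy = (m[:-1, :-1, :] & m[1:, :-1, :] & m[:-1, 1:, :] & m[1:, 1:, :]).sum()
    Fxt = (m[:-1, :, :-1] & m[1:, :, :-1] & m[:-1, :, 1:] & m[1:, :, 1:]).sum()
    Fyt = (m[:, :-1, :-1] & m[:, 1:, :-1] & m[:, :-1, 1:] & m[:, 1:, 1:]).sum()
    C = (
        m[:-1, :-1, :-1] & m[1:, :-1, :-1] & m[:-1, 1:, :-1] & m[:-1, :-1, 1:]
        & m[1:, 1:, :-1] & m[1:, :-1, 1:] & m[:-1, 1:, 1:] & m[1:, 1:, 1:]
    ).sum()
    R0 = P - (Ex + Ey + Et) + (Fxy + Fxt + Fyt) - C
    R1 = (Ex - Fxy - Fxt + C) * rx + (Ey - Fxy - Fyt + C) * ry + (Et - Fxt - Fyt + C) * rt
    R2 = (Fxy - C) * rx * ry + (Fxt - C) * rx * rt + (Fyt - C) * ry * rt
    R3 = C * rx * ry * rt
    return np.array([R0, R1, R2, R3], dtype=float)


def ec_density_f(t, df: tuple[int, int]) -> np.ndarray:
    """Euler-characteristic densities rho_0..rho_3 of an F field at value t.

    The third-order density needs df1 + df2 > 3; at exactly df1 + df2 = 3
    (e.g. a one-sample test on 3 subjects) the 0 * Gamma(0) limit is finite
    and is evaluated by an epsilon perturbation of df2.
    """
    k, v = df
    t = float(t)
    if t < 0:
        raise ValueError("F value must be nonnegative")
    if k + v < 3:
        raise ValueError("3-D EC densities need df1 + df2 >= 3 (more subjects)")
    if k + v == 3:
        v = v + 1e-9
    a = FOUR_LN2 / (2.0 * np.pi)
    b = special.gammaln(v / 2.0) + special.gammaln(k / 2.0)
    x = k * t / v
    rho = np.zeros(4)
    rho[0] = stats.f.sf(t, k, v)
    if t > 0:
        rho[1] = (
            np.sqrt(a) * np.exp(special.gammaln((v + k - 1) / 2.0) - b) * np.sqrt(2.0)
            * x ** (0.5 * (k - 1)) * (1.0 + x) ** (-0.5 * (v + k - 2))
        )
        rho[2] = (
            a * np.exp(special.gammaln((v + k - 2) / 2.0) - b)
            * x ** (0.5 * (k - 2)) * (1.0 + x) ** (-0.5 * (v + k - 2))
            * ((v - 1.0) * x - (k - 1.0))
        )
        rho[3] = (
            a ** 1.5 * np.exp(special.gammaln((v + k - 3) / 2.0) - b) / np.sqrt(2.0)
            * x ** (0.5 * (k - 3)) * (1.0 + x) ** (-0.5 * (v + k - 2))
            * ((v - 1.0) * (v - 2.0) * x ** 2 - (2.0 * v * k - v - k - 1.0) * x
               + (k - 1.0) * (k - 2.0))
        )
    return rho


def expected_ec(t, df: tuple[int, int], resels: np.ndarray) -> float:
    """Expected Euler characteristic of the excursion set above t."""
    return float(np.dot(np.asarray(resels, dtype=float), ec_density_f(t, df)))


def fwe_threshold(
    df: tuple[int, int],
    fwhm_est: np.ndarray,
    mask: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, np.ndarray]:
    """Voxel-level FWE threshold: smallest F with expected EC <= alpha.

    Root of ``expected_ec(F) = alpha`` found by bisection to 1e-6. Returns
    the threshold and the resel counts used.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if df[1] <= 3:
        raise ValueError(
            "voxel-level RFT needs df2 > 3 (>= 5 subjects for a one-sample test): "
            "the 3-D expected EC of an F field with heavier tails never falls below alpha"
        )
    resels = resel_counts(mask, fwhm_est)
    # The expected-EC curve is not monotone over all F (it can dip negative at
    # low thresholds); the FWE threshold is the rightmost crossing of alpha,
    # on the decreasing upper branch where EC -> 0 from above.
    hi = 10.0
    while expected_ec(hi, df, resels) > alpha:
        hi *= 2.0
        if hi > 1e8:
            raise RuntimeError("could not bracket the FWE threshold")
    lo = hi / 2.0
    while expected_ec(lo, df, resels) <= alpha:
        hi = lo
        lo /= 2.0
        if lo < 1e-9:
            return lo, resels  # the whole field already satisfies EC <= alpha
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if expected_ec(mid, df, resels) > alpha:
            lo = mid
        else:
            hi = mid
    return hi, resels


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def extract_clusters(
    F_vol: np.ndarray,
    threshold: float,
    df: tuple[int, int],
    resels: np.ndarray,
    times_ms: np.ndarray,
    pixel_size_mm: float,
    peak_sep_mm: float = 8.0,
    peak_sep_ms: float = 8.0,
    max_peaks: int = 3,
) -> pd.DataFrame:
    """Cluster table of suprathreshold voxels (26-connectivity in x, y, t).

    Per cluster: size in voxels and up to ``max_peaks`` local maxima, each
    peak at least ``peak_sep_mm`` away spatially or ``peak_sep_ms`` in time
    from already-accepted peaks, with latency, voxel-level FWE p (expected EC
    at that F), F, and equivalent Z. Rows sorted by cluster size descending.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    supra = np.nan_to_num(F_vol, nan=-np.inf) > threshold
    labels, n_clusters = ndimage.label(supra, structure=_CONN26)
    dt = float(times_ms[1] - times_ms[0]) if times_ms.size > 1 else 1.0
    rows = []
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n_clusters + 1))
    order = np.argsort(sizes)[::-1]
    for rank, ci in enumerate(order, start=1):
        cl = ci + 1
        vox = np.argwhere(labels == cl)
        fvals = F_vol[tuple(vox.T)]
        by_f = np.argsort(fvals)[::-1]
        peaks: list[np.ndarray] = []
        for j in by_f:
            p = vox[j]
            far = all(
                np.hypot(*(np.abs(p[:2] - q[:2]) * pixel_size_mm)) >= peak_sep_mm
                or abs(p[2] - q[2]) * dt >= peak_sep_ms
                for q in peaks
            )
            if not peaks or far:
                peaks.append(p)
                fpk = float(fvals[j])
                rows.append(
                    {
                        "activation": rank,
                        "size": int(sizes[ci]),
                        "latency_ms": float(times_ms[p[2]]),
                        "p_fwe": min(1.0, expected_ec(fpk, df, resels)),
                        "F": fpk,
                        "Z": f_to_z(fpk, df),
                        "peak_ix": int(p[0]),
                        "peak_iy": int(p[1]),
                    }
                )
            if len(peaks) >= max_peaks:
                break
    return pd.DataFrame(
        rows,
        columns=["activation", "size", "latency_ms", "p_fwe", "F", "Z", "peak_ix", "peak_iy"],
    )


def group_inference(
    sample: GroupSample,
    mask3d: np.ndarray,
    times_ms: np.ndarray,
    pixel_size_mm: float,
    alpha: float = 0.05,
) -> tuple[SPMMap, RFTResult, pd.DataFrame]:
    """One-sample F inference with voxel-level RFT FWE correction.

    ``sample.subject_maps`` are flat (S, V) over the True entries of the 3-D
    ``mask3d``; returns the SPM, the RFT correction summary, and the cluster
    table.
    """
    spm = one_sample_F(sample)
    x = sample.subject_maps
    resid = x - x.mean(axis=0, keepdims=True)
    res_vols = np.zeros((x.shape[0],) + mask3d.shape)
    res_vols[:, mask3d] = resid
    fwhm = estimate_smoothness(res_vols, mask3d)
    thr, resels = fwe_threshold(spm.df, fwhm, mask3d, alpha)

    F_vol = np.full(mask3d.shape, np.nan)
    finite = np.isfinite(spm.F)
    flat = np.full(spm.F.shape, np.nan)
    flat[finite] = spm.F[finite]
    F_vol[mask3d] = flat
    sig = np.zeros(mask3d.shape, dtype=bool)
    sig[mask3d] = finite & (spm.F > thr)
    rft = RFTResult(
        fwhm_est=fwhm,
        resel_counts=resels,
        search_volume=int(mask3d.sum()),
        alpha=alpha,
        f_threshold=thr,
        significant_mask=sig,
    )
    table = extract_clusters(F_vol, thr, spm.df, resels, times_ms, pixel_size_mm)
    return spm, rft, table
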