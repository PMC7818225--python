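"""Scalp x time volumes: the voxel space of all statistics.

Each mean ERP (channels x samples) is flattened to a sequence of 32 x 32
scalp maps — one per sample in the 50-500 ms analysis window, 226 frames at
500 Hz — then stacked into a 3-D space x time image and smoothed with a
[16 mm, 16 mm, 16 ms] FWHM Gaussian kernel. Pixels outside the electrode
convex hull are NaN and stay NaN through every operation.

Geometry. Electrodes are flattened with an azimuthal-equidistant projection
about the vertex (arc distance from Cz preserved up to a single scale), then
uniformly scaled so the outermost electrode sits one pixel inside the grid
edge. The physical pitch is 4.25 mm/pixel by default, so the 32-pixel grid
spans 136 mm; this scale is what converts the mm smoothing FWHM into pixels.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError

from .montage import Montage

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))

DEFAULT_WINDOW_MS = (50.0, 500.0)


@dataclass(frozen=True)
class ScalpGrid:
    """Square pixel grid the scalp is flattened onto.

    ``pixel_size_mm`` fixes the physical scale of the plane (and therefore of
    the smoothing kernel); ``head_radius_mm`` scales arc distances before the
    fit-to-grid step; ``fit_margin_px`` is how far inside the grid edge the
    outermost electrode is placed.
    """

    n_pixels: int = 32
    pixel_size_mm: float = 4.25
    head_radius_mm: float = 85.0
    fit_margin_px: float = 1.0

    def __post_init__(self) -> None:
        if self.n_pixels < 2 or self.pixel_size_mm <= 0 or self.head_radius_mm <= 0:
            raise ValueError("grid must have >=2 pixels and positive physical scales")

    @property
    def pixel_centers_mm(self) -> np.ndarray:
        """1-D coordinates of pixel centers (same for both axes), mm."""
        n = self.n_pixels
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_size_mm

    @property
    def half_extent_mm(self) -> float:
        """Distance from grid center to the outer pixel edge, mm."""
        return self.n_pixels * self.pixel_size_mm / 2.0

    @property
    def fit_radius_mm(self) -> float:
        """Radius the outermost projected electrode is scaled to, mm."""
        return ((self.n_pixels - 1) / 2.0 - self.fit_margin_px) * self.pixel_size_mm


def project_electrodes(montage: Montage, grid: ScalpGrid) -> np.ndarray:
    """Flatten scalp electrodes to 2-D mm coordinates on the grid plane.

    Azimuthal-equidistant projection about the vertex: the radial coordinate
    is ``head_radius_mm * polar angle`` (arc length from Cz) and the azimuth
    is preserved, followed by one uniform scale that keeps every electrode
    ``fit_margin_px`` pixels inside the grid. An electrode at the vertex maps
    exactly to (0, 0); left/right mirror pairs map to mirror-image x.
    """
    pos = montage.positions
    theta = np.arccos(np.clip(pos[:, 2], -1.0, 1.0))
    rho = np.hypot(pos[:, 0], pos[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = np.where(rho[:, None] > 0, pos[:, :2] / np.where(rho == 0, 1.0, rho)[:, None], 0.0)
    xy = grid.head_radius_mm * theta[:, None] * direction
    r_max = np.linalg.norm(xy, axis=1).max()
    if r_max > grid.fit_radius_mm:
        xy = xy * (grid.fit_radius_mm / r_max)
    return xy


class FrameInterpolator:
    """Barycentric-linear interpolation from electrodes onto the pixel grid.

    Precomputes, once per (montage, grid), the Delaunay triangulation of the
    projected electrodes and a dense weight matrix mapping channel values to
    in-hull pixel values, so whole volumes are interpolated with one matmul.
    Interpolation is exact for affine fields; pixels outside the hull are NaN.
    """

    def __init__(self, coords_mm: np.ndarray, grid: ScalpGrid):
        coords_mm = np.asarray(coords_mm, dtype=float)
        if coords_mm.ndim != 2 or coords_mm.shape[1] != 2:
            raise ValueError("coords must be (n_channels, 2)")
        try:
            tri = Delaunay(coords_mm)
        except QhullError as err:
            raise ValueError(
                "need at least 3 non-collinear electrodes for scalp interpolation"
            ) from err
        self.grid = grid
        self.coords_mm = coords_mm
        c = grid.pixel_centers_mm
        px, py = np.meshgrid(c, c, indexing="ij")
        pts = np.column_stack([px.ravel(), py.ravel()])
        simplex = tri.find_simplex(pts)
        inside = simplex >= 0
        self.mask = inside.reshape(grid.n_pixels, grid.n_pixels)
        self._flat_idx = np.flatnonzero(inside)
        # barycentric weights of each in-hull pixel w.r.t. its simplex vertices
        simp = simplex[inside]
        trans = tri.transform[simp]
        bary2 = np.einsum("nij,nj->ni", trans[:, :2, :], pts[inside] - trans[:, 2, :])
        bary = np.column_stack([bary2, 1.0 - bary2.sum(axis=1)])
        verts = tri.simplices[simp]
        n_ch = coords_mm.shape[0]
        W = np.zeros((inside.sum(), n_ch))
        rows = np.repeat(np.arange(inside.sum()), 3)
        W[rows, verts.ravel()] = bary.ravel()
        self.weights = W

    @property
    def n_in_mask(self) -> int:
        return self._flat_idx.size

    def __call__(self, channel_values: np.ndarray) -> np.ndarray:
        """Interpolate one frame; returns a (n, n) image with NaN outside the hull."""
        v = np.asarray(channel_values, dtype=float)
        if v.shape != (self.weights.shape[1],):
            raise ValueError(f"expected {self.weights.shape[1]} channel values, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("channel values must be finite")
        out = np.full(self.grid.n_pixels ** 2, np.nan)
        out[self._flat_idx] = self.weights @ v
        return out.reshape(self.grid.n_pixels, self.grid.n_pixels)

    def interpolate_many(self, frames: np.ndarray) -> np.ndarray:
        """Interpolate (n_frames, n_channels) values to (n, n, n_frames)."""
        vals = self.weights @ np.asarray(frames, dtype=float).T  # (n_pix_in, n_frames)
        out = np.full((self.grid.n_pixels ** 2, frames.shape[0]), np.nan)
        out[self._flat_idx] = vals
        return out.reshape(self.grid.n_pixels, self.grid.n_pixels, frames.shape[0])


def interpolate_frame(
    channel_values: np.ndarray, coords_mm: np.ndarray, grid: ScalpGrid
) -> np.ndarray:
    """One-shot barycentric-linear scalp map (see :class:`FrameInterpolator`)."""
    return FrameInterpolator(coords_mm, grid)(channel_values)


@dataclass(frozen=True)
class SmoothingSpec:
    """Gaussian kernel FWHM: [x mm, y mm, t ms]."""

    fwhm: tuple[float, float, float] = (16.0, 16.0, 16.0)

    def __post_init__(self) -> None:
        if len(self.fwhm) != 3 or any(f <= 0 for f in self.fwhm):
            raise ValueError("FWHM must be three positive values (x mm, y mm, t ms)")

    def sigmas_voxels(self, pixel_size_mm: float, dt_ms: float) -> tuple[float, float, float]:
        fx, fy, ft = self.fwhm
        return (
            fx / pixel_size_mm * FWHM_TO_SIGMA,
            fy / pixel_size_mm * FWHM_TO_SIGMA,
            ft / dt_ms * FWHM_TO_SIGMA,
        )


@dataclass
class ScalpTimeVolume:
    """A space x time image: (n, n, T) in uV, NaN outside the scalp mask."""

    values: np.ndarray
    times_ms: np.ndarray
    grid: ScalpGrid
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        n = self.grid.n_pixels
        if self.values.shape[:2] != (n, n) or self.values.shape[2] != self.times_ms.size:
            raise ValueError("volume shape must be (n_pixels, n_pixels, n_times)")

    @property
    def mask(self) -> np.ndarray:
        """In-scalp pixel mask (2-D); the NaN pattern is shared by all frames."""
        return np.isfinite(self.values[:, :, 0])

    @property
    def dt_ms(self) -> float:
        if self.times_ms.size < 2:
            raise ValueError("volume has fewer than 2 frames")
        return float(self.times_ms[1] - self.times_ms[0])

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            values=self.values,
            times_ms=self.times_ms,
            grid=np.array(
                [self.grid.n_pixels, self.grid.pixel_size_mm,
                 self.grid.head_radius_mm, self.grid.fit_margin_px]
            ),
            provenance=json.dumps(self.provenance),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ScalpTimeVolume":
        with np.load(path, allow_pickle=False) as f:
            g = f["grid"]
            grid = ScalpGrid(int(g[0]), float(g[1]), float(g[2]), float(g[3]))
            return cls(
                values=f["values"],
                times_ms=f["times_ms"],
                grid=grid,
                provenance=json.loads(str(f["provenance"])),
            )

    def to_nifti(self):
        """Export as NIfTI-1 with (x, y, t) axes; pixel/sample pitch in the header."""
        import nibabel as nib

        affine = np.diag([self.grid.pixel_size_mm, self.grid.pixel_size_mm, self.dt_ms, 1.0])
        img = nib.Nifti1Image(self.values.astype(np.float32), affine)
        img.header.set_zooms((self.grid.pixel_size_mm, self.grid.pixel_size_mm, self.dt_ms))
        return img


def build_volume(
    erp: np.ndarray,
    times_ms: np.ndarray,
    interp: FrameInterpolator,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    provenance: dict | None = None,
) -> ScalpTimeVolume:
    """Interpolate every sample of an ERP in the closed analysis window.

    Parameters
    ----------
    erp : ndarray, (n_scalp_channels, n_samples)
        Mean ERP in uV; channel order must match the interpolator's montage.
    times_ms : ndarray
        Sample times of ``erp``.
    window_ms : (start, end)
        Closed window; at 500 Hz the default 50-500 ms window yields 226 frames.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    lo, hi = window_ms
    if lo > hi:
        raise ValueError("window start must not exceed window end")
    if lo < times_ms[0] - 1e-9 or hi > times_ms[-1] + 1e-9:
        raise ValueError(
            f"analysis window [{lo}, {hi}] ms outside epoch [{times_ms[0]}, {times_ms[-1]}] ms"
        )
    sel = (times_ms >= lo - 1e-9) & (times_ms <= hi + 1e-9)
    frames = np.asarray(erp, dtype=float).T[sel]  # (n_frames, n_channels)
    values = interp.interpolate_many(frames)
    return ScalpTimeVolume(
        values=values,
        times_ms=times_ms[sel],
        grid=interp.grid,
        provenance=provenance or {},
    )


def smooth_volume(vol: ScalpTimeVolume, spec: SmoothingSpec = SmoothingSpec()) -> ScalpTimeVolume:
    """Separable Gaussian smoothing with mask-normalized (NaN-aware) convolution.

    Out-of-mask voxels are excluded from the kernel support and the kernel is
    renormalized over the mask, so every smoothed value is a convex
    combination of in-mask inputs; the NaN pattern is unchanged.
    """
    sig = spec.sigmas_voxels(vol.grid.pixel_size_mm, vol.dt_ms)
    mask2d = vol.mask
    mask3d = np.broadcast_to(mask2d[:, :, None], vol.values.shape)
    filled = np.where(mask3d, vol.values, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sig, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(mask3d.astype(float), sigma=sig, mode="constant", cval=0.0)
    out = np.full_like(vol.values, np.nan)
    np.divide(num, den, out=out, where=mask3d)
    return ScalpTimeVolume(
        values=out,
        times_ms=vol.times_ms.copy(),
        grid=vol.grid,
        provenance={**vol.provenance, "smoothed_fwhm": list(spec.fwhm)},
    )


def smooth_volumes(
    values: np.ndarray,
    mask2d: np.ndarray,
    grid: ScalpGrid,
    dt_ms: float,
    spec: SmoothingSpec = SmoothingSpec(),
) -> np.ndarray:
    """Batched mask-normalized smoothing of stacked volumes (k, n, n, T).

    Identical to applying :func:`smooth_volume` to each volume; the kernel
    normalization over the scalp mask is computed once for the whole stack.
    """
    values = np.asarray(values, dtype=float)
    sig = spec.sigmas_voxels(grid.pixel_size_mm, dt_ms)
    mask3d = np.broadcast_to(mask2d[:, :, None], values.shape[1:])
    filled = np.where(mask3d[None], values, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=(0.0, *sig), mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(mask3d.astype(float), sigma=sig, mode="constant", cval=0.0)
    out = np.full_like(values, np.nan)
    np.divide(num, den[None], out=out, where=mask3d[None])
    return out


def volume_matrix(vols: list[ScalpTimeVolume]) -> tuple[np.ndarray, np.ndarray]:
    """Stack volumes into a (n_volumes, V) matrix over in-mask voxels.

    Returns ``(Y, voxel_mask)`` where ``voxel_mask`` is the 3-D boolean mask
    (identical across volumes) used to flatten each volume.
    """
    mask3d = np.broadcast_to(vols[0].mask[:, :, None], vols[0].values.shape)
    for v in vols[1:]:
        if not np.array_equal(v.mask, vols[0].mask):
            raise ValueError("volumes have differing scalp masks")
    Y = np.stack([v.values[mask3d] for v in vols])
    return Y, np.array(mask3d)


def unflatten(values: np.ndarray, mask3d: np.ndarray) -> np.ndarray:
    """Scatter a flat in-mask vector back into a NaN-padded 3-D volume."""
    out = np.full(mask3d.shape, np.nan)
    out[mask3d] = values
    return out
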