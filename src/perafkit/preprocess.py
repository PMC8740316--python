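"""Pre-PerAF preprocessing: volume discard, motion screening, detrending, smoothing.

The pipeline order is fixed: discard initial volumes -> motion screen ->
linear detrend -> Gaussian smooth.  Every step is pure (the input volume is
never modified in place).  Realignment and spatial normalization are out of
scope; synthetic cohorts are generated motion-free and a per-subject scalar
motion trace carries the exclusion rule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "Bold4D",
    "MotionDecision",
    "discard_initial_volumes",
    "motion_screen",
    "detrend_linear",
    "smooth_gaussian",
    "fwhm_to_sigma",
]

# FWHM = 2*sqrt(2 ln 2) * sigma for a Gaussian
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class Bold4D:
    """A 4D BOLD volume: spatial axes (x, y, z) then time.

    Parameters
    ----------
    data
        Intensity array of shape ``(nx, ny, nz, nt)``.
    affine
        4x4 voxel-index-to-mm map (NIfTI convention).
    tr_seconds
        Repetition time between consecutive volumes, seconds.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(float)
        affine = np.asarray(self.affine, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"Bold4D requires a 4D array, got shape {data.shape}")
        if data.shape[3] < 2:
            raise ValueError("Bold4D requires at least 2 time points")
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine spatial block must be invertible")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray) -> "Bold4D":
        return dataclasses.replace(self, data=data)


@dataclass(frozen=True)
class MotionDecision:
    include: bool
    max_displacement_mm: float
    threshold_mm: float

    def __bool__(self) -> bool:  # truthy == include
        return self.include


def discard_initial_volumes(vol: Bold4D, k: int) -> Bold4D:
    """Drop the first ``k`` volumes (signal-equilibration discard).

    ``k`` must be smaller than the number of time points; affine and TR are
    unchanged.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= vol.n_timepoints:
        raise ValueError(
            f"cannot discard {k} volumes from a series of {vol.n_timepoints}"
        )
    return vol.with_data(vol.data[..., k:].copy())


def motion_screen(trace_mm: np.ndarray, threshold_mm: float = 3.0) -> MotionDecision:
    """Exclude a subject whose maximum head displacement exceeds the threshold.

    The rule is strict ("over"): a maximum of exactly ``threshold_mm`` is
    still included.
    """
    trace = np.asarray(trace_mm, dtype=float)
    if trace.size == 0:
        raise ValueError("empty motion trace")
    if np.any(trace < 0):
        raise ValueError("motion displacements must be non-negative")
    if not threshold_mm > 0:
        raise ValueError("threshold_mm must be positive")
    mx = float(trace.max())
    return MotionDecision(include=not (mx > threshold_mm),
                          max_displacement_mm=mx,
                          threshold_mm=float(threshold_mm))


def detrend_linear(vol: Bold4D, mask: np.ndarray | None = None) -> Bold4D:
    """Remove the per-voxel least-squares linear trend, keeping the mean.

    Only the slope is removed; the original temporal mean is retained so that
    the PerAF denominator (the raw temporal mean) is unchanged.  Out-of-mask
    voxels are returned untouched.
    """
    nt = vol.n_timepoints
    if nt < 3:
        raise ValueError("detrend_linear requires at least 3 time points")
    data = vol.data
    t = np.arange(nt, dtype=data.dtype)
    tc = t - t.mean()
    denom = float((tc.astype(float) ** 2).sum())
    # slope per voxel: sum_t tc * x / sum_t tc^2
    slope = np.tensordot(data, tc, axes=([3], [0])) / denom
    slope = slope.astype(data.dtype)
    detrended = data - slope[..., None] * tc  # mean-preserving: tc sums to 0
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != vol.spatial_shape:
            raise ValueError("mask shape does not match volume")
        out = data.copy()
        out[mask] = detrended[mask]
    else:
        out = detrended
    return vol.with_data(out)


def fwhm_to_sigma(fwhm_mm: np.ndarray | float) -> np.ndarray:
    """Convert Gaussian FWHM to standard deviation (same units)."""
    return np.asarray(fwhm_mm, dtype=float) / _FWHM_PER_SIGMA


def smooth_gaussian(vol: Bold4D, fwhm_mm: float | tuple[float, float, float]) -> Bold4D:
    """Convolve each time frame with a separable spatial Gaussian.

    ``fwhm_mm`` is the kernel full width at half maximum per spatial axis in
    millimetres; it is converted to voxel units through the affine.  Reflect
    padding is used at the boundary so the per-frame flux is conserved.
    ``fwhm = 0`` is the identity.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,)).copy()
    if np.any(fwhm < 0):
        raise ValueError("FWHM must be non-negative")
    if np.all(fwhm == 0):
        return vol.with_data(vol.data.copy())
    sigma_vox = fwhm_to_sigma(fwhm) / vol.voxel_size_mm
    smoothed = ndimage.gaussian_filter(
        vol.data, sigma=tuple(sigma_vox) + (0.0,), mode="reflect"
    )
    return vol.with_data(smoothed)
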