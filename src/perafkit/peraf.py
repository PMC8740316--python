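"""Percent amplitude of fluctuation (PerAF).

For a voxel time series :math:`x_1..x_n` with temporal mean
:math:`\\mu = \\frac{1}{n}\\sum_i x_i`,

.. math::

    \\mathrm{PerAF} = \\frac{1}{n}\\sum_{i=1}^{n}
        \\left|\\frac{x_i - \\mu}{\\mu}\\right| \\times 100\\%

i.e. the mean absolute deviation from the temporal mean, as a percentage of
that mean.  PerAF is invariant to per-voxel gain (scaling the series leaves
it unchanged) but not to a global amplitude difference between subjects; the
mPerAF variant divides each map by its within-mask mean to remove that
nuisance before group statistics.

Voxels whose temporal mean is non-positive have no meaningful PerAF; they
are recorded as undefined (NaN) and counted, never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import Bold4D

__all__ = ["PerAFMap", "peraf_series", "peraf_map", "mperaf_standardize"]


@dataclass
class PerAFMap:
    """A 3D map of per-voxel PerAF values in percent.

    ``values`` holds NaN outside the mask and at undefined in-mask voxels;
    ``defined`` flags in-mask voxels with a valid value.  ``standardized``
    is ``"raw"`` or ``"mperaf"``.
    """

    values: np.ndarray
    mask: np.ndarray
    standardized: str = "raw"
    n_undefined: int = 0
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.standardized not in ("raw", "mperaf"):
            raise ValueError("standardized must be 'raw' or 'mperaf'")

    @property
    def defined(self) -> np.ndarray:
        return self.mask & np.isfinite(self.values)

    def in_mask_values(self) -> np.ndarray:
        return self.values[self.defined]


def peraf_series(x: np.ndarray) -> float:
    """PerAF of a single time series, in percent.

    Returns NaN when the temporal mean is non-positive (undefined voxel).
    Raises for series shorter than 2 points.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1D time series")
    if x.size < 2:
        raise ValueError("PerAF requires at least 2 time points")
    if not np.all(np.isfinite(x)):
        raise ValueError("time series contains non-finite values")
    mu = x.mean()
    if mu <= 0:
        return float("nan")
    return float(np.abs(x - mu).mean() / mu * 100.0)


def peraf_map(vol: Bold4D, mask: np.ndarray) -> PerAFMap:
    """Apply PerAF voxel-wise over a 4D volume.

    Out-of-mask voxels are NaN; in-mask voxels with non-positive temporal
    mean are NaN and counted in ``n_undefined``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.spatial_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume {vol.spatial_shape}"
        )
    if not mask.any():
        warnings.warn("empty mask: PerAF map has no in-mask voxels", stacklevel=2)
    data = vol.data
    mu = data.mean(axis=3)
    values = np.full(vol.spatial_shape, np.nan)
    ok = mask & (mu > 0)
    if ok.any():
        dev = np.abs(data[ok] - mu[ok, None]).mean(axis=1)
        values[ok] = dev / mu[ok] * 100.0
    n_undefined = int(mask.sum() - ok.sum())
    return PerAFMap(values=values, mask=mask, standardized="raw",
                    n_undefined=n_undefined, affine=vol.affine)


def mperaf_standardize(pmap: PerAFMap) -> PerAFMap:
    """Divide a PerAF map by its in-mask mean (mPerAF).

    The resulting in-mask mean is exactly 1; standardizing an already
    standardized map is the identity.  A non-positive in-mask mean is an
    error.
    """
    vals = pmap.in_mask_values()
    if vals.size == 0:
        raise ValueError("cannot standardize an empty map")
    m = vals.mean()
    if m <= 0:
        raise ValueError("in-mask mean must be positive for mPerAF")
    out = pmap.values / m
    return PerAFMap(values=out, mask=pmap.mask, standardized="mperaf",
                    n_undefined=pmap.n_undefined, affine=pmap.affine)
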