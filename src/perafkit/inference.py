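"""Group-level voxel-wise inference with Monte-Carlo cluster-extent correction.

The contrast is a pooled-variance two-sample t at every in-mask voxel
(optionally a least-squares group contrast with covariates), thresholded at
a per-voxel two-tailed p (cluster-forming threshold), with connected
suprathreshold components screened by a minimum extent calibrated by
Monte-Carlo simulation of smooth Gaussian null fields — the AlphaSim
procedure.  Smoothness of the statistical field is estimated from
standardized residual maps with the classic first-differences FWHM
estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .peraf import PerAFMap
from .preprocess import fwhm_to_sigma

__all__ = [
    "StatMap",
    "Cluster",
    "ClusterNullDistribution",
    "SmoothnessEstimate",
    "voxelwise_t",
    "estimate_smoothness",
    "simulate_cluster_null",
    "extract_clusters",
    "apply_cluster_correction",
    "connectivity_structure",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D binary structuring element for 6-, 18- or 26-neighbor adjacency."""
    try:
        rank = _CONNECTIVITY_RANK[connectivity]
    except KeyError:
        raise ValueError("connectivity must be one of 6, 18, 26") from None
    return ndimage.generate_binary_structure(3, rank)


@dataclass
class StatMap:
    """Voxel-wise t statistics with their two-tailed p values."""

    t: np.ndarray
    df: int
    p_voxel: np.ndarray
    mask: np.ndarray
    affine: np.ndarray | None = None

    @property
    def defined(self) -> np.ndarray:
        return self.mask & np.isfinite(self.t)


@dataclass
class Cluster:
    """A connected suprathreshold component of a statistical map."""

    voxels: np.ndarray  # (k, 3) voxel indices
    size: int
    peak_t: float  # signed; |peak_t| = max |t| in the cluster
    peak_xyz_mm: tuple[float, float, float]
    sign: str  # "increase" | "decrease"
    p_thresh: float
    connectivity: int
    corrected_p: float | None = None


@dataclass
class SmoothnessEstimate:
    fwhm_mm: np.ndarray  # per spatial axis

    def __post_init__(self) -> None:
        self.fwhm_mm = np.asarray(self.fwhm_mm, dtype=float)
        if np.any(self.fwhm_mm <= 0):
            raise ValueError("FWHM estimates must be positive")


@dataclass
class ClusterNullDistribution:
    """Monte-Carlo distribution of the maximum null cluster extent.

    ``threshold(alpha)`` is the smallest extent whose null exceedance
    fraction is at most ``alpha``; clusters at least that large survive.
    """

    n_iter: int
    p_thresh: float
    fwhm_mm: np.ndarray
    connectivity: int
    max_sizes: np.ndarray

    def threshold(self, alpha: float) -> int:
        if not 0 < alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        sizes = np.sort(self.max_sizes)[::-1]
        # smallest s with P(max >= s) <= alpha; exceedance of s is
        # (count of max_sizes >= s) / n_iter, non-increasing in s
        k = int(np.floor(alpha * self.n_iter))  # allowed exceedance count
        if k >= self.n_iter:
            return 1
        # need count(max >= s) <= k  =>  s > sizes[k] (k-th largest, 0-based)
        return int(sizes[k]) + 1

    def corrected_p(self, size: int) -> float:
        return float(np.mean(self.max_sizes >= size)) if size > 0 else 1.0


def _stack_maps(maps: list[PerAFMap], mask: np.ndarray) -> np.ndarray:
    arrs = []
    for m in maps:
        if m.values.shape != mask.shape:
            raise ValueError("map shape does not match mask")
        arrs.append(m.values[mask])
    return np.asarray(arrs, dtype=float)


def voxelwise_t(
    group_a: list[PerAFMap],
    group_b: list[PerAFMap],
    mask: np.ndarray,
    covariates: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> StatMap:
    """Two-sample t map, B minus A (positive t = group B larger).

    With no covariates this is the pooled-variance two-sample t.  With an
    ``(n_a + n_b, q)`` covariate matrix the statistic is the group-contrast
    t from an ordinary least-squares fit of ``[intercept, group, covariates]``
    and df drops accordingly.  Voxels with zero residual variance are
    undefined (NaN, excluded from the map's defined set).
    """
    mask = np.asarray(mask, dtype=bool)
    n_a, n_b = len(group_a), len(group_b)
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    if affine is None:
        for m in group_a + group_b:
            if m.affine is not None:
                affine = m.affine
                break
    A = _stack_maps(group_a, mask)  # (n_a, V)
    B = _stack_maps(group_b, mask)
    Y = np.vstack([A, B])
    g = np.concatenate([np.zeros(n_a), np.ones(n_b)])
    with np.errstate(divide="ignore", invalid="ignore"):
        if covariates is None:
            df = n_a + n_b - 2
            ma, mb = A.mean(axis=0), B.mean(axis=0)
            sp2 = ((A - ma).var(axis=0, ddof=0) * n_a +
                   (B - mb).var(axis=0, ddof=0) * n_b) / df
            se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
            t = (mb - ma) / se
        else:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            if C.shape[0] != n_a + n_b:
                raise ValueError("covariate rows must match total subjects")
            X = np.column_stack([np.ones(n_a + n_b), g, C])
            df = X.shape[0] - X.shape[1]
            if df < 1:
                raise ValueError("not enough subjects for the covariate model")
            pinv = np.linalg.pinv(X)
            beta = pinv @ Y
            resid = Y - X @ beta
            sigma2 = (resid ** 2).sum(axis=0) / df
            xtx_inv = np.linalg.inv(X.T @ X)
            se = np.sqrt(sigma2 * xtx_inv[1, 1])
            t = beta[1] / se
    t = np.where(np.isfinite(t), t, np.nan)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    t_map = np.full(mask.shape, np.nan)
    p_map = np.full(mask.shape, np.nan)
    t_map[mask] = t
    p_map[mask] = p
    return StatMap(t=t_map, df=int(df), p_voxel=p_map, mask=mask, affine=affine)


def _axis_fwhm(resid: np.ndarray, mask: np.ndarray, axis: int, voxel: float) -> float:
    """First-differences FWHM along one axis for one standardized map."""
    shifted = np.roll(mask, -1, axis=axis)
    # drop wrap-around pairs
    sl = [slice(None)] * 3
    sl[axis] = slice(-1, None)
    valid = mask & shifted
    valid[tuple(sl)] = False
    if valid.sum() < 2:
        return np.nan
    d = np.take(resid, np.arange(1, resid.shape[axis]), axis=axis) - np.take(
        resid, np.arange(0, resid.shape[axis] - 1), axis=axis
    )
    vmask = np.take(valid, np.arange(0, valid.shape[axis] - 1), axis=axis)
    var_d = d[vmask].var()
    var = resid[mask].var()
    if var <= 0:
        return np.nan
    rho_arg = 1.0 - var_d / (2.0 * var)
    if rho_arg <= 0:
        return np.inf  # rougher than white noise along this axis
    fwhm = voxel * np.sqrt(-2.0 * np.log(2.0) / np.log(rho_arg))
    # smoothness below one voxel is unresolvable on the sampling lattice
    # (and unrepresentable in the Monte-Carlo null): floor at voxel size
    return max(fwhm, voxel)


def estimate_smoothness(
    residual_maps: list[np.ndarray],
    mask: np.ndarray,
    voxel_size_mm: tuple[float, float, float],
) -> SmoothnessEstimate:
    """Per-axis spatial FWHM from standardized residual maps.

    Uses the variance of first spatial differences of each in-mask
    standardized residual map (the AFNI-style estimator
    ``FWHM = voxel * sqrt(-2 ln 2 / ln(1 - var(diff) / (2 var)))``),
    averaged over maps.  Data rougher than white noise along an axis fall
    back to the voxel size with a warning.
    """
    if len(residual_maps) < 2:
        raise ValueError("need at least 2 residual maps")
    mask = np.asarray(mask, dtype=bool)
    voxel = np.asarray(voxel_size_mm, dtype=float)
    per_map = []
    for r in residual_maps:
        r = np.asarray(r, dtype=float)
        vals = r[mask]
        sd = vals.std()
        if sd <= 0:
            continue  # constant map: carries no smoothness information
        z = np.where(mask, (r - vals.mean()) / sd, 0.0)
        per_map.append(
            [_axis_fwhm(z, mask, ax, voxel[ax]) for ax in range(3)]
        )
    if not per_map:
        raise ValueError("all residual maps are constant; smoothness undefined")
    est = np.asarray(per_map, dtype=float)
    fwhm = np.empty(3)
    for ax in range(3):
        col = est[:, ax]
        col = col[np.isfinite(col)]
        if col.size == 0:
            warnings.warn(
                f"residuals rougher than white noise along axis {ax}; "
                "falling back to voxel-size FWHM",
                stacklevel=2,
            )
            fwhm[ax] = voxel[ax]
        else:
            fwhm[ax] = col.mean()
    return SmoothnessEstimate(fwhm_mm=fwhm)


def simulate_cluster_null(
    mask: np.ndarray,
    fwhm_mm: np.ndarray | tuple[float, float, float],
    voxel_size_mm: tuple[float, float, float],
    p_thresh: float,
    connectivity: int = 18,
    n_iter: int = 1000,
    seed: int | None = None,
) -> ClusterNullDistribution:
    """Monte-Carlo null distribution of the maximum cluster extent.

    Each iteration draws Gaussian white noise over the grid, smooths it to
    the target FWHM, re-standardizes within the mask, applies the two-tailed
    voxel threshold, and records the largest connected component over both
    signs.  Deterministic given ``seed``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if not 0 < p_thresh < 1:
        raise ValueError("p_thresh must be in (0, 1)")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    voxel = np.asarray(voxel_size_mm, dtype=float)
    sigma_vox = fwhm_to_sigma(fwhm) / voxel
    struct = connectivity_structure(connectivity)
    zc = stats.norm.isf(p_thresh / 2.0)
    rng = np.random.default_rng(seed)
    max_sizes = np.zeros(n_iter, dtype=np.int64)
    for it in range(n_iter):
        field_ = rng.standard_normal(mask.shape)
        if np.any(sigma_vox > 0):
            field_ = ndimage.gaussian_filter(field_, sigma=sigma_vox, mode="reflect")
        vals = field_[mask]
        z = (field_ - vals.mean()) / vals.std()
        best = 0
        for supra in (mask & (z > zc), mask & (z < -zc)):
            if supra.any():
                lab, n_lab = ndimage.label(supra, structure=struct)
                if n_lab:
                    best = max(best, int(np.bincount(lab.ravel())[1:].max()))
        max_sizes[it] = best
    return ClusterNullDistribution(
        n_iter=n_iter,
        p_thresh=p_thresh,
        fwhm_mm=np.array(fwhm, dtype=float),
        connectivity=connectivity,
        max_sizes=max_sizes,
    )


def extract_clusters(
    stat: StatMap, p_thresh: float, connectivity: int = 18
) -> list[Cluster]:
    """Connected suprathreshold components, split by contrast sign.

    Positive-t (increase) and negative-t (decrease) voxels form separate
    clusters.  Each cluster reports its extent, signed peak t and the peak
    location in mm through the affine.  Clusters are returned sorted by
    size, largest first.
    """
    struct = connectivity_structure(connectivity)
    defined = stat.defined
    supra = defined & (stat.p_voxel < p_thresh)
    affine = stat.affine if stat.affine is not None else np.eye(4)
    clusters: list[Cluster] = []
    for sign, name in ((1, "increase"), (-1, "decrease")):
        blob = supra & (np.sign(stat.t) == sign)
        if not blob.any():
            continue
        lab, n_lab = ndimage.label(blob, structure=struct)
        for li in range(1, n_lab + 1):
            vox = np.argwhere(lab == li)
            tvals = stat.t[tuple(vox.T)]
            ipk = int(np.argmax(np.abs(tvals)))
            peak_vox = vox[ipk]
            xyz = affine @ np.append(peak_vox, 1.0)
            clusters.append(
                Cluster(
                    voxels=vox,
                    size=int(vox.shape[0]),
                    peak_t=float(tvals[ipk]),
                    peak_xyz_mm=tuple(float(v) for v in xyz[:3]),
                    sign=name,
                    p_thresh=p_thresh,
                    connectivity=connectivity,
                )
            )
    clusters.sort(key=lambda c: c.size, reverse=True)
    return clusters


def apply_cluster_correction(
    clusters: list[Cluster],
    null: ClusterNullDistribution,
    alpha: float = 0.05,
) -> list[Cluster]:
    """Keep clusters meeting the Monte-Carlo extent threshold at ``alpha``.

    Each surviving cluster gets a corrected p: the fraction of null maximum
    extents at least as large.  Refuses a null computed at a different
    cluster-forming threshold or connectivity than the clusters.
    """
    for c in clusters:
        if abs(c.p_thresh - null.p_thresh) > 1e-12 or c.connectivity != null.connectivity:
            raise ValueError(
                "cluster-forming threshold/connectivity of the null does not "
                "match the clusters; recompute the null with matching settings"
            )
    k = null.threshold(alpha)
    out = []
    for c in clusters:
        if c.size >= k:
            c.corrected_p = null.corrected_p(c.size)
            out.append(c)
    return out
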