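"""End-to-end analysis: preprocessing -> PerAF -> group inference -> ROI stats.

`run_pipeline` takes a cohort (materialized, streamed from a synthetic
configuration, or loaded from disk by the CLI) and a
:class:`~perafkit.config.PipelineConfig`, and produces the group t map, the
cluster report after Monte-Carlo extent correction, and the ROI-level
ROC/correlation report, together with a run log holding every parameter,
seed, exclusion and undefined-voxel count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import PipelineConfig
from .inference import (
    Cluster,
    ClusterNullDistribution,
    SmoothnessEstimate,
    StatMap,
    apply_cluster_correction,
    estimate_smoothness,
    extract_clusters,
    simulate_cluster_null,
    voxelwise_t,
)
from .peraf import PerAFMap, mperaf_standardize, peraf_map
from .preprocess import (
    Bold4D,
    detrend_linear,
    discard_initial_volumes,
    fwhm_to_sigma,
    motion_screen,
    smooth_gaussian,
)
from .roi import pearson_r, roc_auc, roi_mean
from .synthetic import Cohort, SyntheticCohortConfig, generate_phenotypes, iter_subject_bold

__all__ = ["PipelineResult", "subject_peraf_map", "run_pipeline", "cluster_report_frame"]


def _smooth_map_masked(
    values: np.ndarray, defined: np.ndarray, fwhm_mm, voxel_size_mm
) -> np.ndarray:
    """Normalized (mask-aware) Gaussian smoothing of a 3D map."""
    sigma = fwhm_to_sigma(np.broadcast_to(np.asarray(fwhm_mm, float), (3,)))
    sigma = sigma / np.asarray(voxel_size_mm, dtype=float)
    v = np.where(defined, values, 0.0)
    num = ndimage.gaussian_filter(v, sigma=tuple(sigma), mode="reflect")
    den = ndimage.gaussian_filter(defined.astype(float), sigma=tuple(sigma), mode="reflect")
    out = np.full(values.shape, np.nan)
    ok = defined & (den > 1e-12)
    out[ok] = num[ok] / den[ok]
    return out


def subject_peraf_map(
    vol: Bold4D, mask: np.ndarray, cfg: PipelineConfig
) -> PerAFMap:
    """One subject's PerAF map through the fixed preprocessing chain.

    Order: discard initial volumes, linear detrend (mean-preserving),
    spatial smoothing (of the 4D data by default, of the PerAF map when
    ``cfg.smooth_target == "peraf"``), PerAF, optional mPerAF
    standardization.
    """
    v = discard_initial_volumes(vol, cfg.discard_k) if cfg.discard_k else vol
    v = detrend_linear(v, mask)
    if cfg.smooth_target == "bold" and cfg.fwhm_mm > 0:
        v = smooth_gaussian(v, cfg.fwhm_mm)
    pmap = peraf_map(v, mask)
    if cfg.smooth_target == "peraf" and cfg.fwhm_mm > 0:
        pmap = PerAFMap(
            values=_smooth_map_masked(
                pmap.values, pmap.defined, cfg.fwhm_mm, v.voxel_size_mm
            ),
            mask=pmap.mask,
            standardized=pmap.standardized,
            n_undefined=pmap.n_undefined,
            affine=pmap.affine,
        )
    if cfg.mperaf:
        pmap = mperaf_standardize(pmap)
    return pmap


def cluster_report_frame(clusters: list[Cluster]) -> pd.DataFrame:
    """Tabular cluster report: one row per cluster, peak coordinates in mm."""
    rows = []
    for i, c in enumerate(clusters, start=1):
        rows.append(
            {
                "cluster_id": i,
                "peak_x_mm": c.peak_xyz_mm[0],
                "peak_y_mm": c.peak_xyz_mm[1],
                "peak_z_mm": c.peak_xyz_mm[2],
                "n_voxels": c.size,
                "peak_t": c.peak_t,
                "corrected_p": c.corrected_p,
                "direction": c.sign,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "peak_x_mm", "peak_y_mm", "peak_z_mm",
            "n_voxels", "peak_t", "corrected_p", "direction",
        ],
    )


@dataclass
class PipelineResult:
    stat_map: StatMap
    smoothness: SmoothnessEstimate
    null: ClusterNullDistribution
    clusters: list[Cluster]  # surviving after extent correction
    cluster_report: pd.DataFrame
    roi_means: pd.DataFrame  # per subject x ROI
    roi_report: pd.DataFrame  # AUC + CI per ROI, r/p per (ROI, phenotype)
    log: dict


def _iter_cohort(source) :
    if isinstance(source, Cohort):
        for sid, grp, vol in zip(source.subject_ids, source.groups, source.bolds):
            yield sid, grp, vol, None
    elif isinstance(source, SyntheticCohortConfig):
        yield from iter_subject_bold(source)
    else:  # sequence of (subject_id, group, Bold4D)
        for sid, grp, vol in source:
            yield sid, grp, vol, None


def run_pipeline(
    source: Cohort | SyntheticCohortConfig | list,
    cfg: PipelineConfig,
    labels: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    phenotypes: pd.DataFrame | None = None,
    motion_traces: dict[str, np.ndarray] | None = None,
    patient_group: str = "patient",
) -> PipelineResult:
    """Run the full analysis on a cohort.

    ``source`` may be a materialized :class:`Cohort`, a
    :class:`SyntheticCohortConfig` (subjects are then streamed one at a
    time to bound memory), or an explicit list of ``(id, group, Bold4D)``.
    ``labels``/``mask``/``phenotypes`` are taken from the cohort when not
    given.  Subjects whose motion trace exceeds the threshold are excluded
    and logged.  Deterministic given ``cfg.seed`` (and the cohort's own
    seed).
    """
    from .synthetic import generate_label_volume

    truth_amps = None
    if isinstance(source, Cohort):
        labels = source.labels if labels is None else labels
        mask = source.mask if mask is None else mask
        phenotypes = source.phenotypes if phenotypes is None else phenotypes
    elif isinstance(source, SyntheticCohortConfig):
        lab, msk = generate_label_volume(source)
        labels = lab if labels is None else labels
        mask = msk if mask is None else mask
    if mask is None:
        raise ValueError("a brain mask is required")
    mask = np.asarray(mask, dtype=bool)

    maps: dict[str, PerAFMap] = {}
    groups: dict[str, str] = {}
    excluded: dict[str, float] = {}
    n_undefined: dict[str, int] = {}
    voxel_size = None
    affine = None
    amp_rows: dict[str, dict] = {}
    for sid, grp, vol, amp in _iter_cohort(source):
        if motion_traces is not None and sid in motion_traces:
            decision = motion_screen(motion_traces[sid], cfg.motion_thresh_mm)
            if not decision.include:
                excluded[sid] = decision.max_displacement_mm
                continue
        pmap = subject_peraf_map(vol, mask, cfg)
        maps[sid] = pmap
        groups[sid] = grp
        n_undefined[sid] = pmap.n_undefined
        voxel_size = vol.voxel_size_mm
        affine = vol.affine
        if amp is not None:
            amp_rows[sid] = amp

    if isinstance(source, SyntheticCohortConfig) and phenotypes is None and amp_rows:
        roi_ids_cfg = [e.roi_id for e in source.effects]
        true_amp = pd.DataFrame(
            [[amp_rows[s].get(r, np.nan) for r in roi_ids_cfg] for s in amp_rows],
            index=pd.Index(list(amp_rows), name="subject_id"),
            columns=roi_ids_cfg,
        )
        phenotypes = generate_phenotypes(source, true_amp)
        phenotypes.insert(0, "group", [groups[s] for s in amp_rows])

    ids_a = [s for s, g in groups.items() if g != patient_group]  # controls
    ids_b = [s for s, g in groups.items() if g == patient_group]  # patients
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("group inference requires >= 2 subjects per group")
    maps_a = [maps[s] for s in ids_a]
    maps_b = [maps[s] for s in ids_b]

    # patients minus controls: positive t = patients > controls
    stat = voxelwise_t(maps_a, maps_b, mask, affine=affine)

    residuals = []
    for grp_maps in (maps_a, maps_b):
        stack = np.asarray([m.values for m in grp_maps])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN out of mask
            mean = np.nanmean(stack, axis=0)
        residuals.extend([m.values - mean for m in grp_maps])
    smooth = estimate_smoothness(residuals, mask & stat.defined, tuple(voxel_size))

    null = simulate_cluster_null(
        mask,
        smooth.fwhm_mm,
        tuple(voxel_size),
        p_thresh=cfg.p_voxel,
        connectivity=cfg.connectivity,
        n_iter=cfg.n_iter,
        seed=cfg.seed,
    )
    all_clusters = extract_clusters(stat, cfg.p_voxel, cfg.connectivity)
    surviving = apply_cluster_correction(all_clusters, null, cfg.alpha)

    # ROI stage: means per labelled region, ROC per ROI, brain-behavior r
    roi_ids = sorted(int(r) for r in np.unique(labels) if r != 0) if labels is not None else []
    mean_rows = {}
    for sid, pmap in maps.items():
        mean_rows[sid] = {rid: roi_mean(pmap, labels, rid) for rid in roi_ids}
    roi_means = pd.DataFrame.from_dict(mean_rows, orient="index")
    roi_means.index.name = "subject_id"
    roi_means.insert(0, "group", [groups[s] for s in roi_means.index])

    report_rows = []
    grp_arr = roi_means["group"].to_numpy()
    for rid in roi_ids:
        scores = roi_means[rid].to_numpy(dtype=float)
        roc = roc_auc(
            scores,
            grp_arr,
            positive_group=patient_group,
            ci_method=cfg.ci_method,
            n_boot=cfg.n_boot,
            seed=cfg.seed + 1,
        )
        report_rows.append(
            {
                "roi_id": rid,
                "measure": "auc",
                "value": roc.auc,
                "ci_low": roc.ci95[0],
                "ci_high": roc.ci95[1],
                "p": np.nan,
                "n": len(scores),
            }
        )
        if phenotypes is not None:
            pheno_num = phenotypes.drop(columns=["group"], errors="ignore")
            aligned = pheno_num.reindex(roi_means.index)
            for col in aligned.columns:
                y = aligned[col].to_numpy(dtype=float)
                try:
                    corr = pearson_r(scores, y)
                except ValueError:
                    continue
                report_rows.append(
                    {
                        "roi_id": rid,
                        "measure": f"pearson_r:{col}",
                        "value": corr.r,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p": corr.p_two_tailed,
                        "n": corr.n,
                    }
                )
    roi_report = pd.DataFrame(
        report_rows,
        columns=["roi_id", "measure", "value", "ci_low", "ci_high", "p", "n"],
    )

    log = {
        "config": cfg.to_dict(),
        "n_subjects": len(maps),
        "excluded_motion": excluded,
        "undefined_voxels": n_undefined,
        "smoothness_fwhm_mm": [float(f) for f in smooth.fwhm_mm],
        "extent_threshold": null.threshold(cfg.alpha),
        "df": stat.df,
        "n_clusters_uncorrected": len(all_clusters),
        "n_clusters_surviving": len(surviving),
    }
    return PipelineResult(
        stat_map=stat,
        smoothness=smooth,
        null=null,
        clusters=surviving,
        cluster_report=cluster_report_frame(surviving),
        roi_means=roi_means,
        roi_report=roi_report,
        log=log,
    )
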