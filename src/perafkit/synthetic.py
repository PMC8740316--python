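"""Synthetic resting-state cohorts with planted amplitude effects.

The generator emulates a two-group resting-state fMRI study (default 17
patients vs 17 controls) in which every in-brain voxel carries a stable
positive baseline, a band-limited low-frequency oscillation, and temporally
autocorrelated noise.  Regional effects are planted as amplitude
multipliers inside labelled ROIs for one group, and behavioral phenotypes
are drawn with a chosen correlation to the true regional amplitude, so the
whole downstream pipeline — preprocessing, PerAF, group inference,
ROC/correlation — can be exercised and its recovery properties measured
against known ground truth.

Voxel model (in-mask):

    x_t = baseline * (1 + a_v * s_t) + eps_t

where ``s_t`` is a unit-peak-amplitude band-limited oscillation shared by
all voxels of a subject, ``a_v`` is the amplitude fraction (base value
times the ROI multiplier where a planted effect applies to the subject's
group, times a per-subject lognormal factor), and ``eps_t`` is stationary
AR(1) Gaussian noise.  Out-of-mask voxels contain zero-mean noise only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .preprocess import Bold4D

__all__ = [
    "EffectSpec",
    "PhenotypeModel",
    "SyntheticCohortConfig",
    "Cohort",
    "cube_roi",
    "generate_label_volume",
    "simulate_subject_bold",
    "generate_phenotypes",
    "generate_cohort",
    "iter_subject_bold",
    "subject_true_amplitudes",
]

PATIENT = "patient"
CONTROL = "control"
_GROUPS = (PATIENT, CONTROL)


def cube_roi(corner: tuple[int, int, int], edge: int) -> np.ndarray:
    """Voxel coordinates of an axis-aligned cube: ``edge**3`` voxels."""
    ax = [np.arange(c, c + edge) for c in corner]
    g = np.meshgrid(*ax, indexing="ij")
    return np.stack([a.ravel() for a in g], axis=1)


@dataclass(frozen=True)
class EffectSpec:
    """A planted regional amplitude effect.

    ``amplitude_multiplier`` scales the fluctuation amplitude of the ROI's
    voxels for subjects of ``group`` (1.5 = 50% larger amplitude, values
    below 1 = reduced amplitude).
    """

    roi_id: int
    roi_voxels: np.ndarray  # (k, 3) integer voxel coordinates
    group: str = PATIENT
    amplitude_multiplier: float = 1.5

    def __post_init__(self) -> None:
        vox = np.asarray(self.roi_voxels, dtype=int)
        if vox.ndim != 2 or vox.shape[1] != 3 or vox.shape[0] == 0:
            raise ValueError("roi_voxels must be a non-empty (k, 3) array")
        if self.roi_id <= 0:
            raise ValueError("roi_id must be a positive integer label")
        if self.group not in _GROUPS:
            raise ValueError(f"group must be one of {_GROUPS}")
        if not self.amplitude_multiplier > 0:
            raise ValueError("amplitude_multiplier must be positive")
        object.__setattr__(self, "roi_voxels", vox)


@dataclass(frozen=True)
class PhenotypeModel:
    """A per-subject behavioral/ocular score, optionally tied to an ROI.

    When ``linked_roi_id`` is set, scores are drawn as

        y = mean + sd * (r * z + sqrt(1 - r^2) * eta)

    with ``z`` the cohort-standardized true ROI amplitude and ``eta``
    independent standard normal, so the population correlation between the
    score and the regional amplitude is ``target_r``.  Rounding and bounds
    are applied last (they attenuate the realized correlation slightly, as
    for any discretized instrument).
    """

    name: str
    linked_roi_id: int | None = None
    target_r: float = 0.0
    mean: float = 0.0
    sd: float = 1.0
    rounding: str = "none"  # "none" | "integer"
    floor: float | None = None
    ceiling: float | None = None

    def __post_init__(self) -> None:
        if not abs(self.target_r) <= 1:
            raise ValueError("|target_r| must be <= 1")
        if not self.sd > 0:
            raise ValueError("sd must be positive")
        if self.rounding not in ("none", "integer"):
            raise ValueError("rounding must be 'none' or 'integer'")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults mirror a typical 3T resting-state acquisition: TR 2 s, 240
    volumes, 3 mm isotropic voxels, 0.01-0.08 Hz signal band, baseline
    intensity 1000 with 3% fluctuation amplitude and 1% noise SD.
    """

    n_per_group: int = 17
    grid_shape: tuple[int, int, int] = (24, 24, 18)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_timepoints: int = 240
    tr_seconds: float = 2.0
    baseline_mean: float = 1000.0
    oscillation_band_hz: tuple[float, float] = (0.01, 0.08)
    base_amplitude_fraction: float = 0.03
    noise_sd_fraction: float = 0.01
    ar1_coefficient: float = 0.3
    n_oscillators: int = 5
    single_frequency_hz: float | None = None
    subject_amplitude_jitter_sd: float = 0.1
    effects: tuple[EffectSpec, ...] = ()
    phenotype_models: tuple[PhenotypeModel, ...] = ()
    seed: int = 0
    dtype: str = "float32"  # volume storage precision

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", tuple(self.effects))
        object.__setattr__(self, "phenotype_models", tuple(self.phenotype_models))
        if self.n_per_group < 1 or self.n_timepoints < 1 or self.n_oscillators < 1:
            raise ValueError("counts must be >= 1")
        if any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape entries must be >= 1")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if not self.baseline_mean > 0:
            raise ValueError("baseline_mean must be positive")
        lo, hi = self.oscillation_band_hz
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if not (0 <= lo < hi < nyquist):
            raise ValueError(
                f"oscillation band must satisfy 0 <= low < high < {nyquist} Hz"
            )
        if not (0 <= self.ar1_coefficient < 1):
            raise ValueError("ar1_coefficient must be in [0, 1)")
        if self.noise_sd_fraction < 0 or self.base_amplitude_fraction <= 0:
            raise ValueError("amplitude/noise fractions out of range")
        if not np.issubdtype(np.dtype(self.dtype), np.floating):
            raise ValueError("dtype must be a floating type")
        self._validate_rois()
        roi_ids = {e.roi_id for e in self.effects}
        for m in self.phenotype_models:
            if m.linked_roi_id is not None and m.linked_roi_id not in roi_ids:
                raise ValueError(
                    f"phenotype '{m.name}' links to unknown ROI {m.linked_roi_id}"
                )

    def _validate_rois(self) -> None:
        shape = np.asarray(self.grid_shape)
        seen: set[tuple[int, int, int]] = set()
        ids: set[int] = set()
        for eff in self.effects:
            if eff.roi_id in ids:
                raise ValueError(f"duplicate roi_id {eff.roi_id}")
            ids.add(eff.roi_id)
            vox = eff.roi_voxels
            if np.any(vox < 0) or np.any(vox >= shape):
                raise ValueError(f"ROI {eff.roi_id} extends outside the grid")
            for v in map(tuple, vox):
                if v in seen:
                    raise ValueError("effect ROIs overlap")
                seen.add(v)

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-mm map: scaled axes, world origin at the grid center."""
        aff = np.eye(4)
        vs = np.asarray(self.voxel_size_mm, dtype=float)
        aff[:3, :3] = np.diag(vs)
        aff[:3, 3] = -vs * (np.asarray(self.grid_shape) - 1) / 2.0
        return aff

    def subject_ids(self) -> list[str]:
        n = self.n_per_group
        return [f"patient{i + 1:02d}" for i in range(n)] + [
            f"control{i + 1:02d}" for i in range(n)
        ]

    def subject_groups(self) -> list[str]:
        n = self.n_per_group
        return [PATIENT] * n + [CONTROL] * n


def generate_label_volume(
    config: SyntheticCohortConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Build the integer label volume and brain mask for a cohort.

    The brain is an ellipsoid inscribed in the grid, unioned with every ROI
    so all planted effects are in-mask.  Background label is 0 and each
    effect's ``roi_id`` labels exactly its voxels.
    """
    shape = config.grid_shape
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) / 2.0 - 0.5
    semi = np.maximum(semi, 0.5)
    idx = np.indices(shape)
    dist2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    mask = dist2 <= 1.0
    labels = np.zeros(shape, dtype=np.int32)
    for eff in config.effects:
        i, j, k = eff.roi_voxels.T
        labels[i, j, k] = eff.roi_id
        mask[i, j, k] = True
    return labels, mask


def _subject_rng(config: SyntheticCohortConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, subject_index]))


def _oscillation(config: SyntheticCohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Unit-peak-amplitude band-limited oscillation, length n_timepoints."""
    t = np.arange(config.n_timepoints) * config.tr_seconds
    if config.single_frequency_hz is not None:
        return np.sin(2 * np.pi * config.single_frequency_hz * t)
    lo, hi = config.oscillation_band_hz
    freqs = rng.uniform(lo, hi, size=config.n_oscillators)
    phases = rng.uniform(0, 2 * np.pi, size=config.n_oscillators)
    s = np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)
    peak = np.abs(s).max()
    if peak > 0:
        s = s / peak
    return s


def _ar1_noise(
    shape: tuple[int, ...],
    sd: float,
    phi: float,
    rng: np.random.Generator,
    dtype: np.dtype = np.float32,
) -> np.ndarray:
    """Stationary AR(1) noise along the last axis, marginal SD ``sd``."""
    if sd == 0:
        return np.zeros(shape, dtype=dtype)
    e = rng.standard_normal(shape, dtype=dtype)
    if phi == 0:
        e *= sd
        return e
    e *= sd * np.sqrt(1.0 - phi * phi)
    # exact stationary start: first sample at the marginal SD
    e[..., 0] /= np.sqrt(1.0 - phi * phi)
    coeffs = np.asarray([1.0], dtype=dtype), np.asarray([1.0, -phi], dtype=dtype)
    return lfilter(coeffs[0], coeffs[1], e, axis=-1)


def _amplitude_field(
    config: SyntheticCohortConfig,
    group: str,
    subject_factor: float,
    mask: np.ndarray,
) -> tuple[np.ndarray, dict[int, float]]:
    a = np.where(mask, config.base_amplitude_fraction, 0.0)
    for eff in config.effects:
        if eff.group == group:
            i, j, k = eff.roi_voxels.T
            a[i, j, k] = config.base_amplitude_fraction * eff.amplitude_multiplier
    a *= subject_factor
    true_amp = {}
    for eff in config.effects:
        i, j, k = eff.roi_voxels.T
        true_amp[eff.roi_id] = float(a[i, j, k].mean())
    return a, true_amp


def subject_true_amplitudes(
    config: SyntheticCohortConfig, subject_index: int, group: str
) -> dict[int, float]:
    """The subject's true amplitude fraction per ROI, without simulating
    the volume (same random stream as :func:`simulate_subject_bold`)."""
    if group not in _GROUPS:
        raise ValueError(f"group must be one of {_GROUPS}")
    rng = _subject_rng(config, subject_index)
    factor = float(np.exp(rng.normal(0.0, config.subject_amplitude_jitter_sd)))
    out = {}
    for eff in config.effects:
        mult = eff.amplitude_multiplier if eff.group == group else 1.0
        out[eff.roi_id] = config.base_amplitude_fraction * mult * factor
    return out


def simulate_subject_bold(
    config: SyntheticCohortConfig,
    subject_index: int,
    group: str,
    mask: np.ndarray | None = None,
) -> tuple[Bold4D, dict[int, float]]:
    """Simulate one subject's 4D BOLD volume.

    Deterministic in ``(config.seed, subject_index)``.  Returns the volume
    and the subject's true amplitude fraction per ROI (the quantity the
    phenotype generator links to).
    """
    if group not in _GROUPS:
        raise ValueError(f"group must be one of {_GROUPS}")
    if mask is None:
        _, mask = generate_label_volume(config)
    rng = _subject_rng(config, subject_index)
    subject_factor = float(
        np.exp(rng.normal(0.0, config.subject_amplitude_jitter_sd))
    )
    s = _oscillation(config, rng)
    a, true_amp = _amplitude_field(config, group, subject_factor, mask)
    noise_sd = config.noise_sd_fraction * config.baseline_mean
    shape4 = config.grid_shape + (config.n_timepoints,)
    dtype = np.dtype(config.dtype)
    eps = _ar1_noise(shape4, noise_sd, config.ar1_coefficient, rng, dtype=dtype)
    data = eps
    signal = config.baseline_mean * (
        1.0 + a[mask, None].astype(dtype) * s[None, :].astype(dtype)
    )
    data[mask] += signal.astype(dtype)
    vol = Bold4D(data=data, affine=config.affine, tr_seconds=config.tr_seconds)
    return vol, true_amp


def iter_subject_bold(
    config: SyntheticCohortConfig,
) -> Iterator[tuple[str, str, Bold4D, dict[int, float]]]:
    """Stream ``(subject_id, group, bold, true_roi_amplitudes)`` tuples.

    Memory-friendly alternative to :func:`generate_cohort` for pipelines
    that reduce each subject to a 3D map before moving on.
    """
    _, mask = generate_label_volume(config)
    for i, (sid, grp) in enumerate(zip(config.subject_ids(), config.subject_groups())):
        vol, amp = simulate_subject_bold(config, i, grp, mask=mask)
        yield sid, grp, vol, amp


def generate_phenotypes(
    config: SyntheticCohortConfig,
    true_roi_amplitudes: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw per-subject phenotype scores from the configured models.

    ``true_roi_amplitudes`` must be indexed by subject id with one column
    per ROI id (as produced by :func:`generate_cohort`); linkage
    standardizes each ROI's amplitudes across the whole cohort.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10_000_019]))
    n = len(true_roi_amplitudes)
    out = pd.DataFrame(index=true_roi_amplitudes.index.copy())
    for m in config.phenotype_models:
        eta = rng.standard_normal(n)
        if m.linked_roi_id is not None:
            if m.linked_roi_id not in true_roi_amplitudes.columns:
                raise ValueError(
                    f"phenotype '{m.name}' links to unknown ROI {m.linked_roi_id}"
                )
            amp = true_roi_amplitudes[m.linked_roi_id].to_numpy(dtype=float)
            sd = amp.std()
            z = (amp - amp.mean()) / sd if sd > 0 else np.zeros(n)
            r = m.target_r
            y = m.mean + m.sd * (r * z + np.sqrt(1.0 - r * r) * eta)
        else:
            y = m.mean + m.sd * eta
        if m.floor is not None or m.ceiling is not None:
            y = np.clip(y, m.floor, m.ceiling)
        if m.rounding == "integer":
            y = np.rint(y)
        out[m.name] = y
    return out


@dataclass
class Cohort:
    """A fully materialized synthetic cohort plus its ground truth."""

    config: SyntheticCohortConfig
    subject_ids: list[str]
    groups: list[str]
    bolds: list[Bold4D]
    mask: np.ndarray
    labels: np.ndarray
    phenotypes: pd.DataFrame  # index subject_id; columns: group + model names
    true_roi_amplitudes: pd.DataFrame  # index subject_id; columns: roi ids

    @property
    def affine(self) -> np.ndarray:
        return self.config.affine


def generate_cohort(config: SyntheticCohortConfig) -> Cohort:
    """Generate the full two-group cohort deterministically from the seed."""
    labels, mask = generate_label_volume(config)
    ids, groups = config.subject_ids(), config.subject_groups()
    bolds, amps = [], []
    for i, grp in enumerate(groups):
        vol, amp = simulate_subject_bold(config, i, grp, mask=mask)
        bolds.append(vol)
        amps.append(amp)
    roi_ids = [e.roi_id for e in config.effects]
    true_amp = pd.DataFrame(
        [[a.get(r, np.nan) for r in roi_ids] for a in amps],
        index=pd.Index(ids, name="subject_id"),
        columns=roi_ids,
    )
    pheno = generate_phenotypes(config, true_amp)
    pheno.insert(0, "group", groups)
    return Cohort(
        config=config,
        subject_ids=ids,
        groups=groups,
        bolds=bolds,
        mask=mask,
        labels=labels,
        phenotypes=pheno,
        true_roi_amplitudes=true_amp,
    )
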