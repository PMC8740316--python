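"""NIfTI and table I/O with provenance stamping."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import Bold4D
from .synthetic import Cohort

__all__ = [
    "read_nifti",
    "read_bold4d",
    "write_nifti",
    "write_bold4d",
    "read_motion_trace",
    "write_cohort",
    "config_hash",
]


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping (for provenance)."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def write_nifti(
    path: str | Path,
    data: np.ndarray,
    affine: np.ndarray,
    description: str = "",
    tr_seconds: float | None = None,
) -> None:
    """Write an array as NIfTI-1; ``.nii`` and ``.nii.gz`` both supported."""
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float))
    if description:
        img.header["descrip"] = description.encode()[:79]
    if tr_seconds is not None and data.ndim == 4:
        img.header.set_zooms(img.header.get_zooms()[:3] + (tr_seconds,))
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray, str]:
    """Read a NIfTI file; returns ``(data, affine, header description)``."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad input
        raise ValueError(f"could not read NIfTI file {path}: {exc}") from exc
    descrip = img.header["descrip"].tobytes().rstrip(b"\x00").decode(errors="replace")
    return np.asarray(img.get_fdata()), img.affine.copy(), descrip


def read_bold4d(path: str | Path, tr_seconds: float | None = None) -> Bold4D:
    """Load a 4D BOLD NIfTI.  TR is taken from the header unless given."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got shape {data.shape}")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return Bold4D(data=data, affine=img.affine.copy(), tr_seconds=tr_seconds)


def write_bold4d(path: str | Path, vol: Bold4D, description: str = "") -> None:
    write_nifti(path, vol.data, vol.affine, description, tr_seconds=vol.tr_seconds)


def read_motion_trace(path: str | Path) -> np.ndarray:
    """Single-column TSV of per-volume maximum displacement in mm."""
    arr = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float).ravel()
    return arr


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Serialize a synthetic cohort: per-subject 4D NIfTI, mask, labels,
    phenotype TSV and a ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    stamp = f"perafkit seed={cfg.seed} cfg={config_hash(cfg.__dict__)}"
    aff = cohort.affine
    for sid, vol in zip(cohort.subject_ids, cohort.bolds):
        write_bold4d(out / f"{sid}_bold.nii.gz", vol, description=stamp)
    write_nifti(out / "mask.nii.gz", cohort.mask.astype(np.uint8), aff, stamp)
    write_nifti(out / "labels.nii.gz", cohort.labels.astype(np.int16), aff, stamp)
    pheno = cohort.phenotypes.copy()
    pheno.to_csv(out / "phenotypes.tsv", sep="\t")
    truth = {
        "seed": cfg.seed,
        "config_hash": config_hash(cfg.__dict__),
        "effects": [
            {
                "roi_id": e.roi_id,
                "group": e.group,
                "amplitude_multiplier": e.amplitude_multiplier,
                "n_voxels": int(e.roi_voxels.shape[0]),
            }
            for e in cfg.effects
        ],
        "true_roi_amplitudes": {
            str(sid): {str(k): float(v) for k, v in row.items()}
            for sid, row in cohort.true_roi_amplitudes.iterrows()
        },
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
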