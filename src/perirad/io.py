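"""Readers and writers: NIfTI volumes/masks, clinical CSV, provenance JSON.

NIfTI is the canonical volume format; masks must share the volume grid
exactly — no implicit resampling is ever performed.  World coordinates are in
millimetres with a diagonal affine (axis order fixed to the array order).
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import ImageVolume
from .phantoms import CLINICAL_COLUMNS, COVARIATE_TABLES

CATEGORICAL_LEVELS = {
    "hpv_status": {"pos", "neg"},
    "gender": set(COVARIATE_TABLES["pos"]["gender"]),
    "smoking": set(COVARIATE_TABLES["pos"]["smoking"]),
    "drinking": set(COVARIATE_TABLES["pos"]["drinking"]),
    "t_stage": set(COVARIATE_TABLES["pos"]["t_stage"]),
    "n_stage": set(COVARIATE_TABLES["pos"]["n_stage"]),
    "ajcc_stage": set(COVARIATE_TABLES["pos"]["ajcc_stage"]) | {"IV"},
}


def _affine(spacing_mm, origin_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = origin_mm
    return aff


def write_volume(path, volume: ImageVolume) -> None:
    img = nib.Nifti1Image(
        np.asarray(volume.data, dtype=np.float32),
        _affine(volume.spacing_mm, volume.origin_mm),
    )
    nib.save(img, str(path))


def read_volume(path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return ImageVolume(data, spacing, origin)


def write_mask(path, mask: np.ndarray, spacing_mm, origin_mm=(0.0, 0.0, 0.0)) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing_mm, origin_mm))
    nib.save(img, str(path))


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def read_mask_for(path, volume: ImageVolume) -> np.ndarray:
    """Read a mask and verify it shares the volume grid."""
    mask = read_mask(path)
    if mask.shape != volume.shape:
        raise ValueError(
            f"mask grid {mask.shape} does not match volume grid {volume.shape} ({path})"
        )
    return mask


def read_clinical(path) -> pd.DataFrame:
    """Read and validate a clinical table.

    Columns follow the documented dictionary (``patient_id``, ``hpv_status``,
    ``gender``, ``smoking``, ``drinking``, ``t_stage``, ``n_stage``,
    ``ajcc_stage``, ``age``, ``time_years``, ``event``).  Rows with an event
    flag outside {0, 1}, a non-positive follow-up time, or an unknown
    categorical level are rejected with their row number.
    """
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    bad = ~df["event"].isin([0, 1])
    if bad.any():
        raise ValueError(f"event flag not in {{0,1}} at rows {list(df.index[bad])}")
    bad = ~(df["time_years"] > 0)
    if bad.any():
        raise ValueError(f"non-positive time_years at rows {list(df.index[bad])}")
    for col, levels in CATEGORICAL_LEVELS.items():
        bad = ~df[col].isin(list(levels))
        if bad.any():
            raise ValueError(
                f"unknown {col} level(s) {sorted(df.loc[bad, col].unique())} "
                f"at rows {list(df.index[bad])}"
            )
    return df


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def write_provenance(outdir, config, seed: int | None = None) -> None:
    """Record the exact configuration (and seed) that produced an output dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"config": _jsonable(config)}
    if seed is not None:
        payload["seed"] = int(seed)
    write_json(outdir / "provenance.json", payload)
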