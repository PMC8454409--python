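"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageVolume:
    """A 3-D CT-like intensity grid with physical voxel spacing.

    Parameters
    ----------
    data
        Intensity array, shape ``(nx, ny, nz)``, Hounsfield-unit-like values.
    spacing_mm
        Per-axis voxel size in millimetres, e.g. ``(1.0, 1.0, 2.5)`` for a
        typical anisotropic head-and-neck planning CT.
    origin_mm
        Physical offset of the first voxel centre, in millimetres.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive values, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def check_mask(mask: np.ndarray, volume_shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Validate a binary tumor mask and return it as boolean."""
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask must be binary (values in {0, 1})")
    if volume_shape is not None and mask.shape != tuple(volume_shape):
        raise ValueError(
            f"mask grid {mask.shape} does not match volume grid {tuple(volume_shape)}"
        )
    return mask.astype(bool)


@dataclass
class FeatureMatrix:
    """Patients x descriptors with explicit normalization state.

    ``values`` is a pandas DataFrame (rows: patient ids, columns: canonical
    descriptor names ``family.params.statistic.compartment``).  Missing values
    (e.g. from an emptied peritumoral ring) are NaN and listed in
    ``missing_flags`` so they are never silent.
    """

    values: "object"  # pandas.DataFrame
    normalization: str = "raw"  # "raw" | "zscored"
    missing_flags: dict = field(default_factory=dict)
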