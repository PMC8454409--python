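"""Intratumoral and peritumoral compartment construction.

The peritumoral region is split into annular rings by thresholding the
spacing-aware Euclidean distance from each voxel to the nearest tumor voxel.
Distance thresholding is equivalent to morphologic dilation with a Euclidean
structuring element but avoids discretization artifacts of an explicit
structuring element on anisotropic grids.

Ring intervals are half-open ``(lo, hi]`` so every peritumoral voxel belongs
to exactly one ring; a distance of exactly 0 mm means the voxel is tumor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import ImageVolume, check_mask

log = logging.getLogger(__name__)

#: Minimum tumor size considered sufficient for texture extraction.
MIN_TUMOR_VOXELS = 200

#: Default HU window used to exclude air / background voxels from rings.
DEFAULT_BODY_HU_RANGE = (-300.0, 3000.0)

COMPARTMENT_LABELS = ("intra", "ring0_5", "ring5_10", "ring10_15")


@dataclass
class QCResult:
    passed: bool
    reason: str | None = None
    voxel_count: int = 0

    def __bool__(self) -> bool:
        return self.passed


def qc_tumor_mask(mask: np.ndarray, min_voxels: int = MIN_TUMOR_VOXELS) -> QCResult:
    """Case-level quality filter: reject tumors too small for extraction.

    A tumor with fewer than ``min_voxels`` voxels (default 200) carries too few
    pixels for stable texture statistics and fails QC.
    """
    mask = check_mask(mask)
    count = int(mask.sum())
    if count == 0:
        return QCResult(False, "empty mask", 0)
    if count < min_voxels:
        return QCResult(False, f"tumor has {count} voxels (< {min_voxels})", count)
    return QCResult(True, None, count)


@dataclass
class CompartmentSet:
    """The intratumoral mask plus disjoint annular ring masks.

    Invariants (asserted on construction): the four masks are pairwise
    disjoint, and the union of the rings is exactly the set of non-tumor
    voxels within ``radii_mm[-1]`` of the tumor surface.
    """

    intratumoral: np.ndarray
    rings: list  # list of boolean masks, inner to outer
    radii_mm: tuple
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        masks = [self.intratumoral] + list(self.rings)
        total = np.zeros(self.intratumoral.shape, dtype=np.int64)
        for m in masks:
            total += m.astype(np.int64)
        if total.max() > 1:
            raise AssertionError("compartment masks are not pairwise disjoint")

    @property
    def labels(self) -> tuple:
        names = ["intra"]
        prev = 0
        for r in self.radii_mm:
            names.append(f"ring{_fmt_mm(prev)}_{_fmt_mm(r)}")
            prev = r
        return tuple(names)

    def as_dict(self) -> dict:
        return dict(zip(self.labels, [self.intratumoral] + list(self.rings)))


def _fmt_mm(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x).replace(".", "p")


def distance_to_tumor(mask: np.ndarray, spacing_mm) -> np.ndarray:
    """Euclidean distance (mm) from each voxel centre to the nearest tumor voxel centre."""
    mask = check_mask(mask)
    if not mask.any():
        raise ValueError("cannot compute distances to an empty mask")
    return ndimage.distance_transform_edt(~mask, sampling=spacing_mm)


def build_ring_masks(
    mask: np.ndarray,
    spacing_mm,
    radii_mm=(5.0, 10.0, 15.0),
    mode: str = "3d",
) -> CompartmentSet:
    """Build the intratumoral compartment and peritumoral ring masks.

    Ring ``k`` contains the voxels whose distance to the nearest tumor voxel
    lies in ``(radii_mm[k-1], radii_mm[k]]`` (with an implicit leading 0).

    Parameters
    ----------
    mode
        ``"3d"`` (default) computes fully three-dimensional distances;
        ``"2d"`` computes in-plane distances slice by slice (slices without
        tumor then have no peritumoral voxels).
    """
    mask = check_mask(mask)
    radii = tuple(float(r) for r in radii_mm)
    if len(radii) == 0 or any(b <= a for a, b in zip((0.0,) + radii, radii)):
        raise ValueError(f"radii must be strictly increasing and positive, got {radii}")
    if mode not in ("3d", "2d"):
        raise ValueError(f"mode must be '3d' or '2d', got {mode!r}")

    if mode == "3d":
        dist = distance_to_tumor(mask, spacing_mm)
    else:
        dist = np.full(mask.shape, np.inf)
        for z in range(mask.shape[2]):
            if mask[:, :, z].any():
                dist[:, :, z] = ndimage.distance_transform_edt(
                    ~mask[:, :, z], sampling=spacing_mm[:2]
                )
    # snap to nanometre precision so voxels exactly on a ring radius fall on
    # the same side regardless of the order of float operations
    dist = np.round(dist, 9)

    rings = []
    prev = 0.0
    for r in radii:
        rings.append((dist > prev) & (dist <= r))
        prev = r

    # Truncation check: the outermost shell touches the grid boundary if any
    # boundary voxel is within the largest radius.
    boundary_within = False
    for axis in range(3):
        for sl in (0, -1):
            idx = [slice(None)] * 3
            idx[axis] = sl
            if np.any(dist[tuple(idx)] < radii[-1]):
                boundary_within = True
    if boundary_within:
        warnings.warn(
            f"peritumoral region truncated at the grid boundary (radius {radii[-1]} mm)",
            stacklevel=2,
        )
        log.warning("ring masks truncated at grid boundary")

    comps = CompartmentSet(
        intratumoral=mask.copy(),
        rings=rings,
        radii_mm=radii,
        provenance={"radii_mm": list(radii), "mode": mode, "spacing_mm": list(spacing_mm)},
    )
    # Coverage invariant: rings tile the non-tumor voxels within the outer radius.
    union = np.zeros(mask.shape, dtype=bool)
    for m in rings:
        union |= m
    expected = (dist > 0) & (dist <= radii[-1])
    if not np.array_equal(union, expected & ~mask):
        raise AssertionError("ring union does not cover the peritumoral shell")
    return comps


def apply_body_mask(
    ring_mask: np.ndarray,
    volume: ImageVolume,
    hu_range=DEFAULT_BODY_HU_RANGE,
) -> np.ndarray:
    """Remove ring voxels whose intensity falls outside the body HU window.

    Peritumoral rings can extend into air (e.g. the airway); texture pooled
    over air voxels is meaningless, so they are excluded by intensity.
    """
    lo, hi = hu_range
    if not lo < hi:
        raise ValueError(f"hu_range must satisfy lo < hi, got {hu_range}")
    ring_mask = check_mask(ring_mask, volume.shape)
    kept = ring_mask & (volume.data >= lo) & (volume.data <= hi)
    if ring_mask.any() and not kept.any():
        warnings.warn("body mask emptied a peritumoral ring entirely", stacklevel=2)
        log.warning("ring emptied by body mask (hu_range=%s)", hu_range)
    return kept


def apply_body_mask_set(
    comps: CompartmentSet, volume: ImageVolume, hu_range=DEFAULT_BODY_HU_RANGE
) -> CompartmentSet:
    """Apply the body HU window to every ring of a CompartmentSet."""
    rings = [apply_body_mask(r, volume, hu_range) for r in comps.rings]
    prov = dict(comps.provenance)
    prov["body_hu_range"] = list(hu_range)
    return CompartmentSet(comps.intratumoral, rings, comps.radii_mm, prov)
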