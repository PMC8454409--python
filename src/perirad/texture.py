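"""Six per-pixel texture-feature families, compartment aggregation, z-scoring.

Families (per-pixel response maps on 2-D slices):

* ``gray``    — local intensity statistics (mean, median, SD, range) in
  windows of 3, 5, 7, 9 pixels: 16 maps.
* ``gradient``— 10 windowed statistics of the intensity gradient field
  per window: 40 maps.
* ``haralick``— 13 co-occurrence (GLCM) metrics per window: 52 maps.
* ``laws``    — the 20 ordered pairs of distinct 1-D Laws kernels
  (levels/edges/spots/waves/ripples): 20 maps.
* ``gabor``   — magnitude responses of zero-mean Gabor filters at 7
  orientations x 4 wavelengths: 28 maps.
* ``collage`` — 13 co-occurrence metrics applied to quantized dominant
  local gradient orientations per window: 52 maps.

Maps are computed slice-wise on the slices containing tumor, pooled over all
pixels of each compartment across those slices, and summarized by five
statistics (mean, median, SD, skewness, excess kurtosis).  Conventions for
degenerate pools (constant or empty) are documented in ``pool_statistics``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gabor_kernel

from .compartments import CompartmentSet
from .core import FeatureMatrix, ImageVolume
from .haralick import METRIC_NAMES, cooccurrence_maps, quantize

STATISTIC_NAMES = ("mean", "median", "std", "skewness", "kurtosis")

FAMILY_NAMES = ("gray", "gradient", "haralick", "laws", "gabor", "collage")

LAWS_KERNELS = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}

#: 22.5 deg steps, as used for oriented filtering of head-and-neck CT.
DEFAULT_GABOR_ORIENTATIONS_DEG = (22.5, 45.0, 67.5, 90.0, 112.5, 135.0, 157.5)
DEFAULT_GABOR_WAVELENGTHS_PX = (2.0, 4.0, 8.0, 12.0)

GRAY_STATS = ("mean", "median", "std", "range")

GRADIENT_MEASURES = (
    "mean_gx", "mean_gy", "std_gx", "std_gy", "mean_mag",
    "std_mag", "range_mag", "mean_abs_gx", "mean_abs_gy", "energy_mag",
)


@dataclass(frozen=True)
class TextureConfig:
    """Feature-vocabulary configuration.

    The default reproduces the per-family map counts 16 + 40 + 52 + 20 + 28
    + 52 = 208; times 5 pooled statistics and 4 compartments this yields a
    4,160-descriptor vocabulary.  ``fast()`` is a reduced desk-scale
    configuration for large simulated cohorts.
    """

    families: tuple = FAMILY_NAMES
    windows: tuple = (3, 5, 7, 9)
    glcm_levels: int = 64
    collage_bins: int = 64
    gabor_orientations_deg: tuple = DEFAULT_GABOR_ORIENTATIONS_DEG
    gabor_wavelengths_px: tuple = DEFAULT_GABOR_WAVELENGTHS_PX
    # quantization range for the intensity GLCM: "crop" (the processed
    # region's range, shared by all compartments) or a fixed (lo, hi) pair
    glcm_range: object = "crop"

    def __post_init__(self):
        for f in self.families:
            if f not in FAMILY_NAMES:
                raise ValueError(f"unknown family {f!r}")
        for w in self.windows:
            if w < 3 or w % 2 == 0:
                raise ValueError(f"windows must be odd and >= 3, got {w}")
        if any(l < 1 for l in self.gabor_wavelengths_px):
            raise ValueError("gabor wavelengths must be >= 1 pixel")

    @classmethod
    def default(cls) -> "TextureConfig":
        return cls()

    @classmethod
    def fast(cls) -> "TextureConfig":
        """Reduced vocabulary for large simulated cohorts on one CPU."""
        return cls(
            families=("gray", "gradient", "collage"),
            windows=(3,),
            glcm_levels=8,
            collage_bins=8,
            gabor_orientations_deg=(22.5, 112.5),
            gabor_wavelengths_px=(2.0, 4.0),
        )

    def map_names(self, family: str) -> list:
        """Deterministic per-family response-map names."""
        if family == "gray":
            return [f"{s}_w{w}" for w in self.windows for s in GRAY_STATS]
        if family == "gradient":
            return [f"{m}_w{w}" for w in self.windows for m in GRADIENT_MEASURES]
        if family in ("haralick", "collage"):
            return [f"{m}_w{w}" for w in self.windows for m in METRIC_NAMES]
        if family == "laws":
            names = list(LAWS_KERNELS)
            return [f"{a}{b}" for a in names for b in names if a != b]
        if family == "gabor":
            return [
                f"t{t:g}_l{l:g}"
                for t in self.gabor_orientations_deg
                for l in self.gabor_wavelengths_px
            ]
        raise ValueError(f"unknown family {family!r}")


def vocabulary(config: TextureConfig, compartments=("intra", "ring0_5", "ring5_10", "ring10_15")) -> list:
    """Full canonical descriptor list ``family.map.statistic.compartment``."""
    names = []
    for fam in config.families:
        for m in config.map_names(fam):
            for stat in STATISTIC_NAMES:
                for comp in compartments:
                    names.append(f"{fam}.{m}.{stat}.{comp}")
    return names


# --------------------------------------------------------------------------
# Window statistic helpers (reflection boundary)
# --------------------------------------------------------------------------

def _win_mean(a, w):
    return ndimage.uniform_filter(a, size=w, mode="reflect")


def _win_std(a, w):
    m = _win_mean(a, w)
    m2 = _win_mean(a * a, w)
    return np.sqrt(np.maximum(m2 - m * m, 0.0))


def _win_range(a, w):
    return ndimage.maximum_filter(a, size=w, mode="reflect") - ndimage.minimum_filter(
        a, size=w, mode="reflect"
    )


# --------------------------------------------------------------------------
# Families
# --------------------------------------------------------------------------

def gray_stats_maps(slice2d: np.ndarray, windows=(3, 5, 7, 9)) -> dict:
    """Local intensity mean / median / SD / range per window."""
    a = _check_slice(slice2d, max(windows))
    out = {}
    for w in windows:
        out[f"mean_w{w}"] = _win_mean(a, w)
        out[f"median_w{w}"] = ndimage.median_filter(a, size=w, mode="reflect")
        out[f"std_w{w}"] = _win_std(a, w)
        out[f"range_w{w}"] = _win_range(a, w)
    return out


def gradient_maps(slice2d: np.ndarray, windows=(3, 5, 7, 9)) -> dict:
    """Windowed statistics of the in-plane intensity gradient field.

    The 10 measures per window are the window mean and SD of each gradient
    component, the mean/SD/range/energy of the gradient magnitude, and the
    mean absolute value of each component.  All are invariant to adding a
    constant to the slice; on a constant slice every map is 0.
    """
    a = _check_slice(slice2d, max(windows))
    gx, gy = np.gradient(a)
    mag = np.hypot(gx, gy)
    out = {}
    for w in windows:
        out[f"mean_gx_w{w}"] = _win_mean(gx, w)
        out[f"mean_gy_w{w}"] = _win_mean(gy, w)
        out[f"std_gx_w{w}"] = _win_std(gx, w)
        out[f"std_gy_w{w}"] = _win_std(gy, w)
        out[f"mean_mag_w{w}"] = _win_mean(mag, w)
        out[f"std_mag_w{w}"] = _win_std(mag, w)
        out[f"range_mag_w{w}"] = _win_range(mag, w)
        out[f"mean_abs_gx_w{w}"] = _win_mean(np.abs(gx), w)
        out[f"mean_abs_gy_w{w}"] = _win_mean(np.abs(gy), w)
        out[f"energy_mag_w{w}"] = _win_mean(mag * mag, w)
    return out


def haralick_maps(
    slice2d: np.ndarray,
    windows=(3, 5, 7, 9),
    n_levels: int = 64,
    intensity_range=None,
    pixel_mask=None,
) -> dict:
    """Per-pixel GLCM co-occurrence metrics per window (13 x windows maps)."""
    a = _check_slice(slice2d, max(windows))
    lo, hi = (None, None) if intensity_range is None else intensity_range
    codes = quantize(a, n_levels, lo, hi)
    out = {}
    for w in windows:
        maps = cooccurrence_maps(codes, n_levels, w, pixel_mask=pixel_mask)
        for m, v in maps.items():
            out[f"{m}_w{w}"] = v
    return out


def laws_maps(slice2d: np.ndarray) -> dict:
    """Separable 2-D Laws filters: the 20 ordered pairs of distinct kernels.

    Name ``AB`` applies kernel A along axis 0 and B along axis 1.  Every pair
    contains at least one zero-sum kernel, so all responses vanish on a
    constant slice.
    """
    a = _check_slice(slice2d, 5)
    out = {}
    for na, ka in LAWS_KERNELS.items():
        along0 = ndimage.convolve1d(a, ka, axis=0, mode="reflect")
        for nb, kb in LAWS_KERNELS.items():
            if na == nb:
                continue
            out[f"{na}{nb}"] = ndimage.convolve1d(along0, kb, axis=1, mode="reflect")
    return out


@lru_cache(maxsize=64)
def _gabor_kernel_cached(wavelength: float, theta_deg: float):
    k = gabor_kernel(frequency=1.0 / wavelength, theta=np.deg2rad(theta_deg))
    k = np.asarray(k)
    return k - k.mean()  # zero-mean: no response to constant input


def gabor_maps(
    slice2d: np.ndarray,
    orientations_deg=DEFAULT_GABOR_ORIENTATIONS_DEG,
    wavelengths_px=DEFAULT_GABOR_WAVELENGTHS_PX,
) -> dict:
    """Magnitude responses of zero-mean Gabor filters (orientation x scale)."""
    if len(orientations_deg) == 0 or len(wavelengths_px) == 0:
        raise ValueError("orientation and wavelength grids must be nonempty")
    if any(l < 1 for l in wavelengths_px):
        raise ValueError("gabor wavelength below 1 pixel")
    a = _check_slice(slice2d, 3)
    out = {}
    for t in orientations_deg:
        for l in wavelengths_px:
            k = _gabor_kernel_cached(float(l), float(t))
            re = ndimage.convolve(a, k.real, mode="reflect")
            im = ndimage.convolve(a, k.imag, mode="reflect")
            out[f"t{t:g}_l{l:g}"] = np.hypot(re, im)
    return out


def dominant_orientation(slice2d: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel dominant gradient orientation in [0, pi) and gradient energy.

    The orientation of the principal singular vector of the stacked window
    gradients equals the principal eigenvector of the windowed structure
    tensor, computed here in closed form.
    """
    a = np.asarray(slice2d, dtype=np.float64)
    gx, gy = np.gradient(a)
    jxx = _win_mean(gx * gx, window)
    jxy = _win_mean(gx * gy, window)
    jyy = _win_mean(gy * gy, window)
    theta = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)
    theta = np.mod(theta, np.pi)
    energy = jxx + jyy
    return theta, energy


def collage_maps(slice2d: np.ndarray, windows=(3, 5, 7, 9), n_bins: int = 64, pixel_mask=None) -> dict:
    """Co-occurrence metrics of quantized dominant gradient orientations.

    Windows with no gradient energy have an undefined orientation; they are
    assigned bin 0 (documented convention).
    """
    a = _check_slice(slice2d, max(windows))
    out = {}
    for w in windows:
        theta, energy = dominant_orientation(a, w)
        bins = np.minimum((theta / np.pi * n_bins).astype(np.int64), n_bins - 1)
        bins[energy <= 1e-12] = 0
        maps = cooccurrence_maps(bins, n_bins, w, pixel_mask=pixel_mask)
        for m, v in maps.items():
            out[f"{m}_w{w}"] = v
    return out


def _check_slice(slice2d, min_size) -> np.ndarray:
    a = np.asarray(slice2d, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D slice, got shape {a.shape}")
    if min(a.shape) < min_size:
        raise ValueError(f"window {min_size} larger than slice {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("slice contains non-finite values")
    return a


def family_maps(
    family: str,
    slice2d: np.ndarray,
    config: TextureConfig,
    intensity_range=None,
    pixel_mask=None,
) -> dict:
    """Dispatch one family's response maps for one slice.

    ``pixel_mask`` restricts the expensive co-occurrence families to the
    pixels that will actually be pooled.
    """
    if family == "gray":
        return gray_stats_maps(slice2d, config.windows)
    if family == "gradient":
        return gradient_maps(slice2d, config.windows)
    if family == "haralick":
        rng = None if config.glcm_range == "crop" else config.glcm_range
        rng = intensity_range if (config.glcm_range == "crop") else rng
        return haralick_maps(slice2d, config.windows, config.glcm_levels, rng, pixel_mask=pixel_mask)
    if family == "laws":
        return laws_maps(slice2d)
    if family == "gabor":
        return gabor_maps(slice2d, config.gabor_orientations_deg, config.gabor_wavelengths_px)
    if family == "collage":
        return collage_maps(slice2d, config.windows, config.collage_bins, pixel_mask=pixel_mask)
    raise ValueError(f"unknown family {family!r}")


# --------------------------------------------------------------------------
# Aggregation
# --------------------------------------------------------------------------

def pool_statistics(pool: np.ndarray) -> dict:
    """Five statistics of a pooled pixel sample.

    Conventions: population SD (ddof=0); Fisher-Pearson skewness and excess
    kurtosis (both biased, i.e. the plain moment estimators); a constant pool
    has SD 0, skewness 0, and excess kurtosis 0; an empty pool yields NaN for
    all five statistics.
    """
    pool = np.asarray(pool, dtype=np.float64).ravel()
    if pool.size == 0:
        return {s: np.nan for s in STATISTIC_NAMES}
    if np.all(pool == pool[0]):  # exactly constant, before float round-off
        return {"mean": float(pool[0]), "median": float(pool[0]),
                "std": 0.0, "skewness": 0.0, "kurtosis": 0.0}
    mean = pool.mean()  # direct moment estimators; scipy's wrappers are too
    d = pool - mean     # slow for ~10^3 calls per case
    m2 = np.mean(d * d)
    sd = float(np.sqrt(m2))
    if sd == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(np.mean(d**3) / m2**1.5)
        kurt = float(np.mean(d**4) / (m2 * m2) - 3.0)
    return {
        "mean": float(pool.mean()),
        "median": float(np.median(pool)),
        "std": sd,
        "skewness": skew,
        "kurtosis": kurt,
    }


def _pool_statistics_rows(arr: np.ndarray) -> np.ndarray:
    """Vectorized :func:`pool_statistics` over the rows of ``(n_maps, n_px)``.

    Returns an array of shape ``(n_maps, 5)`` in ``STATISTIC_NAMES`` order.
    """
    mean = arr.mean(axis=1)
    med = np.median(arr, axis=1)
    constant = (arr.max(axis=1) - arr.min(axis=1)) == 0
    mean = np.where(constant, arr[:, 0], mean)
    d = arr - mean[:, None]
    d2 = d * d
    m2 = d2.mean(axis=1)
    m3 = (d2 * d).mean(axis=1)
    m4 = (d2 * d2).mean(axis=1)
    sd = np.where(constant, 0.0, np.sqrt(m2))
    safe = np.where(m2 > 0, m2, 1.0)
    skew = np.where(sd > 0, m3 / (safe * np.sqrt(safe)), 0.0)
    kurt = np.where(sd > 0, m4 / (safe * safe) - 3.0, 0.0)
    return np.column_stack([mean, med, sd, skew, kurt])


def aggregate_compartment(maps: dict, compartment_mask: np.ndarray) -> dict:
    """Pool each response map over the compartment pixels and summarize.

    ``maps`` values and the mask must share one 2-D grid; for multi-slice
    pooling use :func:`extract_features`, which concatenates pixel pools
    across the tumor-bearing slices before summarizing.
    """
    mask = np.asarray(compartment_mask, dtype=bool)
    out = {}
    for name, m in maps.items():
        if m.shape != mask.shape:
            raise ValueError(f"map {name!r} shape {m.shape} != mask {mask.shape}")
        st = pool_statistics(m[mask])
        for s, v in st.items():
            out[f"{name}.{s}"] = v
    return out


def extract_features(
    volume: ImageVolume,
    comps: CompartmentSet,
    config: TextureConfig | None = None,
) -> pd.Series:
    """Evaluate the full descriptor vocabulary on one case.

    Maps are computed slice-wise on the slices that contain tumor, on a
    bounding box around the dilated (tumor + rings) region padded by the
    largest window half-width; pooled pixels always come from real voxels,
    never from boundary padding.  Returns a Series indexed by the canonical
    descriptor names; compartments that are empty on the tumor-bearing
    slices yield NaN (and a warning), never silent omissions.
    """
    config = config or TextureConfig.default()
    comp_masks = comps.as_dict()
    comp_labels = list(comp_masks)
    union = np.zeros(volume.shape, dtype=bool)
    for m in comp_masks.values():
        union |= m
    tumor_z = np.where(comps.intratumoral.any(axis=(0, 1)))[0]
    if len(tumor_z) == 0:
        raise ValueError("tumor mask is empty")

    pad = max(config.windows) // 2 + 1
    xs, ys = np.where(union.any(axis=2))[0], np.where(union.any(axis=(0, 2)))[0]
    x0, x1 = max(xs.min() - pad, 0), min(xs.max() + 1 + pad, volume.shape[0])
    y0, y1 = max(ys.min() - pad, 0), min(ys.max() + 1 + pad, volume.shape[1])

    full_names = [(fam, m) for fam in config.families for m in config.map_names(fam)]
    blocks: dict = {comp: [] for comp in comp_labels}
    for z in tumor_z:
        crop = np.asarray(volume.data[x0:x1, y0:y1, z], dtype=np.float64)
        irange = (float(crop.min()), float(crop.max()))
        union2d = union[x0:x1, y0:y1, z]
        map_list = []
        for fam in config.families:
            maps = family_maps(fam, crop, config, intensity_range=irange, pixel_mask=union2d)
            map_list.extend(maps[m] for m in config.map_names(fam))
        stacked = np.stack(map_list)  # (n_maps, H, W)
        for comp in comp_labels:
            cmask = comp_masks[comp][x0:x1, y0:y1, z]
            if cmask.any():
                blocks[comp].append(stacked[:, cmask])

    values = {}
    empty_comps = []
    for comp in comp_labels:
        if blocks[comp]:
            st = _pool_statistics_rows(np.concatenate(blocks[comp], axis=1))
        else:
            st = np.full((len(full_names), len(STATISTIC_NAMES)), np.nan)
            empty_comps.append(comp)
        for (fam, mname), row in zip(full_names, st):
            for s, v in zip(STATISTIC_NAMES, row):
                values[f"{fam}.{mname}.{s}.{comp}"] = float(v)
    if empty_comps:
        warnings.warn(
            f"compartments empty on tumor-bearing slices, features set to NaN: "
            f"{sorted(empty_comps)}",
            stacklevel=2,
        )
    order = vocabulary(config, compartments=tuple(comp_labels))
    return pd.Series(values, dtype=float).reindex(order)


def extract_feature_matrix(cases, config: TextureConfig | None = None) -> FeatureMatrix:
    """Extract features for an iterable of ``(patient_id, volume, comps)``."""
    rows, index = [], []
    for pid, vol, comps in cases:
        rows.append(extract_features(vol, comps, config))
        index.append(pid)
    df = pd.DataFrame(rows, index=index)
    flags = {
        pid: list(df.columns[df.loc[pid].isna()]) for pid in index if df.loc[pid].isna().any()
    }
    return FeatureMatrix(values=df, normalization="raw", missing_flags=flags)


# --------------------------------------------------------------------------
# z-scoring
# --------------------------------------------------------------------------

@dataclass
class ZScoreParams:
    mu: pd.Series
    sigma: pd.Series
    zero_sd_columns: list = field(default_factory=list)


def zscore_fit(train: pd.DataFrame) -> ZScoreParams:
    """Fit per-column z-score parameters (population SD) on training data."""
    if len(train) < 2:
        raise ValueError("z-scoring needs at least 2 training rows")
    mu = train.mean(axis=0)
    sigma = train.std(axis=0, ddof=0)
    zero = list(sigma.index[sigma == 0])
    if zero:
        warnings.warn(f"{len(zero)} constant column(s) flagged during z-scoring", stacklevel=2)
    return ZScoreParams(mu=mu, sigma=sigma, zero_sd_columns=zero)


def zscore_apply(params: ZScoreParams, matrix: pd.DataFrame) -> pd.DataFrame:
    """Apply training z-score parameters; zero-SD columns map to 0."""
    sigma = params.sigma.replace(0.0, np.nan)
    out = (matrix - params.mu) / sigma
    out[params.zero_sd_columns] = 0.0
    return out
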