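"""Synthetic CT-like phantoms with planted texture phenotypes and survival.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without clinical data:

* an ellipsoidal "tumor" on an anisotropic grid (default 1 x 1 x 2.5 mm);
* two texture phenotypes: ``pos`` (HPV+ analog) is a smooth, long-range
  correlated Gaussian random field inside the tumor and its rim, while
  ``neg`` (HPV- analog) has shorter correlation, higher variance and an
  oriented-ripple component with per-patch random orientation in the
  0-10 mm rim, so that co-occurrence-correlation and gradient-orientation
  disorder features separate the classes;
* clinical covariates drawn from configurable frequency tables modeled on an
  oropharyngeal-cancer cohort;
* censored survival times whose hazard depends on planted texture summaries
  of each phantom through stated coefficients.

All randomness derives from one root seed through named substreams.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ImageVolume, check_mask
from .compartments import distance_to_tumor


# --------------------------------------------------------------------------
# Seeding
# --------------------------------------------------------------------------

def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible RNG substream derived from one root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


# --------------------------------------------------------------------------
# Phantom specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TextureParams:
    """Per-class texture parameters.

    corr_length_mm
        Gaussian-random-field correlation length (the smoothing sigma), mm.
    noise_sd
        Marginal SD of the random field, HU.  With ``noise_sd == 0`` and
        ``ripple_amplitude == 0`` the tumor region is exactly constant.
    ripple_amplitude
        Amplitude (HU) of the oriented sinusoidal ripple added in the
        0-10 mm rim; orientation is randomized per in-plane patch, which is
        what makes gradient-orientation disorder features fire.
    """

    corr_length_mm: float = 3.0
    noise_sd: float = 10.0
    ripple_amplitude: float = 0.0
    ripple_wavelength_mm: float = 4.0
    ripple_patch_mm: float = 8.0


#: Default phenotypes: the positive class is homogeneous / highly pixel
#: correlated; the negative class is heterogeneous with disordered rim
#: gradient orientations.
POS_TEXTURE = TextureParams(corr_length_mm=3.0, noise_sd=8.0, ripple_amplitude=4.0)
NEG_TEXTURE = TextureParams(corr_length_mm=1.8, noise_sd=16.0, ripple_amplitude=12.0)

#: Margin (mm) required between the tumor surface and the grid edge so the
#: 15-mm peritumoral shell fits, with 1 mm slack for voxelization.
REQUIRED_MARGIN_MM = 16.0


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple = (64, 64, 16)
    spacing_mm: tuple = (1.0, 1.0, 2.5)
    tumor_axes_mm: tuple = (10.0, 8.0, 4.0)
    class_label: str = "pos"
    texture: TextureParams = field(default_factory=lambda: POS_TEXTURE)
    tumor_mean: float = 80.0
    background_level: float = 40.0
    seed: int = 0

    def validate(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise ValueError(f"grid_shape axes must all be >= 8, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if self.class_label not in ("pos", "neg"):
            raise ValueError(f"class_label must be 'pos' or 'neg', got {self.class_label!r}")
        for n, sp, ax in zip(self.grid_shape, self.spacing_mm, self.tumor_axes_mm):
            half_extent = n * sp / 2.0
            if ax + REQUIRED_MARGIN_MM > half_extent:
                raise ValueError(
                    f"tumor semi-axis {ax} mm does not fit: needs "
                    f"{ax + REQUIRED_MARGIN_MM} mm half-extent but the grid "
                    f"provides {half_extent} mm on that axis"
                )


def _grid_coords_mm(shape, spacing):
    """Per-axis voxel-centre coordinates (mm), centred on the grid middle."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * sp for n, sp in zip(shape, spacing)
    ]


def _grf(shape, spacing, corr_length_mm, rng) -> np.ndarray:
    """Unit-variance Gaussian random field with given correlation length.

    White noise smoothed by a Gaussian kernel, normalized analytically by the
    kernel l2 norm so the marginal variance is exactly 1 regardless of the
    correlation length.
    """
    white = rng.standard_normal(shape)
    sigmas = [corr_length_mm / sp for sp in spacing]
    if all(s < 1e-12 for s in sigmas):
        return white
    smooth = ndimage.gaussian_filter(white, sigma=sigmas, mode="wrap")
    # l2 norm of the separable kernel, computed per axis from an impulse
    norm2 = 1.0
    for n, s in zip(shape, sigmas):
        imp = np.zeros(max(n, int(8 * s) + 9))
        imp[len(imp) // 2] = 1.0
        k = ndimage.gaussian_filter1d(imp, sigma=s, mode="constant")
        norm2 *= float(np.sum(k**2))
    return smooth / np.sqrt(norm2)


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, np.ndarray]:
    """Generate one phantom volume and its ellipsoidal tumor mask."""
    spec.validate()
    coords = _grid_coords_mm(spec.grid_shape, spec.spacing_mm)
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    a, b, c = spec.tumor_axes_mm
    mask = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    if not mask.any():
        raise ValueError("tumor ellipsoid contains no voxels on this grid")

    dist = distance_to_tumor(mask, spec.spacing_mm)
    rim10 = (dist > 0) & (dist <= 10.0)
    textured = mask | rim10

    vol = np.full(spec.grid_shape, spec.background_level, dtype=np.float64)
    vol[mask] = spec.tumor_mean

    tp = spec.texture
    if tp.noise_sd > 0:
        rng_tex = substream(spec.seed, "texture")
        field3d = _grf(spec.grid_shape, spec.spacing_mm, tp.corr_length_mm, rng_tex)
        vol[textured] += tp.noise_sd * field3d[textured]

    if tp.ripple_amplitude > 0:
        rng_rip = substream(spec.seed, "ripple")
        nxp = max(1, int(np.ceil(spec.grid_shape[0] * spec.spacing_mm[0] / tp.ripple_patch_mm)))
        nyp = max(1, int(np.ceil(spec.grid_shape[1] * spec.spacing_mm[1] / tp.ripple_patch_mm)))
        thetas = rng_rip.uniform(0.0, np.pi, size=(nxp, nyp))
        phases = rng_rip.uniform(0.0, 2 * np.pi, size=(nxp, nyp))
        px = np.minimum((X[:, :, 0] - X.min()) // tp.ripple_patch_mm, nxp - 1).astype(int)
        py = np.minimum((Y[:, :, 0] - Y.min()) // tp.ripple_patch_mm, nyp - 1).astype(int)
        th, ph = thetas[px, py], phases[px, py]
        wave2d = np.sin(
            2 * np.pi * (X[:, :, 0] * np.cos(th) + Y[:, :, 0] * np.sin(th))
            / tp.ripple_wavelength_mm
            + ph
        )
        vol += tp.ripple_amplitude * wave2d[:, :, None] * rim10

    volume = ImageVolume(vol.astype(np.float32), spec.spacing_mm)
    return volume, mask


# --------------------------------------------------------------------------
# Survival simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalParams:
    """Exponential (or Weibull) proportional-hazards survival model.

    baseline_scale
        Scale (years) of the baseline time distribution; with shape 1 and a
        zero linear predictor the mean event time equals this value.
    censor_rate
        Target probability of censoring before the event for a baseline
        subject; censoring times are independent exponentials.
    weibull_shape
        Weibull shape k (1 = exponential), hazard remains proportional to
        ``exp(linear_predictor)``.
    """

    baseline_scale: float = 6.0
    censor_rate: float = 0.5
    weibull_shape: float = 1.0


def simulate_survival(
    linear_predictor,
    baseline_scale: float = 6.0,
    censor_rate: float = 0.5,
    seed: int = 0,
    weibull_shape: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (time, event) per subject under a proportional-hazards model.

    Event times follow a Weibull PH model with hazard proportional to
    ``exp(linear_predictor)``; censoring is an independent exponential whose
    rate is calibrated so a baseline subject is censored with probability
    ``censor_rate``.  Observed time is the minimum; the event flag is 1 when
    the event precedes censoring.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor contains non-finite values")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError(f"censor_rate must be in [0, 1), got {censor_rate}")
    if baseline_scale <= 0 or weibull_shape <= 0:
        raise ValueError("baseline_scale and weibull_shape must be positive")

    rng = substream(seed, "survival")
    e = rng.exponential(1.0, size=lp.shape)
    t_event = baseline_scale * (e / np.exp(lp)) ** (1.0 / weibull_shape)
    if censor_rate == 0.0:
        return t_event, np.ones(lp.shape, dtype=int)
    # For shape 1 and lp = 0: P(censor first) = rc / (rc + 1/scale).
    rate_c = (censor_rate / (1.0 - censor_rate)) / baseline_scale
    t_cens = rng.exponential(1.0 / rate_c, size=lp.shape)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


# --------------------------------------------------------------------------
# Clinical covariates
# --------------------------------------------------------------------------

#: Marginal covariate frequencies per phenotype, modeled on the training-split
#: demographics of an oropharyngeal-cancer cohort.
COVARIATE_TABLES = {
    "pos": {
        "gender": {"male": 0.82, "female": 0.18},
        "smoking": {"never": 0.41, "former": 0.39, "current": 0.20},
        "drinking": {"light": 0.82, "former": 0.06, "heavy": 0.12},
        "t_stage": {"T1": 0.23, "T2": 0.36, "T3": 0.30, "T4": 0.11},
        "n_stage": {"N0": 0.13, "N1": 0.53, "N2": 0.27, "N3": 0.07},
        "ajcc_stage": {"I": 0.42, "II": 0.41, "III": 0.17},
    },
    "neg": {
        "gender": {"male": 0.725, "female": 0.275},
        "smoking": {"never": 0.063, "former": 0.375, "current": 0.562},
        "drinking": {"light": 0.488, "former": 0.112, "heavy": 0.40},
        "t_stage": {"T1": 0.087, "T2": 0.288, "T3": 0.375, "T4": 0.25},
        "n_stage": {"N0": 0.287, "N1": 0.40, "N2": 0.238, "N3": 0.075},
        "ajcc_stage": {"I": 0.275, "II": 0.40, "III": 0.325},
    },
}

CLINICAL_COLUMNS = (
    "patient_id", "hpv_status", "gender", "smoking", "drinking",
    "t_stage", "n_stage", "ajcc_stage", "age", "time_years", "event",
)


def _sample_categorical(rng, table: dict, n: int) -> np.ndarray:
    levels = list(table)
    p = np.array([table[k] for k in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=n, p=p)


# --------------------------------------------------------------------------
# Planted texture summaries
# --------------------------------------------------------------------------

def _tumor_mean_intensity(vol, mask, dist):
    return float(vol.data[mask].mean())


def _tumor_intensity_sd(vol, mask, dist):
    return float(vol.data[mask].std())


def _rim_intensity_sd(vol, mask, dist):
    rim = (dist > 0) & (dist <= 10.0)
    return float(vol.data[rim].std()) if rim.any() else 0.0


def _tumor_volume_mm3(vol, mask, dist):
    return float(mask.sum() * np.prod(vol.spacing_mm))


def _neighbor_correlation(data: np.ndarray, region: np.ndarray) -> float:
    """In-plane lag-1 neighbor correlation of intensities within a region."""
    a_list, b_list = [], []
    for axis in (0, 1):
        sl1 = [slice(None)] * 3
        sl2 = [slice(None)] * 3
        sl1[axis] = slice(None, -1)
        sl2[axis] = slice(1, None)
        both = region[tuple(sl1)] & region[tuple(sl2)]
        a_list.append(data[tuple(sl1)][both])
        b_list.append(data[tuple(sl2)][both])
    a = np.concatenate(a_list)
    b = np.concatenate(b_list)
    if a.size < 10 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _tumor_neighbor_correlation(vol, mask, dist):
    return _neighbor_correlation(np.asarray(vol.data, dtype=np.float64), mask)


def _rim_neighbor_correlation(vol, mask, dist):
    rim = (dist > 0) & (dist <= 10.0)
    return _neighbor_correlation(np.asarray(vol.data, dtype=np.float64), rim)


#: Scalar image summaries the survival hazard may be planted on.
SUMMARY_FUNCTIONS = {
    "tumor_mean_intensity": _tumor_mean_intensity,
    "tumor_intensity_sd": _tumor_intensity_sd,
    "rim_intensity_sd": _rim_intensity_sd,
    "tumor_volume_mm3": _tumor_volume_mm3,
    "tumor_neighbor_correlation": _tumor_neighbor_correlation,
    "rim_neighbor_correlation": _rim_neighbor_correlation,
}


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

@dataclass
class Patient:
    patient_id: str
    volume: ImageVolume
    mask: np.ndarray
    clinical: dict
    summaries: dict


@dataclass
class CohortBundle:
    patients: list
    seed: int
    planted_effects: dict
    survival: SurvivalParams

    def clinical_frame(self) -> pd.DataFrame:
        rows = [p.clinical for p in self.patients]
        return pd.DataFrame(rows, columns=list(CLINICAL_COLUMNS))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [p.summaries for p in self.patients],
            index=[p.patient_id for p in self.patients],
        )

    def save(self, outdir) -> None:
        from . import io as _io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for p in self.patients:
            _io.write_volume(outdir / f"{p.patient_id}_image.nii.gz", p.volume)
            _io.write_mask(outdir / f"{p.patient_id}_mask.nii.gz", p.mask, p.volume.spacing_mm)
        self.clinical_frame().to_csv(outdir / "clinical.csv", index=False)
        meta = {
            "seed": self.seed,
            "planted_effects": self.planted_effects,
            "survival": asdict(self.survival),
            "patient_ids": [p.patient_id for p in self.patients],
        }
        (outdir / "cohort.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, outdir) -> "CohortBundle":
        from . import io as _io

        outdir = Path(outdir)
        meta = json.loads((outdir / "cohort.json").read_text())
        clin = _io.read_clinical(outdir / "clinical.csv")
        patients = []
        for pid in meta["patient_ids"]:
            vol = _io.read_volume(outdir / f"{pid}_image.nii.gz")
            mask = _io.read_mask(outdir / f"{pid}_mask.nii.gz")
            row = clin.loc[clin.patient_id == pid].iloc[0].to_dict()
            patients.append(Patient(pid, vol, check_mask(mask, vol.shape), row, {}))
        return cls(
            patients=patients,
            seed=meta["seed"],
            planted_effects=meta["planted_effects"],
            survival=SurvivalParams(**meta["survival"]),
        )


@dataclass(frozen=True)
class CohortHeterogeneity:
    """Per-patient jitter applied to phantom parameters.

    Without patient-to-patient variation every planted summary would be a
    constant and no prognostic signal could exist; the defaults give the
    planted summaries a realistic spread.
    """

    noise_sd_log_sd: float = 0.25
    corr_length_log_sd: float = 0.15
    tumor_mean_sd: float = 6.0
    axis_scale_range: tuple = (0.85, 1.15)


def generate_cohort(
    n_pos: int,
    n_neg: int,
    planted_effects: dict | None = None,
    survival_params: SurvivalParams | None = None,
    seed: int = 0,
    grid_shape=(64, 64, 16),
    spacing_mm=(1.0, 1.0, 2.5),
    tumor_axes_mm=(10.0, 8.0, 4.0),
    pos_texture: TextureParams = POS_TEXTURE,
    neg_texture: TextureParams = NEG_TEXTURE,
    pos_tumor_mean: float = 90.0,
    neg_tumor_mean: float = 78.0,
    heterogeneity: CohortHeterogeneity = CohortHeterogeneity(),
    covariate_tables: dict | None = None,
    id_prefix: str = "P",
    patient_hook=None,
    keep_volumes: bool = True,
) -> CohortBundle:
    """Generate a cohort of phantoms with covariates and planted survival.

    ``planted_effects`` maps summary names (keys of ``SUMMARY_FUNCTIONS``) to
    log-hazard-ratio coefficients per SD of that summary across the cohort.

    ``patient_hook(patient_id, volume, mask)`` is called for every patient as
    it is generated (e.g. to extract features on the fly); with
    ``keep_volumes=False`` the image is then dropped to keep large cohorts
    memory-light (the bundle is no longer savable).
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must both be >= 1")
    planted_effects = dict(planted_effects or {})
    for name in planted_effects:
        if name not in SUMMARY_FUNCTIONS:
            raise KeyError(
                f"unknown planted-effect summary {name!r}; known: {sorted(SUMMARY_FUNCTIONS)}"
            )
    survival_params = survival_params or SurvivalParams()
    covariate_tables = covariate_tables or COVARIATE_TABLES

    rng_geom = substream(seed, "geometry")
    rng_cov = substream(seed, "covariates")
    labels = ["pos"] * n_pos + ["neg"] * n_neg
    n = len(labels)

    patients = []
    for i, lab in enumerate(labels):
        tex = pos_texture if lab == "pos" else neg_texture
        mean = pos_tumor_mean if lab == "pos" else neg_tumor_mean
        ax_scale = rng_geom.uniform(*heterogeneity.axis_scale_range)
        # Largest semi-axes that still leave the 15-mm shell inside the grid.
        ax_max = [
            n * sp / 2.0 - REQUIRED_MARGIN_MM
            for n, sp in zip(grid_shape, spacing_mm)
        ]
        jitter_sd = float(np.exp(rng_geom.normal(0.0, heterogeneity.noise_sd_log_sd)))
        jitter_cl = float(np.exp(rng_geom.normal(0.0, heterogeneity.corr_length_log_sd)))
        jitter_mean = float(rng_geom.normal(0.0, heterogeneity.tumor_mean_sd))
        tex_i = TextureParams(
            corr_length_mm=tex.corr_length_mm * jitter_cl,
            noise_sd=tex.noise_sd * jitter_sd,
            ripple_amplitude=tex.ripple_amplitude * jitter_sd,
            ripple_wavelength_mm=tex.ripple_wavelength_mm,
            ripple_patch_mm=tex.ripple_patch_mm,
        )
        spec = PhantomSpec(
            grid_shape=tuple(grid_shape),
            spacing_mm=tuple(spacing_mm),
            tumor_axes_mm=tuple(
                min(a * ax_scale, mx) for a, mx in zip(tumor_axes_mm, ax_max)
            ),
            class_label=lab,
            texture=tex_i,
            tumor_mean=mean + jitter_mean,
            seed=int(rng_geom.integers(0, 2**31 - 1)),
        )
        vol, mask = generate_phantom(spec)
        dist = distance_to_tumor(mask, spec.spacing_mm)
        summaries = {
            name: fn(vol, mask, dist) for name, fn in SUMMARY_FUNCTIONS.items()
        }
        pid = f"{id_prefix}{i:04d}"
        if patient_hook is not None:
            patient_hook(pid, vol, mask)
        if not keep_volumes:
            vol, mask = None, None
        patients.append(Patient(pid, vol, mask, {}, summaries))

    # Hazard from planted summaries.  Coefficients are log hazard ratios per
    # *within-class* SD of the summary, so each phenotype arm sees the stated
    # effect size regardless of the between-class summary gap.
    lp = np.zeros(n)
    summ = pd.DataFrame([p.summaries for p in patients])
    lab_arr = np.asarray(labels)
    for name, coef in planted_effects.items():
        col = summ[name].to_numpy(dtype=float)
        for lab in ("pos", "neg"):
            cls = lab_arr == lab
            sd = col[cls].std()
            if sd > 0:
                lp[cls] += coef * (col[cls] - col[cls].mean()) / sd
    time, event = simulate_survival(
        lp,
        baseline_scale=survival_params.baseline_scale,
        censor_rate=survival_params.censor_rate,
        seed=int(substream(seed, "survival-seed").integers(0, 2**31 - 1)),
        weibull_shape=survival_params.weibull_shape,
    )

    for lab in ("pos", "neg"):
        idx = [i for i, l in enumerate(labels) if l == lab]
        tables = covariate_tables[lab]
        cov = {k: _sample_categorical(rng_cov, tbl, len(idx)) for k, tbl in tables.items()}
        age_mu = 60.4 if lab == "pos" else 65.5
        age_sd = 9.1 if lab == "pos" else 10.4
        ages = rng_cov.normal(age_mu, age_sd, size=len(idx))
        for j, i in enumerate(idx):
            patients[i].clinical = {
                "patient_id": patients[i].patient_id,
                "hpv_status": lab,
                "gender": cov["gender"][j],
                "smoking": cov["smoking"][j],
                "drinking": cov["drinking"][j],
                "t_stage": cov["t_stage"][j],
                "n_stage": cov["n_stage"][j],
                "ajcc_stage": cov["ajcc_stage"][j],
                "age": round(float(ages[j]), 1),
                "time_years": float(time[i]),
                "event": int(event[i]),
            }

    return CohortBundle(patients, seed, planted_effects, survival_params)
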