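"""Pipeline orchestration: the three experiments on simulated cohorts.

* ``exp1_hpv``       — phenotype (HPV-status analog) classification:
  pruning, repeated-CV MRMR selection, LDA, ROC on training and validation.
* ``exp2_prognosis`` — LASSO-Cox risk scores per phenotype, median-split
  Kaplan-Meier / log-rank / HR, stage-stratified analysis, univariable
  screening into a multivariable Cox model.
* ``exp3_nomogram``  — clinical (M_c), pathologic (M_p), and radiomic
  (M_p+RRS) nomograms compared by concordance, calibration, and net benefit.

``run_experiment`` is deterministic given its config and writes a
machine-readable JSON summary (plus CSV tables) when an output directory is
given; every output directory carries the exact config and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as _io
from .compartments import apply_body_mask_set, build_ring_masks, qc_tumor_mask
from .core import FeatureMatrix
from .hpv import evaluate_roc, prune_correlated, select_top_features, train_lda
from .nomogram import (
    bootstrap_cindex,
    build_nomogram,
    c_index,
    calibration_curve,
    decision_curve,
)
from .phantoms import SurvivalParams, generate_cohort, substream
from .survival import (
    RiskModel,
    compare_risk_groups,
    compute_rrs,
    lasso_cox,
    median_split,
    screen_then_multivariable,
    stratified_km,
)
from .texture import TextureConfig, extract_features, zscore_apply, zscore_fit

EXPERIMENTS = ("exp1_hpv", "exp2_prognosis", "exp3_nomogram")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one experiment run."""

    experiment: str = "exp1_hpv"
    seed: int = 0
    # cohort sizes: training 100 pos / 80 neg, validation 237 pos / 45 neg
    n_train_pos: int = 100
    n_train_neg: int = 80
    n_val_pos: int = 237
    n_val_neg: int = 45
    grid_shape: tuple = (64, 64, 16)
    spacing_mm: tuple = (1.0, 1.0, 2.5)
    ring_radii_mm: tuple = (5.0, 10.0, 15.0)
    body_hu_range: tuple = (-300.0, 3000.0)
    texture: TextureConfig = field(default_factory=TextureConfig.fast)
    # prognostic effect planted on the peritumoral (0-10 mm rim) intensity
    # SD: texture amplitude is both a leading class discriminator (so its
    # descriptors reach the top-k set the risk score is restricted to) and
    # tightly tracked by the local gray-SD / gradient-magnitude descriptors
    planted_effects: dict = field(
        default_factory=lambda: {"rim_intensity_sd": 0.7}
    )
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    scc_threshold: float = 0.80
    mrmr_runs: int = 20
    mrmr_folds: int = 3
    top_k: int = 15
    lda_threshold: float = 0.4
    lasso_folds: int = 10
    horizons: tuple = (2.0, 5.0)
    roc_bootstrap: int = 500
    cindex_bootstrap: int = 200

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {EXPERIMENTS}")


# --------------------------------------------------------------------------
# Cohort simulation + feature extraction
# --------------------------------------------------------------------------

def simulate_and_extract(config: PipelineConfig, split: str, seed: int):
    """Generate one cohort split and extract its feature matrix on the fly.

    Returns ``(clinical DataFrame, FeatureMatrix)``; volumes are discarded
    after extraction to keep memory flat.
    """
    if split == "train":
        n_pos, n_neg, prefix = config.n_train_pos, config.n_train_neg, "T"
    elif split == "val":
        n_pos, n_neg, prefix = config.n_val_pos, config.n_val_neg, "V"
    else:
        raise ValueError(f"split must be 'train' or 'val', got {split!r}")

    rows, index = [], []

    def hook(pid, vol, mask):
        qc = qc_tumor_mask(mask)
        if not qc:
            raise RuntimeError(f"phantom {pid} failed tumor QC: {qc.reason}")
        comps = build_ring_masks(mask, vol.spacing_mm, config.ring_radii_mm)
        comps = apply_body_mask_set(comps, vol, config.body_hu_range)
        rows.append(extract_features(vol, comps, config.texture))
        index.append(pid)

    bundle = generate_cohort(
        n_pos,
        n_neg,
        planted_effects=config.planted_effects,
        survival_params=config.survival,
        seed=seed,
        grid_shape=config.grid_shape,
        spacing_mm=config.spacing_mm,
        id_prefix=prefix,
        patient_hook=hook,
        keep_volumes=False,
    )
    clinical = bundle.clinical_frame().set_index("patient_id")
    feats = pd.DataFrame(rows, index=index).loc[clinical.index]
    flags = {
        pid: list(feats.columns[feats.loc[pid].isna()])
        for pid in feats.index
        if feats.loc[pid].isna().any()
    }
    summaries = bundle.summary_frame().loc[clinical.index]
    return (
        clinical,
        FeatureMatrix(values=feats, normalization="raw", missing_flags=flags),
        summaries,
    )


def clinical_design(clinical: pd.DataFrame) -> pd.DataFrame:
    """Encode the clinical table as a numeric Cox/nomogram design matrix.

    Binary codes for gender/smoking/drinking, dummy codes for T/N stage
    levels, and ordinal codes (``*_ord``) for T/N/AJCC stage used by the
    nomograms.
    """
    d = pd.DataFrame(index=clinical.index)
    d["female"] = (clinical["gender"] == "female").astype(float)
    d["current_smoker"] = (clinical["smoking"] == "current").astype(float)
    d["heavy_drinker"] = (clinical["drinking"] == "heavy").astype(float)
    for lvl in ("T2", "T3", "T4"):
        d[lvl] = (clinical["t_stage"] == lvl).astype(float)
    for lvl in ("N1", "N2", "N3"):
        d[lvl] = (clinical["n_stage"] == lvl).astype(float)
    for lvl in ("II", "III"):
        d[f"stage_{lvl}"] = (clinical["ajcc_stage"] == lvl).astype(float)
    d["t_stage_ord"] = clinical["t_stage"].map({"T1": 1, "T2": 2, "T3": 3, "T4": 4}).astype(float)
    d["n_stage_ord"] = clinical["n_stage"].map({"N0": 0, "N1": 1, "N2": 2, "N3": 3}).astype(float)
    d["ajcc_ord"] = clinical["ajcc_stage"].map({"I": 1, "II": 2, "III": 3, "IV": 4}).astype(float)
    return d


# --------------------------------------------------------------------------
# Experiment stages
# --------------------------------------------------------------------------

def classification_arm(config, train_clin, train_z, val_clin, val_z, seed):
    labels_train = train_clin["hpv_status"].to_numpy()
    labels_val = val_clin["hpv_status"].to_numpy()
    kept = prune_correlated(train_z, labels_train, config.scc_threshold)
    sel = select_top_features(
        train_z[kept],
        labels_train,
        runs=config.mrmr_runs,
        folds=config.mrmr_folds,
        k=config.top_k,
        seed=int(substream(seed, "mrmr").integers(0, 2**31 - 1)),
    )
    model = train_lda(train_z, labels_train, sel.top_features, threshold=config.lda_threshold)
    roc_train = evaluate_roc(
        model.scores(train_z), labels_train, config.lda_threshold,
        n_bootstrap=config.roc_bootstrap, seed=seed, positive_label="pos",
    )
    roc_val = evaluate_roc(
        model.scores(val_z), labels_val, config.lda_threshold,
        n_bootstrap=config.roc_bootstrap, seed=seed, positive_label="pos",
    )
    return kept, sel, model, roc_train, roc_val


def _prognosis_arm(config, clin_tr, z_tr, clin_va, z_va, top_features, group, seed):
    """LASSO-Cox RRS for one phenotype (``group`` in {'pos','neg'})."""
    tr = clin_tr["hpv_status"] == group
    va = clin_va["hpv_status"] == group
    Xtr = z_tr.loc[tr.to_numpy(), top_features]
    Xva = z_va.loc[va.to_numpy(), top_features]
    t_tr = clin_tr.loc[tr, "time_years"].to_numpy()
    e_tr = clin_tr.loc[tr, "event"].to_numpy()
    t_va = clin_va.loc[va, "time_years"].to_numpy()
    e_va = clin_va.loc[va, "event"].to_numpy()

    res = lasso_cox(Xtr, t_tr, e_tr, cv_folds=config.lasso_folds,
                    seed=int(substream(seed, f"lasso-{group}").integers(0, 2**31 - 1)))
    model = RiskModel.from_lasso(res, tag=f"RRS_{group}")
    out = {"selected": res.selected, "empty_signature": res.empty_signature,
           "lambda": res.chosen_alpha}
    if res.empty_signature:
        return model, res, out, None, None
    rrs_tr = compute_rrs(Xtr, model)
    groups_tr, cutoff = median_split(rrs_tr)
    model.cutoff = cutoff
    rrs_va = compute_rrs(Xva, model)
    groups_va, _ = median_split(rrs_tr, rrs_va, cutoff=cutoff)
    cmp_tr = compare_risk_groups(groups_tr, t_tr, e_tr)
    cmp_va = compare_risk_groups(groups_va, t_va, e_va)
    out.update(
        cutoff=cutoff,
        coefficients={f: float(c) for f, c in zip(model.features, model.coefficients)},
        train={"hr": cmp_tr.hr, "hr_ci": cmp_tr.hr_ci, "logrank_p": cmp_tr.logrank.p_value},
        val={"hr": cmp_va.hr, "hr_ci": cmp_va.hr_ci, "logrank_p": cmp_va.logrank.p_value},
    )
    return model, res, out, (rrs_tr, t_tr, e_tr, tr), (rrs_va, t_va, e_va, va)


def run_experiment(config: PipelineConfig, outdir=None) -> dict:
    """Run one experiment end to end on simulated cohorts.

    Returns a JSON-serializable summary; identical configs produce
    byte-identical summaries.
    """
    seed = config.seed
    clin_tr, fm_tr, _ = simulate_and_extract(config, "train", int(substream(seed, "train-cohort").integers(0, 2**31 - 1)))
    clin_va, fm_va, _ = simulate_and_extract(config, "val", int(substream(seed, "val-cohort").integers(0, 2**31 - 1)))

    zp = zscore_fit(fm_tr.values)
    z_tr = zscore_apply(zp, fm_tr.values)
    z_va = zscore_apply(zp, fm_va.values)

    summary: dict = {
        "experiment": config.experiment,
        "seed": seed,
        "n_train": int(len(clin_tr)),
        "n_val": int(len(clin_va)),
        "n_features": int(z_tr.shape[1]),
    }

    kept, sel, lda_model, roc_tr, roc_va = classification_arm(
        config, clin_tr, z_tr, clin_va, z_va, seed
    )
    summary["classification"] = {
        "n_kept_after_pruning": len(kept),
        "top_features": sel.top_features,
        "train": {"auc": roc_tr.auc, "auc_ci": [roc_tr.ci_low, roc_tr.ci_high],
                  "sensitivity": roc_tr.sensitivity, "specificity": roc_tr.specificity,
                  "accuracy": roc_tr.accuracy, "threshold": roc_tr.threshold},
        "val": {"auc": roc_va.auc, "auc_ci": [roc_va.ci_low, roc_va.ci_high],
                "sensitivity": roc_va.sensitivity, "specificity": roc_va.specificity,
                "accuracy": roc_va.accuracy, "threshold": roc_va.threshold},
    }

    if config.experiment in ("exp2_prognosis", "exp3_nomogram"):
        summary["prognosis"] = {}
        arms = {}
        for group in ("pos", "neg"):
            model, res, out, tr_pack, va_pack = _prognosis_arm(
                config, clin_tr, z_tr, clin_va, z_va, sel.top_features, group, seed
            )
            arms[group] = (model, tr_pack, va_pack)
            summary["prognosis"][group] = out

        # stage-stratified KM for the positive phenotype on validation
        model, tr_pack, va_pack = arms["pos"]
        if va_pack is not None:
            rrs_va, t_va, e_va, va_mask = va_pack
            strat = stratified_km(
                clin_va.loc[va_mask.to_numpy()], rrs_va, model.cutoff, "ajcc_stage"
            )
            summary["prognosis"]["pos"]["by_stage"] = {
                lvl: (
                    None
                    if cmp is None
                    else {"hr": cmp.hr, "hr_ci": cmp.hr_ci, "logrank_p": cmp.logrank.p_value}
                )
                for lvl, cmp in strat.items()
            }
            # univariable screening -> multivariable Cox on training (pos)
            rrs_tr, t_tr, e_tr, tr_mask = tr_pack
            design = clinical_design(clin_tr.loc[tr_mask.to_numpy()])
            design = design.assign(rrs=rrs_tr)
            candidates = {
                "gender": "female",
                "smoking": "current_smoker",
                "drinking": "heavy_drinker",
                "t_stage": ["T2", "T3", "T4"],
                "n_stage": ["N1", "N2", "N3"],
                "ajcc_stage": ["stage_II", "stage_III"],
                "rrs": "rrs",
            }
            scr = screen_then_multivariable(design, t_tr, e_tr, candidates)
            summary["prognosis"]["pos"]["screening"] = {
                "univariable_p": {k: float(v) for k, v in scr.univariable["p"].items()},
                "significant": scr.significant,
                "multivariable": None
                if scr.multivariable is None
                else {
                    c: {"hr": float(r["hr"]), "p": float(r["p"])}
                    for c, r in scr.multivariable.summary.iterrows()
                },
            }

    if config.experiment == "exp3_nomogram":
        model, tr_pack, va_pack = arms["pos"]
        if va_pack is None:
            summary["nomogram"] = {"note": "empty signature; nomograms not built"}
        else:
            rrs_tr, t_tr, e_tr, tr_mask = tr_pack
            rrs_va, t_va, e_va, va_mask = va_pack
            dtr = clinical_design(clin_tr.loc[tr_mask.to_numpy()]).assign(rrs=rrs_tr)
            dva = clinical_design(clin_va.loc[va_mask.to_numpy()]).assign(rrs=rrs_va)
            covsets = {
                "M_c": ["female", "current_smoker", "heavy_drinker"],
                "M_p": ["ajcc_ord", "n_stage_ord"],
                "M_p_rrs": ["t_stage_ord", "rrs"],
            }
            horizon = float(config.horizons[0])
            summary["nomogram"] = {}
            for tag, cols in covsets.items():
                nom = build_nomogram(dtr[cols], t_tr, e_tr, horizons=config.horizons, tag=tag)
                lp_va = nom.linear_predictor(dva)
                boot = bootstrap_cindex(
                    dtr[list(nom.betas.index)], t_tr, e_tr,
                    n_bootstrap=config.cindex_bootstrap,
                    seed=int(substream(seed, f"boot-{tag}").integers(0, 2**31 - 1)),
                )
                pred_surv = nom.predict_survival(dva, horizon)
                cal = calibration_curve(pred_surv, t_va, e_va, horizon)
                dca = decision_curve(1.0 - pred_surv, t_va, e_va, horizon)
                summary["nomogram"][tag] = {
                    "covariates": list(nom.betas.index),
                    "max_points": nom.max_points(),
                    "c_train": boot.c,
                    "c_train_ci": [boot.ci_low, boot.ci_high],
                    "c_val": c_index(lp_va, t_va, e_va),
                    "calibration": cal.reset_index().to_dict(orient="list"),
                    "net_benefit": dca.table.reset_index().to_dict(orient="list"),
                }

    if outdir is not None:
        _io.write_provenance(outdir, dataclasses.asdict(config), seed)
        _io.write_json(f"{outdir}/summary.json", summary)
    return summary


# --------------------------------------------------------------------------
# Planted-signal recovery study
# --------------------------------------------------------------------------

def recovery_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    config: PipelineConfig | None = None,
    planted_summary: str = "rim_intensity_sd",
) -> pd.DataFrame:
    """Replicate the full analysis over seeded cohorts and measure recovery.

    For each seed: simulate training and validation cohorts with a planted
    texture-phenotype contrast and a planted prognostic effect, extract
    features, run the classification arm (held-out AUC), the positive-
    phenotype LASSO-Cox risk-score arm (whether the planted signal is
    selected; median-split validation HR and log-rank p), and compare a
    nomogram that includes the risk score against one restricted to
    outcome-unrelated clinical covariates (validation concordance).

    Returns one row per seed with columns ``val_auc``, ``planted_selected``,
    ``val_hr``, ``logrank_p``, ``c_with_rrs``, ``c_noise``.
    """
    config = config or PipelineConfig()
    rows = []
    for i in range(n_seeds):
        seed = int(np.random.SeedSequence([base_seed, i]).generate_state(1)[0] % (2**31 - 1))
        clin_tr, fm_tr, summ_tr = simulate_and_extract(
            config, "train", int(substream(seed, "train-cohort").integers(0, 2**31 - 1))
        )
        clin_va, fm_va, _ = simulate_and_extract(
            config, "val", int(substream(seed, "val-cohort").integers(0, 2**31 - 1))
        )
        zp = zscore_fit(fm_tr.values)
        z_tr = zscore_apply(zp, fm_tr.values)
        z_va = zscore_apply(zp, fm_va.values)

        kept, sel, lda_model, _, roc_va = classification_arm(
            config, clin_tr, z_tr, clin_va, z_va, seed
        )
        row = {"seed": seed, "val_auc": roc_va.auc}

        model, res, out, tr_pack, va_pack = _prognosis_arm(
            config, clin_tr, z_tr, clin_va, z_va, sel.top_features, "pos", seed
        )
        if va_pack is None:
            row.update(planted_selected=False, val_hr=np.nan, logrank_p=np.nan,
                       c_with_rrs=np.nan, c_noise=np.nan)
            rows.append(row)
            continue
        rrs_tr, t_tr, e_tr, tr_mask = tr_pack
        rrs_va, t_va, e_va, va_mask = va_pack

        # was the planted prognostic signal picked up? a selected descriptor
        # must track the planted image summary across the training phantoms
        planted = summ_tr.loc[tr_mask.to_numpy(), planted_summary]
        planted_sel = False
        for f in res.selected:
            c = np.corrcoef(z_tr.loc[tr_mask.to_numpy(), f], planted)[0, 1]
            if abs(c) >= 0.8:
                planted_sel = True
                break
        row.update(
            planted_selected=bool(planted_sel),
            val_hr=out["val"]["hr"],
            logrank_p=out["val"]["logrank_p"],
        )

        dtr = clinical_design(clin_tr.loc[tr_mask.to_numpy()]).assign(rrs=rrs_tr)
        dva = clinical_design(clin_va.loc[va_mask.to_numpy()]).assign(rrs=rrs_va)
        with_rrs = ["t_stage_ord", "rrs"]
        noise_only = ["female", "current_smoker", "heavy_drinker"]
        noms = {}
        for tag, cols in (("with_rrs", with_rrs), ("noise", noise_only)):
            nom = build_nomogram(dtr[cols], t_tr, e_tr, horizons=config.horizons, tag=tag)
            noms[tag] = c_index(nom.linear_predictor(dva), t_va, e_va)
        row.update(c_with_rrs=noms["with_rrs"], c_noise=noms["noise"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("seed")
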