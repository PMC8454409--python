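"""Prognosis arm: LASSO-Cox radiomic risk scores and survival analysis.

The radiomic risk score (RRS) of a patient is the linear combination
``sum_i beta_i * x_i`` of the signature features selected by an L1-penalized
Cox model, with the penalty chosen by 10-fold cross-validated partial-
likelihood deviance.  Patients are split into high/low risk at the
*training* median RRS, and the groups are compared by Kaplan-Meier curves,
the log-rank test, and Cox hazard ratios.  Both the per-group HR (high vs
low) and the per-unit HR (continuous RRS) are reported, since either scale
may be quoted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sstats
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .phantoms import substream


# --------------------------------------------------------------------------
# Partial likelihood (Breslow) — used for CV deviance scoring
# --------------------------------------------------------------------------

def cox_partial_loglik(lp, times, events) -> float:
    """Breslow partial log-likelihood of fixed linear predictors."""
    lp = np.asarray(lp, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(-times)  # decreasing time
    lp, times, events = lp[order], times[order], events[order]
    # cumulative log-sum-exp over the risk set (all with time >= t)
    mx = lp.max()
    cum = np.cumsum(np.exp(lp - mx))
    ll = 0.0
    i = 0
    n = len(lp)
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        risk = np.log(cum[j - 1]) + mx  # ties: shared risk set (Breslow)
        for m in range(i, j):
            if events[m] == 1:
                ll += lp[m] - risk
        i = j
    return float(ll)


# --------------------------------------------------------------------------
# LASSO-Cox
# --------------------------------------------------------------------------

@dataclass
class LassoCoxResult:
    alphas: np.ndarray
    coef_path: pd.DataFrame          # features x alphas
    cv_deviance: np.ndarray          # mean held-out deviance per alpha
    chosen_alpha: float
    coefficients: pd.Series          # at the chosen alpha
    selected: list
    empty_signature: bool


def lasso_cox(
    matrix: pd.DataFrame,
    times,
    events,
    cv_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 100,
    alpha_min_ratio: float = 1e-4,
) -> LassoCoxResult:
    """L1-penalized Cox fit over a penalty path with CV penalty selection.

    The path is log-spaced over ``n_alphas`` points spanning four decades
    below the smallest penalty that zeroes every coefficient.  The penalty is
    chosen to minimize the mean held-out partial-likelihood deviance over
    ``cv_folds`` folds (stratified by event status).  An all-zero solution at
    the chosen penalty is reported as an explicit empty signature.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValueError("at least one event is required for a Cox fit")
    X = matrix.to_numpy(dtype=float)
    y = Surv.from_arrays(event=events.astype(bool), time=times)

    # normalize=True: the penalty is applied on internally standardized
    # columns (the glmnet default), so path entry order does not depend on
    # per-column scale; reported coefficients are on the original scale
    full = CoxnetSurvivalAnalysis(
        l1_ratio=1.0,
        n_alphas=n_alphas,
        alpha_min_ratio=alpha_min_ratio,
        normalize=True,
        fit_baseline_model=False,
    )
    full.fit(X, y)
    alphas = np.asarray(full.alphas_)
    path = np.asarray(full.coef_)  # (n_features, n_alphas)

    # stratified-by-event K-fold CV of held-out deviance
    rng = substream(seed, "lasso-cv")
    idx_e = rng.permutation(np.flatnonzero(events == 1))
    idx_c = rng.permutation(np.flatnonzero(events == 0))
    folds = [
        np.concatenate([idx_e[f::cv_folds], idx_c[f::cv_folds]]) for f in range(cv_folds)
    ]
    # Verweij-van Houwelingen cross-validated partial likelihood: the fold's
    # contribution is loglik(all data) - loglik(training part), evaluated at
    # the training-fold coefficients.  More stable than scoring the small
    # held-out fold's partial likelihood directly.
    dev = np.zeros((cv_folds, len(alphas)))
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(times)), test_idx)
        if events[train_idx].sum() == 0 or events[test_idx].sum() == 0:
            dev[f] = np.nan
            continue
        m = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=list(alphas), normalize=True, fit_baseline_model=False
        )
        m.fit(X[train_idx], y[train_idx])
        fitted_alphas = np.asarray(m.alphas_)
        coefs = np.asarray(m.coef_)
        for a, alpha in enumerate(alphas):
            j = int(np.argmin(np.abs(fitted_alphas - alpha)))
            lp_all = X @ coefs[:, j]
            ll_all = cox_partial_loglik(lp_all, times, events)
            ll_train = cox_partial_loglik(
                lp_all[train_idx], times[train_idx], events[train_idx]
            )
            dev[f, a] = -2.0 * (ll_all - ll_train)
    mean_dev = np.nanmean(dev, axis=0)
    best = int(np.nanargmin(mean_dev))
    coef = pd.Series(path[:, best], index=matrix.columns)
    selected = list(coef.index[coef != 0.0])
    if not selected:
        warnings.warn("LASSO-Cox selected an empty signature at the chosen penalty", stacklevel=2)
    return LassoCoxResult(
        alphas=alphas,
        coef_path=pd.DataFrame(path, index=matrix.columns, columns=alphas),
        cv_deviance=mean_dev,
        chosen_alpha=float(alphas[best]),
        coefficients=coef,
        selected=selected,
        empty_signature=not selected,
    )


# --------------------------------------------------------------------------
# Risk model / RRS
# --------------------------------------------------------------------------

@dataclass
class RiskModel:
    """A radiomic risk score: named features, Cox coefficients, frozen cutoff."""

    features: list
    coefficients: np.ndarray
    lambda_: float = 0.0
    cutoff: float | None = None
    tag: str = ""

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.features) != len(self.coefficients):
            raise ValueError("features and coefficients must have equal length")

    @property
    def n(self) -> int:
        return len(self.features)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "features": self.features,
                    "coefficients": list(map(float, self.coefficients)),
                    "lambda": self.lambda_,
                    "cutoff": self.cutoff,
                    "tag": self.tag,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        d = json.loads(Path(path).read_text())
        return cls(d["features"], np.asarray(d["coefficients"]), d["lambda"], d["cutoff"], d["tag"])

    @classmethod
    def from_lasso(cls, res: LassoCoxResult, tag: str = "") -> "RiskModel":
        sel = res.selected
        return cls(sel, res.coefficients[sel].to_numpy(), res.chosen_alpha, None, tag)


def compute_rrs(features, model: RiskModel):
    """RRS = sum_i beta_i * x_i.  Missing features raise (no imputation)."""
    if isinstance(features, pd.DataFrame):
        missing = [f for f in model.features if f not in features.columns]
        if missing:
            raise KeyError(f"feature vector missing model features: {missing}")
        return features[model.features].to_numpy(dtype=float) @ model.coefficients
    features = pd.Series(features)
    missing = [f for f in model.features if f not in features.index]
    if missing:
        raise KeyError(f"feature vector missing model features: {missing}")
    return float(features[model.features].to_numpy(dtype=float) @ model.coefficients)


def median_split(scores_train, scores_apply=None, cutoff: float | None = None):
    """High/low risk split at the training-median score.

    Returns ``(groups, cutoff)`` where ``groups`` is an array of
    ``"high"``/``"low"`` labels for ``scores_apply`` (defaults to the
    training scores).  ``high`` means score strictly above the cutoff.
    """
    scores_train = np.asarray(scores_train, dtype=float)
    if scores_train.size == 0:
        raise ValueError("training scores must be nonempty")
    if cutoff is None:
        cutoff = float(np.median(scores_train))
    scores = scores_train if scores_apply is None else np.asarray(scores_apply, dtype=float)
    groups = np.where(scores > cutoff, "high", "low")
    if len(np.unique(groups)) == 1:
        warnings.warn(
            f"degenerate risk split: all scores on one side of cutoff {cutoff:.4g}",
            stacklevel=2,
        )
    return groups, cutoff


# --------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# --------------------------------------------------------------------------

@dataclass
class KMCurve:
    times: np.ndarray       # distinct event times
    survival: np.ndarray    # product-limit estimate at those times
    variance: np.ndarray    # Greenwood variance
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """Step-function value at time t (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Product-limit survival estimator with Greenwood variance.

    At tied times, events are handled before censorings (the standard
    convention: a subject censored at t is still at risk for an event at t).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_times = np.unique(times[events == 1])
    surv = kmf.survival_function_["KM_estimate"]
    # Greenwood from the at-risk table
    d = []
    at_risk = []
    for t in event_times:
        d.append(int(((times == t) & (events == 1)).sum()))
        at_risk.append(int((times >= t).sum()))
    d = np.asarray(d, dtype=float)
    r = np.asarray(at_risk, dtype=float)
    s_vals = np.asarray([surv.loc[:t].iloc[-1] for t in event_times])
    green = s_vals**2 * np.cumsum(d / (r * (r - d).clip(min=1e-300)))
    return KMCurve(event_times, s_vals, green, len(times), int(events.sum()))


@dataclass
class LogrankResult:
    statistic: float
    p_value: float


def logrank_test(groups, times, events) -> LogrankResult:
    """Two-group log-rank chi-square test (1 df)."""
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"exactly two nonempty groups required, got {list(levels)}")
    a = groups == levels[0]
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    return LogrankResult(float(res.test_statistic), float(res.p_value))


# --------------------------------------------------------------------------
# Cox models
# --------------------------------------------------------------------------

@dataclass
class CoxResult:
    summary: pd.DataFrame   # coef, hr, ci_low, ci_high, p per covariate
    log_likelihood: float
    null_log_likelihood: float
    n: int
    n_events: int

    @property
    def lr_p_value(self) -> float:
        """Likelihood-ratio p-value of the whole model."""
        lr = 2.0 * (self.log_likelihood - self.null_log_likelihood)
        return float(sstats.chi2.sf(max(lr, 0.0), df=len(self.summary)))


def cox_fit(design: pd.DataFrame, times, events, warn_epv: bool = True) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) with Wald CIs and p-values."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    const = [c for c in design.columns if design[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant design column(s): {const}")
    if warn_epv and events.sum() < design.shape[1]:
        warnings.warn(
            f"fewer events ({events.sum()}) than covariates ({design.shape[1]})",
            stacklevel=2,
        )
    df = design.copy()
    df["_time"] = times
    df["_event"] = events
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise RuntimeError(
            f"Cox fit failed to converge: {exc}; design columns: {list(design.columns)}"
        ) from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_low": np.exp(s["coef lower 95%"]),
            "ci_high": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    null_ll = cox_partial_loglik(np.zeros(len(times)), times, events)
    return CoxResult(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        null_log_likelihood=null_ll,
        n=len(times),
        n_events=int(events.sum()),
    )


@dataclass
class GroupComparison:
    """Median-split group comparison: KM per group, log-rank, Cox HR."""

    km: dict
    logrank: LogrankResult
    hr: float
    hr_ci: tuple
    hr_p: float
    n_per_group: dict


def compare_risk_groups(groups, times, events) -> GroupComparison:
    """Compare high- vs low-risk groups (HR is high over low)."""
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    km = {g: km_estimate(times[groups == g], events[groups == g]) for g in np.unique(groups)}
    lr = logrank_test(groups, times, events)
    ind = pd.DataFrame({"high_risk": (groups == "high").astype(float)})
    cox = cox_fit(ind, times, events, warn_epv=False)
    row = cox.summary.iloc[0]
    return GroupComparison(
        km=km,
        logrank=lr,
        hr=float(row["hr"]),
        hr_ci=(float(row["ci_low"]), float(row["ci_high"])),
        hr_p=float(row["p"]),
        n_per_group={g: int((groups == g).sum()) for g in np.unique(groups)},
    )


# --------------------------------------------------------------------------
# Univariable screening -> multivariable model
# --------------------------------------------------------------------------

@dataclass
class ScreeningResult:
    univariable: pd.DataFrame       # candidate, p (likelihood-ratio), significant
    significant: list
    multivariable: CoxResult | None


def screen_then_multivariable(
    design: pd.DataFrame,
    times,
    events,
    candidates: dict,
    alpha: float = 0.05,
) -> ScreeningResult:
    """Univariable Cox per candidate; significant ones enter one joint fit.

    ``candidates`` maps a display name to the design column(s) encoding that
    variable (a multi-level factor contributes all its dummy columns and is
    tested jointly by a likelihood-ratio test).  With ``alpha = 0`` the
    multivariable model is always empty, reported explicitly.
    """
    if not candidates:
        raise ValueError("candidates must be nonempty")
    rows = []
    significant = []
    usable_cols: dict = {}
    for name, cols in candidates.items():
        cols = [cols] if isinstance(cols, str) else list(cols)
        cols = [c for c in cols if design[c].nunique() > 1]  # drop empty levels
        if not cols:
            rows.append({"candidate": name, "p": np.nan, "significant": False})
            continue
        try:
            res = cox_fit(design[cols], times, events, warn_epv=False)
            p = res.lr_p_value
        except RuntimeError:
            rows.append({"candidate": name, "p": np.nan, "significant": False})
            continue
        sig = p < alpha
        rows.append({"candidate": name, "p": p, "significant": sig})
        usable_cols[name] = cols
        if sig:
            significant.append(name)
    table = pd.DataFrame(rows).set_index("candidate")
    multi = None
    if significant:
        cols = []
        for name in significant:
            cols.extend(usable_cols[name])
        multi = cox_fit(design[cols], times, events, warn_epv=False)
    return ScreeningResult(univariable=table, significant=significant, multivariable=multi)


# --------------------------------------------------------------------------
# Signature size selection (validation-HR rule)
# --------------------------------------------------------------------------

def signature_candidates(res: LassoCoxResult, train_matrix: pd.DataFrame, sizes=None) -> dict:
    """Risk-model candidates of each support size along the penalty path.

    For each distinct nonzero-coefficient count (first penalty along the path
    reaching that size), builds a RiskModel with the training-median cutoff.
    """
    out: dict = {}
    for a, alpha in enumerate(res.alphas):
        coef = res.coef_path.iloc[:, a]
        sel = list(coef.index[coef != 0.0])
        nnz = len(sel)
        if nnz == 0 or nnz in out:
            continue
        if sizes is not None and nnz not in sizes:
            continue
        model = RiskModel(sel, coef[sel].to_numpy(), float(alpha), None, tag=f"n{nnz}")
        scores = compute_rrs(train_matrix, model)
        model.cutoff = float(np.median(scores))
        out[nnz] = model
    return dict(sorted(out.items()))


@dataclass
class SizeSelectionResult:
    n: int
    table: pd.DataFrame
    selected_model: RiskModel
    provenance: str = "validation-selection"  # selection used validation outcomes


def select_signature_size(
    candidates: dict,
    val_matrix: pd.DataFrame,
    val_times,
    val_events,
) -> SizeSelectionResult:
    """Pick the signature size whose median-split HR is largest on validation.

    This reproduces a selection rule that uses validation outcomes; the
    result carries a prominent ``validation-selection`` provenance flag and
    the default pipeline does not use it for final models.
    """
    if not candidates:
        raise ValueError("at least one candidate model required")
    rows = []
    best_n, best_hr = None, -np.inf
    for n, model in candidates.items():
        scores = compute_rrs(val_matrix, model)
        groups, _ = median_split(scores, cutoff=model.cutoff)
        if len(np.unique(groups)) < 2:
            rows.append({"n": n, "hr": np.nan, "note": "degenerate split, skipped"})
            continue
        try:
            cmp = compare_risk_groups(groups, val_times, val_events)
        except RuntimeError as exc:
            rows.append({"n": n, "hr": np.nan, "note": f"skipped: {exc}"})
            continue
        rows.append({"n": n, "hr": cmp.hr, "note": ""})
        if np.isfinite(cmp.hr) and cmp.hr > best_hr:
            best_n, best_hr = n, cmp.hr
    if best_n is None:
        raise RuntimeError("no candidate produced an evaluable hazard ratio")
    return SizeSelectionResult(
        n=best_n,
        table=pd.DataFrame(rows).set_index("n"),
        selected_model=candidates[best_n],
    )


# --------------------------------------------------------------------------
# Stage-stratified analysis
# --------------------------------------------------------------------------

def stratified_km(
    clinical: pd.DataFrame,
    scores,
    cutoff: float,
    stratum_field: str,
    time_col: str = "time_years",
    event_col: str = "event",
) -> dict:
    """Median-split comparison within each level of a stratification field.

    Strata where either risk group has fewer than 2 subjects are reported as
    not evaluable (value ``None``).
    """
    if stratum_field not in clinical.columns:
        raise KeyError(f"stratum field {stratum_field!r} not in clinical table")
    scores = np.asarray(scores, dtype=float)
    out = {}
    for level in sorted(clinical[stratum_field].unique()):
        sel = (clinical[stratum_field] == level).to_numpy()
        groups, _ = median_split(scores[sel], cutoff=cutoff)
        counts = {g: int((groups == g).sum()) for g in ("high", "low")}
        if min(counts.values()) < 2:
            out[level] = None
            continue
        try:
            out[level] = compare_risk_groups(
                groups, clinical.loc[sel, time_col], clinical.loc[sel, event_col]
            )
        except RuntimeError:
            out[level] = None
    return out
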