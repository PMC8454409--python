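"""Cox-based nomogram point systems and their evaluation.

A nomogram maps each covariate value to points proportional to its
contribution to the Cox linear predictor, scaled so that the covariate with
the largest contribution range spans exactly [0, 100]; total points map to
survival probabilities at stated horizons through the baseline survival
function (Breslow estimator, as fitted by lifelines).  Evaluation uses
Harrell's concordance index with percentile-bootstrap confidence intervals,
calibration curves (predicted vs Kaplan-Meier-observed survival per
prediction bin), and decision-curve analysis (net benefit across decision
thresholds, with Kaplan-Meier accounting for censoring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index

from .phantoms import substream
from .survival import km_estimate


# --------------------------------------------------------------------------
# Nomogram
# --------------------------------------------------------------------------

@dataclass
class Nomogram:
    tag: str
    betas: pd.Series                 # per design-column Cox coefficient
    ranges: dict                     # column -> (lo, hi)
    ref: dict                        # column -> value mapping to 0 points
    points_per_lp: float             # points per unit of linear predictor
    lp_offset: float                 # sum_i beta_i * ref_i
    lp_mean: float                   # beta . xbar (lifelines centering)
    baseline_survival: dict          # horizon -> S0(h) at the covariate mean
    model: object = field(repr=False, default=None)  # fitted CoxPHFitter

    def points(self, row: pd.Series) -> dict:
        """Per-covariate points (>= 0) for one patient."""
        out = {}
        for c in self.betas.index:
            out[c] = float(
                (self.betas[c] * row[c] - self.betas[c] * self.ref[c]) * self.points_per_lp
            )
        return out

    def total_points(self, row: pd.Series) -> float:
        return float(sum(self.points(row).values()))

    def max_points(self) -> dict:
        """The point span of each covariate over its stated range."""
        return {
            c: abs(self.betas[c]) * (self.ranges[c][1] - self.ranges[c][0]) * self.points_per_lp
            for c in self.betas.index
        }

    def survival_from_points(self, total_points: float, horizon: float) -> float:
        """Survival probability at a horizon from a total-points value."""
        if horizon not in self.baseline_survival:
            raise KeyError(f"horizon {horizon} not tabulated; have {list(self.baseline_survival)}")
        lp = total_points / self.points_per_lp + self.lp_offset
        s0 = self.baseline_survival[horizon]
        return float(s0 ** np.exp(lp - self.lp_mean))

    def predict_survival(self, design: pd.DataFrame, horizon: float) -> np.ndarray:
        """Direct Cox survival prediction at a horizon."""
        sf = self.model.predict_survival_function(design[list(self.betas.index)], times=[horizon])
        return sf.iloc[0].to_numpy(dtype=float)

    def linear_predictor(self, design: pd.DataFrame) -> np.ndarray:
        return design[list(self.betas.index)].to_numpy(dtype=float) @ self.betas.to_numpy()


def build_nomogram(
    design: pd.DataFrame,
    times,
    events,
    horizons=(2.0, 5.0),
    covariate_ranges: dict | None = None,
    tag: str = "",
) -> Nomogram:
    """Fit a Cox model and lay it out as a point-based nomogram.

    ``covariate_ranges`` defaults to the observed min/max of each design
    column.  Zero-range covariates cannot carry points and are excluded with
    a warning before fitting.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    ranges = {}
    cols = []
    for c in design.columns:
        lo, hi = (
            covariate_ranges[c]
            if covariate_ranges and c in covariate_ranges
            else (float(design[c].min()), float(design[c].max()))
        )
        if hi <= lo:
            warnings.warn(f"zero-range covariate {c!r} excluded from nomogram", stacklevel=2)
            continue
        ranges[c] = (lo, hi)
        cols.append(c)
    if not cols:
        raise ValueError("no covariates with nonzero range")

    df = design[cols].copy()
    df["_time"] = times
    df["_event"] = events
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    betas = cph.params_.copy()

    contrib = {c: abs(betas[c]) * (ranges[c][1] - ranges[c][0]) for c in cols}
    biggest = max(contrib.values())
    if biggest <= 0:
        raise ValueError("all covariate contributions are zero")
    points_per_lp = 100.0 / biggest
    # reference value (0 points): the range end minimizing beta * x
    ref = {
        c: (ranges[c][0] if betas[c] >= 0 else ranges[c][1]) for c in cols
    }
    lp_offset = float(sum(betas[c] * ref[c] for c in cols))
    xbar = design[cols].mean()
    lp_mean = float(betas @ xbar)
    baseline = {}
    for h in horizons:
        sf = cph.predict_survival_function(pd.DataFrame([xbar]), times=[h])
        baseline[float(h)] = float(sf.iloc[0, 0])
    return Nomogram(
        tag=tag,
        betas=betas,
        ranges=ranges,
        ref=ref,
        points_per_lp=points_per_lp,
        lp_offset=lp_offset,
        lp_mean=lp_mean,
        baseline_survival=baseline,
        model=cph,
    )


# --------------------------------------------------------------------------
# Concordance
# --------------------------------------------------------------------------

def c_index(risk_scores, times, events) -> float:
    """Harrell's C of a risk score (higher score = higher risk).

    Usable pairs: both events, or an event observed before a censoring
    time; tied scores receive credit 0.5.
    """
    risk_scores = np.asarray(risk_scores, dtype=float)
    if not np.all(np.isfinite(risk_scores)):
        raise ValueError("risk scores contain non-finite values")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise ValueError("concordance undefined: no events, hence no usable pairs")
    try:
        return float(concordance_index(times, -risk_scores, events))
    except ZeroDivisionError as exc:
        raise ValueError("concordance undefined: no usable pairs") from exc


@dataclass
class BootstrapCIndex:
    c: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    n_redrawn: int


def bootstrap_cindex(
    design_or_scores,
    times,
    events,
    n_bootstrap: int = 1000,
    seed: int = 0,
    refit: bool = True,
) -> BootstrapCIndex:
    """Bootstrap Harrell's C with a percentile 95% CI.

    With ``refit=True`` (a design matrix), the Cox model is refit on every
    resample and scored on that resample; with ``refit=False`` fixed risk
    scores are resampled.  Resamples without events are redrawn and counted.
    """
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(times)

    def risk_of(idx):
        if refit:
            design = design_or_scores.iloc[idx].reset_index(drop=True)
            df = design.copy()
            df["_time"] = times[idx]
            df["_event"] = events[idx]
            cph = CoxPHFitter(penalizer=1e-6)
            cph.fit(df, duration_col="_time", event_col="_event")
            return cph.predict_partial_hazard(design).to_numpy(dtype=float)
        return np.asarray(design_or_scores, dtype=float)[idx]

    point = c_index(risk_of(np.arange(n)), times, events)
    rng = substream(seed, "cindex-bootstrap")
    cs = np.empty(n_bootstrap)
    redrawn = 0
    for b in range(n_bootstrap):
        while True:
            idx = rng.integers(0, n, size=n)
            if events[idx].sum() > 0:
                break
            redrawn += 1
        try:
            cs[b] = c_index(risk_of(idx), times[idx], events[idx])
        except Exception:  # degenerate resample (e.g. non-converging refit)
            cs[b] = np.nan
    lo, hi = np.nanpercentile(cs, [2.5, 97.5])
    return BootstrapCIndex(point, float(lo), float(hi), n_bootstrap, redrawn)


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------

def calibration_curve(
    predicted_survival,
    times,
    events,
    horizon: float,
    n_bins: int = 3,
) -> pd.DataFrame:
    """Predicted vs observed survival at a horizon, by prediction bin.

    Patients are binned by predicted survival probability (quantile bins);
    observed survival per bin is the Kaplan-Meier estimate at the horizon
    with its Greenwood standard error.  Bins with nobody still at risk at
    the horizon are flagged not evaluable.
    """
    pred = np.asarray(predicted_survival, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if horizon <= 0 or horizon > times.max():
        raise ValueError(f"horizon {horizon} outside follow-up range (max {times.max():.3g})")
    try:
        bins = pd.qcut(pred, n_bins, labels=False, duplicates="drop")
    except ValueError:
        bins = np.zeros(len(pred), dtype=int)
    if np.all(pd.isna(bins)):
        bins = np.zeros(len(pred), dtype=int)
    bins = np.asarray(bins, dtype=int)
    rows = []
    for b in sorted(np.unique(bins)):
        sel = bins == b
        at_risk = int((times[sel] >= horizon).sum())
        row = {
            "bin": int(b),
            "n": int(sel.sum()),
            "predicted": float(pred[sel].mean()),
            "evaluable": at_risk > 0,
        }
        if at_risk > 0:
            km = km_estimate(times[sel], events[sel])
            row["observed"] = km.survival_at(horizon)
            idx = np.searchsorted(km.times, horizon, side="right") - 1
            row["se"] = float(np.sqrt(km.variance[idx])) if idx >= 0 else 0.0
        else:
            row["observed"] = np.nan
            row["se"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("bin")


# --------------------------------------------------------------------------
# Decision curves
# --------------------------------------------------------------------------

@dataclass
class DecisionCurve:
    horizon: float
    table: pd.DataFrame  # p_t, net_benefit, treat_all, treat_none


def decision_curve(
    predicted_event_prob,
    times,
    events,
    horizon: float,
    p_t_grid=None,
) -> DecisionCurve:
    """Net benefit of treating patients whose predicted event probability
    (by the horizon) exceeds each threshold p_t.

    NB(p_t) = TP/n - (FP/n) * p_t / (1 - p_t), where the event status of
    the treated group at the horizon is estimated by Kaplan-Meier (so
    censoring before the horizon is handled).  Includes treat-all and
    treat-none references.
    """
    pred = np.asarray(predicted_event_prob, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if p_t_grid is None:
        p_t_grid = np.round(np.arange(0.05, 0.90, 0.05), 10)
    p_t_grid = np.asarray(p_t_grid, dtype=float)
    if np.any((p_t_grid <= 0) | (p_t_grid >= 1)):
        raise ValueError("all thresholds p_t must lie strictly inside (0, 1)")
    n = len(times)
    km_all = km_estimate(times, events)
    prevalence = 1.0 - km_all.survival_at(horizon)
    rows = []
    for pt in p_t_grid:
        odds = pt / (1.0 - pt)
        treated = pred > pt
        if not treated.any():
            nb = 0.0
        else:
            km_t = km_estimate(times[treated], events[treated])
            event_rate = 1.0 - km_t.survival_at(horizon)
            frac = treated.sum() / n
            tp = frac * event_rate
            fp = frac * (1.0 - event_rate)
            nb = tp - fp * odds
        rows.append(
            {
                "p_t": float(pt),
                "net_benefit": float(nb),
                "treat_all": float(prevalence - (1.0 - prevalence) * odds),
                "treat_none": 0.0,
            }
        )
    return DecisionCurve(horizon=float(horizon), table=pd.DataFrame(rows).set_index("p_t"))
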