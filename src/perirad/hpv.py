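"""HPV-status classification arm.

Pipeline: Spearman-correlation pruning (|SCC| > 0.80 drops the feature with
the larger Wilcoxon rank-sum p-value), minimum-redundancy-maximum-relevance
(MRMR) ranking inside a repeated stratified cross-validation (default 100
runs x 3 folds), the top-k most frequently selected descriptors (F_t,
default k = 15), a pooled-covariance linear discriminant classifier, and ROC
evaluation at a frozen decision threshold (default 0.4 on the positive-class
posterior, carried from training to validation).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .phantoms import substream


# --------------------------------------------------------------------------
# Wilcoxon rank-sum
# --------------------------------------------------------------------------

def wilcoxon_rank_sum(x0, x1) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration for small samples without ties (both n <= 20), normal
    approximation with tie correction otherwise.  Two identical samples give
    p = 1 by convention.
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    if x0.size == 0 or x1.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x0, x1])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    small = x0.size <= 20 and x1.size <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x0, x1, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


# --------------------------------------------------------------------------
# Correlation pruning
# --------------------------------------------------------------------------

def prune_correlated(
    matrix: pd.DataFrame,
    labels,
    scc_threshold: float = 0.80,
) -> list:
    """Remove one member of every feature pair with |Spearman rho| > threshold.

    For each violating pair the feature with the *larger* Wilcoxon rank-sum
    p-value (less class-discriminative) is removed.  Because the rule is
    order-dependent, pairs are processed in a fixed order: descending |rho|,
    ties broken lexicographically by the name pair.  Constant columns have an
    undefined rank correlation and are dropped first with a warning.
    """
    labels = np.asarray(labels)
    cols = list(matrix.columns)
    const = [c for c in cols if matrix[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping {len(const)} constant column(s) before pruning", stacklevel=2)
        cols = [c for c in cols if c not in const]
    if len(cols) < 2:
        return cols
    sub = matrix[cols]
    rho = stats.spearmanr(sub.to_numpy()).statistic
    rho = np.atleast_2d(rho)
    pvals = {
        c: wilcoxon_rank_sum(sub[c][labels == labels[0]], sub[c][labels != labels[0]])
        for c in cols
    }
    iu, ju = np.triu_indices(len(cols), k=1)
    viol = np.abs(rho[iu, ju]) > scc_threshold
    pairs = sorted(
        (
            (-abs(rho[i, j]), tuple(sorted((cols[i], cols[j]))))
            for i, j in zip(iu[viol], ju[viol])
        ),
    )
    kept = set(cols)
    for _, (a, b) in pairs:
        if a in kept and b in kept:
            if pvals[a] > pvals[b]:
                kept.discard(a)
            elif pvals[b] > pvals[a]:
                kept.discard(b)
            else:  # tie: drop the lexicographically later name
                kept.discard(max(a, b))
    return [c for c in cols if c in kept]


# --------------------------------------------------------------------------
# MRMR
# --------------------------------------------------------------------------

def _quantile_discretize(col: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.unique(np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, col, side="left")


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI (nats) between two small-alphabet integer code vectors."""
    na, nb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb).astype(float)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])))


def mrmr_rank(
    matrix: pd.DataFrame,
    labels,
    k: int,
    n_bins: int = 4,
    variant: str = "MID",
) -> list:
    """Greedy MRMR feature ranking.

    Features are discretized into quantile bins (default 4).  The first
    feature maximizes mutual information with the label; each subsequent
    feature maximizes relevance minus mean redundancy to the already-selected
    set (``MID``, the difference form) or relevance divided by mean
    redundancy (``MIQ``).  Ties break lexicographically by column name.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > matrix.shape[1]:
        raise ValueError(f"k={k} exceeds the number of columns {matrix.shape[1]}")
    if variant not in ("MID", "MIQ"):
        raise ValueError(f"variant must be 'MID' or 'MIQ', got {variant!r}")
    cols = sorted(matrix.columns)
    X = np.column_stack(
        [_quantile_discretize(matrix[c].to_numpy(dtype=float), n_bins) for c in cols]
    )
    y = pd.factorize(np.asarray(labels))[0]
    relevance = np.array([_mutual_information(X[:, j], y) for j in range(len(cols))])

    selected: list[int] = []
    redundancy_sum = np.zeros(len(cols))
    remaining = set(range(len(cols)))
    while len(selected) < k:
        if selected:
            mean_red = redundancy_sum / len(selected)
            score = relevance - mean_red if variant == "MID" else relevance / (mean_red + 1e-12)
        else:
            score = relevance.copy()
        # deterministic tie-break: smallest index among maxima (cols sorted)
        mx = max(score[j] for j in remaining)
        best = min(j for j in remaining if score[j] == mx)
        selected.append(best)
        remaining.discard(best)
        for j in remaining:
            redundancy_sum[j] += _mutual_information(X[:, j], X[:, best])
    return [cols[j] for j in selected]


@dataclass
class FeatureSelectionResult:
    kept_after_pruning: list
    selection_frequency: dict
    mean_rank: dict
    top_features: list  # F_t
    runs: int
    folds: int
    seed: int


def select_top_features(
    matrix: pd.DataFrame,
    labels,
    runs: int = 100,
    folds: int = 3,
    k: int = 15,
    seed: int = 0,
    mrmr_kwargs: dict | None = None,
) -> FeatureSelectionResult:
    """Stability selection: MRMR on each training fold of each CV run.

    The top-k most frequently selected descriptors across all runs x folds
    form F_t.  Frequency ties break by better (lower) mean MRMR rank, then
    lexicographically.  The input matrix must already be pruned/z-scored.
    """
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    min_class = int(np.bincount(y).min())
    if folds < 2 or folds > min_class:
        raise ValueError(
            f"folds={folds} invalid: must be >= 2 and <= smallest class size ({min_class})"
        )
    if runs < 1:
        raise ValueError("runs must be >= 1")
    k_eff = min(k, matrix.shape[1])
    mrmr_kwargs = mrmr_kwargs or {}

    freq: dict = {c: 0 for c in matrix.columns}
    rank_sum: dict = {c: 0.0 for c in matrix.columns}
    rng = substream(seed, "feature-selection")
    for run in range(runs):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(0, 2**31 - 1))
        )
        for train_idx, _ in skf.split(matrix, y):
            ranked = mrmr_rank(matrix.iloc[train_idx], labels[train_idx], k_eff, **mrmr_kwargs)
            for r, c in enumerate(ranked):
                freq[c] += 1
                rank_sum[c] += r
    mean_rank = {
        c: (rank_sum[c] / freq[c] if freq[c] else float("inf")) for c in matrix.columns
    }
    ordered = sorted(matrix.columns, key=lambda c: (-freq[c], mean_rank[c], c))
    return FeatureSelectionResult(
        kept_after_pruning=list(matrix.columns),
        selection_frequency=freq,
        mean_rank=mean_rank,
        top_features=ordered[:k_eff],
        runs=runs,
        folds=folds,
        seed=seed,
    )


# --------------------------------------------------------------------------
# LDA classifier
# --------------------------------------------------------------------------

@dataclass
class ClassifierModel:
    features: list
    coef: np.ndarray
    intercept: float
    classes: list
    threshold: float = 0.4
    shrinkage: float | None = None

    def scores(self, matrix: pd.DataFrame) -> np.ndarray:
        """Posterior-style positive-class score in [0, 1]."""
        X = matrix[self.features].to_numpy(dtype=float)
        z = X @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        return (self.scores(matrix) >= self.threshold).astype(int)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "features": self.features,
                    "coef": list(map(float, self.coef)),
                    "intercept": float(self.intercept),
                    "classes": list(self.classes),
                    "threshold": self.threshold,
                    "shrinkage": self.shrinkage,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        d = json.loads(Path(path).read_text())
        return cls(
            features=d["features"],
            coef=np.asarray(d["coef"]),
            intercept=d["intercept"],
            classes=d["classes"],
            threshold=d["threshold"],
            shrinkage=d.get("shrinkage"),
        )


def train_lda(
    matrix: pd.DataFrame,
    labels,
    features: list | None = None,
    threshold: float = 0.4,
    shrinkage: float | None = None,
) -> ClassifierModel:
    """Pooled-covariance linear discriminant classifier.

    Uses the least-squares solver (weights proportional to
    ``Sigma^-1 (mu1 - mu0)``); if the pooled covariance is singular, Ledoit-
    Wolf shrinkage is applied and recorded on the model.
    """
    features = list(features) if features is not None else list(matrix.columns)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    X = matrix[features].to_numpy(dtype=float)
    y = (labels == classes[1]).astype(int)
    used_shrinkage = shrinkage
    try:
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            lda.fit(X, y)
        if not np.all(np.isfinite(lda.coef_)):
            raise np.linalg.LinAlgError("non-finite LDA weights")
    except (np.linalg.LinAlgError, RuntimeWarning):
        warnings.warn("singular pooled covariance; applying Ledoit-Wolf shrinkage", stacklevel=2)
        used_shrinkage = "auto"
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(X, y)
    return ClassifierModel(
        features=features,
        coef=lda.coef_.ravel().copy(),
        intercept=float(lda.intercept_[0]),
        classes=[str(classes[0]), str(classes[1])],
        threshold=threshold,
        shrinkage=used_shrinkage if used_shrinkage != shrinkage else shrinkage,
    )


# --------------------------------------------------------------------------
# ROC evaluation
# --------------------------------------------------------------------------

def auc_rank(scores, y) -> float:
    """AUC via the rank statistic; tied scores receive half credit."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float
    n_bootstrap: int = 0


def evaluate_roc(
    scores,
    labels,
    threshold: float = 0.4,
    n_bootstrap: int = 2000,
    seed: int = 0,
    positive_label=None,
) -> RocResult:
    """AUC with a stratified-bootstrap CI, plus sens/spec/accuracy at threshold."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("AUC undefined with a single class")
    pos = classes[1] if positive_label is None else positive_label
    y = (labels == pos).astype(int)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores contain non-finite values")

    auc = auc_rank(scores, y)
    pred = (scores >= threshold).astype(int)
    sens = float(np.mean(pred[y == 1] == 1))
    spec = float(np.mean(pred[y == 0] == 0))
    acc = float(np.mean(pred == y))

    lo = hi = auc
    if n_bootstrap > 0:
        rng = substream(seed, "roc-bootstrap")
        idx1 = np.flatnonzero(y == 1)
        idx0 = np.flatnonzero(y == 0)
        aucs = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            i1 = rng.choice(idx1, size=len(idx1), replace=True)
            i0 = rng.choice(idx0, size=len(idx0), replace=True)
            ii = np.concatenate([i1, i0])
            aucs[b] = auc_rank(scores[ii], y[ii])
        lo, hi = np.percentile(aucs, [2.5, 97.5])
    return RocResult(auc, float(lo), float(hi), sens, spec, acc, threshold, n_bootstrap)
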