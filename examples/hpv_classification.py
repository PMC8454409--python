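"""Phenotype (HPV-status analog) classification on simulated cohorts.

Correlation pruning (|Spearman rho| > 0.8), MRMR stability selection over
repeated stratified cross-validation, a linear discriminant classifier, and
ROC evaluation at a frozen 0.4 decision threshold.
"""

import warnings

warnings.filterwarnings("ignore")

from perirad.hpv import evaluate_roc, prune_correlated, select_top_features, train_lda
from perirad.pipeline import PipelineConfig, simulate_and_extract
from perirad.texture import zscore_apply, zscore_fit

cfg = PipelineConfig(n_train_pos=40, n_train_neg=32, n_val_pos=50, n_val_neg=20)
clin_tr, fm_tr, _ = simulate_and_extract(cfg, "train", seed=11)
clin_va, fm_va, _ = simulate_and_extract(cfg, "val", seed=12)

zp = zscore_fit(fm_tr.values)
z_tr, z_va = zscore_apply(zp, fm_tr.values), zscore_apply(zp, fm_va.values)
y_tr, y_va = clin_tr["hpv_status"].to_numpy(), clin_va["hpv_status"].to_numpy()

kept = prune_correlated(z_tr, y_tr)
print(f"{z_tr.shape[1]} descriptors -> {len(kept)} after correlation pruning")

sel = select_top_features(z_tr[kept], y_tr, runs=10, folds=3, k=15, seed=1)
print("top-3 most frequently selected:", sel.top_features[:3])

model = train_lda(z_tr, y_tr, sel.top_features)
roc = evaluate_roc(model.scores(z_va), y_va, threshold=0.4, n_bootstrap=500,
                   seed=1, positive_label="pos")
print(f"validation AUC {roc.auc:.2f} (95% CI {roc.ci_low:.2f}-{roc.ci_high:.2f}); "
      f"sens {roc.sensitivity:.2f} / spec {roc.specificity:.2f} at threshold 0.4")
print("AUC near 1 reflects the strong planted texture contrast between classes.")
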