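"""Train the nested cross-validated gradient-boosted risk model on a cohort
whose true discriminability is known in closed form.

With one standard-normal feature whose case distribution is shifted by d,
the population ROC-AUC is Phi(d / sqrt 2); the out-of-fold estimate should
land within a few hundredths of it.
"""

import numpy as np
from scipy.stats import norm

from riskcarver import studies, synthetic
from riskcarver.risk_model import run_nested_cv

d = 1.19
cohort = synthetic.generate_subjects(studies.single_gaussian_config(effect=d, seed=11))
bundle, probs, metrics = run_nested_cv(
    cohort.features, cohort.labels, seed=7, eta_grid=(0.1, 0.3), nrounds_grid=(50, 100)
)

print(f"cohort: n={len(cohort)}, effect d={d} log-odds per unit")
print(f"analytic AUC  Phi(d/sqrt 2) = {norm.cdf(d / np.sqrt(2)):.4f}")
print(f"out-of-fold AUC             = {metrics.mean['auc']:.4f} "
      f"(95% CI {metrics.ci_lo['auc']:.4f}-{metrics.ci_hi['auc']:.4f})")
print("\nper-fold metrics at threshold 0.5:")
cols = ["fold", "TP", "FP", "TN", "FN", "sensitivity", "specificity", "ppv", "npv", "f1", "auc"]
print(metrics.per_fold[cols].round(3).to_string(index=False))
print("\nchosen hyperparameters per outer fold:",
      [(m.params.eta, m.params.nrounds) for m in bundle.models])
print("\nThe out-of-fold AUC tracks the closed form because every subject is")
print("scored by the one model that never saw it during training or tuning.")
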