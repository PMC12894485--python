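"""ROC inference on plain score vectors: AUROC, bootstrap CI, significance,
and the paired DeLong comparison of two classifiers on the same people.

Everything here works on any (scores, labels) pair -- no cohort machinery
required.
"""

import numpy as np

from mscsf.roc import auroc, bootstrap_auc_ci, delong_paired_test, mason_graham_p

rng = np.random.default_rng(0)
n_pos, n_neg = 96, 64
labels = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]

proteomic = np.r_[rng.normal(1.6, 1, n_pos), rng.normal(0, 1, n_neg)]
conventional = (proteomic + rng.normal(0, 1.6, n_pos + n_neg) > 0.9).astype(float)

res = bootstrap_auc_ci(proteomic, labels, n_boot=2000, seed=1)
print(f"proteomic score: AUROC {res.auc:.3f} "
      f"(95% CI {res.ci_lower:.3f}-{res.ci_upper:.3f})")
print(f"Mason-Graham p vs AUC=0.5: {mason_graham_p(proteomic, labels):.2e}")
print(f"binary marker:  AUROC {auroc(conventional, labels).auc:.3f}")

auc_a, auc_b, z, p = delong_paired_test(proteomic, conventional, labels)
print(f"paired DeLong: {auc_a:.3f} vs {auc_b:.3f}, z = {z:.2f}, p = {p:.2e}")
# The DeLong test exploits the pairing (same participants under both
# scores), which is what makes the comparison powerful at this n.
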