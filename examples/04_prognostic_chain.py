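"""Propagate a CSF-predicted severity score to a predicted follow-up EDSS.

The chain: severity score -> annualized CombiWISE slope (fitted line) ->
CombiWISE change over the follow-up interval -> EDSS change through the
fitted monotone quadratic -> predicted follow-up EDSS. The intermediate
arithmetic lives on the continuous 0-100 CombiWISE scale because per-
interval changes are usually smaller than the 0.5-point EDSS increment.
"""

import numpy as np

from mscsf.prognosis import (
    evaluate_prognosis,
    fit_combiwise_edss_model,
    fit_msdss_slope_model,
    predict_followup_edss,
)
from mscsf.simulate import generate_crosssectional_cw_edss

rng = np.random.default_rng(3)

# training-side fits: severity -> slope line, CombiWISE <-> EDSS quadratic
msdss = rng.normal(1.0, 0.5, 200)
slopes = 0.2 + 0.5 * msdss + rng.normal(0, 0.3, 200)
conv = fit_msdss_slope_model(msdss, slopes)
visits = generate_crosssectional_cw_edss(3000, seed=4)
conv = fit_combiwise_edss_model(visits["combiwise"], visits["edss"], models=conv)
print(f"slope model: slope_cw = {conv.a:.3f} + {conv.b:.3f} * MS-DSS "
      f"(R^2 = {conv.linear_r2:.2f})")
print(f"conversion quadratic: EDSS = {conv.c0:.3f} + {conv.c1:.4f}*cw "
      f"+ {conv.c2:.2e}*cw^2 on [{conv.cw_min:.0f}, {conv.cw_max:.0f}]")

# validation-side chain
n = 84
msdss_pred = rng.normal(1.0, 0.5, n)
baseline = rng.uniform(1.0, 6.0, n)
interval = rng.uniform(3.0, 15.0, n)
preds = predict_followup_edss(msdss_pred, baseline, interval, conv)
measured = np.clip(
    preds["predicted_followup_edss"] + rng.normal(0, 0.8, n), 0, 10
)
report = evaluate_prognosis(preds, measured.to_numpy())
print(f"\npredicted vs measured follow-up: rho = {report.spearman_rho:.2f}")
print(f"explained variance: baseline alone {100*report.r2_base:.0f}% -> "
      f"baseline + predicted change {100*report.r2_augmented:.0f}% "
      f"(gain p = {report.p_gain:.3g})")
# The R^2 gain is the added prognostic value of the CSF-predicted change
# beyond what baseline disability already explains.
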