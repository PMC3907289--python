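"""Collective rate control: response coefficients and the CV budget.

Computes the concentration response coefficients of the 30-min repair
synthesis rate, scans a two-fold perturbation of one factor, and
propagates typical cell-to-cell variability into the expected repair-rate
CV.
"""

import numpy as np

from nerkinetics.control import (
    perturbation_scan,
    propagate_cv,
    response_coefficients,
)
from nerkinetics.model import FACTORS, reference_parameters

params = reference_parameters()
report = response_coefficients(params, target="repair_rate", t_eval=30.0)

print("response coefficients of the 30-min repair rate:")
for f in FACTORS:
    print(f"  {f:6s} {report.R[f]:.3f}")
print(f"  lesions (R_L) {report.R_L:.3f}")
print(f"max factor coefficient {report.max_factor():.3f} -> no singular "
      "rate-limiting component; control is shared")

folds = np.array([0.5, 0.75, 1.0, 1.5, 2.0])
scan = perturbation_scan(params, "XPA", folds)
print("two-fold XPA perturbation (normalised 30-min flux):",
      np.round(scan, 3),
      "- decreases follow the linear prediction; increases saturate as "
      "repair depletes the lesions within the readout window")

budget = propagate_cv(report, cv_factors=0.25, cv_lesions=0.32)
print(f"propagated repair-rate CV: {budget.cv_rate:.2f} "
      "(factor CVs 0.25, lesion-dose CV 0.32)")
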