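"""Single-cell variability: scatter, correlations and measurement error.

Simulates a heterogeneous population (lognormal factor expression, variable
lesion dose), correlates expression with repair synthesis, and shows the
error-ellipse estimate of antibody measurement error on synthetic
two-channel data.
"""

import numpy as np

from nerkinetics.datasets import generate_paired_measurements
from nerkinetics.model import reference_parameters
from nerkinetics.population import (
    PopulationSpec,
    correlate,
    error_ellipse,
    simulate_population,
)

params = reference_parameters()
spec = PopulationSpec(n_cells=300, cv_factors=0.25, cv_lesions=0.32,
                      times=(30.0, 240.0), seed=42)
cells = simulate_population(params, spec)
print(f"simulated {len(cells)} cells")

edu30 = cells["edu_30min"]
print(f"EdU(30 min) CV across cells: {edu30.std(ddof=1) / edu30.mean():.2f}")
edu240 = cells["edu_240min"]
print(f"EdU(4 h) CV: {edu240.std(ddof=1) / edu240.mean():.2f} "
      "(repair complete -> collapses onto the lesion-dose CV)")

r, (lo, hi) = correlate(cells["conc_XPC_uM"], edu30, n_boot=1000, seed=1)
print(f"XPC concentration vs EdU(30 min): r = {r:.2f} [{lo:.2f}, {hi:.2f}] "
      "(significant but weak -> robustness to expression noise)")

pairs = generate_paired_measurements(n=332, signal_cv=0.3,
                                     relative_error=0.11, seed=7)
err, r_ch = error_ellipse(pairs["channel_a"], pairs["channel_b"])
print(f"error ellipse on synthetic GFP-vs-antibody pairs: "
      f"relative error {err:.1f}% (generative 11%), channel r = {r_ch:.2f}")
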