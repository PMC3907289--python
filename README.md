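# nerkinetics

Kinetic modelling of nucleotide-excision repair (NER) in mammalian cells:
how hour-scale, first-order DNA repair emerges from repair proteins that
bind and dissociate on a time scale of seconds to minutes, and why no
single factor limits the repair rate.

The package is aimed at systems biologists studying chromatin-associated
machines (repair, transcription, replication). It provides, as an
importable Python library:

* **Assembly theory** (`nerkinetics.assembly`) — a continuous-time Markov
  chain of `N` components assembling (sequentially or in random order) on
  a DNA lesion, with exact mean repair times from first-passage linear
  solves, completion curves, Gillespie sampling, and the comparison of
  reversible (mono-exponential) versus irreversible (sigmoidal) assembly.
* **Mechanistic pathway model** (`nerkinetics.model`) — five DNA
  intermediates (damaged -> unwound -> incised -> resynthesized ->
  rechromatinized) interconverted by catalytic steps alpha–epsilon, with
  seven repair factors (XPC, TFIIH, XPG, XPF, XPA, RPA, PCNA) binding
  reversibly and independently; simulated observables include factor
  accumulation, cumulative repair synthesis (EdU), the incised fraction
  and FLIP curves.
* **Inference** (`nerkinetics.inference`) — weighted-least-squares
  (Gaussian maximum-likelihood) fitting with latin-hypercube multi-starts,
  profile-likelihood confidence intervals and identifiability verdicts,
  prediction profiles, and the stand-alone first-order EdU fit
  `EdU(t) = EdU_max (1 - e^{-lambda t})`.
* **Control analysis** (`nerkinetics.control`) — response coefficients
  `R_i = d ln v / d ln C_i` of the repair (or incision) rate, finite
  perturbation scans, and propagation of cell-to-cell variability:
  `CV_v^2 = sum_i R_i^2 CV_i^2 + R_L^2 CV_L^2`.
* **Population variability** (`nerkinetics.population`) — per-cell
  lognormal factor expression and lesion doses, one ODE solve per cell,
  bootstrap correlations, CV decomposition by source, and the
  orthogonal-regression ("error ellipse") estimator of channel
  measurement error.
* **Synthetic data** (`nerkinetics.datasets`) — seed-reproducible
  generators for every input the pipeline consumes, emulating the noise
  structure of the quantitative-microscopy assays.

## Worked example

```python
>>> from nerkinetics.assembly import AssemblyScheme, mean_repair_time
>>> mean_repair_time(AssemblyScheme(9, "random", k_on=1.0, k_off=1.0, rho=600.0))
68.30730158729924
```

Nine components that each bind and unbind once per minute, with catalysis
at 10 per second, still take ~68 minutes on average to repair a lesion:
slow repair is an emergent property of reversible assembly, not of any
slow step. The narrative scripts in `examples/` walk through each
capability; `python examples/04_rate_control.py` prints

```
response coefficients of the 30-min repair rate:
  XPC    0.292
  TFIIH  0.180
  XPG    0.292
  XPF    0.290
  XPA    0.292
  RPA    0.127
  PCNA   -0.020
  lesions (R_L) 0.925
max factor coefficient 0.292 -> no singular rate-limiting component; control is shared
propagated repair-rate CV: 0.33 (factor CVs 0.25, lesion-dose CV 0.32)
```

No coefficient exceeds ~0.3: the repair rate is controlled collectively
by all factors and is therefore robust against expression noise in any
one of them. Propagating typical cell-to-cell variability (factor CVs
0.25, lesion-dose CV 0.32) through these coefficients predicts a
repair-rate CV of ~0.33, dominated by the lesion dose.

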