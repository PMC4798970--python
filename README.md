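# nfkbsync

NF-κB (p65/RELA) shuttles between cytoplasm and nucleus under
inflammatory stimulation, and its nuclear concentration oscillates with
a natural period T₀ ≈ 90 min. In single cells the oscillations are
heterogeneous and damped, so an unsynchronized population looks almost
non-oscillating — which makes it hard to connect NF-κB dynamics to the
transcription they drive. Periodic TNF-α forcing resolves this: a
damped oscillator driven at period T_f adopts the forcing period and
phase, the population oscillates in synchrony, and downstream
transcription can be read against a known clock.

`nfkbsync` is a toolkit for that experimental logic, aimed at systems
biologists who model NF-κB dynamics or quantify single-cell
translocation traces. It provides:

* **model_core** — a normalized ODE model with the two canonical
  negative feedbacks (IκBα and A20):

  d*K*/dt = −d_K·K + S(t)/(1+Aⁿ),
  d*N*/dt = d(1−N) + γd_I(1−N) + pK(1−N) − aIN,
  plus telegraph-style gene modules (G, R) for IκBα, A20 and any
  NF-κB-controlled gene; stiff adaptive integration with exact handling
  of square/sawtooth forcing discontinuities, and the microscopy
  observable NCI = r·N/(1−N).
* **stability** — fixed points, analytic Jacobian, damped-vs-sustained
  classification (sustained ⇔ some Re λ > 0), randomized-parameter
  stability scans over per-rate uncertainty degrees D (multiplicative
  factors in [10⁻ᴰ, 10ᴰ]), and forcing-period scans T_numerical/T_f.
* **trace_analysis** — min–max–min peak detection with the θ > 0.15
  significance rule, oscillation phase (2π at maxima, π at minima),
  inter-peak periods T_exp, phase differences Δφ = 2πΔT/T_f against the
  forcing, and the entropy-based synchrony intensity
  η = 1 − S/S_max over 8 phase bins (0 = asynchronous, 1 = locked).
* **fitting** — the relative-distance objective
  d = (1/N)Σ|X−x|/max(X,x), MCMC exploration plus Levenberg–Marquardt
  refinement in log-parameter space, shared-network (P_NF-κB) and
  per-gene (P_G) fits of NCI and fold-change time courses.
* **expression_patterns** — detection filtering, |log2FC| > 1
  deregulation calls, shape standardization, hand-rolled fuzzy c-means
  (m = 1.5) with membership cores ≥ 0.5, cluster-count selection,
  overlap coefficients and Fisher-exact target enrichment.
* **synthetic_data** — generators for heterogeneous single-cell NCI
  cohorts and archetype-labelled expression panels with exact ground
  truth, used by the test suite and usable as benchmarks.
* a `nfkbsync` CLI (`simulate`, `scan`, `analyze`, `synth`, `fit`,
  `cluster`, `pipeline`) that writes a provenance manifest per run.

## Worked example

```python
import numpy as np
from nfkbsync import (BASELINE, CohortSpec, ForcingSignal,
                      analyze_cohort, classify_stability, generate_cohort)

# 1. the baseline network is a damped oscillator at saturating TNF-α
rep = classify_stability(BASELINE, S_const=2.0)
lam = rep.eigenvalues
dom = lam[lam.imag > 1e-9][np.argmax(lam[lam.imag > 1e-9].real)]
print(f"classification: {rep.classification}")
print(f"dominant eigenvalue pair: {dom:.3f} h^-1 "
      f"(period {2*np.pi/dom.imag*60:.1f} min)")

# 2. drive a synthetic 60-cell cohort at T_f = 90 min and quantify it
forcing = ForcingSignal(kind="square", S_high=2.0, S_low=0.0, T1=45, T2=45)
traces, _ = generate_cohort(CohortSpec(n_cells=60, forcing=forcing, seed=7))
res = analyze_cohort(traces, forcing)
print(f"cells analyzed: {res['n_included']} of {res['n_cells']}")
print(f"pooled inter-peak intervals: n={len(res['periods'])}, "
      f"median {np.median(res['periods']):.0f} min")
print(f"synchrony intensity eta = {res['eta']:.3f}")
```

prints

```
classification: damped
dominant eigenvalue pair: -1.778+4.309j h^-1 (period 87.5 min)
cells analyzed: 50 of 60
pooled inter-peak intervals: n=349, median 90 min
synchrony intensity eta = 0.608
```

The negative real part of every eigenvalue classifies the fixed point
as stable — oscillations are damped, with an intrinsic ringing period
of ~87 min. Driving the cohort with 90-min square pulses makes the
peaks follow the forcing (median inter-peak interval 90 min, the
sampling resolution of the 6-min grid) and the cohort phase-locks to
the stimulus: η = 0.61 rather than ~0 for an unforced population. Ten
of the 60 simulated cells were dropped by the 7-h minimum-track filter,
as in a real tracking experiment.

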