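# axoregen

Quantitative analysis of how neural stem cells in the axolotl spinal cord
switch from slow, neurogenic divisions to fast, proliferative divisions
during tail regeneration. The package implements, as tested reusable
components, the statistical machinery such a study needs:

* **Cell-cycle kinetics from cumulative labeling** — under continuous
  availability of a thymidine analog (BrdU/EdU) from *t* = 0, an
  asynchronous population with fixed phase lengths accumulates label as
  cells transit S-phase. The labeled fraction among cycling cells is

  R′(t) = [r^((T_G2+M+T_S)/T_C) − r^((T_G2+M−t)/T_C)] / (r−1)  for 0 ≤ t < T_G2+M,
  1 − [r^((T_C+T_G2+M−t)/T_C) − r^((T_G2+M+T_S)/T_C)] / (r−1)  for T_G2+M ≤ t < T_C−T_S,
  and 1 afterwards (for r = 1 this reduces to (T_S+t)/T_C capped at 1),

  where T_C, T_S, T_G2+M are the cycle, S-phase and combined G2+M
  lengths and *r* is the number of daughters per division that remain
  progenitors (1 = neurogenic, 2 = proliferative). Quiescent cells dilute
  the signal through the growth fraction g(t): constant at GF for r = 1,
  g(t) = GF·r^(t/T_C) / (GF·r^(t/T_C) + 1 − GF) for r = 2, so the
  observable is R(t) = g(t)·R′(t). Parameters are estimated by weighted
  least squares (SSE = Σ((Rexp_i − R(t_i))/σ_i)²) with 68% confidence
  intervals from the parabolic ΔSSE = 1 approximation, and phase lengths
  follow as T_M = mi·T_C and T_G1 = T_C − T_G2+M − T_S with linear error
  propagation.

* **Mitotic index from sections** — per-section index N_M/(N_PCNA·l_s/l_c)
  with the denominator scaled from an optical plane to the section
  thickness; per-replicate errors use the finite-population-corrected
  s.e.m. √((N−n)/(N−1))·σ/√n, and the population error adds the mean
  intra-replicate error to the inter-replicate s.e.m.

* **Division-orientation statistics** — the absolute projection of the
  unit spindle vector on the unit anterior–posterior axis,
  Proj = |S·AP| ∈ [0,1]. For uniformly random 3D orientations Proj is
  exactly Uniform(0,1), so N cells are called AP-oriented when their
  mean projection exceeds 0.5 + 1.96/√(12N) (one-sided level 0.025).
  Cleavage-plane angles (complement of the spindle–apical angle, folded
  to [0°, 90°]) are compared between groups by Mann-Whitney U.

* **nCounter expression analysis** — positive-control (geometric-mean)
  normalization, detection calls against negative controls (one-tailed
  Student's t), background subtraction (mean + 3 s.d., floored at 1),
  housekeeping normalization, a negative-binomial exact conditional test
  per gene with Benjamini-Hochberg adjustment, and a concordance tally
  of regeneration DE calls against a developmental reference gene set
  with Fisher's exact test.

* **Synthetic data with ground truth** — an exact agent-based simulator
  of asynchronously cycling populations (the brute-force oracle for the
  closed-form curve), Watson-type axial orientation samplers, NB count
  matrices with spike-in controls, and section-count generators.

## Worked example

Simulate a proliferative-population labeling experiment (5 animals per
timepoint, 12 h sampling to 120 h) and fit it:

```python
import numpy as np
from axoregen import cell_cycle as cc, synthetic_data as sd

tc, truth = sd.simulate_labeling_experiment(sd.SimConfig(
    params=cc.CellCycleParams(T_C=119, T_S=88, T_G2M=9, GF=0.96, r=2),
    sampling_times=tuple(np.arange(0.0, 121.0, 12.0)),
    n_replicates=5, cells_per_replicate=150, seed=42))
res = cc.fit_cell_cycle(tc, r=2, fixed={"T_G2M": 9.0})
print(res.summary())
pl = res.derive_phase_lengths(mi=0.05, dmi=0.01)
print(f"T_M  = {pl.T_M:.2f} ± {pl.dT_M:.2f} h")
print(f"T_G1 = {pl.T_G1:.2f} ± {pl.dT_G1:.2f} h")
```

prints

```
Cumulative-labeling cell-cycle fit
==============================================
population:     synthetic
division mode:  r = 2 (proliferative)
n timepoints:   11
SSE:            10.47
converged:      True
----------------------------------------------
   param     estimate   68% CI (±)   status
     T_C        103.8         7.76     free
     T_S        74.49         7.07     free
   T_G2M            9           --    fixed
      GF       0.9569      0.00294     free
----------------------------------------------
derived T_G1 = T_C - T_G2M - T_S = 20.27 h
T_M  = 5.19 ± 1.11 h
T_G1 = 20.27 ± 10.49 h
```

The cycle length recovered from this noisy replicate-level experiment
(103.8 h ± 7.8 h) brackets the generating truth of 119 h within two
intervals; the growth fraction (0.957 ± 0.003) recovers the generating
0.96. T_M converts the mitotic index into an M-phase length; T_G1 is the
remainder of the cycle after S and G2+M.

The same analyses are available from the shell:

```sh
axoregen simulate labeling --seed 42 --out sim/
axoregen fit-cellcycle --input sim/labeling.tsv --population synthetic \
    --division-mode proliferative --fix T_G2M=9 --out fit.json
axoregen orientation --cells spindles.tsv --zone 0,429 --out orient.json
axoregen nanostring de --counts counts.tsv --groups groups.yaml \
    --compare day0,day6 --out de.tsv
```

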