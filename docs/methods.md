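# Methods

This note documents the models, estimators and numerical choices behind
`axoregen`, the assumptions they rest on, and what the synthetic-data
generators do and do not emulate.

## Cumulative-labeling cell-cycle model

**Model.** A population of cycling cells with *identical, fixed* phase
lengths (G1 → S → G2+M partitioning a cycle of length T_C), dividing
*asynchronously* (ages spread over the cycle at steady state), takes up
a DNA label that is *continuously available* from t = 0. Every cell
transiting S-phase becomes (and stays) labeled, and daughters inherit
the label. The labeled fraction among cycling cells, R′(t), is piecewise
in three regimes — before T_G2+M (only cells in or entering S since
onset are labeled), between T_G2+M and T_C − T_S (each mitosis adds
labeled daughters), and saturation at 1 from T_C − T_S on. The division
mode enters through r, the mean number of daughters per division that
remain progenitors: r = 1 (asymmetric neurogenic) or r = 2 (symmetric
proliferative). The r ≠ 1 branch is continuous at both breakpoints,
reduces exactly to the r = 1 line in the r → 1 limit, and has
R′(0) = (r^((T_G2+M+T_S)/T_C) − r^(T_G2+M/T_C))/(r−1), the steady-state
S-phase occupancy of an exponentially growing population — all three
properties are enforced by tests.

Quiescent cells enter through the growth fraction g(t). For r = 2 the
cycling pool doubles every T_C while quiescent cells are constant, so
g(t) = GF·r^(t/T_C)/(GF·r^(t/T_C) + 1 − GF) rises toward 1; for r = 1
the counted pool is constant (the postmitotic daughter is excluded from
counting, mirroring the exclusion of rounded neuronal nuclei at the
microscope) and g = GF. The observable is R(t) = g(t)·R′(t): for r = 1
it plateaus at GF, for r = 2 it keeps creeping toward 1 after
"complete" labeling at T_C − T_S.

**Idealisations.** Repeated label injections are modeled as truly
continuous availability; label dilution, washout, cell death and
inter-cell parameter variability are not modeled. These are the standard
assumptions of cumulative-labeling analysis, and the synthetic generator
makes exactly the same ones — so passing recovery tests demonstrates
internal consistency of model + estimator, not robustness to biological
heterogeneity.

**Fitting.** Weighted least squares, SSE = Σ((Rexp_i − R(t_i))/σ_i)²,
minimized over the free parameters subject to positivity, GF ∈ (0, 1]
and T_S + T_G2+M < T_C. r is never fitted; it is fixed by the population
type. T_G2+M defaults to fixed at 9 h — estimated separately from the
time at which all mitotic figures are labeled (`estimate_tg2m`: the
percentage-labeled-mitoses logic; a cell in M at time t was in S a time
≤ t ago only if its G2+M transit is shorter than t) — but may be freed
via configuration. σ_i = 0 is rejected for weighted fitting; an explicit
`unweighted=True` flag fits with σ = 1.

The SSE surface is piecewise and multimodal (breakpoints move across
data points as parameters vary), so the optimizer contract is: score a
coarse grid over T_C ∈ {50, 100, …, 500} h, T_S ∈ {0.1, …, 0.5}·T_C,
GF ∈ {0.5, …, 1.0}; polish the 8 best grid points with Nelder-Mead
(xatol 1e-6, fatol 1e-10, one restart from each polish's own optimum to
escape premature simplex collapse); keep the best. A single-start polish
was measured to strand roughly a quarter of noisy fits in local minima;
the multi-start version removed essentially all of them.

**Confidence intervals.** 68% ("1σ") symmetric half-widths from the
parabolic approximation of the SSE surface: the ΔSSE = 1 contour,
evaluated as √(2·diag(H⁻¹)) with H a central finite-difference Hessian
(relative step 1e-3) of the *unpenalized* SSE at the optimum, so
boundary optima (GF = 1) keep a defined curvature; a non-positive-definite
Hessian falls back to per-parameter 1D curvatures. This is the HESSE
convention of MINUIT-style fitters. Note these intervals assume the σ_i
are the true standard errors of the fitted points; they are not rescaled
by SSE/dof.

**Derived quantities.** T_M = mi·T_C with
ΔT_M = √((mi·ΔT_C)² + (T_C·Δmi)²); T_G1 = T_C − T_G2+M − T_S with
ΔT_G1 = √(ΔT_C² + ΔT_G2+M² + ΔT_S²), fixed parameters contributing zero
error. Covariances between fitted parameters are ignored, as is standard
for this propagation. `extrapolate_full_cycle_differentiation` linearly
rescales an observed differentiated fraction by the fraction of cells
that completed a cycle within the chase (capped at 1); the
completed-cycle fraction is an input, not recomputed.

## Agent-based labeling simulator

Because all cells share the same phase lengths, the two daughters of a
division are born simultaneously at age 0 and an entire clone remains
perfectly synchronised forever. The simulator therefore evolves each
founder's clone in closed form: given the founder's age a at onset, the
clone's division count ⌊(a+t)/T_C⌋, size r^divisions, shared age and
label status (labeled iff t exceeds the founder's time-to-S,
(T_G1 − a) mod T_C, zero if in S at onset) are deterministic. This is
the same stochastic process an event-driven agent simulation realises,
without discretisation error, and runs 10⁵ founders × a sampling grid in
milliseconds. Founder ages are drawn from the steady-state density
(uniform for r = 1; ∝ r^(−a/T_C) for r = 2, by inverse CDF); a fraction
GF of founders is proliferative.

Two sampling modes:

* **Oracle mode** (`labeled_fraction_oracle`): used to validate the
  closed-form curve. Ages are drawn by *stratified* inverse-CDF sampling
  (one jittered draw per equal-probability stratum) and the
  proliferative count is fixed at round(GF·n), shrinking the Monte-Carlo
  error of the recorded fraction from O(1/√n) to O(1/n) — far below the
  binomial standard error the equivalence tests budget for. With plain
  iid sampling the clone synchrony of r = 2 populations inflates the
  sampling s.d. 1.0–1.25× above binomial, which makes a strict
  3-binomial-s.e. criterion over hundreds of grid points fail by chance;
  variance reduction removes the Monte-Carlo error rather than widening
  the tolerance.

* **Replicate mode**: emulates a real experiment — each timepoint is
  measured on its own set of animals (harvesting is destructive, so
  timepoints are independent), default 5 animals × 150 counted cells,
  plain iid sampling. The recorded value is the across-animal mean and
  σ_i is its standard error (s.d./√n). Weighting the fit by the standard
  error of the fitted point is what makes the ΔSSE = 1 intervals
  approximately calibrated; weighting by the raw across-animal s.d.
  over-covers by ~√n. Measured at the default design (12 h grid to
  120 h, r = 2, T_C = 119 h): median relative error of T_C ≈ 7%, 68% CI
  coverage ≈ 60% — slightly below nominal because σ_i is itself
  estimated from 5 animals (a t-with-4-df effect the parabolic
  approximation ignores).

## Mitotic index

N_P = N_PCNA·l_s/l_c converts an optical-plane count into a full-section
count of proliferating cells (l_s section thickness, l_c mean AP nucleus
length, supplied per replicate with a pooled-mean fallback); the
per-section index is N_M/N_P. Sections with N_P = 0 and N_M = 0 are
excluded and logged; N_M > 0 with N_P = 0 is an error. The
per-replicate error is the survey-sampling s.e.m. with finite-population
correction, √((N−n)/(N−1))·σ/√n, where N = (l_max − l_min)/l_s (rounded
to the nearest integer, warning when not integral) is the number of
sections the region holds — scoring every section is a census with zero
sampling error under this model, even though within-section counting
noise remains. The population error *adds* the mean intra-replicate
error to the inter-replicate s.e.m.; quadrature combination, though more
conventional, is available behind `quadrature=True` for sensitivity
analysis only. The synthetic section generator spreads the scored
sections evenly across the region (non-consecutive sections, as scored
in practice), draws the optical-plane count as Poisson and the mitotic
count as binomial at the true index. Whole-mount data use the areal PH3⁺
density (count/area) instead.

## Division orientation and cleavage planes

Each mitotic cell carries its own anterior–posterior axis (two points in
the central canal at the ends of its z-stack); no global axis is
assumed. The statistic is Proj = |S·AP| of the unit vectors — the
absolute value folds the arbitrary pole and axis labelling, and for
uniformly random 3D directions |cos θ| is *exactly* Uniform(0, 1), which
is the test's null: the mean of N null projections has mean 0.5 and s.d.
(1/√12)/√N, so divisions are called oriented when the sample mean
exceeds 0.5 + 1.96/√(12N), a one-sided normal-approximation test at
level 0.025. No small-N exact correction is applied (a documented
limitation; the approximation is adequate for the N ≥ 10 samples this
is used on, and Monte-Carlo tests confirm the empirical level stays at
or below nominal for N ∈ {10, …, 53}). Zone membership is a closed
interval on the AP position; zone bounds are inputs.

The orientation generator draws directions from a Watson-type axial
density ∝ exp(κ(u·μ)²) by rejection sampling (κ = 0 reduces exactly to
the uniform sphere); `kappa_for_mean_projection` inverts the mean
projection numerically for power studies.

Cleavage planes are analysed in 2D longitudinal sections: the cleavage
trace is the spindle rotated 90° in the section plane, and the reported
angle is the acute line–line angle to the apical surface, folded to
[0°, 90°] — so it is the exact complement of the spindle–apical angle
(90° = vertical cleavage). Group comparisons use the Mann-Whitney U test
(exact enumeration when the combined n ≤ 20 without ties, otherwise the
midrank normal approximation with tie-corrected variance) plus median,
IQR and s.d. dispersion summaries.

## nCounter analysis

Normalization chain, in order: (1) per-sample scaling by the geometric
mean of the spike-in positive probes (factor = mean-of-geomeans /
sample geomean; applied to all probes); (2) detection calls per gene by
a one-tailed pooled-variance Student's t-test of the gene's counts in
the analysed samples against the pooled negative-control counts of the
same samples — a zero-variance tie yields p = 0.5 by convention — with
absent genes (p ≥ 0.05) blanketed to 1; (3) background subtraction of
mean + 3 s.d. of each sample's own negative probes (background is
sample-specific chemistry; a pooled variant exists behind a flag),
floored at 1, with the negative probes consumed (set to 0) so the chain
is idempotent; (4) housekeeping scaling of biological probes only (spike-ins
measure chemistry, not input material) to the across-sample mean
housekeeping count. Rescaling a sample's raw counts uniformly changes the
normalized matrix only by one global factor and leaves all downstream
calls untouched.

Differential expression uses a two-group negative-binomial exact
conditional test in the classic style: per-gene dispersions by method of
moments on within-group variances (df-weighted across groups, truncated
at 0), shrunk toward a parametric mean–dispersion trend
α(μ) = a₀ + a₁/μ fitted by least squares over informative genes — with
so few replicates the per-gene weight is df/(df+4), and the shrunk value
never drops below the trend (conservative sharing), floored at 1e-8.
The p-value conditions on the two-group total k: group sums are NB with
mean n·μ and size n/α, and p is the total probability of splits no more
likely than the observed one. Normalized counts are rounded to integers
for the conditional test. log2 fold change uses group means floored at
1, so a gene blanketed everywhere has log2FC = 0. Significance is raw
p < 0.05, with BH-adjusted values reported alongside; on all-null
synthetic matrices the realized false-positive rate sits at the nominal
level, and 20 spiked genes at |log2FC| = 2, dispersion 0.05, n = 3 vs 3
are recovered with the correct sign in >90% of cases (both properties
are tests). Exact numerical replication of any external DE package is a
non-goal.

Concordance against the developmental reference (genes high or low in
the embryonic stem zone + pre-neural tube versus neural tube): a
development-low gene is concordant if called significantly down at
either regeneration timepoint, a development-high gene if up at either;
the 2×2 table (low/high × concordant/not) is tested by Fisher's exact
test (two-sided: sum of tables with point probability ≤ observed).
Reference genes absent from the DE results are excluded with a warning.

## Numerical and interface conventions

Times are hours, lengths μm, tables tab-separated UTF-8 with mandatory
headers; no unit inference. Every generator is deterministic given
(configuration, seed), and every CLI run emits a manifest with the
package version, a canonical config hash and the seed. Degenerate
inputs fail loudly: zero-variance weights, coincident geometry points,
empty samples, negative counts and out-of-range probabilities all raise
with the offending field named.

## Problem sizes used by the test suite

The statistical acceptance tests run at the sizes the properties are
stated for: 10⁵ directions for the uniform-null moments, 10⁴ null
samples for test calibration, 20 random parameter sets × 10⁵ founders
per division mode for oracle equivalence, 200 simulated experiments for
parameter recovery, 200 seeded runs for mitotic-index recovery, 40
all-null and 10 spiked 100-gene matrices for the DE chain, and
exhaustive enumeration sweeps for the exact tests. The whole suite
completes in about a minute on one core.

## Known limitations

* The cell-cycle CIs are parabolic and unrescaled; strongly asymmetric
  SSE surfaces (profile widths ~10% larger than Hessian widths in the
  measured designs) and estimated weights push empirical coverage a few
  points below nominal.
* The additive error combination for the population mitotic index is
  reproduced as published; it is not a variance-consistent estimator.
* The orientation test is an asymptotic normal test; very small N would
  need an exact null, which is not implemented.
* The NB test's dispersion shrinkage targets calibration at n = 3 per
  group; with many replicates the trend-floor makes it conservative.
* Synthetic data share the models' own assumptions (fixed phase lengths,
  perfect detection, no cell death); recovery results certify the
  estimators, not robustness to violations of those assumptions.
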