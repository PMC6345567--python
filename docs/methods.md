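# Methods

## The model family

All models describe a single cell at steady state. Free Notch receptor
(N) and free Delta ligand (D) are produced at constant rates α_N, α_D
and degrade with first-order rates γ_N, γ_D. Receptor and ligand
associate in *cis* into an activating complex C⁺ (mass-action, rates
k⁺_C+/k⁻_C+, degradation γ_C+), and — depending on the model — into an
inactive complex C⁻ (rates k⁺_C−/k⁻_C−, degradation γ_C−):

| id | C⁻ scheme | states |
|----|-----------|--------|
| M0 | none | N, D, C⁺ |
| M1 | N + D ⇌ C⁻ (independent of C⁺) | N, D, C⁺, C⁻ |
| M2a | N + D + C⁺ ⇌ C⁻ (single termolecular step) | N, D, C⁺, C⁻ |
| M2b | C⁺ + C⁺ ⇌ C⁻ | N, D, C⁺, C⁻ |
| M2c | D + C⁺ ⇌ C⁻ | N, D, C⁺, C⁻ |
| M2d | 2N + 2D ⇌ C⁻ | N, D, C⁺, C⁻ |
| M2c_trans | M2c plus N + D_trans ⇌ T (activating) | …, T |
| M2c_trans_inhib | M2c plus N + D_trans ⇌ T⁻ (inactive) | …, T⁻ |

The trans-complex (T or T⁻) uses the same formation, dissociation and
degradation rates as C⁺; D_trans is a fixed extracellular ligand level,
not a dynamic species, and dissociating trans-complexes do not feed a
finite ligand pool. T⁻ has identical kinetics to T but never counts
toward activation; total activation is C⁺ + T.

All quantities are dimensionless (arbitrary concentration/time units);
no unit conversion layer exists because the ensemble scan treats every
rate as a dimensionless sample.

### The M2b/M2d stoichiometric convention

In M2b and M2d the C⁻ formation term enters the consumed species'
equations with coefficient 1 while dissociation returns two units
(+2k⁻_C−·C⁻). This asymmetry is deliberate and load-bearing. In the
strictly mass-conserving variant of M2b, steady states satisfy

    γ_C+·C⁺ + 2k⁺_C−·γ_C−·(C⁺)²/(γ_C− + k⁻_C−) = α_N − γ_N·N

whose left side is strictly increasing in C⁺, making C⁺ provably
monotone in α_D — the model could never produce the non-monotonic
profiles this family is meant to probe. Under the asymmetric convention
the quadratic coefficient is proportional to (γ_C− − k⁻_C−), which
changes sign when dissociation outpaces C⁻ degradation; that regime is
what generates interior C⁺ peaks in M2b/M2d. The cost is that the
C⁺/C⁻ cycle is then a net source of complex when dissociation dominates,
so a minority of sampled parameter sets (a fifth to a quarter of the
M2b/M2d ensembles) has no finite steady state. Such sets are reported
honestly as non-converged and excluded from ensemble denominators. A
further consequence is bistability in a sliver of parameter space
(~2–3% of doubly-converged sets), where root finding from the canonical
initial condition and forward integration legitimately settle on
different flux-balanced steady states; the reported state is always the
root-found one, mirroring the original procedure.

## Steady-state solving

Steady states are found by root finding (hybrid Powell) on the
right-hand side from the fixed initial condition
(α_N/γ_N, α_D/γ_D, 1, …, 1) — free species at their binding-free
equilibrium, every complex at 1. Uniqueness is not assumed; the reported
state is the one reached from this initial condition, mirroring how the
ensemble was originally analyzed.

*Convergence criterion.* A root is accepted when the max-abs derivative
is ≤ tol·max(1, S), with tol = 1e-10 and S the largest per-species sum
of absolute flux magnitudes at the solution. The flux scaling is
necessary, not cosmetic: sampled rates reach 1e2 and free-species levels
α/γ reach 1e4, so individual fluxes reach ~1e10 and the best residual
double precision can express after cancellation is ~1e-6. A strict
absolute 1e-10 criterion would brand a large, systematically biased
(high-concentration) chunk of parameter space "non-converged". For
O(1) systems the criterion reduces to the absolute rule.

*Negative components.* Components in (−1e-9, 0) are clamped to zero
(floating-point noise); anything more negative rejects the root and
triggers the fallback, since concentrations must be physical.

*Fallback.* On rejection, the system is integrated (LSODA) over
geometrically growing horizons up to t_max = 1e6 — at least 1e4
characteristic times of the slowest sampled rate (1e-2) — with loose
tolerance (rtol 1e-6), then polished by a second root solve. The
integrator's absolute tolerance scales with the initial-condition
magnitude, and a terminal event aborts trajectories whose state exceeds
1e12 (the diverging M2b/M2d regions; see above). Non-convergence is
recorded, never raised, in batch contexts.

*Independent oracle.* `integrate_to_steady` doubles as a
solver-validation oracle at tighter tolerance (rtol 1e-8); root- and
integration-based states are required to agree within 1e-4 relative
(with a small magnitude-scaled floor for trace-level species) across
random ensembles. A second audit, `flux_balance_residual`, checks the
k-free production/degradation balance per free species, counting complex
stoichiometry (C⁻ carries 2 N + 2 D in M2a, 1 N + 2 D in M2c; in
M2b/M2d the exact printed-form combination carries the net dissociation
source +k⁻_C−·C⁻); it vanishes at any true steady state regardless of
how it was found.

## Ensemble scan

Each model's scanned kinetic parameters (9 dimensions; 6 for M0) are
drawn by Latin Hypercube Sampling — exactly one draw per equal-width
stratum per dimension — over [1e-2, 1e2]. Stratification is uniform in
log10 by default, because the range spans four symmetric decades and the
dose grid is logarithmic; a `sampling_scale="linear"` switch supports
sensitivity analysis. The scale genuinely matters for the minor models:
under linear sampling the M2b non-monotonic subpopulation's median
decline rises from ~0.14 to ~0.31 and M2c's non-monotonic fraction from
~46% to ~62%; the log default keeps the M2c headline fraction closest to
the reported "over 40%". Seeds spawn per-model substreams keyed on a
canonical model index, so adding a model never perturbs another model's
draws, and identical configurations are bit-reproducible.

For each set, α_D is swept over `n_alpha_d` = 10 log-equispaced doses
spanning a 100-fold range symmetric (in log) around the sampled α_N,
i.e. α_N·10^±1. The steady-state C⁺ profile yields:

* peak_index — first 1-based index attaining the maximum (ties break to
  the first, so flat profiles are monotonic);
* incline = (C_max − C_first)/C_max and decline = (C_max − C_last)/C_max,
  both clamped to [0, 1]. Normalizing by C_max (rather than by the
  endpoint values) keeps both features on a common [0, 1] percentage
  scale, the only reading under which "declines of 30–40%" and
  "nearly complete attenuation" can coexist on one axis;
* non-monotonic ⇔ 2 ≤ peak_index ≤ n_alpha_d − 2 (2..8 for the default
  grid, inclusive at 8).

Profiles with any non-converged dose are excluded from ensemble
fraction denominators and counted separately.

### Observed ensemble behavior and known discrepancies

At 2,000 sets per model (seed 0, defaults): M0 and M1 give exactly zero
non-monotonic converged profiles; M2c gives ~46% with median decline
0.83 and profiles exceeding 0.99; M2b gives ~0.7% (median decline 0.14)
and M2d ~3% (median decline 0.02, max 0.27).

Two expectations from the source material do not reproduce and are left
failing in the acceptance suite rather than masked:

* **M2a produces no non-monotonic profiles at all** — 0 hits in more
  than 24,000 sampled sets across both sampling scales and several
  seeds. The termolecular conversion flux k⁺_C−·N·D·C⁻ loses its sting
  at high ligand because N depletion offsets D growth, unlike M2c's
  D·C⁺ flux which grows without bound.
* **The median declines of the M2b/M2d non-monotonic subpopulations
  fall well short of 0.30 under the default (log) sampling.** Under
  linear sampling M2b reaches ~0.31 but M2d stays near 0.16. The
  "30–40%" characterization evidently describes the visible upper range
  of those scatter clouds, not their medians; the M2c-specific claims
  (fraction > 40%, near-complete attenuation, strongest declines of all
  models) reproduce robustly under both scales.

## Cis/trans signal integration

For non-monotonic M2c sets, the trans-level axis reuses the set's own
cis scale: the steady-state free-D values obtained at D_trans = 0 across
the cis dose grid, sorted ascending. The activating-trans model is
solved at every (trans level, cis dose) cell; total activation is
C⁺ + T, and the sensitivity matrix holds adjacent-column differences
(the response to one constant fold-change in cis ligand, since the cis
axis is log-equispaced). Row sums of the sensitivity matrix telescope to
last-minus-first activation columns exactly.

Quadrant medians (the low/high cis x low/high trans regimes) split each
axis at its midpoint index — a parameter-free, configurable choice made
here because the regime boundary is not otherwise defined; summaries are
reported per parameter set (one point per set), with pooling across
cells available via the long-format output. The sensitivity matrix's own
column axis is midpoint-split; for degenerate 2-column grids the low-cis
quadrants carry no sensitivity cells.

The inhibitory-trans analysis pins α_D at the cis-only profile's argmax
and doses D_trans over 0 plus the set's free-D levels. Both raw and
zero-trans-normalized curves are emitted (the appropriate y-scaling is a
presentation choice); the across-set median curve aligns sets by dose
rank because each set lives on its own concentration scale. Receptor
competition makes every converged curve non-increasing; this is asserted
for ensembles of ≥100 sets.

## Trace pipeline

Traces are integrated nuclear fluorescence, background-subtracted, at
30-minute frames. Missing frames are linearly interpolated. Division
correction ("continuization") adds the sister cell's first
post-division value to all frames from the division onward, corrections
accumulating across divisions — restoring the pool lost at each split
without attributing the sister's subsequent production to the tracked
cell. Production rate is a 3-frame centered moving average of the
trace, first-differenced, then smoothed again with the same window
(edges truncate the window); window and which-side smoothing are
configurable since only "smoothed" is specified by the source
procedure, and a 3-frame window is the minimal smoothing consistent
with 30-minute sampling. The peak activation rate is the maximum over
intervals ending strictly before the first division. OLS of peak rate
on nearest-engineered-neighbor distance, with a t-based 95% slope CI,
is the cell-autonomy check.

## Synthetic data generator

The generator emulates what the trace pipeline assumes about real
movies: cumulative accumulation of a stable H2B reporter (no
photobleaching, maturation or degradation), division at configurable
frames splitting the pool by a Beta(50, 50) fraction (tight, symmetric
splits around 0.5), the sister's first-frame value recorded as real
tracking software would, and additive Gaussian measurement noise
(default sd 20 a.u. against a default plateau accumulation of 100
a.u./frame) applied last to both the trace and the recorded sister
values. Defaults — 48 frames at 30 min, reporter onset at frame 6, one
division at frame 24 (~12 h cell cycle) — mirror an overnight imaging
session of engineered fibroblast-like cells. Ground truth (per-frame
rate and cumulative curve, per-cell pre-division peak rate, neighbor
distance drawn independently of rate) is emitted alongside.

What passing recovery tests shows: the pipeline's arithmetic (division
correction, smoothing bias, peak extraction, null regression) is
correct under the stated noise model. What it does not show: robustness
to segmentation dropouts beyond simple gaps, correlated or
multiplicative noise, photobleaching, cell-cycle-dependent expression,
or tracking errors — none of which the generator emulates.

`generate_reporter_traces_from_model` links model space to trace space:
the production rate is a gain times the steady-state activating-complex
level, so dose-dependent predictions (e.g. peak-dose vs highest-dose
activity ratios) can be checked end-to-end through the trace pipeline.

## Problem sizes

Ensemble analyses default to 2,000 sets per model (binomial SE ≈ 1.1%
near a fraction of 0.45), 10-dose profiles, and ≤100-set trans/inhibitory
ensembles; these sizes resolve every qualitative contrast studied here
while keeping a full run on a single core in the minutes range. The
full-scale 10,000-set scan is a command-line flag away
(`--n-sets 10000`).
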