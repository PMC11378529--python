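# Methods

## The dynamical model

The state **y** = (GP, StrD1, StrD2, SNcVTA, DRN, LC)ᵀ collects the average
activation frequency of six areas in Hz.  Each area obeys

    dy_a/dt = −y_a/τ_a + Σ_s ±α_a^s y_s (+ β_S^LC LC² for SNcVTA) + α_a^ext

equivalently **ẏ** = A**y** + C(**y**∘**y**) + **b** with A carrying the
leaks (−1/τ on the diagonal) and the signed couplings, C a single entry
β at (SNcVTA, LC), and **b** the external drives.  The circuit signs encode
the anatomy: striatal inhibition of GP; serotonergic excitation of GP and
striatum; dopaminergic excitation of StrD1, LC and inhibition of StrD2, DRN;
serotonergic inhibition of SNcVTA and LC; noradrenergic excitation of DRN
and mixed (linear-inhibitory, quadratic-excitatory) action on SNcVTA.  The
DRN→SNcVTA projection is reported as possibly mixed; only the inhibitory
variant is modeled.  Coefficients are stored unsigned (all are positive rate
constants); the signs live in the matrix assembler.

Units are strict and audited: τ in seconds (tabulated in ms, converted at
ingestion), couplings α in Hz, external drives α^ext in Hz/s, β pure; every
equation term comes out in Hz/s (`dimensional_audit`).

A state is *physically valid* iff every component lies in [0, F_max].  The
model gives no ceiling, so F_max defaults to 500 Hz (far above any plausible
population rate) and is configurable; negative rates are always invalid.

## Equilibria and stability

Because the only quadratic term is β·LC² in one row, every equilibrium has
the closed form ȳ = u + β·LC²·w with u = −A⁻¹b, w = −A⁻¹e_SNcVTA and LC
solving the scalar quadratic q·LC² − LC + u_LC = 0 (q = β·w_LC).  The
principal branch LC = 2u_LC/(1 + √(1−4qu_LC)) is continuous in β→0 and is
taken as the physiological root; a negative discriminant means no real
equilibrium.  A damped Newton iteration from the literature rest rates is
the generic root-finder; tests require the two routes to agree.

Asymptotic stability is certified by linearization: J = A + 2C·diag(ȳ) must
have every eigenvalue real part below −margin.  The verdict margin defaults
to 1e-6 s⁻¹ (strict negativity is numerically fragile).  During *fitting* a
much stronger margin of −ln(0.01)/0.1 s ≈ 46 s⁻¹ is imposed: the fitness
reads steady states off the equilibrium rather than a trajectory, and
without a settling-rate requirement the optimizer can return models with
slow coupling-induced modes whose transients are not over by the 0.1 s
window the 0.5 s simulation horizon assumes (the slowest leak alone gives
5·18 ms = 90 ms).  With the margin, the slowest mode is ≥99% decayed at
0.1 s for every accepted model.

## Simulation

scipy's variable-order, variable-step BDF integrator, rtol 1e-8 / atol
1e-10, horizon 0.5 s, default initial state all areas silent (y₀ = 0).
Leaving the physical box terminates the run through root-finding events on
min(y) and F_max − max(y), with a 1e-6 Hz slack below zero tolerating
solver-level undershoot of a boundary start; a flagged trajectory never
raises.  The settled state is by default the mean of samples past a 0.1 s
transient cut (robust to ripple); the `last` mode returns the endpoint,
which is the high-precision extractor (the residual transient in the mean
is O(1e-4) relative at the default cut, the endpoint's is O(1e-12)) and is
what the fitness integration path and the acceptance script use.

## Synthetic cohort

No single experiment measures all six areas in one animal, so study
conditions are emulated: per subject, each healthy area rate is drawn from
N(μ, μ/8) truncated by resampling (no boundary atoms) to ±50% of the
literature centers — the ±50% band is exactly 4σ — and the lesioned targets
are multiplicative in the subject's own healthy values (LDA: SNcVTA×0.1,
LC×0.8, GP unchanged; L5HT: DRN×0.3, GP×0.65; LNE: LC×0.2, GP unchanged;
combined lesions constrain GP only to a range, [0.65, 0.75]·GP and
[0.65, 1.0]·GP).  Areas without a labeled value inherit the healthy value in
the exported reference matrix but are *unconstrained predictions* in the
fitness — otherwise the model could not reproduce the observed cross-lesion
effects (e.g. the DRN increase under dopamine depletion).  Time constants
get a per-subject N(0, 0.3 ms) jitter (resampled positive, disabled by a
flag) and are shared across conditions — lesions are assumed not to change
neuron-type time constants.  Subjects are assigned round-robin to the six
experimental groups (40 per group at the default n = 240) for
laboratory-style reporting; the full per-subject condition set is retained.
What the generator does *not* emulate: inter-area target correlations beyond
the shared healthy baseline, measurement noise, or any within-subject
dynamics of lesion onset — passing tests therefore speak to the fitting and
analysis machinery under the stated distributional assumptions, not to real
recordings.

## Fitness

All figures map a non-negative penalty into (0, 1] as 1/(1+penalty) and are
composed as f = min·mean, so one failed figure zeroes f while the mean
rewards uniform quality.  Per-area errors use relative deviations,
1/(1+((sim−target)/target)²), so DRN (~1.4 Hz) and GP (~22 Hz) weigh
comparably; range figures penalize the relative distance to the nearest
bound (bounds inclusive); the stability figure is 1/(1+max(0, λ_max+margin));
the stimulation figure is 1/(1+max(0, S_base−S_treat)).  A model with no
real equilibrium, an aborted simulation or a steady state outside the
physical box scores 0 outright.  The acceptance gate f ≥ 1−10⁻⁸ implies
every figure ≥ 1−10⁻⁸, hence every relative steady-state error ≤ ~10⁻⁴.

## Fitting

A subject has 36 parameters; the 6 time constants are literature-fixed and
30 are optimized *simultaneously*: the 20 healthy rate parameters plus
4 (LDA) + 3 (L5HT) + 3 (LNE) lesion replacements.  Joint optimization is
structural, not a convenience: a lesion's free parameters live entirely in
the lesioned area's equation, so the lesioned steady state of every other
area (e.g. GP×0.65 under L5HT) is decided by the healthy couplings, which
must be shaped by the cross-condition targets.  `fit_condition` remains for
genuinely staged problems (healthy-only recovery, treatments).

Search bounds are wide positive boxes from the dimensional analysis:
couplings [0, 10³] Hz, drives [0, 10⁵] Hz/s, β [0, 10²].  Each retry runs
DE/best/1/exp (Cr = F = 0.95, Halton init, population 15×dimension) with all
equilibrium/eigenvalue evaluations vectorized over the DE population, then
refines the champion with bounded trust-region least squares on the smooth
residual vector (relative errors, range/stability/box hinges, an analytic
continuation through the fold of the quadratic).  Because the composed
fitness is ~0 over most of the box, the refinement rather than DE does the
precision work; when the champion's basin fails, a second refinement starts
from a structured guess drawn with the attempt's seed — couplings drawn as
uniform random shares of each area's equilibrium drive budget y/τ (so
magnitudes scale correctly across areas whose leaks span 55–1250 s⁻¹), free
drives solved in closed form from the equilibrium conditions.  Refinement
box hinges use a 0.1 Hz interior floor so no area of an accepted model rests
at numerically zero activity (where any perturbation would cross the hard
zero bound).  A candidate that reaches the gate is finally audited by full
BDF integration from silence in every condition; a transient that leaves
the physical box voids the attempt.  The outer cycle retries with fresh
seeds (cap 10).  Under the default cohort the first attempt converges for
essentially every subject at ~2 s/subject on one CPU.

## Sensitivity analysis

For each healthy free parameter v the sweep grid is
(i/(n−1) + (n−3)/(2(n−1)))·v, i = 1…n (n = 100), hitting exactly
[0.5v, 1.5v] in uniform steps.  For every grid value the settled state of
each area is recorded; sweeps losing the equilibrium, stability or the
physical box are discarded together with their grid value.  Sweep values
and responses are pooled across the cohort, and
I = std(A/median(A))/std(V/median(V)) with population (ddof = 0) standard
deviations — the convention cancels in the final normalization to the
matrix maximum.  Note a consequence of pooling: each entry also carries the
cross-subject spread of fitted values and targets, so the matrix mixes
local influence with population heterogeneity; the per-subject (n = 1)
matrix isolates pure influence.  Under the cohorts fitted here the external
drives of the striatum and the serotonergic system dominate the pooled
matrix, and the LC drive ranks mid-table: the lesion tables pin GP at its
control value under both LDA and LNE, which steers fitted solutions toward
weak LC output couplings.  The functional centrality of noradrenaline is
instead expressed in the treatment results below.

## Treatments

Treated models start from the subject's fitted dopamine-depleted (LDA)
parameters and free only the external drive of LC (cLC), DRN (cDRN) or both
(cCOMB).  The fitness restores the non-stimulated areas to the subject's
healthy targets (the stimulated area is ignored by its own measure),
requires stability, and forces stimulation over inhibition through
1/(1+max(0, S_base−S_treat)); equivalently the search box floor is the
untreated drive (a flag removes both, a pure relaxation).  The responder
threshold defaults to f ≥ 1−10⁻⁴ (each restored area within ~1% of target):
a published fitness cutoff of "5" is incompatible with f ∈ [0, 1], so the
threshold is configurable rather than hard-coded.  On fitted cohorts here,
LC stimulation restores the measured areas in the large majority of
subjects, DRN-only stimulation never succeeds (raising DRN further inhibits
the depleted SNcVTA), and in combined mode the optimizer's relative DRN
increments are many orders of magnitude below the LC ones.

## Reporting

Group comparisons use D'Agostino–Pearson normality per group, one-way ANOVA
and Tukey's HSD (scipy), with stars at **** ≤ 1e-4 < *** ≤ 1e-3 < ** ≤ 1e-2
< * ≤ 0.05.  Constant groups are flagged and skipped.  Responder vs
non-responder parameter contrasts are reported through the same table, not
through any predictive model.

## Problem sizes and determinism

Default analysis sizes in this repository: 10-subject cohorts for fitting
and sensitivity checks, 20 subjects for treatment studies, n = 240 for
generator-level properties; these desk scales keep a full pipeline run in
tens of seconds while exercising every code path, and all stages —
generation, fits, treatments, reports — are bit-reproducible from a single
master seed.  Known limitations: the fitted parameter set is a point on a
high-dimensional solution manifold (the map from parameters to steady
states is many-to-one), so parameter-space summaries (sensitivity ranking,
responder covariates) characterize this package's solution distribution,
not uniquely identified biology; no receptor-level mechanisms, no
additional areas (cortex, thalamus, STN, SNr), and no stochastic dynamics.
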