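# monoamine-net

A bio-constrained dynamical model of the interplay between dopamine (DA),
noradrenaline (NA) and serotonin (5-HT) in a parkinsonian animal model.  The
package is aimed at computational neuroscientists who want to simulate how
lesions of the monoamine source nuclei reshape basal-ganglia activity, and to
probe candidate treatments in silico.

## The model

Six brain areas are described by their average activation frequency (Hz):
the globus pallidus (GP), the D1- and D2-expressing striatal populations
(StrD1, StrD2), the merged substantia nigra pars compacta / ventral tegmental
area complex (SNcVTA, the DA source), the dorsal raphe nucleus (DRN, the 5-HT
source) and the locus coeruleus (LC, the NA source).  Each area follows a
first-order rate equation with a leak, signed linear couplings along the
anatomical projections, and a constant external drive; NA acts on SNcVTA
both linearly (inhibitory) and quadratically (excitatory), e.g.

```
dSNcVTA/dt = -SNcVTA/τ_S − α_S^DRN·DRN − α_S^LC·LC + β_S^LC·LC² + α_S^ext
```

or compactly **ẏ** = A**y** + C(**y**∘**y**) + **b**.  Time constants come
from the electrophysiology literature (0.8–18 ms); all couplings are
positive, with signs fixed by the circuit.  Every accepted model must have an
asymptotically stable equilibrium (all eigenvalues of the linearization
A + 2C·diag(ȳ) in the left half plane).

A *subject* is a healthy (SHAM) parameter set plus lesion overlays that
replace only the lesioned area's equation parameters: dopaminergic (LDA,
SNcVTA equation), serotonergic (L5HT, DRN equation), noradrenergic (LNE, LC
equation) and their combinations.  Subjects are fitted to a synthetic cohort:
healthy targets drawn per area from N(μ, μ/8) truncated to ±50% of the
literature rest rates, lesioned targets derived multiplicatively (e.g.
SNcVTA·0.1 under LDA, DRN·0.3 under L5HT, LC·0.2 under LNE, GP·0.65 under
L5HT).  Fitting runs differential evolution (DE/best/1/exp, Cr = F = 0.95,
Halton-initialized) over the 30 free parameters of all conditions
simultaneously, refined by a bounded trust-region least-squares stage, with a
composed fitness f = min(fᵢ)·mean(fᵢ) over per-area error, range, stability
and physicality figures; a model is accepted at f ≥ 1 − 10⁻⁸.

On top of the fitted cohort the package computes a one-at-a-time parameter
sensitivity matrix (±50% sweeps, index std(A/med A)/std(V/med V), pooled
across subjects and normalized to its maximum) and optimizes in-silico
treatments of dopamine-depleted subjects by stimulating the external drive
of LC, DRN or both.

## Worked example

```python
import monoamine_net as mn

member = mn.generate_population(
    mn.PopulationConfig(n=1, seed=0, rel_sigma=0.0, jitter_tau=False))[0]
fit = mn.fit_subject(member, seed=42)
for cond in mn.EXPERIMENT_CONDITIONS:
    m = mn.assemble_matrices(mn.apply_condition(fit.subject, cond))
    y = mn.physiological_equilibrium(m)
    states = "  ".join(f"{a}={v:6.2f}" for a, v in zip(mn.AREAS, y))
    print(f"{cond:9s} f={fit.results[cond].fitness:.9f}  {states}")
```

prints (a subject at the population centers):

```
SHAM      f=1.000000000  GP= 22.00  StrD1= 10.00  StrD2=  9.00  SNcVTA=  4.47  DRN=  1.41  LC=  2.30
LDA       f=1.000000000  GP= 22.00  StrD1=  9.06  StrD2= 11.28  SNcVTA=  0.45  DRN=  1.59  LC=  1.84
L5HT      f=1.000000000  GP= 14.30  StrD1=  8.72  StrD2=  7.55  SNcVTA=  4.94  DRN=  0.42  LC=  2.98
LNE       f=1.000000000  GP= 22.00  StrD1=  9.92  StrD2=  9.19  SNcVTA=  4.13  DRN=  1.43  LC=  0.46
LDA+L5HT  f=1.000000000  GP= 15.64  StrD1=  8.06  StrD2=  9.95  SNcVTA=  1.06  DRN=  0.77  LC=  2.43
LDA+LNE   f=1.000000000  GP= 22.00  StrD1=  9.12  StrD2= 11.13  SNcVTA=  0.70  DRN=  1.58  LC=  0.10
```

The healthy row sits exactly on the literature rest rates; under the
dopaminergic lesion SNcVTA collapses by 90% and LC by 20% while GP is held
at its control value, and the unconstrained areas (StrD1 down, StrD2 up) are
model predictions.  Stimulating the LC drive of the depleted model restores
the measured areas:

```python
res = mn.optimize_treatment(fit.subject, "LDA+cLC", member.targets, seed=1)
# responder=True, fitness=1.000000, LC drive increment=1.53x
```

A command line mirrors the library:
`monet generate-population`, `monet fit`, `monet simulate`,
`monet sensitivity`, `monet treat`, `monet report`.

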