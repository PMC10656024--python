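# Methods

## Placental transport model

The model tracks molar concentrations of each IgG species in five
compartments of the maternal–fetal interface: maternal blood (volume
`V_M`), syncytiotrophoblast endosomes (`V_STB`), villous stroma
(`V_STR`), fetal endothelial-cell endosomes (`V_EC`), and fetal blood
(`V_F`).  Per species there are seven states — free IgG in STB
endosomes, stroma, EC endosomes and fetal blood, plus three
receptor–IgG complexes (STB FcRn, EC FcRn, EC-surface FcγRIIb).  The
assumptions: all processes follow mass action; IgG binds FcRn at
acidified endosomal pH inside STBs and ECs after fluid-phase uptake,
and FcγRIIb at the EC surface directly from the stroma; binding to
either receptor commits the complex to transcytosis; unbound endosomal
IgG is degraded in lysosomes; FcRn recycling to the apical surface is
neglected; maternal concentrations, volumes, and affinities are
constant across gestation; the transport rate constants are shared
across layers and subclasses.

**Unit system.** Time in weeks, concentrations molar, volumes liters.
The transport constants `k_up`, `k_trans`, `k_deg`, `δ_Ab` are
clearances (L/week): the molar flux leaving a compartment at
concentration C is `k·C` mol/week, and the receiving compartment's
concentration derivative divides by its own volume.  Binding kinetics
tabulated per second are converted by ×604 800 s/week.  Every exchange
term is written as a mole flux divided by the destination volume, so
with degradation and fetal decay switched off total IgG moles are
conserved exactly; the stroma ↔ EC-surface binding consequently carries
a `V_EC/V_STR` factor on the stromal side.  IgG mass–molar conversions
use a fixed molecular weight of 150 kDa for all subclasses.

**Receptor schedules.** Total FcRn(STB), FcRn(EC) and FcγRIIb(EC)
expression each follow a convex, monotone quadratic in gestational
week, zero at conception and anchored to a calibrated term value:
`R(t) = R_end (t/t_end)²` by default, with arbitrary `(a, b, c)`
coefficients accepted under the same constraints (the underlying rodent
expression data constrain the shape to a convex quadratic but do not
pin its coefficients).  Free receptor is computed algebraically as
total minus bound — equivalent to integrating a separate free-receptor
equation with a synthesis source, since synthesis adds only free
receptor — which keeps a stiff conservation constraint out of the
integrator.

**Parameters.** Eleven parameters (three transport clearances, three
term receptor-expression levels, five volumes) are calibrated
quantities with published plausible ranges; the packaged default is the
midpoint of each range, since ranges rather than point estimates are
what the calibration yields.  Dissociation constants per
receptor–subclass pair come from surface plasmon resonance literature
with a shared `k_off = 0.15/s` and `k_on = k_off/K_D`.  Two candidate
values exist for fetal IgG decay: the tabulated clearance 0.02 L/week
and the 31-day half-life reported for infant IgG (≈0.041 L/week at the
default fetal volume); both are exposed as named constants and the
default is 0.02 L/week.

**Integration.** Per-second binding against per-week transport makes
the system stiff; `solve_ivp(method="LSODA")` with `rtol=1e-8`,
`atol=1e-12` M is used everywhere, with weekly dense output.  The
maternal compartment is a prescribed boundary (constant, or an
arbitrary time course for vaccine-induced species); a
`deplete_maternal` flag integrates it instead, which together with zero
degradation underlies the mass-balance tests (drift < 1e-8 relative;
measured ~1e-14).  Trajectories are validated post hoc for
non-negativity and bound-receptor ≤ scheduled-total (1e-9 M slack)
rather than raising inside the right-hand side, where trial steps may
transiently overshoot.

**Hierarchy determination.** The subclass transfer hierarchy holds iff
the four F:M ratios at delivery are strictly ordered
IgG1 > IgG3 > IgG4 > IgG2; ties count as "not satisfied".  Receptor
sweeps report the hierarchy threshold as the midpoint between the last
passing and first failing grid point.

## Transwell HUVEC model

A seven-state nM/minute model of IgG1/IgG4 competition for FcRn in an
endothelial monolayer: apical IgG binds free receptor, complexes
dissociate or transcytose (`k_trans = 2.5e-5/min`), transcytosed IgG
accumulates, and the receptor recycles on transcytosis so
`[FcRn]+[C1]+[C4]` is exactly conserved.  The printed model equations
carry no degradation term although a lysosomal rate was optimized
alongside them; the default integrates the equations as printed and a
`with_degradation` variant adds `−k_deg·[IgG]` to the free apical
species.  The quasi-steady-state reduction (ligand in excess, receptor
conserved) gives the competitive-Langmuir closed form
`C4 = R0 (I4/K4)/(1 + I4/K4 + I1/K1)`.

**Saturation point.** The 120-minute dose-response rises linearly while
free receptor is abundant and plateaus once the apical dose exhausts
the 2200 nM receptor pool.  Because the approach to the plateau is
hyperbolic (marginal slope ≈ `K_D·R0/s²` beyond the kink), a
small-fractional-slope cutoff lands far past the visual kink; the
saturation point is instead defined as the breakpoint where the
low-dose tangent intersects the plateau tangent (each fit to the three
edge points of the sweep), which recovers the stoichiometric value
≈0.33 mg/ml.  Competition onset is the first IgG1 level at which IgG4
transcytosis falls more than 5% below its IgG1-free value.

## Tdap immunization model

A linear cascade in days: an antigen bolus `Ag0` decays at `δ_Ag` while
generating short-lived (fraction ρ = 96%) and long-lived
antibody-secreting cells, which secrete anti-pertussis-toxin (α-PT) IgG
decaying at `δ_IgG`.  Linearity admits an exact sum-of-exponentials
solution, used as the prescribed maternal α-PT concentration (and
verified against direct integration).  The response peaks at day ≈22
post-dose, inside the expected 14–28-day window, and scales exactly
linearly with `Ag0`.

**Coupling.** The cascade was fit to cohort titer data, so its output
is a relative titer rather than a literal mass concentration: taken
literally as mg/ml the simulated maternal α-PT response would peak near
70 mg/ml, several-fold above *total* serum IgG.  One titer unit is
therefore mapped to 1 µg/ml (`TITER_TO_MG_ML = 1e-3`), making the α-PT
response a trace species (~0.07 mg/ml peak) consistent with the
physiological magnitude of antigen-specific IgG.  The α-PT pool is
split equally across the four subclasses, each transported with that
subclass's affinities as a fifth–eighth species competing with the
endogenous pool for the shared receptors.  The integration is restarted
at `t_vax` so the solver never steps across the source discontinuity.
A consequence of the trace regime is that the α-PT species' receptor
occupancy is proportional to its association rate: an isolated 10-fold
K_D improvement on the vaccine-induced species multiplies its
competitive share ~10-fold and yields a several-fold transfer gain,
rather than the modest gain seen when the vaccine pool itself saturates
the receptors.

**Scenarios.** Timing optimization sweeps `t_vax` on a 1-week grid
(10–38 weeks, clipped below the gestational length) with 0.25-week
refinement around the coarse argmax.  Receptor-deficiency scenarios
report percent change in fetal α-PT IgG at delivery versus the
default-parameter baseline at `t_vax = 25`; dose compensation scans
integer dose multipliers 1–10×; affinity scenarios scale only the α-PT
species' association rates.

## Calibration

Sample-prune calibration over the free-parameter box: LHS-sample
`n ≥ 50` sets, simulate each, and pass a run iff, per subclass, the
simulated fetal concentration at the first target week is ≤ mean + 1 SD
(one-sided, because early-gestation fetal IgG approaches zero) and at
the final target week lies within mean ± 1.5 SD; a flag switches to a
total-IgG variant with SDs combined in quadrature.  Each parameter's
range then shrinks to the [2.5, 97.5] percentile envelope of the
passing draws — a reproducible pruning rule preserving the documented
pass/terminate semantics — and iteration stops once ≥95% of runs pass.
Everything is deterministic given the integer seed.  Intermediate
target weeks feed an RMSE diagnostic only.

## Synthetic data

The cordocentesis-style generator simulates a known truth parameter
set, samples fetal subclass concentrations at weeks 17–41 (default
4-week spacing, emulating a 107-subject cohort), sets the target means
to the simulated values (optionally with lognormal noise of a given CV)
and the SDs to `CV × mean` with CV = 0.25 — the relative spread typical
of cohort antibody measurements.  It emulates the gestational-age
coverage and noise scale of real cordocentesis data but not subject
dropout, assay floors, or non-lognormal outliers, so calibration tests
certify parameter recovery under the model's own dynamics, not
performance on real cohorts.  The vaccine-response generator samples
the α-PT cascade at scheduled days with the same noise model; because
the cascade is linear, only the product `k_ASC·k_IgG·Ag0` is
identifiable when refitting, and the round-trip tests assert recovery
of that product.

## Sensitivity analysis

Designs are uniform Latin hypercubes over the calibrated ranges
(SciPy's `qmc.LatinHypercube`, seeded).  The regression is a
2-latent-variable PLS1 (NIPALS) on z-scored X and y, followed by a
post-hoc rotation of the latent plane so LV1 carries the entire
explained-y direction; the rotation leaves predictions unchanged
(verified against a plain 2-component PLS).  VIP scores use the
standard formula over the unrotated components (weights squared,
weighted by per-component explained y-variance, normalized so
ΣVIP² = p) and are signed afterward by each parameter's rotated-LV1
loading.  Q² = 1 − PRESS/TSS over held-out 5-fold predictions;
significance is the fraction of label-permuted refits whose
cross-validated MSE is at most the real model's (ties count for the
null).  Failed forward runs are dropped pairwise, aborting above a 5%
failure fraction.  X columns are used on their natural scale (a
log-scale option exists); within the narrow calibrated ranges the
response is near-linear, so scaling choice is immaterial there.

## Numerical and design notes

- Sweep grids: receptor-variant sweeps default to 50 log-spaced points
  per decade; analyses accept custom grids, and the benchmark scripts
  use a 0.01-resolution ratio grid around the hierarchy threshold and a
  0.02 mg/ml grid for the Transwell sweep.  Reported problem sizes are
  the grids and n = 1000 LHS rows used throughout.
- Degenerate inputs: all-zero fetal subclass vectors make entropy
  undefined (error); empty sweep grids, non-monotone dose-responses,
  constant outcome vectors and infeasible calibration targets raise
  typed errors rather than returning sentinel values.
- Known divergences of this reconstruction: (i) larger endosomal
  volumes slow lysosomal clearance relative to binding, so across the
  joint LHS box the small endosomal-volume loadings can turn positive
  through interactions even though every volume is locally diluting
  (one-at-a-time sweeps within the calibrated ranges decrease term
  fetal IgG for every volume); (ii) the subclass-entropy OPLSR ranks
  `k_trans` and STB FcRn expression above EC FcγRIIb expression,
  because the calibrated FcγRIIb range is the narrowest of the three
  and entropy responds strongly to the stromal supply that sets the
  degree of FcγRIIb saturation; (iii) the trace-coupling consequence
  for isolated affinity scenarios described above.
- F:M ratios at term come out lower (IgG1 ≈ 0.6) than the >1 ratios
  typical of term cohorts; the hierarchy, its receptor dependence, and
  all competition phenomena are unaffected, but absolute fetal titers
  should be read as model-scale, not cohort-scale, values.
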