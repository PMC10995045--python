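# Methods

This note documents the models, parameters, numerical choices and
limitations behind `kneeflex`, in the order the pipeline uses them.

## Muscle–tendon model

Each muscle–tendon unit (MTU) is an isometric Hill-type model: a
contractile fiber (active + passive force–length curves) in series with an
elastic tendon, pennated at a constant-thickness angle
`α(ℓf) = asin(ℓf_o·sin α_o / ℓf)`. All simulated contractions are
isometric, so no force–velocity relation or activation dynamics are
modelled; activation is an input.

Normalized curves:

* **Active**: `f_AL(l̃) = exp(−(l̃−1)²/γ)`, γ = 0.20 for every muscle.
  The single-Gaussian form is the simplest curve consistent with a
  "Gaussian shape factor"; it is maximal (1) at the optimal fiber length
  and symmetric about it.
* **Passive**: zero at or below optimal length, exponential toe
  `f_PE(l̃) = (e^{k(l̃−1)/0.6} − 1)/(e^k − 1)` with k = 4, reaching 1 at a
  fiber strain of 0.6 above optimal. The passive curve shapes the
  equilibrium but is excluded from reported moments (below).
* **Tendon**: zero for slack tendon; an exponential toe (shape k = 3,
  ending at 2/3 of ε_t0) joined with matching value and slope to a linear
  region anchored exactly at (ε_t0, 1), with ε_t0 = 4.9% for all tendons.
  Any strictly increasing continuous curve through (0,0) and (0.049, 1)
  would serve; these constants are fixed in `mtu_model` and recorded here.

**Equilibrium solve.** The unknown is the fiber projection
`p = ℓf·cos α`; geometric closure `p + ℓt = L_MTU` holds by construction
and Brent's method finds the zero of the normalized residual
`(a·f_AL + f_PE)·cos α − f_T(ε)` on `p ∈ [10⁻⁴·ℓf_o, L_MTU)`. The
normalized equilibrium state is independent of F_max (the residual is
force-normalized), which the sweep engine exploits. With zero activation
and a slack tendon the zero-force state is degenerate; the solver returns
the convention "tendon exactly at slack length". Residuals are below
10⁻⁸·F_max for physiological tendons; for an artificially near-rigid
tendon (ε_t0 → 0) the curve slope approaches the reciprocal of machine
precision and the proportional residual bound is unattainable, so the
hard failure bound is a loose 10⁻³·F_max and the 10⁻⁸ contract is
enforced by the test suite at the standard stiffness.

**Reported moment-generating force.** Joint moments use the *active*
fiber force projected along the tendon. This mirrors the experimental
baseline subtraction, which removes passive (limb-weight and elastic)
contributions from measured torque. The total (active + passive) force is
also exposed for completeness.

## Knee geometry

Per-muscle knee moment arms are cubic polynomials in knee angle (degrees;
0° = full extension; valid on [0°, 90°]; hip and ankle locked).
Musculotendon length follows the tendon-excursion relation integrated in
closed form: flexors shorten, extensors lengthen, as the knee flexes.
Quadriceps act through a single effective extension moment-arm curve per
muscle (no patella body or wrapping surfaces). Biarticular muscles carry a
constant hip moment arm (positive = lengthens with hip flexion:
hamstrings ≈ +6–6.5 cm; rectus femoris and sartorius negative) so the
flexed-hip posture is a linear length offset. A single multiplicative
scale, measured thigh length / 0.413 m, maps the reference skeleton to a
participant; fiber and tendon lengths rescale by the same ratio, which
preserves normalized fiber length and tendon strain at every pose.

Muscles: semitendinosus (ST), semimembranosus, biceps femoris long and
short heads, gracilis, sartorius (flexors); rectus femoris and three vasti
(extensors). The gastrocnemii are excluded: their activation–angle
behaviour during knee-flexion MVC is too uncertain to set a maximal
activation without overstating their contribution.

**Default geometry values.** The packaged moment-arm cubics, reference
MTU lengths and anatomical operating points are this package's own
calibrated asset. Starting values came from published knee moment-arm
anatomy (ST's flexion arm grows from ≈3 cm near extension to ≈5 cm at 90°,
hamstring arms peak at mid-flexion, quadriceps effective arms ≈3–4 cm);
they were then tuned once, within anatomically plausible bounds
(0.5–6 cm), so the baseline model reproduces the reference group's
moment–angle windows, and committed as data (`data/default_model.json`).
Users can replace any of it through the config. Because the defaults are a
calibrated approximation rather than a shared geometry file, the simulated
percentages are reproduced as orderings and feasibility verdicts, not
digit-for-digit.

## Baseline personalization

Anthropometry is the regenerated-subgroup group mean (mass 75.8 kg,
height 1.74 m, thigh 41.3 cm); the package builds one representative
model, not per-participant fits. Non-ST muscle volumes come from linear
regressions `V = b1·(mass·height) + b2`; the packaged coefficients are
per-muscle fits chosen to reproduce typical adult volumes at the group
anthropometry, and direct volume overrides are accepted. Then
`F_max = σ_m·V/ℓf_o` with σ_m = 60 N/cm².

The ST is personalized from imaging: it is modelled as one segment
spanning both compartments, `ℓf_anat = mean(20.5, 24.5) = 22.5 cm`;
`ℓf_o = ℓf_anat·(2.7 µm/ℓ_sarc)` with ℓ_sarc = 2.89 µm (so
ℓf_o = 21.02 cm and the anatomical normalized length is
2.89/2.7 = 1.070); `F_max = σ_m·ACSA_max = 60·11.8 = 708 N`. ACSA_max is
used instead of volume so radial and longitudinal changes separate
cleanly.

**Tendon-slack calibration.** For every muscle, ℓT_s is root-found so the
equilibrium fiber length at the anatomical pose (knee 0°, hip 0°) with
activation 0.01 equals the anatomical target (ST: 22.5 cm; others: the
configured normalized operating point × ℓf_o). The fiber-length residual
is monotone in ℓT_s, so the root is unique on the bracket
[10⁻³ m, 0.95·L_MTU]; calibration is idempotent to <10⁻⁹ m.

## Simulated conditions

The resultant knee-flexion moment is the agonist moment (all flexors at
a = 1) minus the antagonist moment (each quadriceps at a = 0.075). The
calibrated baseline value at each angle (15/45/60/90°) is the reference;
all comparisons use (condition − baseline)/baseline.

Reconstructed-leg conditions, swept in exact 1% steps inclusive of both
bounds (grids of 31 and 12 points; combined conditions take the Cartesian
product — the pairing of the two measured differences is unknown, and the
product is the superset of any pairing):

* **Radial atrophy**: ACSA_max × (1+δ), δ ∈ [−22%, +8%]; F_max follows,
  lengths untouched. Because the tendon is elastic, the active force does
  not scale perfectly linearly with F_max (the operating point shifts
  slightly); the deviation is ≤3% at flexed angles.
* **Serial sarcomere loss**: ℓf_anat × (1+δ), δ ∈ [−17%, −6%], sarcomere
  length unchanged, so ℓf_o scales identically and the anatomical
  normalized length is preserved exactly.
* **Sarcomere shortening**: ℓf_anat and ℓ_sarc both × (1+δ). The scaling
  cancels algebraically in the ℓf_o relation, so ℓf_o is carried over
  bit-identically; the anatomical operating point moves to shorter
  normalized lengths. At long MTU lengths (hip flexed 90°) this mechanism
  makes the muscle *stronger* than baseline.

Both sarcomere mechanisms re-calibrate ℓT_s to the new ℓf_anat. Every
reconstructed-leg condition also reduces each quadriceps F_max by 10%
(consistently reported quadriceps atrophy) at unchanged co-activation, so
the resultant can exceed baseline (by ≈2–3% across angles when ST is
unchanged).

**Decision rule.** A condition "can fully induce" the measured weakness
at an angle if its sweep range [min, max] of relative differences
intersects the experimental Student-t 95% CI of the between-leg
difference, as closed intervals.

**Impairment + compensation.** The ST F_max is scaled (root-found to
10⁻⁴) until the model's relative difference equals the measured deficit at
one angle; if even complete removal cannot reach it, the floor difference
is reported. An activation-scaling impairment variant is available behind
a flag for sensitivity checks. Then the F_max of all five synergists is
raised simultaneously in 1% steps to +20%; the first step whose resultant
reaches or surpasses baseline compensates (no interpolation between
steps; the search starts at +1%).

## Dynamometry

Traces are sampled at 2000 Hz. "Zero-lag fourth-order Butterworth at
20 Hz" is implemented as a 2nd-order filter applied forward and backward
(the standard biomechanics reading of that phrase: the net magnitude
response is 4th-order and the phase is zero), with 1 s reflection padding.
A trial's moment is the maximum 500 ms moving average (causal windows of
round(0.5·fs) samples) minus the mean of the *first* 500 ms; the source
protocol does not state where the baseline window sits, so the
first-half-second convention is this package's documented choice, and the
generator guarantees ≥1 s of pre-contraction rest. Baseline subtraction
doubles as the gravity/limb-weight correction. The MVC is the maximum
across ≥3 trials; another trial is warranted when the last trial is at
least 5% above the best previous one (inclusive boundary, compared as a
ratio so the 5% boundary is exact in floating point). Group summaries use
the Student-t 95% CI, `mean ± t₀.₉₇₅,ₙ₋₁·sd/√n`.

## Synthetic cohorts

The generator emulates the study conditions: n = 7 participants; per-angle
contralateral MVC ~ Normal(mean, SD) truncated positive by redraw
(negligible at the default means/SDs); per-angle between-leg relative
difference drawn directly ~ Normal(mean, SD) — the protocol reports the
mean and SD of per-participant ratios, so generating the ratio directly is
the simplest structure matching those statistics. Defaults are the
regenerated-subgroup values (e.g. 90°: 63.5 ± 18.3 Nm, −32.1 ± 7.9%).
Morphology differences use the midpoint/half-range of the sweep bounds
(ACSA −7% ± 15%, length −11.5% ± 5.5%); the regeneration flag is
Bernoulli(0.7). Traces: 1 s baseline at a 3 Nm offset, 0.5 s half-cosine
ramps, 2 s plateau, Gaussian noise (SD 0.8 Nm), multiplicative
trial-to-trial variability (SD 3%); extra trials are generated while the
continuation rule fires on the true trial values.

What the generator does *not* emulate: between-leg and between-angle
correlations (unreported; assumed independent, configurable), fatigue or
learning across trials, drift or line noise in the traces, and any
participant-level coupling between morphology and strength. Passing
recovery tests therefore show the processing chain is unbiased and the CI
has nominal coverage under the assumed structure — not that real data
meet that structure.

## Problem sizes and tolerances

Stochastic checks use 1000 replicate cohorts for CI coverage (accepted
band 93–97%) and the first 500 for recovery means (accepted within 3
standard errors of the generating mean). The solver-vs-oracle property
uses 100 random parameter draws against a two-stage brute-force grid
(10⁴-point coarse pass, 10⁶-point refinement) at 10⁻⁶·ℓf_o agreement.
Calibration tolerance is 10⁻⁶ m on fiber length; impairment matching
10⁻⁴ on relative difference; sweep grids are integer percentages.

## Known limitations

* One representative group-mean model; no subject-specific fitting.
* Effective 2-D geometry: no wrapping surfaces, patellofemoral mechanics,
  tibial rotation, or insertion-point shifts of the regenerated tendon.
* Isometric only; no force–velocity, activation dynamics, or energetics.
* Maximal flexor activation by assumption (neural factors excluded by
  design); quadriceps co-activation fixed at 0.075.
* The hip-flexed posture is a linear length offset, not full hip geometry.
* Default geometry is a calibrated approximation (see above): orderings
  and feasibility verdicts are the reproducible contract, not exact
  percentages.
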