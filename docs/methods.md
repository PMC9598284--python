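# Methods

## Model structure and assumptions

The model is a minimal whole-body PBPK structure: blood and a single
well-stirred, perfusion-limited lumped tissue compartment close the
systemic loop; the CNS is resolved into brain vasculature, brain
extracellular fluid (ECF) behind the blood–brain barrier (BBB) and cranial
CSF behind the blood–CSF barrier (BCSFB). All exchange is passive and
linear: no saturable transporters, no active efflux, no intracellular
brain compartment. That makes the model appropriate for drugs like
metronidazole (efflux ratio < 2 in vitro) and a deliberate simplification
for anything that is a transporter substrate.

Elimination is a single total blood clearance `CL` acting on the blood
compartment, as the transfer equations are written; no separate renal and
hepatic routes are resolved. Drug enters the CNS only through the two
barrier clearances `PS_ECF` and `PS_CSF` (L/h), moves from ECF to CSF by
bulk flow `Q_bulk`, and leaves CSF by reabsorption `Q_sink` back into the
brain vasculature and, when a drain is present, by the EVD flow `Q_EVD`
into an absorbing collection bag. The drain is assumed to substitute for
blocked physiological CSF outflow, so `Q_sink = max(Q_sink,physio − Q_EVD, 0)`;
the clamp at zero covers drains running faster than physiological
reabsorption.

States are stored as amounts (mg); concentrations are derived by dividing
by compartment volumes. This keeps the variable-volume EVD bag clean: the
bag accrues amount at `C_CSF·Q_EVD` and the per-interval bag volume
converts it to a concentration.

An individual is characterized by total body weight: the lumped tissue
volume is the body volume (1 kg taken as 1 L, i.e. unit body density) minus
blood, brain-vascular, ECF and CSF volumes, and the blood-flow budget
requires the tissue flow fraction `fd` plus the brain fraction
`Q_brain/CO` to stay at or below one. The default `fd = 0.86` is the
maximum allowed value at the default physiology, rounded to two decimals.

## Key parameters

| symbol | meaning | unit | default |
|---|---|---|---|
| `CL` | total blood clearance of unbound drug | L/h | 7.28 |
| `Kp` | unbound tissue-to-blood partition coefficient | – | 0.796 |
| `PS_ECF` | BBB permeability–surface clearance | L/h | 6.4 |
| `PS_CSF` | BCSFB clearance, half of `PS_ECF` (half surface area) | L/h | 3.2 |
| `fd` | fraction of cardiac output to lumped tissue | – | 0.86 |
| `Q_bulk` | ECF→CSF bulk flow | L/h | 0.0105 |
| `Q_sink,physio` | physiological CSF reabsorption | L/h | 0.024 |
| `CO`, `Q_brain` | cardiac output, cerebral blood flow | L/h | 312, 42 |
| `V_blood`, `V_brain,vasc`, `V_ECF`, `V_CSF` | volumes | L | 5.85, 0.0637, 0.24, 0.130 |
| `SA_BBB`, `B_W` | BBB surface area, brain weight | cm²/g, g | 157, 1274 |

Units are fixed package-wide (h, L, mg, mg/L); no unit conversion happens
inside the core. The in-vitro scaling converts a Caco-2 apparent
permeability in cm/s to L/h as `Papp·3600·SA_BBB·B_W/1000`.

## Observation model

Plasma samples are point observations of the unbound blood concentration
(the dataset is assumed to contain unbound concentrations on the blood
scale; the blood-to-plasma ratio, default 0.82, is carried in the drug
parameters for conversions outside the core). Microdialysate fractions
are interval observations: the written integral form of the dialysate
observation is dimensionally a concentration×time, so it is interpreted —
per standard microdialysis practice — as the **time-average** of the ECF
concentration over the collection interval, i.e. the integral divided by
the interval length. Dialysate values are assumed to be already corrected
by the in vivo probe recovery; an option applies the correction from raw
values. EVD observations are the bag concentrations
`Q_EVD·∫C_CSF dt / V_EVD` per collection interval. The bag volume should
equal `Q_EVD·Δt`; because it may also be measured independently, a
mismatch beyond a configurable relative tolerance (default 5%) raises a
warning rather than an error.

## Numerics

The system is linear with piecewise-constant coefficients (infusion
on/off, EVD collection intervals), so each segment is propagated exactly
with a matrix exponential; the state is augmented with running time
integrals of the blood, ECF and CSF amounts so interval averages and AUCs
are analytic, not grid-dependent. The default output grid is 0.05 h,
cosmetic only. Steady state under repeated dosing solves the periodicity
condition `x(τ) = x(0)` with the within-interval propagator; a residual
and spectral-radius check guards the solve, falling back to repeated
dosing (relative tolerance 1e-8, up to 500 cycles) and raising with the
residual if the system has no stable cycle (e.g. `CL = 0`). Zero dose
short-circuits to the zero state.

The estimation hot path evaluates predictions for many (subject,
clearance) cases in a single pass: segment generators are assembled as a
stacked array and exponentiated with a vectorized scaling-and-squaring
Padé-13 routine (`expm_batch`), because exponentiating thousands of 8×8
matrices one by one dominates run time otherwise. The batched engine is
cross-checked in the test suite against the reference simulator (agreement
~1e-12) and the reference simulator against an independent adaptive ODE
solve (1e-6).

## Population estimation

Between-subject variability is a log-normal random effect on clearance
only (`CL_i = CL·exp(η_i)`); residual error is proportional plus additive
for plasma and proportional for the CNS streams. The marginal likelihood
is approximated by the Laplace method: per-subject posterior modes of `η`
are found by a safeguarded Newton iteration run in lockstep across
subjects (warm-started between objective evaluations), and the curvature
from a central difference (step 1e-3) supplies the Laplace correction.
This is a conditional-estimation approximation in the same family as
FOCE; exact agreement with any particular estimation software is not a
goal — parameter recovery is. The test suite checks the Laplace marginal
against brute-force quadrature over `η` (agreement well under 1%).

Free parameters (`CL`, `Kp`, IIV SD, four residual SDs, optionally the two
barrier clearances) are optimized in log space with Nelder-Mead
(`xatol 5e-4`, `fatol 1e-4`) from three jittered starting points by
default, best objective kept and ties broken by first convergence.
Starting values: `CL` from the naive pooled dose-rate over the median
plasma concentration, `Kp = 1`, SDs at 20% (additive 1 mg/L). `fd` is
fixed at 0.86 and the barrier clearances at 6.4/3.2 L/h unless the
`estimate_ps` mode frees them. Parameter uncertainty comes from a
nonparametric subject-level bootstrap (resample subjects with
replacement, refit from the original estimates, percentile intervals);
more than 20% refit failures abort with an error.

Two estimator properties worth knowing. First, with proportional residual
error the likelihood contains `−log(pred)` terms, so even noise-free data
pull the individual clearance modes slightly above the generating value
(smaller predictions mean smaller modelled variance); this is inherent to
proportional-error maximum likelihood, visible in the empirical-Bayes
modes, and small at the study's noise levels. Second, with only eight
subjects the two barrier clearances are weakly identifiable when freed:
single-replicate estimates of the `PS_ECF:PS_CSF` ratio scatter widely and
the 2:1 generating ratio is recovered in the median over replicate
cohorts, not in each one.

## Synthetic cohorts

The generator reproduces the study design: 500 mg infused over 0.5 h every
8 h at steady state; four subjects with microdialysis (dialysate stream)
and four with an EVD (bag stream); 7–13 plasma samples per subject thinned
from a 13-point candidate schedule (0.25–8 h; exact clinical sampling
times were not recorded, so a plausible schedule is used); CNS fractions
at 0.5-h intervals to 3 h (the midpoint of the 2–4 h range used
clinically, configurable) and 1-h intervals to 8 h. Body weights are
uniform over 75–115 kg (the observed range) or an explicit list; probe
recoveries uniform over 0.40–0.90 (plausible for in vivo microdialysis of
a small hydrophilic drug; the study values were not reported); EVD flows
drawn per collection interval uniformly over 0.001–0.04 L/h, bag volumes
consistent with flow×duration (optional jitter exercises the consistency
warning). Residual noise follows the fitted error model, redrawn when a
draw lands at or below zero.

What the generator does **not** emulate: covariate effects on clearance,
within-day changes in physiology, assay limits of quantification, missing
samples, or measurement-time error. Passing recovery tests therefore show
that the estimation machinery is consistent with the model and design —
not that the model is right for any particular patient population.

## Sensitivity analyses

One-at-a-time sweeps after a single 500 mg/0.5-h infusion, AUC horizon
0–24 h (more than five elimination half-lives at the default clearance):
barrier clearances ×1–5 (both together, preserving the 2:1 ratio,
mirroring pathological permeability increase), ECF volume ×1–1.4 (oedema),
cerebral blood flow ×0.2–1 (hypoperfusion to critical ischemia), all other
parameters at reference values and a 90 kg reference patient. "No
effect" is operationalized as below 5% AUC deviation, a stated threshold
for what is otherwise qualitative language. The EVD sweep covers drain
flows 0–0.04 L/h with the sink coupling, reporting the single-dose CSF AUC
deviation and the steady-state dose fraction recovered in the bag. For
the default high-permeability drug all deviations are well under the 5%
threshold; the bag fraction grows with drain flow and stays in the
sub-percent range (about 0.27% at 0.02 L/h, about 0.5% at the clamped
0.04 L/h extreme).

## Problem sizes in the shipped experiments

The recovery experiment in the acceptance script uses 20 replicate
8-subject cohorts for `CL`/`Kp` (median across replicates) and 10
replicate 50-subject cohorts for the IIV %CV, with 2 and 1 optimizer
starts respectively; these sizes give stable medians while keeping a full
run around ten minutes on one CPU. The package default remains 3 starts.

## Known limitations

- Strictly linear kinetics: no transporter saturation, no nonlinear
  binding; superposition is exact by construction.
- The blood clearance acts on the blood-compartment concentration exactly
  as the transfer equation is written; no plasma/blood scale subtleties
  inside the core.
- GOF fold errors compare trapezoid AUCs on the observed sampling times
  for both observed and predicted values, so sparse-sampling bias cancels
  between the two rather than being corrected.
- Barrier clearances are practically unidentifiable for high-permeability
  drugs (CNS profiles shadow blood); the `estimate_ps` mode is meaningful
  only for low-permeability scenarios.
- The VPC uses plain (not prediction-corrected) percentile bands, binned
  by each observation's own sampling slot.
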