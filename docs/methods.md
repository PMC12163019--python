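# Methods

This note documents the models, calibrations and numerical choices behind
`zabedopk`, and what the synthetic-data experiments do and do not show.

## The structural PK model

Zabedosertib's exposure rises sub-proportionally with dose, and its
multiple-dose accumulation (RA_AUC 1.1–1.7) falls far short of the
1/(1 − 2^(−τ/t½)) ≈ 3.65 implied by the ~26 h terminal half-life. The model
captures both with two mechanisms on top of a one-compartment backbone:

1. **Dose-dependent oral bioavailability.** The published analysis states
   only that availability decreases with dose; the functional form is not
   public. We adopt a saturable hyperbola anchored at the measured absolute
   bioavailability of the 120 mg reference dose,

       F(D) = F_ref · (1 + 120/D₅₀) / (1 + D/D₅₀),   F_ref = 0.739,

   with D₅₀ = 220 mg calibrated once against the published single-dose AUC
   geometric means (the simulated AUC(480)/AUC(120) ratio is 1.57 vs the
   printed 188/119 = 1.58). This is a modeling choice of this package, not a
   published claim.

2. **Capacity-limited, kinetically slow plasma binding.** A high-affinity,
   low-capacity binding site (AGP-like; K_d 0.4 µM, B_max 14.9 µM,
   dissociation half-life 12 h, hence koff = ln2/12 h⁻¹ and
   kon = koff/K_d ≈ 0.144 µM⁻¹h⁻¹) exchanges drug with the unbound pool via
   second-order association and first-order dissociation. Elimination acts on
   the unbound concentration (CLu). The equilibrium unbound fraction is
   fu(Cu) = (K_d + Cu)/(K_d + Cu + B_max): 2.61% at trace concentrations
   (inside the measured pre-dose range of 1.44–4.00%) and rising with
   concentration, which is exactly the observed behavior.

States are gut amount A (µmol), unbound Cu and bound CB (µM); total plasma
concentration is Cu + CB. IV doses enter the central compartment directly.
Oral doses deposit F(D)·D into the gut, i.e. availability is applied at dose
time (equivalent to scaling the absorption flux).

### Calibration (fixed once, then left alone)

| Parameter | Value | Source/rationale |
|---|---|---|
| CLu | 0.551/fu(0) ≈ 21.1 L/h | trace-level total clearance = 0.551 L/h (IV microtracer) |
| V | 20.1 L | published terminal volume; gives the 25.3 h linear-limit t½ |
| ka | 1.0 h⁻¹ | tmax ≈ 3.7 h, inside the observed 1.5–5 h |
| t_lag | 0 h | the 2–6 h absorption plateau is not mechanistically modeled |
| F_ref, D₅₀ | 0.739, 220 mg | see above |
| K_d, B_max, koff | 0.4 µM, 14.9 µM, ln2/12 h⁻¹ | published binding estimates |
| mw | 464.5 g/mol | externally supplied; see below |

**Molecular weight.** The publications never print the compound's molecular
weight, which any µM-scale binding model needs against mg/L concentrations.
`DEFAULT_MW = 464.5 g/mol` is supplied as an external registry-scale
constant; every molar-scale result (notably the occupancy projection) is
conditional on it, and it is a plain config value (`BindingParams.mw`).

### Known deviations from the published profile

- The *emergent* terminal half-life of the calibrated nonlinear model is
  ~36 h, not the observed ~26 h: with a 12 h dissociation half-life the
  terminal phase is dissociation-limited. The published 25.3 h figure is
  reproduced exactly in the linear (B_max → 0) limit with CL 0.551 L/h and
  Vz 20.1 L, which is what the model-structure tests assert.
- Simulated unbound concentrations spike sharply just after each oral dose
  (slow association cannot buffer a fast absorption flux), so simulated
  unbound Cmax and PTF exceed the published unbound values severalfold while
  interval AUC and Cav remain close. Published summary statistics of
  *unbound* peaks should therefore not be compared quantitatively against
  the generator.
- The observed 1.44-fold fed/fasted Cmax ratio is not reachable in this
  model by changing the absorption rate alone (binding caps the effect near
  1.28); the generator's food factors (ka ×3.0 high-fat, ×2.8 moderate-fat,
  ×1.5 light meal) produce a direction-correct, smaller effect with AUC
  unchanged. Food-effect *statistics* are validated on their own ground
  (the crossover ANOVA reproduces known injected effects and the printed
  ratios from printed geometric means).

## Numerics

ODE integration uses LSODA with rtol 1e-8 / atol 1e-10 (relaxed to 1e-6
inside optimization loops, where residuals are ≥1% anyway). Dose events
split the integration into segments; grid points at a dose time report the
pre-dose (left-limit) state. `steady_state_profile` repeats an interval
until its total-concentration AUC changes <0.1% (cap 30 intervals; ~8
intervals at 120 mg BID). The finite-difference step of the least-squares
fit is 1e-4 on log-parameters, chosen to dominate integration noise — with
the scipy default step the Jacobian is numerically meaningless and the
optimizer stalls.

λz selection: best adjusted R² over all contiguous terminal windows of ≥3
positive concentrations (excluding Cmax, unless the profile starts at its
maximum, as an IV bolus does), preferring windows spanning ≥2 estimated
half-lives; slopes ≥ −1e-12 are treated as not estimable. AUC uses
linear-up/log-down trapezoids by default (pure linear and pure log variants
exist for oracle tests), and AUC(0–∞) = AUC(0–tlast) + Clast/λz.

## The microtracer co-simulation

The absolute-bioavailability design gives a 0.100 mg IV stable-isotope
tracer *on top of* the 120 mg oral dose. In a nonlinear-binding system this
detail is load-bearing: a tracer simulated alone sits in the trace-binding
regime (total clearance 0.551 L/h), while the real tracer shares the binding
pool with the cold dose and samples the disposition at the therapeutic
operating point — which is why (AUC/D)_oral/(AUC/D)_IV recovers F. The
generator therefore co-simulates both species with shared free binding
sites. In the linear limit the recovered F is exact; with full binding and
the 96 h sampling horizon the NCA estimate of F carries a ~5% downward
extrapolation bias, which the tests document.

## Target-occupancy projection

Occupancy follows dTO/dt = kon·Cu(t)·(1 − TO) − koff·TO with
koff = 60/residence-time (12 h⁻¹ for 5 min) and kon = koff/K_d, K_d set
equal to the whole-blood IL-6 IC50 of 86 nM (50% inhibition ⇔ 50%
occupancy; no Hill correction). Drug is assumed in excess of target, so Cu
is an external forcing. The ODE is linear in TO given Cu and is advanced
with exact exponential steps on midpoint-interpolated Cu (substeps capped —
the step is exact for constant Cu, so refinement only needs to resolve Cu's
variation). Because the residence time is minutes against day-scale PK,
kinetic occupancy tracks the quasi-equilibrium value Cu/(Cu + K_d) to <1%
except during the first ~15 minutes after an oral dose, where the simulated
unbound spike rises on a ~90 s timescale and the kinetic solution genuinely
lags by a few percent; trough occupancy (the decision quantity) is
unaffected (<0.1%).

The dose→trough curve simulates a virtual population (default lognormal
ω = 0.25 on CLu, V, ka and logit-F), reads occupancy at the end of the
steady-state interval, and averages across subjects. The band propagates
only the IC50 95% CI (60–122 nM) through the same computation — PK parameter
uncertainty is deliberately excluded, matching how the published projection
frames its interval. With the calibration above, the projection gives ~0.75
at 120 mg BID (published mean 0.79, interval 0.72–0.84) and ~0.67 at 240 mg
QD (published 0.67); both figures are conditional on the supplied molecular
weight and on this package's calibration, since the underlying population
parameters are unpublished.

## Synthetic-data generator

The generator's defaults are the study conditions: SAD single doses
5–480 mg (6 active + 2 placebo per group, one 240 mg split arm), MAD
45/120 mg QD and 60/120/200 mg BID for 10 days (8 + 2 per group, dosing
after a light meal), FE three-period crossover of 120 mg
(fasted/high-fat/moderate-fat, two sequences of 5) with the IV microtracer
in the fasted period. Between-subject variability is lognormal with
ω = 0.25 on CLu, V, ka and logit-scale F — the true magnitudes are in an
unpublished report; 0.25 reproduces the ~20–30% geometric CVs of the
published exposure tables. Residual error is proportional
(c·exp(σε), σ = 0.15 by default, homoscedastic on logs; an additive
LLOQ/2 floor is available), and observations below the LLOQ (defaults
1e-3 mg/L total, 1e-5 mg/L unbound/tracer) are censored. Sampling uses a
rich 0–96 h schedule (the real schedules are in an unpublished supplement).
One root seed drives everything; per-subject generators come from
deterministic `SeedSequence` spawn keys, so adding arms or subjects never
changes existing ones.

What passing tests show: the statistical machinery (NCA identities,
ratio/ANOVA estimators, fitting, occupancy kinetics) is correct against
independent oracles, and the calibrated model reproduces the program's
headline quantitative anchors and qualitative findings. What they do not
show: that real trial data would yield these numbers — the generator omits
dropout, the absorption plateau, assay batch effects, and uses calibrated
(not reported) variability magnitudes.

## Estimation

Population estimation is deliberately two-stage rather than nonlinear
mixed-effects: each subject is fit by least squares on log concentrations
(proportional error ⇒ homoscedastic on logs), parameters on the log scale
with ±100× bounds, three starts (the initial values plus two jittered ×/÷
uniform [1, 2] per parameter, seeded), keeping the best solution and
guaranteeing the objective never exceeds its value at the initial point.
Converged subjects are summarized as geometric means and geometric CVs
(100·√(exp(s²) − 1)). At phase-1 scale (rich sampling, 5–10 subjects per
group) this recovers typical values and CVs well — the recovery report shows
<2% bias for CLu and V at 10% residual noise — but it is not a substitute
for mixed-effects inference on sparse data, and the module interface would
admit such a backend.

Default free parameters are (CLu, V, ka) with availability and binding fixed;
D₅₀ is identifiable only from designs spanning a wide dose range, and the
binding koff is weakly identifiable from single-dose data — both are left
fixed unless explicitly requested.
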