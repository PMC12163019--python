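# zabedopk

Phase-1 PK/PD analysis chain for **zabedosertib**, an oral IRAK4 (interleukin-1
receptor-associated kinase 4) inhibitor developed for immune-mediated
inflammatory diseases. The package re-implements, as tested reusable code, the
computational pipeline behind an early clinical program of that kind:

- **Noncompartmental analysis (NCA)** — terminal slope λz (best adjusted-R²
  window), linear-up/log-down AUC/AUMC, single-dose parameters (AUC(0–∞),
  Cmax, t½ = ln2/λz, CL/F = D/AUC, Vz/F = CL/F/λz, MRT, Vss) and multiple-dose
  parameters (AUCτ, Cav = AUCτ/τ, PTF, accumulation ratio
  RA_AUC = AUCτ,ss/AUCτ,sd, linearity factor R_LIN).
- **Exposure statistics** — geometric-mean ratios with 90% t-based CIs,
  dose-normalized ANOVA ratios, the dose-proportionality power model
  log E = α + β·log D, crossover food-effect ANOVA (subject + period +
  treatment on logs), and absolute bioavailability from an IV microtracer,
  F = (AUC/D)_oral / (AUC/D)_IV.
- **Structural PK model** — one compartment, first-order absorption,
  elimination on the *unbound* concentration, dose-dependent bioavailability
  F(D) = F_ref·(1+120/D₅₀)/(1+D/D₅₀), and capacity-limited plasma binding
  (AGP-like site, K_d 0.4 µM, B_max 14.9 µM, dissociation t½ ≈ 12 h) modeled
  kinetically:

      dCu/dt = ka·A/V − (CLu/V)·Cu − kon·Cu·(Bmax − CB) + koff·CB
      dCB/dt = kon·Cu·(Bmax − CB) − koff·CB,      C_total = Cu + CB

  This reproduces the compound's signature nonlinearities: sub-proportional
  exposure with dose and multiple-dose accumulation far below the
  1/(1 − 2^(−τ/t½)) ≈ 3.65 expected from the ~26 h half-life alone.
- **Two-stage population fit** — per-subject weighted least squares on log
  concentrations (multi-start, log-scale parameters), lognormal population
  summaries, and simulate-then-fit recovery reports.
- **Target-occupancy projection** — sigmoidal-Emax IC50 estimation from
  whole-blood IL-6 inhibition data, kinetic IRAK4 binding driven by unbound
  PK (K_d = IC50 = 86 nM, residence time ≈ 5 min, drug in target excess), and
  dose → steady-state trough-occupancy curves with an IC50-uncertainty band.
- **Synthetic-trial generator** — the clinical datasets are not public, so a
  seeded generator emulates the three study designs (SAD 5–480 mg single
  doses; MAD 45/120 mg QD and 60/120/200 mg BID × 10 days; a three-period
  food-effect crossover of 120 mg with a 0.100 mg IV microtracer co-simulated
  against the shared binding pool), with lognormal between-subject
  variability, proportional residual error and LLOQ censoring.

Intended users: clinical pharmacologists and pharmacometricians who want a
transparent, scriptable version of this analysis chain, and anyone needing a
realistic nonlinear-PK test bed.

## Worked example

```python
>>> import numpy as np, zabedopk as z
>>> p = z.default_params()                 # calibrated typical subject
>>> z.bioavailability_of_dose(120.0, p)    # F at the reference dose
0.739
>>> t = np.linspace(0, 96, 200)
>>> prof = z.simulate_profile(p, [z.DoseEvent(0.0, 120.0)], t)
>>> res = z.nca_single(t, prof.c_total, dose=120.0)
>>> round(res.cmax, 2), round(res.auc_inf, 1)
(2.58, 129.0)
>>> round(z.theoretical_accumulation(26.0, 12.0), 4)  # linear expectation, BID
3.6525
```

The simulated 120 mg profile peaks near 2.6 mg/L with AUC(0–∞) ≈ 129 mg·h/L
(published geometric means: 3.30 and 119), and the linear-superposition
accumulation benchmark is 3.65 — against which the model's simulated RA_AUC
of ~1.6–1.9 demonstrates the binding-driven accumulation shortfall.

The full analysis is a numbered pipeline:

```bash
python analysis/01_simulate_trials.py      # synthetic SAD/MAD/FE datasets
python analysis/02_single_dose_nca.py      # single-dose NCA tables
python analysis/03_multiple_dose_nca.py    # day-10 NCA, accumulation
python analysis/04_exposure_statistics.py  # dose proportionality, food, F
python analysis/05_fit_structural_model.py # two-stage fit + recovery
python analysis/06_occupancy_projection.py # dose->trough occupancy curve
```

Each script prints its findings and writes tables under `results/`. A thin
CLI (`zabedo-pkpd simulate|nca|stats|occupancy|run`) wraps the same library
calls; `zabedo-pkpd run --config cfg.yaml` drives the whole chain with a
manifest for reproducibility.

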