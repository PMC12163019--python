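"""Published phase-1 summary statistics for zabedosertib.

The raw clinical data are not public; the published reports print per-group
geometric means (with geometric CVs) for the noncompartmental parameters, the
food-effect ratios, and the target-binding constants. Those printed summaries
are inputs to desk-level reproductions (ratio arithmetic, model anchoring)
and fixture anchors for the synthetic-data generator. Units: mg, h, mg/L
unless noted; the IV-microtracer areas are on a µg·h/L scale (a 0.100 mg
dose with ~0.55 L/h clearance forces that scale).
"""

from __future__ import annotations

# -- single-dose, tablets, fasted: geometric means by dose [mg] --------------
# AUC = AUC(0-inf) [mg·h/L]; Cmax [mg/L]; t_half [h]; CL/F [L/h]; Vz/F [L]
SINGLE_DOSE_FASTED = {
    15:  {"auc": 32.1, "cmax": 1.13, "t_half": 24.0, "cl_f": 0.467, "vz_f": 16.2},
    30:  {"auc": 69.5, "cmax": 1.92, "t_half": 26.5, "cl_f": 0.432, "vz_f": 16.5},
    60:  {"auc": 107.0, "cmax": 2.91, "t_half": 26.7, "cl_f": 0.561, "vz_f": 21.6},
    120: {"auc": 119.0, "cmax": 3.30, "t_half": 24.4, "cl_f": 1.01, "vz_f": 35.6},
    240: {"auc": 182.0, "cmax": 4.43, "t_half": 24.3, "cl_f": 1.32, "vz_f": 46.2},
    480: {"auc": 188.0, "cmax": 4.65, "t_half": 22.8, "cl_f": 2.56, "vz_f": 84.2},
}

# -- multiple-dose (day 10), unbound, fed: geometric means by regimen --------
# auc_tau [mg·h/L over the dosing interval]; c_av, c_max [mg/L]; ratios unitless
MULTIPLE_DOSE_UNBOUND = {
    "45 mg QD":   {"dose": 45.0, "tau": 24.0, "auc_tau": 1.65, "c_av": 0.0689,
                   "c_max": 0.109, "ra_auc": 1.26, "r_lin": 0.757},
    "120 mg QD":  {"dose": 120.0, "tau": 24.0, "auc_tau": 3.17, "c_av": 0.132,
                   "c_max": 0.217, "ra_auc": 1.14, "r_lin": 0.628},
    "60 mg BID":  {"dose": 60.0, "tau": 12.0, "auc_tau": 1.94, "c_av": 0.161,
                   "c_max": 0.190, "ra_auc": 1.72, "r_lin": 0.455},
    "120 mg BID": {"dose": 120.0, "tau": 12.0, "auc_tau": 3.20, "c_av": 0.267,
                   "c_max": 0.351, "ra_auc": 1.61, "r_lin": 0.521},
    "200 mg BID": {"dose": 200.0, "tau": 12.0, "auc_tau": 3.26, "c_av": 0.272,
                   "c_max": 0.366, "ra_auc": 1.56, "r_lin": 0.484},
}

# -- published dose-proportionality LS-mean ratios (unbound, multiple dose) --
DOSE_PROPORTIONALITY_RATIOS = {
    ("c_av", "120 mg QD", "45 mg QD"): 0.718,
    ("c_av", "200 mg BID", "120 mg BID"): 0.612,
    ("c_max", "120 mg QD", "45 mg QD"): 0.745,
    ("c_max", "200 mg BID", "120 mg BID"): 0.627,
}

# -- food-effect / absolute-bioavailability study (n = 10) -------------------
# oral 120 mg per condition; tracer 0.100 mg IV; tracer areas in µg·h/L
FOOD_EFFECT_STUDY = {
    "high-fat": {"cmax": 4.63, "auc": 158.0, "t_half": 25.7},
    "fasted":   {"cmax": 3.22, "auc": 161.0, "t_half": 26.1},
    "moderate-fat": {"cmax": 4.59, "auc": 172.0, "t_half": 27.0},
    "iv_tracer": {"dose_mg": 0.100, "cmax_ugL": 10.7, "auc_ughL": 181.0,
                  "t_half": 25.3, "cl_Lh": 0.551, "vz_L": 20.1, "vss_L": 17.7,
                  "mrt_h": 32.2},
}

#: published geometric-LS-mean food-effect ratios with 90% CIs
FOOD_EFFECT_RATIOS = {
    ("cmax", "high-fat", "fasted"): (1.44, (1.29, 1.61)),
    ("auc", "high-fat", "fasted"): (0.980, (0.916, 1.049)),
    ("cmax", "moderate-fat", "fasted"): (1.43, (1.29, 1.58)),
    ("auc", "moderate-fat", "fasted"): (1.07, (0.967, 1.18)),
}

#: absolute oral bioavailability at 120 mg fasted, % (point, 90% CI)
ABSOLUTE_BIOAVAILABILITY_PCT = (73.9, (68.5, 80.8))

# -- plasma binding and target-occupancy constants ---------------------------
AGP_BINDING = {"kd_uM": 0.4, "b_max_uM": 14.9, "dissociation_t_half_h": 12.0}
PREDOSE_FU_RANGE_PCT = (1.44, 4.00)   # ex vivo unbound fraction, pre-dose
AGP_RANGE_G_L = (0.41, 0.91)

WHOLE_BLOOD_IC50_NM = (86.0, (60.0, 122.0))   # IL-6 inhibition, mean (95% CI)
TARGET_RESIDENCE_TIME_MIN = 5.0

#: projected steady-state trough occupancy, mean (CI from IC50 uncertainty)
TROUGH_OCCUPANCY = {
    "120 mg BID": (0.79, (0.72, 0.84)),
    "240 mg QD": (0.67, (0.58, 0.74)),
}

#: terminal half-life (~26 h) and BID interval used for the theoretical
#: linear accumulation ratio of 3.65
ACCUMULATION_INPUTS = {"t_half_h": 26.0, "tau_h": 12.0, "expected": 3.65}
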