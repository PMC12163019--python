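"""Seeded generator of SAD / MAD / FE-style phase-1 trial datasets.

The designs emulate the zabedosertib phase-1 program: a single-ascending-dose
study (5-480 mg, 6 active + 2 placebo per group, with a split-dose arm), a
multiple-ascending-dose study (45/120 mg QD and 60/120/200 mg BID for 10
days, 8 active + 2 placebo per group), and a food-effect/absolute-
bioavailability study (three-period crossover of 120 mg oral fasted /
high-fat / moderate-fat plus a 0.100 mg IV microtracer in the fasted period,
n = 10).

Statistical structure: lognormal inter-individual variability on CLu, V and
ka (logit-normal on F), a proportional (lognormal) residual error, and LLOQ
censoring. One root seed drives everything; per-subject substreams are
derived from deterministic spawn keys so adding arms or subjects never
perturbs existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from .structural_model import (StructuralParams, default_params,
                               simulate_profile, simulate_with_tracer)
from .trial_data import ConcentrationRecord, DoseEvent, Subject, TrialDataset

__all__ = [
    "TrialArm", "TrialDesign", "PopulationParams", "make_design",
    "simulate_trial", "draw_individual", "DEFAULT_SAMPLING_TIMES",
]

#: default rich single-dose sampling schedule [h]
DEFAULT_SAMPLING_TIMES = (0, 0.5, 1, 1.5, 2, 3, 4, 5, 6, 8, 12, 16, 24, 36, 48, 72, 96)

#: multiplicative absorption-rate factors by food state; food speeds early
#: absorption (raising Cmax ~1.4-fold) without changing the absorbed fraction
FOOD_KA_FACTOR = {"fasted": 1.0, "light-meal": 1.5, "moderate-fat": 2.8, "high-fat": 3.0}

REGIMENS = ("single", "split", "QD", "BID")


@dataclass(frozen=True)
class TrialArm:
    label: str
    dose_mg: float           # per administration (split: total per day)
    regimen: str             # single | split | QD | BID
    n_active: int
    n_placebo: int = 2
    treatment_days: int = 1
    route: str = "oral"
    formulation: str = "tablet"
    food_state: str = "fasted"

    def __post_init__(self):
        if self.regimen not in REGIMENS:
            raise ValueError(f"unknown regimen {self.regimen!r}")
        if self.n_active < 1:
            raise ValueError("n_active must be >= 1")

    @property
    def tau(self) -> float:
        return 24.0 if self.regimen in ("single", "QD") else 12.0


@dataclass(frozen=True)
class TrialDesign:
    study_tag: str
    arms: tuple[TrialArm, ...]
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING_TIMES
    washout_days: float = 14.0
    # food-effect crossover specifics
    crossover_states: tuple[str, ...] = ()      # per-period food states
    n_crossover: int = 0
    iv_tracer_mg: float | None = None           # given in the fasted period

    def __post_init__(self):
        ts = self.sampling_times
        if any(t < 0 for t in ts) or any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("sampling times must be nonnegative and increasing")
        if self.washout_days < 0:
            raise ValueError("washout must be >= 0")


def make_design(study_tag: str) -> TrialDesign:
    """The phase-1 program's designs by tag: 'SAD', 'MAD' or 'FE'."""
    tag = study_tag.upper()
    if tag == "SAD":
        arms = tuple(
            TrialArm(f"{d:g} mg SD", float(d), "single", n_active=6)
            for d in (5, 15, 30, 60, 120, 240, 480)
        ) + (TrialArm("240 mg split", 240.0, "split", n_active=6, food_state="light-meal"),)
        return TrialDesign("SAD", arms)
    if tag == "MAD":
        arms = (
            TrialArm("45 mg QD", 45.0, "QD", n_active=8, treatment_days=10,
                     food_state="light-meal"),
            TrialArm("120 mg QD", 120.0, "QD", n_active=8, treatment_days=10,
                     food_state="light-meal"),
            TrialArm("60 mg BID", 60.0, "BID", n_active=8, treatment_days=10,
                     food_state="light-meal"),
            TrialArm("120 mg BID", 120.0, "BID", n_active=8, treatment_days=10,
                     food_state="light-meal"),
            TrialArm("200 mg BID", 200.0, "BID", n_active=8, treatment_days=10,
                     food_state="light-meal"),
        )
        return TrialDesign("MAD", arms)
    if tag == "FE":
        arm = TrialArm("120 mg crossover", 120.0, "single", n_active=10, n_placebo=0)
        return TrialDesign(
            "FE", (arm,),
            crossover_states=("fasted", "high-fat", "moderate-fat"),
            n_crossover=10, iv_tracer_mg=0.100,
        )
    raise ValueError(f"unknown study tag {study_tag!r}; choose SAD, MAD or FE")


@dataclass(frozen=True)
class PopulationParams:
    """Typical parameters plus the population's statistical structure.

    ``omega`` holds lognormal inter-individual SDs for cl_u, v, ka and (on
    the logit scale) f; defaults of 0.25 reproduce the ~20-30% geometric CVs
    of the published exposure tables. ``sigma_prop`` is the proportional
    residual SD (applied as exp(sigma*eps), homoscedastic on logs).
    """

    typical: StructuralParams = field(default_factory=default_params)
    omega: dict = field(default_factory=lambda: {
        "cl_u": 0.25, "v": 0.25, "ka": 0.25, "f": 0.25})
    sigma_prop: float = 0.15
    agp_median: float = 0.612      # g/L, fasted pre-dose geometric mean
    agp_sigma: float = 0.18        # lognormal SD spanning ~0.41-0.91 g/L
    lloq: dict = field(default_factory=lambda: {
        "total": 1e-3, "unbound": 1e-5, "tracer": 1e-5})  # mg/L
    additive_floor: bool = False   # optional additive error floor of LLOQ/2

    def __post_init__(self):
        if any(w < 0 for w in self.omega.values()) or self.sigma_prop < 0:
            raise ValueError("variability parameters must be >= 0")


def draw_individual(pop: PopulationParams, rng: np.random.Generator,
                    ) -> tuple[StructuralParams, dict]:
    """Draw one subject's parameters; returns (params, random-effect labels)."""
    om = pop.omega
    eta = {k: float(rng.standard_normal()) for k in ("cl_u", "v", "ka", "f")}
    typ = pop.typical
    f_i = float(expit(logit(typ.f_ref) + om.get("f", 0.0) * eta["f"]))
    ind = replace(
        typ,
        cl_u=typ.cl_u * math.exp(om.get("cl_u", 0.0) * eta["cl_u"]),
        v=typ.v * math.exp(om.get("v", 0.0) * eta["v"]),
        ka=typ.ka * math.exp(om.get("ka", 0.0) * eta["ka"]),
        f_ref=f_i,
    )
    agp = float(pop.agp_median * math.exp(pop.agp_sigma * rng.standard_normal()))
    agp = min(max(agp, 0.2), 2.0)
    return ind, {"eta": eta, "agp": agp}


def _dose_events(arm: TrialArm, food_state: str | None = None):
    """Dose-event list for one arm (times in h from first dose)."""
    food = food_state or arm.food_state
    evs = []
    if arm.regimen == "single":
        evs.append(DoseEvent(0.0, arm.dose_mg, arm.route, arm.formulation,
                             food, arm.label))
    elif arm.regimen == "split":
        half = arm.dose_mg / 2.0
        for t in (0.0, 12.0):
            evs.append(DoseEvent(t, half, arm.route, arm.formulation, food, arm.label))
    else:
        per_day = 1 if arm.regimen == "QD" else 2
        tau = arm.tau
        for day in range(arm.treatment_days):
            for j in range(per_day):
                evs.append(DoseEvent(day * 24.0 + j * tau, arm.dose_mg, arm.route,
                                     arm.formulation, food, arm.label))
    return evs


def _sampling_times(arm: TrialArm, base: tuple[float, ...]) -> np.ndarray:
    """Observation schedule: rich first interval; for multiple dosing, daily
    troughs plus a rich final interval and a 72 h post-treatment tail."""
    if arm.regimen in ("single", "split"):
        return np.asarray(base, dtype=float)
    tau = arm.tau
    rich = [t for t in base if t < tau] + [tau]
    t_last = (arm.treatment_days - 1) * 24.0 + (tau if arm.regimen == "BID" else 0.0)
    troughs = [day * 24.0 for day in range(1, arm.treatment_days)]
    final = [t_last + t for t in rich]
    tail = [t_last + tau + t for t in (12.0, 24.0, 36.0, 60.0)]
    times = sorted(set(rich) | set(troughs) | set(final) | set(tail))
    return np.asarray(times, dtype=float)


def _observe(prof_value: float, analyte: str, t: float, pop: PopulationParams,
             rng: np.random.Generator) -> ConcentrationRecord:
    lloq = pop.lloq[analyte]
    c = prof_value * math.exp(pop.sigma_prop * rng.standard_normal())
    if pop.additive_floor:
        c = abs(c + (lloq / 2.0) * rng.standard_normal())
    if c < lloq:
        return ConcentrationRecord(t, None, analyte, lloq, blq_flag=True)
    return ConcentrationRecord(t, float(c), analyte, lloq, blq_flag=False)


def _subject_stream(seed: int, arm_idx: int, subj_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(arm_idx, subj_idx)))


def simulate_trial(design: TrialDesign, pop: PopulationParams | None = None,
                   seed: int = 0) -> TrialDataset:
    """Forward-simulate a trial dataset from the structural model.

    Per subject: draw individual parameters, integrate the structural model
    with the arm's dose events and food-dependent absorption rate, sample at
    the schedule, apply proportional residual error, censor below the LLOQ.
    Total and unbound analytes are both emitted (tracer too in the FE
    design). Fully reproducible for a fixed seed.
    """
    pop = pop or PopulationParams()
    ds = TrialDataset(study_tag=design.study_tag, washout_days=design.washout_days)

    if design.study_tag == "FE":
        _simulate_fe(design, pop, seed, ds)
        return ds.validate()

    for ai, arm in enumerate(design.arms):
        for si in range(arm.n_active):
            sid = f"{design.study_tag}-{ai + 1:02d}-{si + 1:02d}"
            rng = _subject_stream(seed, ai, si)
            ind, labels = draw_individual(pop, rng)
            ind = replace(ind, ka=ind.ka * FOOD_KA_FACTOR[arm.food_state])
            evs = _dose_events(arm)
            times = _sampling_times(arm, design.sampling_times)
            try:
                prof = simulate_profile(ind, evs, times)
            except Exception as exc:
                raise RuntimeError(
                    f"simulation failed for subject {sid} (arm {arm.label})") from exc
            recs = []
            for analyte, curve in (("total", prof.c_total),
                                   ("unbound", prof.c_unbound)):
                for t, c in zip(times, curve):
                    recs.append(_observe(float(c), analyte, float(t), pop, rng))
            ds.subjects.append(Subject(sid, agp_concentration=labels["agp"],
                                       iiv_labels=labels["eta"]))
            ds.doses[(sid, 1)] = evs
            ds.observations[(sid, 1)] = recs
        for sj in range(arm.n_placebo):
            ds.subjects.append(Subject(f"{design.study_tag}-{ai + 1:02d}-P{sj + 1}"))
    return ds.validate()


def _simulate_fe(design: TrialDesign, pop: PopulationParams, seed: int,
                 ds: TrialDataset) -> None:
    arm = design.arms[0]
    states = design.crossover_states
    n = design.n_crossover
    for si in range(n):
        sid = f"FE-{si + 1:02d}"
        rng = _subject_stream(seed, 0, si)
        ind, labels = draw_individual(pop, rng)
        # two sequences: HF->fasted->MF for the first half, fasted->HF->MF else
        if si < n // 2:
            order = (states[1], states[0], states[2])
        else:
            order = (states[0], states[1], states[2])
        ds.subjects.append(Subject(sid, agp_concentration=labels["agp"],
                                   period_assignments=order,
                                   iiv_labels=labels["eta"]))
        for period, food in enumerate(order, start=1):
            ind_p = replace(ind, ka=ind.ka * FOOD_KA_FACTOR[food])
            evs = [DoseEvent(0.0, arm.dose_mg, "oral", "tablet", food, arm.label)]
            times = np.asarray(design.sampling_times, dtype=float)
            if food == "fasted" and design.iv_tracer_mg:
                # the IV microtracer is given on top of the oral dose and
                # competes for the same binding pool (that co-disposition is
                # what lets (AUC/D)oral / (AUC/D)IV recover F)
                tr_ev = DoseEvent(0.0, design.iv_tracer_mg, "iv", "iv-tracer",
                                  food, "IV tracer")
                tr_times = np.asarray(
                    sorted({0.233, 0.5, 1, 2, 4, 8, 12, 24, 36, 48, 72, 96}
                           | set(times[times > 0])), dtype=float)
                prof_full, tr_prof = simulate_with_tracer(
                    ind_p, evs, [tr_ev], tr_times)
                evs = evs + [tr_ev]
                sel = np.isin(tr_times, times)
                recs = []
                for analyte, curve in (("total", prof_full.c_total[sel]),
                                       ("unbound", prof_full.c_unbound[sel])):
                    for t, c in zip(tr_times[sel], curve):
                        recs.append(_observe(float(c), analyte, float(t), pop, rng))
                if 0.0 in times:
                    recs = ([_observe(0.0, "total", 0.0, pop, rng),
                             _observe(0.0, "unbound", 0.0, pop, rng)] + recs)
                for t, c in zip(tr_times, tr_prof.c_total):
                    recs.append(_observe(float(c), "tracer", float(t), pop, rng))
                ds.doses[(sid, period)] = evs
                ds.observations[(sid, period)] = recs
                continue
            prof = simulate_profile(ind_p, evs, times)
            recs = []
            for analyte, curve in (("total", prof.c_total),
                                   ("unbound", prof.c_unbound)):
                for t, c in zip(times, curve):
                    recs.append(_observe(float(c), analyte, float(t), pop, rng))
            ds.doses[(sid, period)] = evs
            ds.observations[(sid, period)] = recs
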