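"""Data model and I/O for phase-1 PK trial datasets.

The interchange format is a NONMEM-style flat CSV (one row per dose event or
concentration observation), the de-facto standard for population-PK work:

    ID,TIME,AMT,DV,EVID,MDV,CMT,ANALYTE,FOOD,FORM,PERIOD,SEQ,LLOQ,DOSEGRP

``EVID=1`` rows are dose events (``AMT`` in mg), ``EVID=0`` rows are
concentration observations (``DV`` in mg/L, "." when missing). Time is in
hours since the first dose of the current period. A comment line of the form
``#UNITS analyte=ug/L`` directly after the header declares a non-default
concentration unit for one analyte (used for IV-microtracer data, which is
quantified on a µg/L scale); values are converted to mg/L at read time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import pandas as pd

ROUTES = ("oral", "iv")
FORMULATIONS = ("tablet", "solution", "iv-tracer")
FOOD_STATES = ("fasted", "light-meal", "moderate-fat", "high-fat")
ANALYTES = ("total", "unbound", "tracer")

CSV_COLUMNS = [
    "ID", "TIME", "AMT", "DV", "EVID", "MDV", "CMT",
    "ANALYTE", "FOOD", "FORM", "PERIOD", "SEQ", "LLOQ", "DOSEGRP",
]

#: unit -> factor converting to mg/L
_UNIT_FACTORS = {"mg/L": 1.0, "ug/L": 1e-3, "µg/L": 1e-3, "ng/L": 1e-6}


class TrialParseError(ValueError):
    """Malformed file content (names the offending line)."""


class TrialValidationError(ValueError):
    """One or more invariant violations; ``violations`` lists all of them."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        msg = "%d validation error(s):\n  " % len(violations)
        super().__init__(msg + "\n  ".join(violations))


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: oral tablet/solution or IV (micro)dose."""

    time: float          # h since first dose of the period
    amount: float        # mg
    route: str = "oral"
    formulation: str = "tablet"
    food_state: str = "fasted"
    regimen_tag: str = ""

    def __post_init__(self):
        if self.amount <= 0:
            raise ValueError(f"dose amount must be > 0 mg, got {self.amount}")
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0 h, got {self.time}")
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if self.formulation not in FORMULATIONS:
            raise ValueError(f"unknown formulation {self.formulation!r}")
        if self.food_state not in FOOD_STATES:
            raise ValueError(f"unknown food state {self.food_state!r}")


@dataclass(frozen=True)
class ConcentrationRecord:
    """One observation of one analyte; ``value`` is mg/L, None when censored."""

    time: float
    value: float | None
    analyte: str = "total"
    lloq: float = 1e-3
    blq_flag: bool = False

    def __post_init__(self):
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if self.lloq <= 0:
            raise ValueError(f"LLOQ must be > 0, got {self.lloq}")
        if not self.blq_flag:
            if self.value is None:
                raise ValueError("non-BLQ record without a value")
            if self.value < self.lloq:
                raise ValueError(
                    f"value {self.value} below LLOQ {self.lloq} but blq_flag is False"
                )

    @property
    def usable(self) -> bool:
        """Whether the record enters λz/AUC computation."""
        return self.value is not None


@dataclass(frozen=True)
class Subject:
    id: str
    agp_concentration: float | None = None   # g/L; physiologic 0.2-2.0
    period_assignments: tuple[str, ...] | None = None
    iiv_labels: dict | None = None           # synthetic data only

    def __post_init__(self):
        a = self.agp_concentration
        if a is not None and not (0.2 <= a <= 2.0):
            raise ValueError(
                f"subject {self.id}: AGP {a} g/L outside physiologic range 0.2-2.0"
            )


@dataclass
class TrialDataset:
    """Subjects, dose events, and observations for one study design.

    Dose events and observations are keyed by ``(subject_id, period)``.
    """

    subjects: list[Subject] = field(default_factory=list)
    doses: dict[tuple[str, int], list[DoseEvent]] = field(default_factory=dict)
    observations: dict[tuple[str, int], list[ConcentrationRecord]] = field(default_factory=dict)
    study_tag: str = ""
    washout_days: float = 0.0

    # -- accessors -------------------------------------------------------

    def subject_ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    def subject(self, sid: str) -> Subject:
        for s in self.subjects:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def periods(self, sid: str) -> list[int]:
        return sorted({p for (i, p) in self.doses if i == sid}
                      | {p for (i, p) in self.observations if i == sid})

    def profile(self, sid: str, period: int = 1, analyte: str = "total"):
        """(times, concentrations) of usable records, in time order."""
        recs = [r for r in self.observations.get((sid, period), ())
                if r.analyte == analyte and r.usable]
        recs.sort(key=lambda r: r.time)
        return [r.time for r in recs], [r.value for r in recs]

    # -- validation ------------------------------------------------------

    def violations(self) -> list[str]:
        """All dataset-level invariant violations (empty when valid)."""
        out: list[str] = []
        ids = set(self.subject_ids())
        for (sid, period), recs in self.observations.items():
            if sid not in ids:
                out.append(f"observations for unknown subject {sid!r}")
            if not self.doses.get((sid, period)):
                out.append(
                    f"subject {sid!r} period {period}: observations without any dose event"
                )
            seen: dict[str, float] = {}
            for r in sorted(recs, key=lambda r: r.time):
                prev = seen.get(r.analyte)
                if prev is not None and r.time <= prev:
                    out.append(
                        f"subject {sid!r} period {period} analyte {r.analyte}: "
                        f"times not strictly increasing at t={r.time}"
                    )
                seen[r.analyte] = r.time
        for (sid, _), evs in self.doses.items():
            if sid not in ids:
                out.append(f"dose events for unknown subject {sid!r}")
            _ = evs
        return out

    def validate(self) -> "TrialDataset":
        v = self.violations()
        if v:
            raise TrialValidationError(v)
        return self


@dataclass(frozen=True)
class CsvDialect:
    """Options of the NONMEM-style CSV dialect."""

    missing_dv: str = "."
    analyte_units: dict | None = None  # e.g. {"tracer": "ug/L"}

    def unit_factor(self, analyte: str) -> float:
        units = self.analyte_units or {}
        unit = units.get(analyte, "mg/L")
        try:
            return _UNIT_FACTORS[unit]
        except KeyError:
            raise TrialParseError(f"unknown concentration unit {unit!r}") from None


def _infer_route(formulation: str) -> str:
    return "iv" if formulation == "iv-tracer" else "oral"


def read_dataset(path, dialect: CsvDialect | None = None) -> TrialDataset:
    """Read and validate a NONMEM-style CSV trial dataset.

    Raises :class:`TrialParseError` for malformed rows (naming the line) and
    :class:`TrialValidationError` listing every violated invariant.
    """
    dialect = dialect or CsvDialect()
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    units = dict(dialect.analyte_units or {})
    body, meta = [], {}
    for ln in lines:
        s = ln.strip()
        if s.startswith("#UNITS"):
            for tok in s.split()[1:]:
                analyte, unit = tok.split("=", 1)
                units[analyte] = unit
        elif s.startswith("#META"):
            for tok in s.split()[1:]:
                k, v = tok.split("=", 1)
                meta[k] = v
        elif s and not s.startswith("#"):
            body.append(ln)
    dialect = replace(dialect, analyte_units=units)

    try:
        df = pd.read_csv(
            io.StringIO("".join(body)),
            na_values=[dialect.missing_dv], keep_default_na=False,
            dtype={"ID": str, "ANALYTE": str, "FOOD": str, "FORM": str,
                   "DOSEGRP": str},
        )
    except Exception as exc:  # noqa: BLE001 - reported as a parse error
        raise TrialParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrialParseError(f"{path}: missing required column(s) {missing}")

    subjects: dict[str, Subject] = {}
    doses: dict[tuple[str, int], list[DoseEvent]] = {}
    obs: dict[tuple[str, int], list[ConcentrationRecord]] = {}
    violations: list[str] = []
    for i, row in df.iterrows():
        line_no = i + 2  # header on line 1
        try:
            sid = str(row["ID"])
            period = int(row["PERIOD"])
            key = (sid, period)
            if sid not in subjects:
                subjects[sid] = Subject(id=sid)
            if int(row["EVID"]) == 1:
                ev = DoseEvent(
                    time=float(row["TIME"]), amount=float(row["AMT"]),
                    route=_infer_route(str(row["FORM"])),
                    formulation=str(row["FORM"]), food_state=str(row["FOOD"]),
                    regimen_tag=str(row["DOSEGRP"]),
                )
                doses.setdefault(key, []).append(ev)
            else:
                analyte = str(row["ANALYTE"])
                factor = dialect.unit_factor(analyte)
                dv = row["DV"]
                missing_dv = pd.isna(dv)
                rec = ConcentrationRecord(
                    time=float(row["TIME"]),
                    value=None if missing_dv else float(dv) * factor,
                    analyte=analyte,
                    lloq=float(row["LLOQ"]) * factor,
                    blq_flag=bool(int(row["MDV"])) if missing_dv else False,
                )
                obs.setdefault(key, []).append(rec)
        except TrialParseError:
            raise
        except ValueError as exc:
            violations.append(f"line {line_no}: {exc}")
    if violations:
        raise TrialValidationError(violations)

    ds = TrialDataset(
        subjects=list(subjects.values()), doses=doses, observations=obs,
        study_tag=meta.get("study", ""),
        washout_days=float(meta.get("washout_days", 0.0)),
    )
    return ds.validate()


def write_dataset(dataset: TrialDataset, path, dialect: CsvDialect | None = None) -> None:
    """Write a dataset in the NONMEM-style CSV dialect (inverse of read)."""
    dialect = dialect or CsvDialect()
    rows = []
    for sid in dataset.subject_ids():
        for period in dataset.periods(sid):
            key = (sid, period)
            items: list[tuple[float, int, object]] = []
            items += [(ev.time, 1, ev) for ev in dataset.doses.get(key, ())]
            items += [(r.time, 0, r) for r in dataset.observations.get(key, ())]
            items.sort(key=lambda x: (x[0], -x[1]))
            for t, evid, item in items:
                if evid == 1:
                    ev = item
                    rows.append(dict(
                        ID=sid, TIME=t, AMT=ev.amount, DV=dialect.missing_dv,
                        EVID=1, MDV=1, CMT=1, ANALYTE="", FOOD=ev.food_state,
                        FORM=ev.formulation, PERIOD=period, SEQ="",
                        LLOQ="", DOSEGRP=ev.regimen_tag,
                    ))
                else:
                    r = item
                    factor = dialect.unit_factor(r.analyte)
                    # BLQ records are written as missing (".", MDV=1); a BLQ
                    # policy must be re-applied after reading.
                    censored = r.blq_flag or r.value is None
                    rows.append(dict(
                        ID=sid, TIME=t, AMT=0,
                        DV=dialect.missing_dv if censored else repr(r.value / factor),
                        EVID=0, MDV=1 if censored else 0, CMT=2,
                        ANALYTE=r.analyte, FOOD="", FORM="", PERIOD=period,
                        SEQ="", LLOQ=repr(r.lloq / factor), DOSEGRP="",
                    ))
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(CSV_COLUMNS) + "\n")
        if dataset.study_tag or dataset.washout_days:
            fh.write(f"#META study={dataset.study_tag} washout_days={dataset.washout_days}\n")
        units = dialect.analyte_units or {}
        if units:
            fh.write("#UNITS " + " ".join(f"{a}={u}" for a, u in units.items()) + "\n")
        df.to_csv(fh, index=False, header=False)


BLQ_POLICIES = ("m1-pre-zero", "exclude-all")


def apply_blq_rule(dataset: TrialDataset, rule: str = "m1-pre-zero") -> TrialDataset:
    """Apply a below-LLOQ handling policy; returns a new dataset.

    ``m1-pre-zero``: BLQ records drawn before the first dose of the period are
    set to exactly 0 (pre-dose samples are expected drug-free), BLQ records
    after dosing are excluded from λz/AUC computation but retained with their
    flag. ``exclude-all`` excludes every BLQ record. Idempotent.
    """
    if rule not in BLQ_POLICIES:
        raise ValueError(f"unknown BLQ policy {rule!r}; choose from {BLQ_POLICIES}")
    new_obs: dict[tuple[str, int], list[ConcentrationRecord]] = {}
    for key, recs in dataset.observations.items():
        dose_times = [ev.time for ev in dataset.doses.get(key, ())]
        first_dose = min(dose_times) if dose_times else 0.0
        out = []
        for r in recs:
            if r.blq_flag:
                if rule == "m1-pre-zero" and r.time <= first_dose:
                    r = replace(r, value=0.0)
                else:
                    r = replace(r, value=None)
            out.append(r)
        new_obs[key] = out
    return TrialDataset(
        subjects=list(dataset.subjects), doses=dict(dataset.doses),
        observations=new_obs, study_tag=dataset.study_tag,
        washout_days=dataset.washout_days,
    )
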