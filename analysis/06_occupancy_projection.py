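#!/usr/bin/env python
"""Dose -> steady-state trough IRAK4-occupancy projection.

Simulates steady-state unbound profiles for a virtual population, drives the
kinetic target-binding model (Kd = whole-blood IC50 86 nM, residence time
5 min), and tabulates mean trough occupancy per dose and regimen with the
band obtained by propagating the IC50 95% CI (60-122 nM). The published
projection reports 79% (72-84%) at 120 mg BID and 67% at 240 mg QD.
"""

from pathlib import Path

import pandas as pd

from zabedopk import OccupancyParams, PopulationParams, trough_occupancy_curve
from zabedopk.reference import (TARGET_RESIDENCE_TIME_MIN, TROUGH_OCCUPANCY,
                                WHOLE_BLOOD_IC50_NM)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20170301


def main() -> None:
    occ = OccupancyParams(kd_t=WHOLE_BLOOD_IC50_NM[0],
                          residence_time=TARGET_RESIDENCE_TIME_MIN,
                          ic50_ci=WHOLE_BLOOD_IC50_NM[1])
    pop = PopulationParams(sigma_prop=0.0)
    results = trough_occupancy_curve([15, 30, 60, 120, 240, 480], ["QD", "BID"],
                                     pop, occ, n_subjects=12, seed=SEED)
    table = pd.DataFrame([{
        "dose_mg": r.dose, "regimen": r.regimen,
        "trough_occupancy": round(r.trough_mean, 3),
        "band_low": round(r.trough_band[0], 3),
        "band_high": round(r.trough_band[1], 3),
    } for r in results])
    table.to_csv(ROOT / "occupancy_curve.csv", index=False)
    print("Projected steady-state trough occupancy (mean; IC50-CI band):")
    print(table.to_string(index=False))
    print("\nPublished projections for comparison:")
    for k, (mean, ci) in TROUGH_OCCUPANCY.items():
        print(f"  {k}: {mean:.2f} ({ci[0]:.2f}-{ci[1]:.2f})")


if __name__ == "__main__":
    main()
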