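#!/usr/bin/env python
"""Generate the three synthetic phase-1 trial datasets (SAD, MAD, FE/abs.BA).

The generator forward-simulates the calibrated structural model with
lognormal inter-individual variability and proportional residual error, then
censors below the LLOQ. Datasets land in results/data/ as NONMEM-style CSVs
(the FE file carries a µg/L unit declaration for the IV-tracer analyte).
"""

from pathlib import Path

from zabedopk import (CsvDialect, PopulationParams, apply_blq_rule,
                      make_design, simulate_trial, write_dataset)

SEED = 20170301  # fixed root seed for the whole analysis
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pop = PopulationParams()  # calibrated defaults: omega 0.25, sigma 15%
    for tag in ("SAD", "MAD", "FE"):
        ds = simulate_trial(make_design(tag), pop, seed=SEED)
        ds = apply_blq_rule(ds, "m1-pre-zero")
        dialect = CsvDialect(analyte_units={"tracer": "ug/L"}) if tag == "FE" else None
        path = OUT / f"{tag.lower()}.csv"
        write_dataset(ds, path, dialect)
        n_obs = sum(len(v) for v in ds.observations.values())
        print(f"{tag}: {len(ds.subjects)} subjects, {n_obs} observation rows -> {path}")


if __name__ == "__main__":
    main()
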