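#!/usr/bin/env python
"""Generate the synthetic paired tumor cohort all later stages analyze.

Writes the cohort fixture (expression, pairing, clinical, somatic tables,
annotation, planted truth) plus the independent validation cohort under
results/cohort/.
"""

from pathlib import Path

from pairedprog import io
from pairedprog.synthetic_data import (
    SimulationConfig,
    generate_cohort,
    generate_somatic_tables,
    generate_validation_cohort,
    write_fixture,
)

OUT = Path("results/cohort")
SEED = 1


def main() -> None:
    config = SimulationConfig(seed=SEED)
    cohort = generate_cohort(config)
    somatic = generate_somatic_tables(config, cohort.pairing, cohort.expression)
    write_fixture(cohort, somatic, OUT, force=True)

    vexpr, vclin, vtruth = generate_validation_cohort(config, cohort.truth)
    io.write_expression(vexpr, OUT / "validation_expression.tsv")
    io.write_clinical(vclin, OUT / "validation_clinical.tsv")
    io.write_json(vtruth.as_json(), OUT / "validation_truth.json")

    n_patients = cohort.pairing["patient_id"].nunique()
    print(f"cohort: {n_patients} patients, {len(cohort.pairing)} recurrent/progressive "
          f"tumors, {cohort.expression.shape[0]} genes")
    print(f"somatic tables cover {somatic.cna.shape[1]} WGS samples")
    print(f"validation cohort: {vexpr.shape[1]} tumors")
    print(f"wrote fixture to {OUT}/")


if __name__ == "__main__":
    main()
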