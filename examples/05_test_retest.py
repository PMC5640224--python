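"""Test-retest variability: how repeatable is an estimated field?

Examines the same simulated patient five times with fresh response noise and
reports the median per-location standard deviation of the estimates.  Lower
SD means clinicians can trust differences between visits to reflect real
change rather than measurement noise.
"""

import numpy as np

from sorsvf import (
    CohortConfig,
    ResponderProfile,
    SorsExamConfig,
    StaircaseConfig,
    default_grid,
    default_normative,
    dts_field,
    examine_sors,
    generate_cohort,
    train_sors,
)
from sorsvf.evaluate import test_retest

grid = default_grid()
normative = default_normative(grid)
train = generate_cohort(CohortConfig(n_patients=120, fields_per_patient=8,
                                     seed=20), grid, normative)
model = train_sors(train, S=36)
test = generate_cohort(CohortConfig(n_patients=5, fields_per_patient=1,
                                    seed=21), grid, normative)
responder = ResponderProfile(true_field=test.field(1))

runs = {
    "dts": lambda g: dts_field(responder, grid, normative, StaircaseConfig(), g),
    "sors-d(36)": lambda g: examine_sors(
        model, responder, normative,
        SorsExamConfig(S=36, local_method="dynamic"), g),
}
for name, run in runs.items():
    res = test_retest(run, n_repeats=5, seed=22)
    print(f"{name:>10}: median per-location SD over 5 repeats "
          f"{res['median_sd']:.2f} dB")
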