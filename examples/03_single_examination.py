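"""Examine one simulated patient: reconstruction-seeded staircases vs DTS.

Both strategies estimate thresholds with the same adaptive staircase; the
meta-strategy tests only 36 of 54 locations in the trained order, infers the
rest from the running least-squares reconstruction, and starts each
staircase 4 dB brighter than the reconstructed prediction.  Fewer
presentations means a shorter examination for the patient.
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
    rmse,
    train_sors,
)

grid = default_grid()
normative = default_normative(grid)
train = generate_cohort(CohortConfig(n_patients=120, fields_per_patient=8,
                                     seed=1), grid, normative)
model = train_sors(train, S=36)

# an unseen glaucomatous patient (responder FP rate 3%, FN rate 1%)
test = generate_cohort(CohortConfig(n_patients=5, fields_per_patient=1,
                                    seed=2), grid, normative)
truth = test.field(0)
responder = ResponderProfile(true_field=truth)

rec_sors = examine_sors(model, responder, normative,
                        SorsExamConfig(S=36, local_method="dynamic"),
                        np.random.default_rng(3))
rec_dts = dts_field(responder, grid, normative, StaircaseConfig(),
                    np.random.default_rng(3))
for rec in (rec_sors, rec_dts):
    err = rmse(truth.values, rec.estimated_field.values)
    print(f"{rec.strategy:>6}: {rec.tested_locations.S} locations tested, "
          f"{rec.total_presentations} presentations, RMSE {err:.2f} dB")
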