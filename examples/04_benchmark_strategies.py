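"""Benchmark testing strategies on a held-out synthetic cohort.

Runs full-field ZEST, DTS and TOP plus the reconstruction meta-strategy
(ZEST- and staircase-based, 36 of 54 locations) on the same simulated
patients and prints per-strategy medians: accuracy (RMSE vs the true field)
against examination length (stimulus presentations).  A Mann-Whitney U test
compares the accuracy of the two staircase-based strategies.
"""

import numpy as np

from sorsvf import (
    CohortConfig,
    SorsExamConfig,
    StaircaseConfig,
    ZestConfig,
    benchmark,
    compare_strategies,
    default_grid,
    default_normative,
    dts_field,
    examine_sors,
    generate_cohort,
    top_field,
    train_sors,
    zest_field,
)

grid = default_grid()
normative = default_normative(grid)
train = generate_cohort(CohortConfig(n_patients=120, fields_per_patient=8,
                                     seed=10), grid, normative)
model = train_sors(train, S=36)
test = generate_cohort(CohortConfig(n_patients=50, fields_per_patient=2,
                                    seed=11), grid, normative)

zcfg, scfg = ZestConfig(), StaircaseConfig()
strategies = {
    "zest": lambda r, g: zest_field(r, grid, normative, zcfg, g),
    "dts": lambda r, g: dts_field(r, grid, normative, scfg, g),
    "top": lambda r, g: top_field(r, grid, normative, g),
    "sors-d(36)": lambda r, g: examine_sors(
        model, r, normative, SorsExamConfig(S=36, local_method="dynamic"), g),
    "sors-z(36)": lambda r, g: examine_sors(
        model, r, normative, SorsExamConfig(S=36, local_method="zest"), g),
}
result = benchmark(strategies, test, grid, normative, seed=12)
print(result.aggregates.to_string(index=False))

cmp = compare_strategies(result, "sors-d(36)", "dts", metric="rmse")
print(f"sors-d vs dts accuracy: Mann-Whitney p = {cmp['p_value']:.3f}")
# lower presentations at comparable RMSE = a better speed-accuracy trade-off
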