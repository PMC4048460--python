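"""The full experiment grid on a small phantom cohort.

Simulates a cohort with graded atrophy (NC < MCI < AD, converters progressing
at the AD rate), extracts all four markers, runs the PLS+LDA pipeline under
leave-one-of-each-class-out cross-validation for every contrast, and prints
the AUC / rank-sum table.  AUC near 1 means the marker separates the groups;
the converter row uses the month-12 minus baseline (delta) features.
"""

import proximark as pm
from proximark import pipeline

grouping = pm.load_groupings("phantom")["brain"]
tables = pm.simulate_marker_tables(
    pm.default_phantom_spec((48, 48, 48)),
    pm.default_atrophy_spec(),
    {"NC": 10, "MCI": 12, "AD": 10},
    seed=7,
    grouping=grouping,
    fraction_defs=pm.phantom_fraction_defs(),
    kinds=("surface", "hp_fraction", "wb_fraction"),
    timepoints=("bl", "m12"),
    n_converters=6,
    include_delta=True,
)

cells = pipeline.default_grid(markers=("surface", "hp_fraction", "wb_fraction"),
                              grouping="brain")
results = pipeline.run_grid(cells, tables, grouping=grouping, seed=0)
print(pipeline.render_report(results))
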