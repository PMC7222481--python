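"""Dose-response statistics on a simulated cytotoxicity series.

Three conditions (vehicle control + two doses with planted cell loss and
shrinkage), three replicate fields each.  Features measured on the planted
labels are compared with control by two-sample Kolmogorov-Smirnov tests.
"""

import numpy as np

from cardioseg import DoseEffect, SceneParams, generate_dose_series, measure_image
from cardioseg.evaluate import dose_response_report

base = SceneParams(width=256, height=256, density_regime="clustered", seed=4)
conditions = {
    "control": DoseEffect(),
    "low": DoseEffect(cell_loss_fraction=0.2, shrink_factor=0.15),
    "high": DoseEffect(cell_loss_fraction=0.6, shrink_factor=0.45),
}
series = generate_dose_series(base, conditions, n_replicates=3)

tables, counts = {}, {}
for cond, scenes in series.items():
    records = []
    per_image = []
    for i, (pair, truth) in enumerate(scenes):
        recs, summary = measure_image(truth.cell_labels, pair, truth.nucleus_labels,
                                      image_id=f"{cond}{i}", condition=cond)
        records.extend(recs)
        per_image.append(summary["cell_number"])
    tables[cond] = records
    counts[cond] = per_image

report = dose_response_report(tables, "control",
                              features=["area", "elongation", "nuclear_cv"],
                              cell_numbers=counts)
cols = ["condition", "feature", "mean", "control_mean", "ks_D", "p_value", "significant"]
print(report[report.feature != "cell_number"][cols].to_string(index=False))
print()
viability = report[report.feature == "cell_number"]
print(viability[["condition", "mean", "pct_of_control"]].to_string(index=False))

# cell_number expressed as % of the control mean is the viability read-out;
# the planted area shrinkage shows up as a significant KS test at the high
# dose while untouched features stay non-significant.
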