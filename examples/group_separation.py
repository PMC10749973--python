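"""Mobility-class separation of asymmetry age trends.

Generates a 1000-subject cohort in which the composite asymmetry burden
depresses fast gait speed (and leaves normal gait and timed-up-and-go
unlinked), then compares the grouped cubic age-trend curves: the fraction
of ages at which the slow group's curve lies above the normal group's.
Values near 100% mean the classes separate systematically; values near 50%
mean no separation.
"""

import numpy as np
import pandas as pd

from thighasym.pipeline import (
    age_average,
    asymmetry_table,
    fit_cubic_trend,
    grouped_trends,
    normalize_indicators,
    select_top_indicators,
)
from thighasym.stats import attach_classes
from thighasym.synthetic import cohort_table, default_config, generate_cohort

cfg = default_config(n_subjects=1000, seed=2, make_histograms=False)
cohort = generate_cohort(cfg)
left = {s.subject_id: s.truth_left for s in cohort}
right = {s.subject_id: s.truth_right for s in cohort}
deltas = asymmetry_table(left, right)
table = normalize_indicators(deltas)
ct = attach_classes(cohort_table(cohort))
ages = ct.loc[deltas.index, "age"]
trends = {c: fit_cubic_trend(age_average(table.values[c], ages, indicator=c))
          for c in table.values.columns}
sel = [s["indicator"] for s in select_top_indicators(trends).values()]
grid = np.arange(71, 99, dtype=float)

for grouping, above, below in [
    ("gait_fast_class", "slow", "normal"),
    ("gait_normal_class", "slow", "normal"),
    ("tug_class", "3", "1"),
]:
    labels = ct.loc[deltas.index, grouping].astype("string")
    res = grouped_trends(labels, table, ages, sel)
    hi = np.mean([res[above][i].trend.predict(grid) for i in sel], axis=0)
    lo = np.mean([res[below][i].trend.predict(grid) for i in sel], axis=0)
    frac = 100 * np.mean(hi > lo)
    print(f"{grouping:<20} {above} above {below} at {frac:5.1f}% of ages")

print("\nOnly the fast-gait split should separate: the generator links the "
      "asymmetry burden to fast gait speed and to nothing else.")
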