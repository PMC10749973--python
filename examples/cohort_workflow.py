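"""Run the full cohort asymmetry workflow on a small simulated cohort.

Simulates 80 subjects (two legs each, 1e5-pixel histograms), fits every
histogram, computes the 11 left-right asymmetry indicators, normalises
them, averages within integer ages, fits cubic age trends, and selects the
best indicator per tissue by R^2. Artifacts land in a run directory.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from thighasym import workflow
from thighasym.synthetic import default_config

out = Path(tempfile.mkdtemp()) / "run"
workflow.run_all(out, cfg=default_config(n_subjects=80, seed=1))

selected = json.loads((out / "selected.json").read_text())
print("selected indicator per tissue (highest cubic-trend R^2):")
for tissue, info in sorted(selected.items()):
    print(f"  {tissue:<12} {info['indicator']:<14} R^2 = {info['r_squared']:.3f}")

ttest = pd.read_csv(out / "ttest.csv").set_index("parameter")
print("\npaired left-vs-right t-tests (per fitted parameter):")
print(ttest[["mean_left", "mean_right", "t_stat", "p_value"]].round(4).to_string())
print("\nA small p-value marks a systematic left-right difference in that "
      "parameter across the cohort; the selected indicators are the ones "
      "whose asymmetry varies most with age.")
print(f"\nartifacts written to {out}")
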