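"""Cohort statistics: paired left-right t-tests and mobility/BMI classes.

Class thresholds are the printed clinical cut-offs (BMI 18.5/25/30 kg/m^2;
normal gait 1.0 m/s; fast gait 1.3 m/s; timed-up-and-go 10/13/29 s) and are
pure functions of the subject's value.  The source class definitions use
strict inequalities on both sides, leaving boundary values unassigned; this
implementation assigns boundaries to the upper class (lower-inclusive
intervals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedTestResult",
    "paired_ttest",
    "paired_ttest_table",
    "classify_bmi",
    "classify_gait_normal",
    "classify_gait_fast",
    "classify_tug",
    "attach_classes",
    "cohort_summary",
    "BMI_CLASS_LABELS",
    "TUG_CLASS_LABELS",
]

BMI_CLASS_LABELS = {1: "below-normal", 2: "normal", 3: "above-normal", 4: "overweight"}
TUG_CLASS_LABELS = {1: "fast", 2: "average", 3: "slow", 4: "very slow"}


@dataclass
class PairedTestResult:
    """Two-sided paired t-test of left vs right values of one parameter."""

    parameter: str
    mean_left: float
    mean_right: float
    sd_left: float
    sd_right: float
    t_stat: float
    p_value: float
    n: int
    undefined: bool = False   # all differences identical (sd(d) == 0)


def paired_ttest(left, right, parameter: str = "") -> PairedTestResult:
    """Paired t-test on d = left - right: t = mean(d) / (sd(d)/sqrt(n)).

    Sample standard deviations (n-1 denominator) throughout; p from the
    Student-t distribution with n-1 degrees of freedom. When every
    difference is zero the statistic is undefined and flagged rather than
    raised (t and p reported as NaN).
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left and right must have equal length")
    n = left.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    if not (np.isfinite(left).all() and np.isfinite(right).all()):
        raise ValueError("paired t-test requires finite values")
    d = left - right
    sd_d = float(d.std(ddof=1))
    if sd_d == 0.0:
        return PairedTestResult(
            parameter, float(left.mean()), float(right.mean()),
            float(left.std(ddof=1)), float(right.std(ddof=1)),
            t_stat=math.nan, p_value=math.nan, n=n, undefined=True,
        )
    t = float(d.mean() / (sd_d / math.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return PairedTestResult(
        parameter, float(left.mean()), float(right.mean()),
        float(left.std(ddof=1)), float(right.std(ddof=1)),
        t_stat=t, p_value=p, n=n,
    )


def paired_ttest_table(left: pd.DataFrame, right: pd.DataFrame) -> pd.DataFrame:
    """Left-vs-right paired t-test for every shared column (parameter).

    Rows follow the column order of ``left``; output mirrors the classic
    per-parameter mean/SD/t/p layout.
    """
    common = left.index.intersection(right.index)
    rows = []
    for col in left.columns:
        r = paired_ttest(
            left.loc[common, col].to_numpy(),
            right.loc[common, col].to_numpy(),
            parameter=col,
        )
        rows.append({
            "parameter": col,
            "mean_left": r.mean_left, "sd_left": r.sd_left,
            "mean_right": r.mean_right, "sd_right": r.sd_right,
            "t_stat": r.t_stat, "p_value": r.p_value,
            "n": r.n, "undefined": r.undefined,
        })
    return pd.DataFrame(rows).set_index("parameter")


def classify_bmi(bmi: float) -> int:
    """BMI class: 1 (<18.5), 2 (18.5-25), 3 (25-30), 4 (>=30) kg/m^2."""
    if not bmi > 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    if bmi < 18.5:
        return 1
    if bmi < 25.0:
        return 2
    if bmi < 30.0:
        return 3
    return 4


def classify_gait_normal(v_norm: float | None) -> str | None:
    """Normal gait speed class: 'slow' below 1.0 m/s, else 'normal'."""
    if v_norm is None or (isinstance(v_norm, float) and math.isnan(v_norm)):
        return None
    if v_norm < 0:
        raise ValueError(f"gait speed must be >= 0, got {v_norm}")
    return "slow" if v_norm < 1.0 else "normal"


def classify_gait_fast(v_fast: float | None) -> str | None:
    """Fast gait speed class: 'slow' below 1.3 m/s, else 'normal'."""
    if v_fast is None or (isinstance(v_fast, float) and math.isnan(v_fast)):
        return None
    if v_fast < 0:
        raise ValueError(f"gait speed must be >= 0, got {v_fast}")
    return "slow" if v_fast < 1.3 else "normal"


def classify_tug(tug: float | None) -> int | None:
    """Timed-up-and-go class: 1 (<10 s), 2 (10-13), 3 (13-29), 4 (>=29)."""
    if tug is None or (isinstance(tug, float) and math.isnan(tug)):
        return None
    if not tug > 0:
        raise ValueError(f"TUG time must be positive, got {tug}")
    if tug < 10.0:
        return 1
    if tug < 13.0:
        return 2
    if tug < 29.0:
        return 3
    return 4


def attach_classes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Augment a cohort table with bmi/gait/TUG class columns.

    Missing mobility values yield missing class labels; such subjects are
    excluded from that grouping only, not from the cohort.
    """
    out = cohort.copy()
    out["bmi_class"] = cohort["bmi"].map(classify_bmi).astype("Int64")
    out["gait_normal_class"] = cohort["v_norm"].map(classify_gait_normal)
    out["gait_fast_class"] = cohort["v_fast"].map(classify_gait_fast)
    out["tug_class"] = cohort["tug"].map(classify_tug).astype("Int64")
    return out


def cohort_summary(cohort: pd.DataFrame, grouping: str, classes=None) -> pd.DataFrame:
    """Per-class N, mean (sample SD) of age, and sex counts.

    ``grouping`` names a class-label column (e.g. ``bmi_class``). When
    ``classes`` lists the full set of possible labels, classes without
    subjects still get a row with N=0 and blank (NaN) statistics; otherwise
    only observed classes appear.
    """
    rows = []
    labels = cohort[grouping].dropna()
    groups = labels.groupby(labels).groups
    for label in classes if classes is not None else groups.keys():
        idx = groups.get(label, [])
        sub = cohort.loc[idx]
        n = len(sub)
        rows.append({
            grouping: label,
            "n": n,
            "age_mean": float(sub["age"].mean()) if n else math.nan,
            "age_sd": float(sub["age"].std(ddof=1)) if n > 1 else math.nan,
            "male_n": int((sub["sex"] == "male").sum()),
            "female_n": int((sub["sex"] == "female").sum()),
        })
    return pd.DataFrame(
        rows, columns=[grouping, "n", "age_mean", "age_sd", "male_n", "female_n"]
    ).set_index(grouping)
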