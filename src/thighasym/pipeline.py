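"""Left-right asymmetry indicators and the cohort trend workflow.

From the 11 fitted radiodensity parameters of each leg, the per-subject
asymmetry indicator is the absolute left-minus-right difference of each
parameter.  Cohort analysis then proceeds: min-max normalisation of each
indicator across the cohort, arithmetic averaging within integer-year age
groups, ordinary least-squares cubic fits of the age-averaged series, and
selection of the indicator with the highest coefficient of determination
per tissue.  Grouped variants recompute the age series and cubic fits
within classes (BMI, gait speed, timed-up-and-go) while reusing the
cohort-wide normalisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import PARAM_NAMES, TISSUE_SLICES, NTRAParams

__all__ = [
    "DELTA_NAMES",
    "AsymmetryVector",
    "NormalizedIndicatorTable",
    "AgeAveragedSeries",
    "TrendFit",
    "DegenerateIndicatorWarning",
    "compute_asymmetry",
    "asymmetry_table",
    "minmax_normalize",
    "normalize_indicators",
    "age_average",
    "fit_cubic_trend",
    "select_top_indicators",
    "grouped_trends",
]

#: Indicator (delta) column names in canonical parameter order.
DELTA_NAMES = tuple(f"d{name}" for name in PARAM_NAMES)


class DegenerateIndicatorWarning(UserWarning):
    """An indicator is constant across the cohort (min == max or SST == 0)."""


@dataclass(frozen=True)
class AsymmetryVector:
    """The 11 absolute left-right parameter differences for one subject."""

    subject_id: str
    delta: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta", np.asarray(self.delta, dtype=float))
        if self.delta.shape != (11,):
            raise ValueError("delta must contain the 11 canonical indicators")
        if (self.delta < 0).any():
            raise ValueError("asymmetry indicators are absolute, hence >= 0")


@dataclass
class NormalizedIndicatorTable:
    """Min-max normalised indicators plus the extrema used, for reproducibility."""

    values: pd.DataFrame          # index: subject_id; columns: DELTA_NAMES
    minima: pd.Series
    maxima: pd.Series
    degenerate: tuple[str, ...] = ()


@dataclass
class AgeAveragedSeries:
    """Mean normalised indicator per integer age; ages with no subjects absent."""

    indicator: str
    ages: np.ndarray
    values: np.ndarray
    n_per_age: np.ndarray


@dataclass
class TrendFit:
    """Cubic age-trend fit of one age-averaged indicator series."""

    indicator: str
    coefficients: np.ndarray      # ascending degree, length 4
    r_squared: float
    n_points: int

    def predict(self, ages) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(ages, float), self.coefficients)


def compute_asymmetry(left: NTRAParams, right: NTRAParams, subject_id: str = "") -> AsymmetryVector:
    """Absolute left-minus-right difference of each canonical parameter."""
    delta = np.abs(left.to_vector() - right.to_vector())
    return AsymmetryVector(subject_id=subject_id, delta=delta)


def asymmetry_table(
    left: dict[str, NTRAParams], right: dict[str, NTRAParams]
) -> pd.DataFrame:
    """Per-subject indicator table for subjects present with both legs.

    Subjects missing either side are silently dropped; callers who need the
    exclusion list can diff the index against their roster.
    """
    rows = {}
    for sid in sorted(set(left) & set(right)):
        rows[sid] = compute_asymmetry(left[sid], right[sid], sid).delta
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(DELTA_NAMES)).rename_axis(
        "subject_id"
    )


def minmax_normalize(values) -> tuple[np.ndarray, float, float]:
    """Rescale one indicator to [0, 1] via (v - min) / (max - min).

    A constant indicator (max == min) is degenerate: all outputs are defined
    as 0 and a :class:`DegenerateIndicatorWarning` is raised.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("min-max normalisation needs at least 2 subjects")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        warnings.warn(
            "constant indicator: min == max, normalised values set to 0",
            DegenerateIndicatorWarning,
            stacklevel=2,
        )
        return np.zeros_like(v), lo, hi
    return (v - lo) / (hi - lo), lo, hi


def normalize_indicators(deltas: pd.DataFrame) -> NormalizedIndicatorTable:
    """Min-max normalise every indicator column across the cohort."""
    out = {}
    minima, maxima, degenerate = {}, {}, []
    for col in deltas.columns:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", DegenerateIndicatorWarning)
            out[col], minima[col], maxima[col] = minmax_normalize(deltas[col].to_numpy())
        if caught:
            degenerate.append(col)
    if degenerate:
        warnings.warn(
            f"degenerate indicators (constant across cohort): {', '.join(degenerate)}",
            DegenerateIndicatorWarning,
            stacklevel=2,
        )
    values = pd.DataFrame(out, index=deltas.index)
    return NormalizedIndicatorTable(
        values=values,
        minima=pd.Series(minima),
        maxima=pd.Series(maxima),
        degenerate=tuple(degenerate),
    )


def age_average(values: pd.Series, ages: pd.Series, indicator: str = "") -> AgeAveragedSeries:
    """Arithmetic mean of one normalised indicator within each integer age."""
    ages = pd.Series(np.asarray(ages, dtype=int), index=values.index)
    grouped = values.groupby(ages)
    mean = grouped.mean()
    n = grouped.size()
    return AgeAveragedSeries(
        indicator=indicator or str(values.name),
        ages=mean.index.to_numpy(dtype=int),
        values=mean.to_numpy(dtype=float),
        n_per_age=n.to_numpy(dtype=int),
    )


def fit_cubic_trend(series: AgeAveragedSeries) -> TrendFit:
    """Unweighted OLS cubic on (age, value); R^2 = 1 - SSE/SST.

    A series with zero variance has SST = 0; R^2 is then defined as 0 and a
    warning is raised. Fewer than 4 distinct ages is an error.
    """
    ages = np.asarray(series.ages, dtype=float)
    vals = np.asarray(series.values, dtype=float)
    if np.unique(ages).size < 4:
        raise ValueError("cubic trend needs at least 4 distinct ages")
    coeffs = np.polynomial.polynomial.polyfit(ages, vals, deg=3)
    fitted = np.polynomial.polynomial.polyval(ages, coeffs)
    sse = float(np.sum((vals - fitted) ** 2))
    sst = float(np.sum((vals - vals.mean()) ** 2))
    if sst == 0.0:
        warnings.warn(
            f"constant series for {series.indicator!r}: R^2 defined as 0",
            DegenerateIndicatorWarning,
            stacklevel=2,
        )
        r2 = 0.0
    else:
        r2 = 1.0 - sse / sst
    return TrendFit(
        indicator=series.indicator,
        coefficients=coeffs,
        r_squared=r2,
        n_points=len(ages),
    )


def select_top_indicators(trends: dict[str, TrendFit]) -> dict[str, dict]:
    """Per tissue, the indicator whose cubic fit has the highest R^2.

    ``trends`` maps indicator name (``dN_fat`` ... ``dalpha_mus``) to its
    :class:`TrendFit`. Ties are broken by canonical parameter order and
    flagged; an all-zero tissue is flagged low-signal.
    """
    missing = set(DELTA_NAMES) - set(trends)
    if missing:
        raise ValueError(f"missing trend fits for: {sorted(missing)}")
    out = {}
    for tissue, sl in TISSUE_SLICES.items():
        candidates = [DELTA_NAMES[i] for i in range(sl.start, sl.stop)]
        r2 = np.array([trends[c].r_squared for c in candidates])
        best = int(np.argmax(r2))  # argmax keeps the first = canonical order on ties
        out[tissue] = {
            "indicator": candidates[best],
            "r_squared": float(r2[best]),
            "tied": bool((r2 == r2[best]).sum() > 1),
            "low_signal": bool(np.all(r2 == 0.0)),
        }
    return out


@dataclass
class GroupTrendResult:
    """Age series and cubic fit of one indicator within one group."""

    group: str
    indicator: str
    series: AgeAveragedSeries
    trend: TrendFit | None
    fittable: bool


def grouped_trends(
    groups: pd.Series,
    table: NormalizedIndicatorTable,
    ages: pd.Series,
    indicators: list[str] | None = None,
) -> dict[str, dict[str, GroupTrendResult]]:
    """Age-averaged series and cubic fits per group label and indicator.

    ``groups`` holds class labels per subject; subjects with a missing label
    are excluded from this grouping only. Normalisation is NOT recomputed:
    the cohort-wide normalised table is split, so curves of different groups
    share a scale. Groups with fewer than 4 distinct ages are marked
    unfittable rather than raising.
    """
    indicators = list(indicators) if indicators is not None else list(table.values.columns)
    groups = groups.reindex(table.values.index)
    ages = ages.reindex(table.values.index)
    out: dict[str, dict[str, GroupTrendResult]] = {}
    for label, idx in groups.dropna().groupby(groups.dropna()).groups.items():
        label = str(label)
        out[label] = {}
        for ind in indicators:
            series = age_average(table.values.loc[idx, ind], ages.loc[idx], indicator=ind)
            fittable = np.unique(series.ages).size >= 4
            trend = fit_cubic_trend(series) if fittable else None
            out[label][ind] = GroupTrendResult(
                group=label, indicator=ind, series=series, trend=trend, fittable=fittable
            )
    return out
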