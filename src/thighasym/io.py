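"""Tabular readers and writers for every pipeline artifact.

All CSV artifacts are UTF-8, comma-separated, with a mandatory header row,
'.' decimal separator and empty fields for missing values. Histograms
travel in long form (subject_id, side, bin_center, count); fitted
parameters, indicators and cohort tables are one row per subject (or per
subject-side). Trend fits are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import FitResult, HUHistogram, HU_MIN, HU_MAX, NTRAParams, PARAM_NAMES
from .pipeline import DELTA_NAMES, NormalizedIndicatorTable, TrendFit

__all__ = [
    "MalformedTableError",
    "read_histograms_csv",
    "write_histograms_csv",
    "read_hu_values_csv",
    "write_fit_results_csv",
    "read_fit_results_csv",
    "params_by_side",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_indicators_csv",
    "read_indicators_csv",
    "trends_to_json",
    "write_trends_json",
    "load_run_config",
    "save_run_config",
]

SIDES = ("L", "R")
_COHORT_COLUMNS = ["age", "sex", "bmi", "v_norm", "v_fast", "tug"]


class MalformedTableError(ValueError):
    """A CSV artifact is missing required columns or contains bad rows."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedTableError(f"{path}: missing column(s) {missing}")


def write_histograms_csv(hists: dict[tuple[str, str], HUHistogram], path) -> None:
    """Write histograms in long form, one row per (subject, side, bin)."""
    frames = []
    for (sid, side), h in hists.items():
        frames.append(pd.DataFrame({
            "subject_id": sid,
            "side": side,
            "bin_center": h.bin_centers.astype(int),
            "count": h.counts,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_histograms_csv(path) -> dict[tuple[str, str], HUHistogram]:
    """Read long-form histograms; bins absent from the file count as zero."""
    df = pd.read_csv(path)
    _require_columns(df, ["subject_id", "side", "bin_center", "count"], path)
    bad_side = ~df["side"].isin(SIDES)
    if bad_side.any():
        line = int(df.index[bad_side][0]) + 2  # header + 1-based
        raise MalformedTableError(f"{path}: line {line}: side must be L or R")
    bad_bin = (df["bin_center"] < HU_MIN) | (df["bin_center"] > HU_MAX)
    if bad_bin.any():
        line = int(df.index[bad_bin][0]) + 2
        raise MalformedTableError(
            f"{path}: line {line}: bin_center outside [{HU_MIN}, {HU_MAX}]"
        )
    out = {}
    for (sid, side), grp in df.groupby(["subject_id", "side"], sort=True):
        counts = np.zeros(HU_MAX - HU_MIN + 1)
        idx = grp["bin_center"].to_numpy(dtype=int) - HU_MIN
        counts[idx] = grp["count"].to_numpy(dtype=float)
        out[(str(sid), str(side))] = HUHistogram(counts=counts)
    return out


def read_hu_values_csv(path) -> dict[tuple[str, str], np.ndarray]:
    """Read raw HU pixel values (subject_id, side, hu_value rows)."""
    df = pd.read_csv(path)
    _require_columns(df, ["subject_id", "side", "hu_value"], path)
    return {
        (str(sid), str(side)): grp["hu_value"].to_numpy(dtype=float)
        for (sid, side), grp in df.groupby(["subject_id", "side"], sort=True)
    }


def write_fit_results_csv(fits: dict[tuple[str, str], FitResult], path) -> None:
    """One row per (subject, side): the 11 parameters in canonical order
    plus residual_sse, converged and iteration count."""
    rows = []
    for (sid, side), fr in fits.items():
        row = {"subject_id": sid, "side": side}
        row.update(zip(PARAM_NAMES, fr.params.to_vector()))
        row.update(residual_sse=fr.residual_sse, converged=fr.converged, n_iter=fr.n_iter)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fit_results_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["subject_id", "side", *PARAM_NAMES], path)
    return df


def params_by_side(fits_df: pd.DataFrame) -> dict[str, dict[str, NTRAParams]]:
    """Reshape a fit-results table into {side: {subject_id: NTRAParams}}."""
    out: dict[str, dict[str, NTRAParams]] = {s: {} for s in SIDES}
    for _, row in fits_df.iterrows():
        vec = row[list(PARAM_NAMES)].to_numpy(dtype=float)
        out[str(row["side"])][str(row["subject_id"])] = NTRAParams.from_vector(vec)
    return out


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["subject_id", *_COHORT_COLUMNS], path)
    return df.set_index("subject_id")


def write_indicators_csv(deltas: pd.DataFrame, table: NormalizedIndicatorTable, path) -> None:
    """Per-subject raw and normalised indicators side by side."""
    norm = table.values.rename(columns={c: f"n{c}" for c in table.values.columns})
    deltas.join(norm).to_csv(path)


def read_indicators_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["subject_id", *DELTA_NAMES], path)
    return df.set_index("subject_id")


def trends_to_json(trends: dict[str, TrendFit]) -> dict:
    return {
        name: {
            "coefficients": [float(c) for c in t.coefficients],
            "r_squared": float(t.r_squared),
            "n_points": int(t.n_points),
        }
        for name, t in trends.items()
    }


def write_trends_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_run_config(path) -> dict:
    """Load a JSON or YAML run/generator configuration by extension."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_run_config(cfg: dict, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    else:
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
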