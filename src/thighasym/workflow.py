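"""File-level orchestration of the cohort asymmetry workflow.

Each stage reads the previous stage's artifacts from the run directory and
writes its own, so a run can be resumed, inspected or re-driven from the
command line. The full chain is:

    simulate -> fit -> asymmetry -> trends -> groups -> ttest -> report

Artifacts (all inside the run directory): ``generator_config.json``,
``histograms.csv``, ``cohort.csv``, ``truth.csv``, ``fits.csv``,
``indicators.csv``, ``normalization.json``, ``trends.json``,
``selected.json``, ``group_trends.json``, ``ttest.csv``, ``report.json``.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .model import FitOptions, PARAM_NAMES, fit_ntra
from .pipeline import (
    DELTA_NAMES,
    DegenerateIndicatorWarning,
    age_average,
    asymmetry_table,
    fit_cubic_trend,
    grouped_trends,
    normalize_indicators,
    select_top_indicators,
)
from .stats import attach_classes, cohort_summary, paired_ttest_table
from .synthetic import GeneratorConfig, cohort_table, default_config, generate_cohort, truth_report

log = logging.getLogger("thighasym")

GROUPINGS = {
    "bmi": "bmi_class",
    "gait_normal": "gait_normal_class",
    "gait_fast": "gait_fast_class",
    "tug": "tug_class",
}


def stage_simulate(out_dir, cfg: GeneratorConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(cfg)
    tio.save_run_config(cfg.to_dict(), out / "generator_config.json")
    tio.write_cohort_csv(cohort_table(cohort), out / "cohort.csv")
    truth_report(cohort).to_csv(out / "truth.csv")
    if cfg.make_histograms:
        hists = {}
        for s in cohort:
            hists[(s.subject_id, "L")] = s.hist_left
            hists[(s.subject_id, "R")] = s.hist_right
        tio.write_histograms_csv(hists, out / "histograms.csv")
    log.info("simulated %d subjects into %s", len(cohort), out)


def stage_fit(out_dir, options: FitOptions | None = None) -> None:
    out = Path(out_dir)
    hists = tio.read_histograms_csv(out / "histograms.csv")
    fits = {}
    n_failed = 0
    for key in sorted(hists):
        fr = fit_ntra(hists[key], options=options)
        if not fr.converged:
            n_failed += 1
            log.warning("fit did not converge for subject %s side %s", *key)
        fits[key] = fr
    tio.write_fit_results_csv(fits, out / "fits.csv")
    log.info("fitted %d histograms (%d not converged)", len(fits), n_failed)


def stage_asymmetry(out_dir) -> None:
    out = Path(out_dir)
    fits = tio.read_fit_results_csv(out / "fits.csv")
    by_side = tio.params_by_side(fits)
    left, right = by_side["L"], by_side["R"]
    one_sided = sorted(set(left) ^ set(right))
    for sid in one_sided:
        log.warning("subject %s has a single leg fitted; excluded from asymmetry", sid)
    deltas = asymmetry_table(left, right)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", DegenerateIndicatorWarning)
        table = normalize_indicators(deltas)
    for w in caught:
        log.warning("%s", w.message)
    tio.write_indicators_csv(deltas, table, out / "indicators.csv")
    tio.write_trends_json(
        {
            "minima": {k: float(v) for k, v in table.minima.items()},
            "maxima": {k: float(v) for k, v in table.maxima.items()},
            "degenerate": list(table.degenerate),
            "excluded_one_sided": one_sided,
        },
        out / "normalization.json",
    )
    log.info("asymmetry indicators computed for %d subjects", len(deltas))


def _load_normalized(out: Path) -> tuple[pd.DataFrame, pd.Series]:
    ind = tio.read_indicators_csv(out / "indicators.csv")
    cohort = tio.read_cohort_csv(out / "cohort.csv")
    unknown = ind.index.difference(cohort.index)
    if len(unknown):
        raise tio.MalformedTableError(
            f"subject ids in indicators.csv absent from cohort.csv: {list(unknown)[:5]}"
        )
    norm = ind[[f"n{c}" for c in DELTA_NAMES]].rename(columns=lambda c: c[1:])
    ages = cohort.loc[norm.index, "age"]
    return norm, ages


def stage_trends(out_dir) -> None:
    out = Path(out_dir)
    norm, ages = _load_normalized(out)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateIndicatorWarning)
        trends = {
            c: fit_cubic_trend(age_average(norm[c], ages, indicator=c)) for c in norm.columns
        }
    selected = select_top_indicators(trends)
    tio.write_trends_json(tio.trends_to_json(trends), out / "trends.json")
    tio.write_trends_json(selected, out / "selected.json")
    log.info(
        "selected indicators: %s",
        {t: s["indicator"] for t, s in selected.items()},
    )


def stage_groups(out_dir, groupings: list[str] | None = None) -> None:
    out = Path(out_dir)
    norm, ages = _load_normalized(out)
    cohort = attach_classes(tio.read_cohort_csv(out / "cohort.csv"))
    selected = json.loads((out / "selected.json").read_text())
    indicators = [s["indicator"] for s in selected.values()]
    from .pipeline import NormalizedIndicatorTable  # local: rebuilt from file

    table = NormalizedIndicatorTable(
        values=norm, minima=norm.min(), maxima=norm.max()
    )
    payload = {}
    for name in groupings or list(GROUPINGS):
        col = GROUPINGS[name]
        labels = cohort.loc[norm.index, col]
        n_missing = int(labels.isna().sum())
        if n_missing:
            log.info("grouping %s: %d subjects missing the grouping value", name, n_missing)
        results = grouped_trends(labels, table, ages, indicators)
        payload[name] = {
            label: {
                ind: {
                    "ages": r.series.ages.tolist(),
                    "values": r.series.values.tolist(),
                    "n_per_age": r.series.n_per_age.tolist(),
                    "fittable": r.fittable,
                    "trend": (
                        {
                            "coefficients": [float(c) for c in r.trend.coefficients],
                            "r_squared": float(r.trend.r_squared),
                            "n_points": int(r.trend.n_points),
                        }
                        if r.trend is not None else None
                    ),
                }
                for ind, r in per_ind.items()
            }
            for label, per_ind in results.items()
        }
    tio.write_trends_json(payload, out / "group_trends.json")


def stage_ttest(out_dir) -> None:
    out = Path(out_dir)
    fits = tio.read_fit_results_csv(out / "fits.csv").set_index(["subject_id", "side"])
    left = fits.xs("L", level="side")[list(PARAM_NAMES)]
    right = fits.xs("R", level="side")[list(PARAM_NAMES)]
    table = paired_ttest_table(left, right)
    table.to_csv(out / "ttest.csv")
    log.info("paired t-tests written for %d parameters", len(table))


def stage_report(out_dir) -> None:
    out = Path(out_dir)
    cohort = attach_classes(tio.read_cohort_csv(out / "cohort.csv"))
    norm_meta = json.loads((out / "normalization.json").read_text())
    ind = tio.read_indicators_csv(out / "indicators.csv")
    report = {
        "n_subjects": int(len(cohort)),
        "n_with_asymmetry": int(len(ind)),
        "excluded_one_sided": norm_meta.get("excluded_one_sided", []),
        "degenerate_indicators": norm_meta.get("degenerate", []),
        "all_indicators_degenerate": len(norm_meta.get("degenerate", [])) == len(DELTA_NAMES),
        "missing_counts": {
            c: int(cohort[c].isna().sum()) for c in ("v_norm", "v_fast", "tug")
        },
        "class_counts": {
            name: {
                str(k): int(v)
                for k, v in cohort[col].value_counts(dropna=True).sort_index().items()
            }
            for name, col in GROUPINGS.items()
        },
        "summaries": {
            name: cohort_summary(cohort, col).reset_index().to_dict(orient="records")
            for name, col in GROUPINGS.items()
        },
    }
    tio.write_trends_json(report, out / "report.json")
    log.info("report written: %d subjects, %d with asymmetry",
             report["n_subjects"], report["n_with_asymmetry"])


def stage_plots(out_dir) -> None:
    """Optional: age-series + cubic overlays for the selected indicators."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    plots = out / "plots"
    plots.mkdir(exist_ok=True)
    norm, ages = _load_normalized(out)
    selected = json.loads((out / "selected.json").read_text())
    trends = json.loads((out / "trends.json").read_text())
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for tissue, info in selected.items():
        ind = info["indicator"]
        series = age_average(norm[ind], ages, indicator=ind)
        coeffs = trends[ind]["coefficients"]
        grid = np.linspace(series.ages.min(), series.ages.max(), 200)
        ax.plot(series.ages, series.values, "o", ms=4, label=f"{tissue}: {ind}")
        ax.plot(grid, np.polynomial.polynomial.polyval(grid, coeffs), "--")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("age-averaged normalised asymmetry")
    ax.legend()
    fig.tight_layout()
    fig.savefig(plots / "selected_trends.png", dpi=120)
    plt.close(fig)

    gt_path = out / "group_trends.json"
    if gt_path.exists():
        groups = json.loads(gt_path.read_text())
        for name, per_label in groups.items():
            fig, ax = plt.subplots(figsize=(7, 4.5))
            for label, per_ind in per_label.items():
                for ind, r in per_ind.items():
                    ax.plot(r["ages"], r["values"], "o", ms=3, alpha=0.5)
                    if r["trend"]:
                        grid = np.linspace(min(r["ages"]), max(r["ages"]), 200)
                        ax.plot(
                            grid,
                            np.polynomial.polynomial.polyval(grid, r["trend"]["coefficients"]),
                            label=f"{label}: {ind}",
                        )
            ax.set_xlabel("age (years)")
            ax.set_ylabel("age-averaged normalised asymmetry")
            ax.legend(fontsize=7)
            fig.tight_layout()
            fig.savefig(plots / f"group_{name}.png", dpi=120)
            plt.close(fig)


def run_all(
    out_dir,
    cfg: GeneratorConfig | None = None,
    n_subjects: int = 50,
    seed: int = 0,
    groupings: list[str] | None = None,
    plots: bool = False,
    fit_options: FitOptions | None = None,
) -> None:
    """Chain the full workflow on a simulated cohort."""
    cfg = cfg or default_config(n_subjects=n_subjects, seed=seed)
    stage_simulate(out_dir, cfg)
    stage_fit(out_dir, fit_options)
    stage_asymmetry(out_dir)
    stage_trends(out_dir)
    stage_groups(out_dir, groupings)
    stage_ttest(out_dir)
    stage_report(out_dir)
    if plots:
        stage_plots(out_dir)
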