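"""Synthetic aging-cohort generator with ground-truth leg parameters.

The restricted source data (per-leg mid-thigh CT histograms of an elderly
cohort) cannot be redistributed, so every pipeline stage is exercised on a
fully synthetic stand-in that emulates its statistical structure:

* ages drawn uniformly on 71-98 years;
* per subject, a left-leg trimodal parameter set = cohort template plus
  Gaussian subject-level jitter, with locations confined to their tissue
  windows;
* a right leg differing from the left by a random-signed half-normal draw
  per parameter whose expected magnitude follows a configurable cubic trend
  in age — asymmetry grows with advancing age, most strongly in muscle
  width, connective-tissue width and fat amplitude;
* HU histograms sampled from each leg's trimodal density (truncated to
  [-200, 200] HU by rejection) so the expected histogram shape equals the
  true curve;
* linked outcomes: BMI, normal/fast gait speed and timed-up-and-go drawn
  from age-dependent models, with fast gait speed optionally depressed by a
  composite asymmetry burden, plus configurable missingness.

Everything is deterministic under the configured seed. The generator also
emits a truth ledger (per-subject true parameters, true asymmetry, class
labels) used as the oracle for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .model import (
    HUHistogram,
    HU_MIN,
    HU_MAX,
    ModeParams,
    NTRAParams,
    PARAM_NAMES,
    TISSUE_WINDOWS,
    TISSUES,
)
from .pipeline import DELTA_NAMES, compute_asymmetry
from . import stats as cohort_stats

__all__ = [
    "GeneratorConfig",
    "SyntheticSubject",
    "default_config",
    "generate_cohort",
    "truth_report",
    "sample_histogram",
]

_SIGMA_BOUNDS = (0.5, 120.0)
_ALPHA_BOUNDS = (-10.0, 10.0)


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    ``asymmetry_model`` maps a canonical parameter name to four ascending
    cubic coefficients in ``x = age - 70`` giving the expected magnitude of
    the left-right difference at that age.  ``outcome_links`` give the
    (signed) effect of the composite asymmetry burden on each mobility
    outcome; ``asym_scales`` are the fixed per-parameter scales used to form
    that composite.  Use :func:`default_config` for study-shaped defaults.
    """

    n_subjects: int
    seed: int
    age_range: tuple[int, int] = (71, 98)
    sampling_mass: float = 1e5
    make_histograms: bool = True
    female_fraction: float = 0.62
    base_params: dict[str, float] = field(default_factory=dict)
    jitter_sd: dict[str, float] = field(default_factory=dict)
    asymmetry_model: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)
    asym_scales: dict[str, float] = field(default_factory=dict)
    outcome_links: dict[str, float] = field(
        default_factory=lambda: {"v_norm": 0.0, "v_fast": -0.4, "tug": 0.0}
    )
    outcome_noise: dict[str, float] = field(
        default_factory=lambda: {"v_norm": 0.18, "v_fast": 0.12, "tug": 0.28, "bmi": 4.0}
    )
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {"v_norm": 0.034, "v_fast": 0.127, "tug": 0.033}
    )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        d["asymmetry_model"] = {k: list(v) for k, v in self.asymmetry_model.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["age_range"] = tuple(d["age_range"])
        d["asymmetry_model"] = {
            k: tuple(float(c) for c in v) for k, v in d.get("asymmetry_model", {}).items()
        }
        return cls(**d)


def default_config(
    n_subjects: int = 500, seed: int = 0, sampling_mass: float = 1e5, **overrides
) -> GeneratorConfig:
    """Study-shaped defaults for the synthetic cohort.

    Amplitudes share the sampling mass as fat 33% / connective 22% /
    muscle 45%; locations sit mid-window (fat -60 HU, connective 15 HU,
    muscle 55 HU); the muscle mode is strongly right-skewed. Asymmetry
    trends rise as cubics in age for muscle width, connective width and fat
    amplitude and stay age-flat for the remaining parameters.
    """
    m = sampling_mass
    base = {
        "N_fat": 0.33 * m, "mu_fat": -60.0, "sigma_fat": 25.0, "alpha_fat": 0.3,
        "N_conn": 0.22 * m, "mu_conn": 15.0, "sigma_conn": 12.0,
        "N_mus": 0.45 * m, "mu_mus": 55.0, "sigma_mus": 13.0, "alpha_mus": 3.1,
    }
    jitter = {
        "N_fat": 0.06 * base["N_fat"], "mu_fat": 6.0, "sigma_fat": 3.0, "alpha_fat": 0.15,
        "N_conn": 0.06 * base["N_conn"], "mu_conn": 4.0, "sigma_conn": 2.0,
        "N_mus": 0.06 * base["N_mus"], "mu_mus": 4.0, "sigma_mus": 2.0, "alpha_mus": 0.4,
    }
    # expected |left - right| as cubic in (age - 70); rising for the three
    # indicators the cohort workflow should single out, flat elsewhere
    rel = m / 1e5  # amplitude trends scale with the sampling mass
    trends = {
        "N_fat": (150.0 * rel, 0.0, 0.0, 0.04 * rel),
        "mu_fat": (0.5, 0.0, 0.0, 0.0),
        "sigma_fat": (0.4, 0.0, 0.0, 0.0),
        "alpha_fat": (0.04, 0.0, 0.0, 0.0),
        "N_conn": (60.0 * rel, 0.0, 0.0, 0.0),
        "mu_conn": (0.4, 0.0, 0.0, 0.0),
        "sigma_conn": (0.8, 0.0, 0.0, 0.00015),
        "N_mus": (70.0 * rel, 0.0, 0.0, 0.0),
        "mu_mus": (0.4, 0.0, 0.0, 0.0),
        "sigma_mus": (1.0, 0.0, 0.0, 0.00022),
        "alpha_mus": (0.05, 0.0, 0.0, 0.0),
    }
    # burden composite is scaled so it approaches 1 at the oldest age
    x_top = 98.0 - 70.0
    scales = {
        p: max(_cubic(trends[p], x_top), 1e-12)
        for p in ("sigma_mus", "sigma_conn", "N_fat")
    }
    cfg = GeneratorConfig(
        n_subjects=n_subjects,
        seed=seed,
        sampling_mass=m,
        base_params=base,
        jitter_sd=jitter,
        asymmetry_model=trends,
        asym_scales=scales,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class SyntheticSubject:
    """One generated subject: true leg parameters, histograms, outcomes."""

    subject_id: str
    age: int
    sex: str
    truth_left: NTRAParams
    truth_right: NTRAParams
    hist_left: HUHistogram | None
    hist_right: HUHistogram | None
    bmi: float
    v_norm: float   # NaN when missing
    v_fast: float
    tug: float


def _cubic(coeffs: Iterable[float], x: float) -> float:
    c0, c1, c2, c3 = coeffs
    return c0 + c1 * x + c2 * x * x + c3 * x ** 3


def _param_bounds(name: str) -> tuple[float, float]:
    kind, tissue = name.split("_")
    window = TISSUE_WINDOWS[{"conn": "connective", "mus": "muscle", "fat": "fat"}[tissue]]
    if kind == "N":
        return 0.0, math.inf
    if kind == "mu":
        return float(window.lo), float(window.hi)
    if kind == "sigma":
        return _SIGMA_BOUNDS
    return _ALPHA_BOUNDS


def _vector_ok(v: np.ndarray) -> bool:
    return all(
        lo <= v[i] <= hi
        for i, name in enumerate(PARAM_NAMES)
        for lo, hi in [_param_bounds(name)]
    )


def _draw_legs(
    cfg: GeneratorConfig, age: int, rng: np.random.Generator, max_attempts: int = 1000
) -> tuple[NTRAParams, NTRAParams]:
    base = np.array([cfg.base_params[p] for p in PARAM_NAMES])
    jit = np.array([cfg.jitter_sd.get(p, 0.0) for p in PARAM_NAMES])
    x = age - 70.0
    # E|half-normal(s)| = s*sqrt(2/pi), so scale the SD to hit the trend mean
    exp_mag = np.array([
        max(_cubic(cfg.asymmetry_model.get(p, (0.0,) * 4), x), 0.0) for p in PARAM_NAMES
    ])
    half_sd = exp_mag * math.sqrt(math.pi / 2.0)
    for _ in range(max_attempts):
        left = base + rng.normal(0.0, 1.0, size=11) * jit
        delta = np.abs(rng.normal(0.0, 1.0, size=11)) * half_sd
        sign = rng.choice([-1.0, 1.0], size=11)
        # canonical vectors carry no connective skewness: it stays 0 on both legs
        right = left + sign * delta
        if _vector_ok(left) and _vector_ok(right):
            return NTRAParams.from_vector(left), NTRAParams.from_vector(right)
    raise RuntimeError(
        f"could not draw in-window leg parameters after {max_attempts} attempts "
        f"(age {age}); loosen jitter or trends"
    )


def _sample_skewnormal(
    n: int, mu: float, sigma: float, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Draws from the amplitude-normalised mode density.

    The mode equals a skew-normal density of shape ``a = -alpha``; sampling
    uses the delta-representation: with u0, u1 iid standard normal and
    ``d = a / sqrt(1 + a^2)``, ``d*|u0| + sqrt(1-d^2)*u1`` is skew-normal(a).
    """
    a = -alpha
    d = a / math.sqrt(1.0 + a * a)
    u0 = rng.standard_normal(n)
    u1 = rng.standard_normal(n)
    z = d * np.abs(u0) + math.sqrt(1.0 - d * d) * u1
    return mu + sigma * z


def sample_histogram(
    params: NTRAParams, rng: np.random.Generator, mass: float | None = None
) -> HUHistogram:
    """Sample a histogram of ``mass`` HU values from the trimodal density.

    ``mass`` defaults to the summed amplitudes, which makes the expected
    histogram equal the model curve itself. Values outside [-200, 200] are
    replaced by fresh draws from their mode (rejection truncation); the
    number rejected is recorded as ``n_discarded``.
    """
    amps = np.array([params.mode(t).N for t in TISSUES])
    total = amps.sum()
    if total <= 0:
        raise ValueError("cannot sample from a zero-amplitude parameter set")
    n = int(round(total if mass is None else mass))
    counts_per_mode = rng.multinomial(n, amps / total)
    values = np.empty(n)
    pos = 0
    n_rejected = 0
    for tissue, k in zip(TISSUES, counts_per_mode):
        m = params.mode(tissue)
        need = k
        out = np.empty(0)
        while need > 0:
            draw = _sample_skewnormal(need, m.mu, m.sigma, m.alpha, rng)
            keep = draw[(draw >= HU_MIN - 0.5) & (draw < HU_MAX + 0.5)]
            n_rejected += need - keep.size
            out = np.concatenate([out, keep])
            need = k - out.size
        values[pos:pos + k] = out
        pos += k
    bins = np.floor(values + 0.5)
    idx = (bins - HU_MIN).astype(np.intp)
    counts = np.bincount(idx, minlength=HU_MAX - HU_MIN + 1).astype(float)
    return HUHistogram(counts=counts, n_discarded=n_rejected)


def _asym_burden(cfg: GeneratorConfig, delta: np.ndarray) -> float:
    """Composite asymmetry burden: scaled mean of the key indicators."""
    # sorted so the summation order (hence the float result) is independent
    # of dict insertion order, e.g. after a config file round-trip
    terms = [
        delta[PARAM_NAMES.index(p)] / s
        for p, s in sorted(cfg.asym_scales.items()) if s > 0
    ]
    return float(np.mean(terms)) if terms else 0.0


def _draw_outcomes(
    cfg: GeneratorConfig, age: int, burden: float, rng: np.random.Generator
) -> tuple[float, float, float, float]:
    noise = cfg.outcome_noise
    links = cfg.outcome_links
    t = age - 71.0
    bmi = rng.normal(26.5, noise.get("bmi", 4.0))
    while bmi <= 12.0:
        bmi = rng.normal(26.5, noise.get("bmi", 4.0))
    v_norm = 1.02 - 0.008 * t + links.get("v_norm", 0.0) * burden + rng.normal(0, noise["v_norm"])
    v_fast = 1.38 - 0.008 * t + links.get("v_fast", 0.0) * burden + rng.normal(0, noise["v_fast"])
    v_norm = max(v_norm, 0.0)
    v_fast = max(v_fast, 0.0)
    tug = math.exp(
        math.log(11.3) + 0.010 * t + links.get("tug", 0.0) * burden + rng.normal(0, noise["tug"])
    )
    return bmi, v_norm, v_fast, tug


def generate_cohort(cfg: GeneratorConfig) -> list[SyntheticSubject]:
    """Generate the synthetic cohort; byte-identical under a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.age_range
    subjects = []
    width = len(str(cfg.n_subjects))
    for i in range(cfg.n_subjects):
        sid = f"S{i + 1:0{width}d}"
        age = int(rng.integers(lo, hi + 1))
        sex = "female" if rng.random() < cfg.female_fraction else "male"
        left, right = _draw_legs(cfg, age, rng)
        delta = np.abs(left.to_vector() - right.to_vector())
        burden = _asym_burden(cfg, delta)
        bmi, v_norm, v_fast, tug = _draw_outcomes(cfg, age, burden, rng)
        for key in ("v_norm", "v_fast", "tug"):
            if rng.random() < cfg.missing_rates.get(key, 0.0):
                if key == "v_norm":
                    v_norm = math.nan
                elif key == "v_fast":
                    v_fast = math.nan
                else:
                    tug = math.nan
        hist_l = hist_r = None
        if cfg.make_histograms:
            hist_l = sample_histogram(left, rng)
            hist_r = sample_histogram(right, rng)
        subjects.append(SyntheticSubject(
            subject_id=sid, age=age, sex=sex,
            truth_left=left, truth_right=right,
            hist_left=hist_l, hist_right=hist_r,
            bmi=bmi, v_norm=v_norm, v_fast=v_fast, tug=tug,
        ))
    return subjects


def truth_report(cohort: list[SyntheticSubject]) -> pd.DataFrame:
    """Per-subject truth ledger: 22 leg parameters, 11 true asymmetry
    indicators, outcomes and class labels — the oracle for recovery tests."""
    rows = []
    for s in cohort:
        row: dict = {"subject_id": s.subject_id, "age": s.age, "sex": s.sex}
        for side, params in (("L", s.truth_left), ("R", s.truth_right)):
            for name, value in zip(PARAM_NAMES, params.to_vector()):
                row[f"{name}_{side}"] = value
        for name, value in zip(
            DELTA_NAMES, compute_asymmetry(s.truth_left, s.truth_right, s.subject_id).delta
        ):
            row[name] = value
        row.update(bmi=s.bmi, v_norm=s.v_norm, v_fast=s.v_fast, tug=s.tug)
        row["bmi_class"] = cohort_stats.classify_bmi(s.bmi)
        row["gait_normal_class"] = cohort_stats.classify_gait_normal(s.v_norm)
        row["gait_fast_class"] = cohort_stats.classify_gait_fast(s.v_fast)
        row["tug_class"] = cohort_stats.classify_tug(s.tug)
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def cohort_table(cohort: list[SyntheticSubject]) -> pd.DataFrame:
    """Demographics/outcome table in the dialect consumed by the stats stage."""
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id, "age": s.age, "sex": s.sex,
                "bmi": s.bmi, "v_norm": s.v_norm, "v_fast": s.v_fast, "tug": s.tug,
            }
            for s in cohort
        ]
    ).set_index("subject_id")
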