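"""Trimodal skew-Gaussian radiodensity model for mid-thigh CT histograms.

A soft-tissue Hounsfield-unit (HU) distribution over [-200, 200] HU is
treated as a quasi-probability density composed of three modes — adipose
(fat), loose connective tissue, and lean muscle — each an amplitude-scaled,
possibly skewed Gaussian:

    phi(x; N, mu, sigma, alpha)
        = N / (sigma * sqrt(2*pi))
          * exp(-(x - mu)**2 / (2 * sigma**2))
          * erfc(alpha * (x - mu) / (sigma * sqrt(2)))

With this normalisation the mode integrates to exactly ``N`` for any
skewness ``alpha`` (it is ``N`` times a skew-normal density of shape
``-alpha``), so ``N`` measures the quantity of that tissue in histogram-mass
units while ``mu``, ``sigma`` and ``alpha`` describe its quality (location,
width and asymmetry of the radiodensity peak).  The connective mode is kept
symmetric (``alpha = 0``), giving 11 free parameters per leg.

Fitting minimises the sum of squared per-bin residuals between the observed
histogram and the trimodal curve under box constraints (each location inside
its tissue window, positive bounded widths, non-negative amplitudes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize, special

__all__ = [
    "TISSUES",
    "PARAM_NAMES",
    "TISSUE_SLICES",
    "TissueWindow",
    "TISSUE_WINDOWS",
    "ModeParams",
    "NTRAParams",
    "HUHistogram",
    "FitResult",
    "FitOptions",
    "InvalidParameterError",
    "EmptyHistogramError",
    "evaluate_mode",
    "evaluate_trimodal",
    "mode_mass",
    "histogram_from_hu_values",
    "default_init",
    "fit_ntra",
]

#: Tissue names in canonical order (low to high HU).
TISSUES = ("fat", "connective", "muscle")

#: Canonical order of the 11 per-leg parameters.
PARAM_NAMES = (
    "N_fat", "mu_fat", "sigma_fat", "alpha_fat",
    "N_conn", "mu_conn", "sigma_conn",
    "N_mus", "mu_mus", "sigma_mus", "alpha_mus",
)

#: Position of each tissue's parameters inside the canonical 11-vector.
TISSUE_SLICES = {"fat": slice(0, 4), "connective": slice(4, 7), "muscle": slice(7, 11)}

HU_MIN, HU_MAX = -200, 200

_SQRT2 = math.sqrt(2.0)
_SQRT2PI = math.sqrt(2.0 * math.pi)


class InvalidParameterError(ValueError):
    """A mode parameter violates its constraints (e.g. sigma <= 0)."""


class EmptyHistogramError(ValueError):
    """A histogram has no usable mass."""


@dataclass(frozen=True)
class TissueWindow:
    """Fixed HU interval assigned to one tissue type."""

    name: str
    lo: int
    hi: int

    def contains(self, x: float) -> bool:
        return self.lo <= x <= self.hi


#: The three fixed tissue windows partitioning integer HU in [-200, 200].
TISSUE_WINDOWS = {
    "fat": TissueWindow("fat", -200, -10),
    "connective": TissueWindow("connective", -9, 40),
    "muscle": TissueWindow("muscle", 41, 200),
}


@dataclass(frozen=True)
class ModeParams:
    """Parameters of one skewed-Gaussian tissue mode.

    Attributes
    ----------
    N : float
        Amplitude; equals the mode's integral over the real line
        (histogram-mass units). Non-negative.
    mu : float
        Location in HU; must lie inside the mode's tissue window.
    sigma : float
        Width in HU; strictly positive.
    alpha : float
        Skewness (dimensionless); fixed to 0 for the connective mode.
    """

    N: float
    mu: float
    sigma: float
    alpha: float = 0.0

    def validate(self, window: TissueWindow | None = None) -> None:
        if not np.isfinite([self.N, self.mu, self.sigma, self.alpha]).all():
            raise InvalidParameterError("mode parameters must be finite")
        if self.sigma <= 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.N < 0:
            raise InvalidParameterError(f"N must be >= 0, got {self.N}")
        if window is not None and not window.contains(self.mu):
            raise InvalidParameterError(
                f"mu={self.mu} outside {window.name} window [{window.lo}, {window.hi}]"
            )


@dataclass(frozen=True)
class NTRAParams:
    """The full 11-parameter trimodal description of one leg."""

    fat: ModeParams
    connective: ModeParams
    muscle: ModeParams

    def __post_init__(self) -> None:
        if self.connective.alpha != 0.0:
            raise InvalidParameterError("connective mode must have alpha == 0")

    def validate(self) -> None:
        for name in TISSUES:
            self.mode(name).validate(TISSUE_WINDOWS[name])

    def mode(self, tissue: str) -> ModeParams:
        return getattr(self, "connective" if tissue == "connective" else tissue)

    def to_vector(self) -> np.ndarray:
        """Flatten to the canonical 11-vector (connective alpha omitted)."""
        f, c, m = self.fat, self.connective, self.muscle
        return np.array([
            f.N, f.mu, f.sigma, f.alpha,
            c.N, c.mu, c.sigma,
            m.N, m.mu, m.sigma, m.alpha,
        ])

    @classmethod
    def from_vector(cls, v: Sequence[float]) -> "NTRAParams":
        v = np.asarray(v, dtype=float)
        if v.shape != (11,):
            raise ValueError(f"expected 11 parameters, got shape {v.shape}")
        return cls(
            fat=ModeParams(v[0], v[1], v[2], v[3]),
            connective=ModeParams(v[4], v[5], v[6], 0.0),
            muscle=ModeParams(v[7], v[8], v[9], v[10]),
        )


@dataclass
class HUHistogram:
    """Binned HU distribution of one leg's mid-thigh cross-section.

    Unit-width bins centred on the 401 integers -200..200; bin ``k`` covers
    ``[k - 0.5, k + 0.5)``.
    """

    counts: np.ndarray
    bin_centers: np.ndarray = field(
        default_factory=lambda: np.arange(HU_MIN, HU_MAX + 1, dtype=float)
    )
    n_discarded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        if self.counts.shape != self.bin_centers.shape:
            raise ValueError("counts and bin_centers must have equal length")
        if not np.isfinite(self.counts).all():
            raise ValueError("histogram counts must be finite")
        if (self.counts < 0).any():
            raise ValueError("histogram counts must be non-negative")

    @property
    def total_mass(self) -> float:
        return float(self.counts.sum())

    def window_mass(self, tissue: str) -> float:
        w = TISSUE_WINDOWS[tissue]
        sel = (self.bin_centers >= w.lo) & (self.bin_centers <= w.hi)
        return float(self.counts[sel].sum())


@dataclass
class FitOptions:
    """Options for :func:`fit_ntra`.

    ``objective`` is either ``"counts"`` (squared residuals on raw bin
    counts) or ``"density"`` (counts first divided by total mass; the fitted
    amplitudes then sum to ~1 and scale back by total mass).
    """

    objective: str = "counts"
    sigma_bounds: tuple[float, float] = (0.5, 120.0)
    alpha_bounds: tuple[float, float] = (-10.0, 10.0)
    amplitude_factor: float = 10.0   # N upper bound = factor * total mass
    ftol: float = 1e-10
    xtol: float = 1e-12
    max_iter: int = 500


@dataclass
class FitResult:
    """Outcome of a trimodal fit: parameters, objective value, status."""

    params: NTRAParams
    residual_sse: float
    converged: bool
    n_iter: int
    message: str = ""


def evaluate_mode(x, mode: ModeParams):
    """Evaluate one skewed-Gaussian mode at HU value(s) ``x``.

    Returns ``N/(sigma*sqrt(2 pi)) * exp(-(x-mu)^2/(2 sigma^2))
    * erfc(alpha*(x-mu)/(sigma*sqrt(2)))``; non-negative everywhere.
    """
    mode.validate()
    x = np.asarray(x, dtype=float)
    z = (x - mode.mu) / mode.sigma
    out = (
        mode.N / (mode.sigma * _SQRT2PI)
        * np.exp(-0.5 * z * z)
        * special.erfc(mode.alpha * z / _SQRT2)
    )
    return out if out.ndim else float(out)


def evaluate_trimodal(x, params: NTRAParams):
    """Pointwise sum of the three tissue modes at HU value(s) ``x``."""
    return (
        evaluate_mode(x, params.fat)
        + evaluate_mode(x, params.connective)
        + evaluate_mode(x, params.muscle)
    )


def mode_mass(mode: ModeParams) -> float:
    """Integral of the mode over the real line.

    The erfc-skewed Gaussian with this normalisation integrates to exactly
    ``N`` for any skewness, so no quadrature is needed.
    """
    mode.validate()
    return float(mode.N)


def histogram_from_hu_values(hu_values) -> HUHistogram:
    """Bin raw HU pixel values into the 401 unit-width bins.

    Values outside [-200.5, 200.5) are discarded; the discard count is kept
    on the returned histogram. Raises :class:`EmptyHistogramError` if no
    value falls in range.
    """
    hu_values = np.asarray(hu_values, dtype=float).ravel()
    if hu_values.size == 0:
        raise EmptyHistogramError("no HU values supplied")
    bins = np.floor(hu_values + 0.5)
    in_range = (bins >= HU_MIN) & (bins <= HU_MAX)
    n_discarded = int((~in_range).sum())
    if n_discarded == hu_values.size:
        raise EmptyHistogramError("all HU values fall outside [-200.5, 200.5)")
    idx = (bins[in_range] - HU_MIN).astype(np.intp)
    counts = np.bincount(idx, minlength=HU_MAX - HU_MIN + 1).astype(float)
    return HUHistogram(counts=counts, n_discarded=n_discarded)


def default_init(hist: HUHistogram) -> NTRAParams:
    """Deterministic moment-based initialisation, one mode per tissue window.

    Per window: N0 = window mass, mu0 = mass centroid, sigma0 = mass standard
    deviation floored at 2 HU, alpha0 = 0. Empty windows start at the window
    midpoint with a small amplitude.
    """
    modes = {}
    for tissue in TISSUES:
        w = TISSUE_WINDOWS[tissue]
        sel = (hist.bin_centers >= w.lo) & (hist.bin_centers <= w.hi)
        c = hist.counts[sel]
        x = hist.bin_centers[sel]
        mass = float(c.sum())
        if mass > 0:
            mu0 = float(np.average(x, weights=c))
            sigma0 = float(np.sqrt(np.average((x - mu0) ** 2, weights=c)))
        else:
            mu0 = 0.5 * (w.lo + w.hi)
            sigma0 = 0.25 * (w.hi - w.lo)
        mu0 = min(max(mu0, w.lo), w.hi)
        modes[tissue] = ModeParams(N=mass, mu=mu0, sigma=max(sigma0, 2.0), alpha=0.0)
    return NTRAParams(fat=modes["fat"], connective=modes["connective"], muscle=modes["muscle"])


def _bounds(total_mass: float, opts: FitOptions) -> tuple[np.ndarray, np.ndarray]:
    slo, shi = opts.sigma_bounds
    alo, ahi = opts.alpha_bounds
    n_hi = opts.amplitude_factor * total_mass
    lo, hi = [], []
    for tissue in TISSUES:
        w = TISSUE_WINDOWS[tissue]
        lo += [0.0, float(w.lo), slo]
        hi += [n_hi, float(w.hi), shi]
        if tissue != "connective":
            lo.append(alo)
            hi.append(ahi)
    return np.array(lo), np.array(hi)


def fit_ntra(
    hist: HUHistogram,
    init: NTRAParams | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit the trimodal model to a histogram by bounded least squares.

    Minimises the sum over the 401 bins of squared residuals between the
    observed counts (or normalised frequencies, per ``options.objective``)
    and the trimodal curve, with each ``mu`` confined to its tissue window,
    ``sigma`` and ``alpha`` box-bounded, ``N >= 0``, and the connective
    skewness fixed at zero. The returned objective value never exceeds the
    objective at the initialisation.

    Optimiser failure yields ``converged=False`` rather than an exception;
    empty or non-finite histograms raise.
    """
    opts = options or FitOptions()
    total = hist.total_mass
    if total <= 0:
        raise EmptyHistogramError("histogram has no mass")

    scale = total if opts.objective == "density" else 1.0
    if opts.objective not in ("counts", "density"):
        raise ValueError(f"unknown objective {opts.objective!r}")
    y = hist.counts / scale
    x = hist.bin_centers

    if init is None:
        init = default_init(hist)
    init.validate()
    v0 = init.to_vector()
    if scale != 1.0:
        v0 = v0.copy()
        for t, sl in TISSUE_SLICES.items():
            v0[sl.start] /= scale  # amplitude entries only
    lo, hi = _bounds(y.sum(), opts)
    v0 = np.clip(v0, lo, hi)

    def residuals(v: np.ndarray) -> np.ndarray:
        return evaluate_trimodal(x, NTRAParams.from_vector(v)) - y

    sse0 = float(np.sum(residuals(v0) ** 2))
    try:
        res = optimize.least_squares(
            residuals,
            v0,
            bounds=(lo, hi),
            method="trf",
            ftol=opts.ftol,
            xtol=opts.xtol,
            gtol=None,
            max_nfev=opts.max_iter * len(v0),
        )
    except Exception as exc:  # pragma: no cover - defensive
        return FitResult(init, sse0, converged=False, n_iter=0, message=str(exc))

    v_hat, sse = res.x, float(2.0 * res.cost)
    converged = bool(res.success)
    if sse > sse0:  # trust-region never worsens, but honour the contract
        v_hat, sse, converged = v0, sse0, False
    if scale != 1.0:
        v_hat = v_hat.copy()
        for t, sl in TISSUE_SLICES.items():
            v_hat[sl.start] *= scale
        sse *= scale ** 2
    params = NTRAParams.from_vector(v_hat)

    # a fit collapsed onto (near) zero total amplitude is degenerate
    if params.fat.N + params.connective.N + params.muscle.N < 1e-12 * total:
        converged = False
    # fewer occupied bins than identifiable structure: report as degenerate
    if int(np.count_nonzero(hist.counts)) < 4:
        converged = False

    return FitResult(
        params=params,
        residual_sse=sse,
        converged=converged,
        n_iter=int(res.nfev),
        message=str(res.message),
    )
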