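"""Estimation of diffusion-model parameters from measured signal curves.

The monoexponential ADC comes from a log-linear least-squares fit over the
whole b-range.  The IVIM biexponential and the stretched-exponential models
are fitted by bounded nonlinear least squares (scipy's trust-region
reflective solver; the bounded variant of the classic Levenberg-Marquardt
least-squares problem -- plain LM cannot honor the parameter boxes the
renal-tissue priors require).

The default IVIM strategy is segmented-then-refine: a log-linear fit
restricted to b >= ``b_split`` isolates the tissue compartment (d_slow and,
through its intercept, the perfusion fraction f), a one-dimensional fit
recovers d_fast, and a full three-parameter refinement polishes all three.
A deterministic 3x3 multistart grid around the segmented estimate guards
against local minima; there is no randomness anywhere in fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .models import (
    BiexpParams,
    BValueScheme,
    MonoParams,
    StretchedParams,
    biexp_signal,
    mono_signal,
    stretched_signal,
)

__all__ = [
    "SignalCurve",
    "FitConfig",
    "FitResult",
    "FitError",
    "fit_mono",
    "fit_biexp",
    "fit_stretched",
    "fit_all_models",
]

#: ADC below this (mm^2/s) is treated as no measurable decay.
_DEGENERATE_ADC = 1e-7


class FitError(RuntimeError):
    """Raised when a curve cannot be fitted (too few usable points, ...)."""


@dataclass(frozen=True)
class SignalCurve:
    """Measured relative signal S(b) on a b-value scheme (one ROI or voxel)."""

    scheme: BValueScheme
    signal: tuple[float, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.signal, dtype=float)
        if s.shape != (len(self.scheme),):
            raise ValueError("signal length must match the b-value scheme")
        if not s[0] > 0:
            raise ValueError("signal at b=0 must be positive")
        object.__setattr__(self, "signal", tuple(float(v) for v in s))

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.signal, dtype=float)

    def normalized(self) -> "SignalCurve":
        """Return the curve scaled so signal[0] == 1."""
        s = self.values
        return SignalCurve(self.scheme, tuple(s / s[0]))


@dataclass(frozen=True)
class FitConfig:
    """Fitting strategy, bounds and solver tolerances.

    Bounds are renal-tissue plausibility boxes (mm^2/s): they keep the two
    biexponential rate constants on disjoint scales, which also enforces
    d_fast > d_slow by construction.
    """

    strategy: str = "segmented_then_refine"  # or "free"
    b_split: float = 200.0
    d_slow_bounds: tuple[float, float] = (0.1e-3, 3.0e-3)
    d_fast_bounds: tuple[float, float] = (3.0e-3, 100e-3)
    f_bounds: tuple[float, float] = (0.0, 1.0)
    ddc_bounds: tuple[float, float] = (0.1e-3, 5.0e-3)
    alpha_bounds: tuple[float, float] = (0.01, 1.0)
    max_iterations: int = 500
    tol: float = 1e-10
    fit_s0: bool = False
    nex_weighting: bool = False

    def __post_init__(self) -> None:
        if self.strategy not in ("segmented_then_refine", "free"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        for name in ("d_slow_bounds", "d_fast_bounds", "f_bounds",
                     "ddc_bounds", "alpha_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an increasing pair")


DEFAULT_FIT_CONFIG = FitConfig()


@dataclass(frozen=True)
class FitResult:
    """Outcome of one model fit."""

    params: object | None
    rss: float
    converged: bool
    n_points_used: int
    flags: tuple[str, ...] = ()


def _prepare(curve: SignalCurve, cfg: FitConfig):
    b = curve.scheme.b
    s = curve.values
    s = s / s[0]
    if cfg.nex_weighting:
        w = np.sqrt(np.asarray(curve.scheme.nex, dtype=float))
    else:
        w = np.ones_like(b)
    return b, s, w


def _rss(model, s, w) -> float:
    r = (model - s) * w
    return float(np.dot(r, r))


def _loglinear(b, s, w):
    """Weighted least-squares line through (b, log s); returns slope, intercept."""
    ls = np.log(s)
    wt = w / w.max()
    # closed-form weighted linear regression
    sw = wt.sum()
    bm = (wt * b).sum() / sw
    lm = (wt * ls).sum() / sw
    cov = (wt * (b - bm) * (ls - lm)).sum()
    var = (wt * (b - bm) ** 2).sum()
    slope = cov / var
    return slope, lm - slope * bm


def fit_mono(curve: SignalCurve, cfg: FitConfig | None = None) -> FitResult:
    """Monoexponential ADC by log-linear least squares over all b-values.

    Non-positive signal samples cannot enter the log and are excluded with
    a warning; at least two usable distinct b-values are required.
    """
    cfg = cfg or DEFAULT_FIT_CONFIG
    b, s, w = _prepare(curve, cfg)
    usable = s > 0
    if not usable.all():
        warnings.warn(
            f"excluding {int((~usable).sum())} non-positive signal point(s) "
            "from the monoexponential fit",
            stacklevel=2,
        )
    bu, su, wu = b[usable], s[usable], w[usable]
    if np.unique(bu).size < 2:
        raise FitError("monoexponential fit needs >= 2 distinct usable b-values")
    slope, _ = _loglinear(bu, su, wu)
    adc = max(-slope, 0.0)
    flags: tuple[str, ...] = ()
    if adc <= _DEGENERATE_ADC:
        flags = ("degenerate",)
        adc = max(adc, _DEGENERATE_ADC)
    params = MonoParams(adc=adc)
    rss = _rss(mono_signal(params, bu), su, wu)
    return FitResult(params, rss, True, int(usable.sum()), flags)


def _refine(residual_fn, x0, lower, upper, cfg):
    x0 = np.clip(x0, lower, upper)
    return least_squares(
        residual_fn,
        x0,
        bounds=(lower, upper),
        method="trf",
        xtol=cfg.tol,
        ftol=cfg.tol,
        gtol=cfg.tol,
        max_nfev=cfg.max_iterations * max(1, len(np.atleast_1d(x0))),
    )


def fit_biexp(curve: SignalCurve, cfg: FitConfig | None = None) -> FitResult:
    """IVIM biexponential fit (d_slow, d_fast, f).

    Segmented initialization followed by bounded nonlinear least-squares
    refinement from a deterministic 3x3 multistart grid; best residual sum
    of squares wins, ties broken by first-found.
    """
    cfg = cfg or DEFAULT_FIT_CONFIG
    b, s, w = _prepare(curve, cfg)
    if np.unique(b).size < 4:
        raise FitError("biexponential fit needs >= 4 distinct b-values")
    hi = b >= cfg.b_split
    if not hi.any() or hi.all():
        raise FitError(
            f"biexponential fit needs points on both sides of b_split={cfg.b_split}"
        )

    lo_ds, hi_ds = cfg.d_slow_bounds
    lo_df, hi_df = cfg.d_fast_bounds
    lo_f, hi_f = cfg.f_bounds

    def residual(x):
        f, ds, df = x
        model = f * np.exp(-b * df) + (1.0 - f) * np.exp(-b * ds)
        return (model - s) * w

    # --- segmented initializer: tissue compartment from the high-b tail
    pos = s > 0
    use = hi & pos
    if use.sum() >= 2:
        slope, intercept = _loglinear(b[use], s[use], w[use])
        ds0 = float(np.clip(-slope, lo_ds, hi_ds))
        f0 = float(np.clip(1.0 - np.exp(intercept), max(lo_f, 1e-3), min(hi_f, 0.7)))
    else:
        ds0, f0 = 1.5e-3, 0.2

    def df_residual(x):
        model = f0 * np.exp(-b * x[0]) + (1.0 - f0) * np.exp(-b * ds0)
        return (model - s) * w

    res_df = _refine(df_residual, np.array([15e-3]), [lo_df], [hi_df], cfg)
    df0 = float(res_df.x[0])
    seg_rss = _rss(f0 * np.exp(-b * df0) + (1 - f0) * np.exp(-b * ds0), s, w)

    if cfg.strategy == "segmented_then_refine":
        starts = [
            (f0 * mf, ds0, df0 * md)
            for mf in (0.5, 1.0, 1.5)
            for md in (0.5, 1.0, 2.0)
        ]
    else:  # free: fixed global grid, independent of the segmented stage
        starts = [
            (fi, ds0, dfi)
            for fi in (0.05, 0.15, 0.30)
            for dfi in (8e-3, 20e-3, 50e-3)
        ]

    lower = np.array([lo_f, lo_ds, lo_df])
    upper = np.array([hi_f, hi_ds, hi_df])
    best = None
    for x0 in starts:
        res = _refine(residual, np.asarray(x0, float), lower, upper, cfg)
        if best is None or res.cost < best.cost:
            best = res
    f, ds, df = best.x
    ds = min(ds, df * (1 - 1e-9))  # guard the strict ordering invariant
    params = BiexpParams(d_slow=float(ds), d_fast=float(df), f=float(f))
    rss = _rss(biexp_signal(params, b), s, w)
    flags = []
    if rss > seg_rss * (1 + 1e-9) + 1e-30:
        flags.append("refinement_worse_than_segmented")
    if f <= 0.01 or f >= 0.99 or df >= hi_df * (1 - 1e-6):
        flags.append("weakly_identified")
    converged = bool(best.status > 0)
    if not converged:
        flags.append("not_converged")
    return FitResult(params, rss, converged, len(b), tuple(flags))


def fit_stretched(curve: SignalCurve, cfg: FitConfig | None = None) -> FitResult:
    """Stretched-exponential fit (ddc, alpha) by bounded least squares."""
    cfg = cfg or DEFAULT_FIT_CONFIG
    b, s, w = _prepare(curve, cfg)
    if np.unique(b).size < 3:
        raise FitError("stretched-exponential fit needs >= 3 distinct b-values")
    lo_d, hi_d = cfg.ddc_bounds
    lo_a, hi_a = cfg.alpha_bounds

    def residual(x):
        ddc, alpha = x
        model = np.exp(-np.power(b * ddc, alpha))
        return (model - s) * w

    pos = s > 0
    if pos.sum() >= 2:
        slope, _ = _loglinear(b[pos], s[pos], w[pos])
        ddc0 = float(np.clip(-slope, lo_d, hi_d))
    else:
        ddc0 = 2e-3
    lower = np.array([lo_d, lo_a])
    upper = np.array([hi_d, hi_a])
    best = None
    for a0 in (0.55, 0.75, 0.95):
        res = _refine(residual, np.array([ddc0, a0]), lower, upper, cfg)
        if best is None or res.cost < best.cost:
            best = res
    ddc, alpha = best.x
    params = StretchedParams(ddc=float(ddc), alpha=float(alpha))
    rss = _rss(stretched_signal(params, b), s, w)
    flags = []
    if alpha <= lo_a * (1 + 1e-6):
        flags.append("weakly_identified")
    converged = bool(best.status > 0)
    if not converged:
        flags.append("not_converged")
    return FitResult(params, rss, converged, len(b), tuple(flags))


_FITTERS = {"mono": fit_mono, "biexp": fit_biexp, "stretched": fit_stretched}


def fit_all_models(curve: SignalCurve, cfg: FitConfig | None = None) -> dict[str, FitResult]:
    """Fit all three models to one curve; per-model failures do not cascade.

    A model that raises :class:`FitError` is reported as a non-converged
    result with ``params=None`` and an ``error:`` flag.
    """
    out: dict[str, FitResult] = {}
    for name, fitter in _FITTERS.items():
        try:
            out[name] = fitter(curve, cfg)
        except FitError as exc:
            out[name] = FitResult(None, np.inf, False, 0, (f"error: {exc}",))
    return out
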