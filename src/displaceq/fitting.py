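"""Nonlinear least-squares estimation for titration experiments.

Covers the probe-binding dissociation constant via the ligand-depletion
quadratic isotherm, binding-site multiplicity selection by residual
comparison, single-proton pKa fits of pH titrations, and four-parameter
logistic IC50 fits of displacement titrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .equilibria import QuadraticBindingModel, eq1_fluorescence
from .errors import FitError, IdentifiabilityError, ValidationError

__all__ = [
    "TitrationSeries",
    "KdFit",
    "PkaFit",
    "Ic50Fit",
    "MultiplicityEstimate",
    "fit_kd",
    "estimate_site_multiplicity",
    "fit_pka",
    "fit_ic50",
]

#: Relative RMS misfit (vs. the signal range) above which a selected
#: multiplicity fit is flagged as suspect.
LACK_OF_FIT_THRESHOLD = 0.05


@dataclass(frozen=True)
class TitrationSeries:
    """Paired (x, y) observations for one titration.

    ``x`` holds concentrations in nM (or pH values for protonation
    titrations); ``y`` holds the measured signal. ``meta`` is a free-form
    label describing the titrated species and fixed assay components.
    """

    x: np.ndarray
    y: np.ndarray
    meta: str = ""

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.ndim != 1 or self.y.ndim != 1:
            raise ValidationError("x and y must be one-dimensional")
        if len(self.x) != len(self.y):
            raise ValidationError(
                f"x and y must have equal length, got {len(self.x)} and {len(self.y)}"
            )
        if not np.all(np.isfinite(self.x)):
            raise ValidationError("all x values must be finite")

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class KdFit:
    """Result of a quadratic-isotherm dissociation-constant fit."""

    kd: float
    f0: float
    fb: float
    psi_multiplier: int
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")
    n_points: int = 0

    def predict(self, concentrations, probe_total: float):
        model = QuadraticBindingModel(self.f0, self.fb, self.kd, probe_total)
        return eq1_fluorescence(model, self.psi_multiplier * np.asarray(concentrations, float))


@dataclass(frozen=True)
class PkaFit:
    """Result of a single-proton ionization fit."""

    pka: float
    signal_mono: float
    signal_di: float
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")
    n_points: int = 0


@dataclass(frozen=True)
class Ic50Fit:
    """Result of a four-parameter logistic dose-response fit."""

    ic50: float
    hill: float
    top: float
    bottom: float
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")
    n_points: int = 0


@dataclass(frozen=True)
class MultiplicityEstimate:
    """Binding-site multiplicity selected by residual comparison."""

    n_sites: int
    residuals: dict
    fit: KdFit
    lack_of_fit: bool = False


def _check_series(series: TitrationSeries, min_points: int, concentrations: bool = True):
    if len(series) < min_points:
        raise ValidationError(
            f"need at least {min_points} points for this fit, got {len(series)}"
        )
    if not np.all(np.isfinite(series.y)):
        raise ValidationError("all y values must be finite")
    if concentrations and np.any(series.x < 0):
        raise ValidationError("concentrations must be >= 0")


def _check_not_flat(y: np.ndarray):
    scale = max(np.max(np.abs(y)), 1.0)
    if np.ptp(y) <= 1e-10 * scale:
        raise IdentifiabilityError("signal series is flat: no transition to fit")


def _stderr_from_cov(pcov, names):
    if pcov is None or not np.all(np.isfinite(pcov)):
        return {name: float("nan") for name in names}
    diag = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return {name: float(se) for name, se in zip(names, diag)}


def fit_kd(series: TitrationSeries, psi_multiplier: int, probe_total: float) -> KdFit:
    """Fit (f0, fb, kd) of the quadratic isotherm to a titration.

    ``series.x`` is the RNA concentration in nM; the binding-site
    concentration used in the model is ``psi_multiplier * x``. Starting
    values are taken from the signal extremes and the half-transition
    concentration, so the fit is deterministic for identical inputs.
    """

    _check_series(series, 4)
    _check_not_flat(series.y)
    if int(psi_multiplier) < 1:
        raise ValidationError(f"psi_multiplier must be >= 1, got {psi_multiplier}")
    if not probe_total > 0:
        raise ValidationError(f"probe_total must be > 0, got {probe_total}")
    mult = int(psi_multiplier)
    x, y = series.x, series.y

    def model(conc, f0, fb, kd):
        m = QuadraticBindingModel(f0=f0, fb=fb, kd=kd, probe_total=probe_total)
        return eq1_fluorescence(m, mult * conc)

    f0_0 = float(np.max(y))
    fb_0 = float(np.min(y))
    mid = 0.5 * (f0_0 + fb_0)
    kd_0 = float(max(x[np.argmin(np.abs(y - mid))], 1e-3))
    try:
        popt, pcov = curve_fit(
            model,
            x,
            y,
            p0=[f0_0, fb_0, kd_0],
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"kd fit did not converge: {exc}") from exc
    resid = y - model(x, *popt)
    return KdFit(
        kd=float(popt[2]),
        f0=float(popt[0]),
        fb=float(popt[1]),
        psi_multiplier=mult,
        stderr=_stderr_from_cov(pcov, ["f0", "fb", "kd"]),
        rss=float(np.sum(resid**2)),
        n_points=len(series),
    )


def estimate_site_multiplicity(
    series: TitrationSeries,
    probe_total: float,
    candidates=range(1, 9),
) -> MultiplicityEstimate:
    """Select the integer sites-per-RNA multiplier with minimal residual.

    Fits the quadratic isotherm once per candidate multiplier and returns
    the candidate with the smallest residual sum of squares, breaking ties
    toward the smallest multiplier. The selection is flagged when even the
    best fit leaves a large residual relative to the signal range (the true
    multiplicity may lie outside the candidate set).
    """

    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ValidationError("candidate set must be non-empty")
    residuals: dict[int, float] = {}
    fits: dict[int, KdFit] = {}
    last_error: FitError | None = None
    for n in candidates:
        try:
            fits[n] = fit_kd(series, n, probe_total)
            residuals[n] = fits[n].rss
        except FitError as exc:
            last_error = exc
    if not fits:
        raise FitError(f"all candidate fits failed; last error: {last_error}")
    best_rss = min(residuals.values())
    # tie-break toward the smallest multiplier (parsimony)
    n_best = min(n for n, rss in residuals.items() if rss <= best_rss * (1 + 1e-9))
    fit = fits[n_best]
    rel_rmse = math.sqrt(fit.rss / len(series)) / max(np.ptp(series.y), 1e-300)
    return MultiplicityEstimate(
        n_sites=n_best,
        residuals=residuals,
        fit=fit,
        lack_of_fit=rel_rmse > LACK_OF_FIT_THRESHOLD,
    )


def fit_pka(series: TitrationSeries) -> PkaFit:
    """Fit the single-proton ionization model to a signal-vs-pH titration.

    The fitted pKa must lie inside the observed pH range; otherwise the
    transition is not identifiable from the data.
    """

    _check_series(series, 4, concentrations=False)
    _check_not_flat(series.y)
    x, y = series.x, series.y
    if np.ptp(x) < 1.5:
        raise ValidationError(
            f"pH range must span at least 1.5 units, got {np.ptp(x):.2f}"
        )

    def model(ph, pka, mono, di):
        return mono + (di - mono) / (1.0 + 10.0 ** (pka - ph))

    mid = 0.5 * (np.max(y) + np.min(y))
    pka_0 = float(x[np.argmin(np.abs(y - mid))])
    # orient asymptotes from the ends of the pH axis: low pH -> monoanion
    order = np.argsort(x)
    mono_0, di_0 = float(y[order[0]]), float(y[order[-1]])
    try:
        popt, pcov = curve_fit(model, x, y, p0=[pka_0, mono_0, di_0], maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"pKa fit did not converge: {exc}") from exc
    pka = float(popt[0])
    if not (np.min(x) <= pka <= np.max(x)):
        raise IdentifiabilityError(
            f"fitted pKa {pka:.2f} lies outside the observed pH range "
            f"[{np.min(x):.2f}, {np.max(x):.2f}]"
        )
    resid = y - model(x, *popt)
    return PkaFit(
        pka=pka,
        signal_mono=float(popt[1]),
        signal_di=float(popt[2]),
        stderr=_stderr_from_cov(pcov, ["pka", "signal_mono", "signal_di"]),
        rss=float(np.sum(resid**2)),
        n_points=len(series),
    )


def fit_ic50(series: TitrationSeries) -> Ic50Fit:
    """Fit a four-parameter logistic in log10(concentration).

    Model: ``y = bottom + (top - bottom) / (1 + 10**(hill*(log10 IC50 - log10 x)))``
    so the IC50 is the inflection point. Requires strictly positive
    concentrations that bracket the transition.
    """

    _check_series(series, 5)
    _check_not_flat(series.y)
    x, y = series.x, series.y
    if np.any(x <= 0):
        raise ValidationError("all concentrations must be > 0 for a log-scale fit")
    if len(np.unique(x)) < 4:
        raise IdentifiabilityError(
            "need at least 4 distinct concentrations to fit a dose-response curve"
        )
    logx = np.log10(x)

    def model(lx, top, bottom, logic50, hill):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logic50 - lx)))

    order = np.argsort(x)
    top_0 = float(y[order[-1]])
    bottom_0 = float(y[order[0]])
    mid = 0.5 * (top_0 + bottom_0)
    logic50_0 = float(logx[np.argmin(np.abs(y - mid))])
    try:
        popt, pcov = curve_fit(
            model, logx, y, p0=[top_0, bottom_0, logic50_0, 1.0], maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"IC50 fit did not converge: {exc}") from exc
    top, bottom, logic50, hill = (float(v) for v in popt)
    ic50 = 10.0**logic50
    if not (np.min(x) <= ic50 <= np.max(x)):
        raise IdentifiabilityError(
            f"fitted IC50 {ic50:.3g} nM is not bracketed by the titrated "
            f"concentrations [{np.min(x):.3g}, {np.max(x):.3g}] nM"
        )
    if top == bottom:
        raise IdentifiabilityError("fitted top equals bottom: no response window")
    resid = y - model(logx, *popt)
    stderr = _stderr_from_cov(pcov, ["top", "bottom", "log_ic50", "hill"])
    # delta-method conversion of the log-scale error to nM
    stderr["ic50"] = stderr.pop("log_ic50") * ic50 * math.log(10.0)
    return Ic50Fit(
        ic50=ic50,
        hill=hill,
        top=top,
        bottom=bottom,
        stderr=stderr,
        rss=float(np.sum(resid**2)),
        n_points=len(series),
    )
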