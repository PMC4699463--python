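"""Binding and protonation equilibria.

Closed-form tight-binding (ligand-depletion) fluorescence isotherm, the
numeric two-ligand/one-site-class competitive mass-balance solver that
backs displacement simulations, the two-state fluorescein ionization
model, and the conversion of a probe pKa shift into an apparent
electrostatic potential of the binding site.

All concentrations are in nM throughout the public API.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import ConvergenceError, ValidationError

__all__ = [
    "GAS_CONSTANT",
    "AVOGADRO",
    "ELEMENTARY_CHARGE",
    "DEFAULT_TEMPERATURE_K",
    "LOG10_FACTOR",
    "QuadraticBindingModel",
    "EquilibriumState",
    "ProtonationModel",
    "ElectrostaticResult",
    "eq1_fluorescence",
    "solve_competitive_equilibrium",
    "dianion_fraction",
    "electrostatic_potential",
]

# Constants as used in the source analysis (not CODATA): R in J mol^-1 K^-1,
# Avogadro's number, elementary charge in C, assay temperature in K, and the
# ln(10) factor rounded to 2.303.
GAS_CONSTANT = 8.312
AVOGADRO = 6.023e23
ELEMENTARY_CHARGE = 1.602e-19
DEFAULT_TEMPERATURE_K = 298.2
LOG10_FACTOR = 2.303

#: Relative discriminant magnitude below which a negative discriminant is
#: treated as round-off and clamped to zero.
_DISCRIMINANT_GUARD = 1e-9

#: Relative mass-balance residual accepted from the competitive solver.
_RESIDUAL_TOL = 1e-9


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class QuadraticBindingModel:
    """Forward model of probe fluorescence vs. binding-site concentration.

    Parameters
    ----------
    f0 : float
        Fluorescence of the free probe (arbitrary units).
    fb : float
        Fluorescence of the fully bound probe (same units). Quenching
        assays have ``fb < f0`` but the model accepts ``fb >= f0``.
    kd : float
        Probe-site dissociation constant in nM.
    probe_total : float
        Total probe concentration in nM.
    """

    f0: float
    fb: float
    kd: float
    probe_total: float

    def __post_init__(self):
        for name in ("f0", "fb", "kd", "probe_total"):
            _require_finite(name, getattr(self, name))
        if self.kd <= 0:
            raise ValidationError(f"kd must be > 0, got {self.kd}")
        if self.probe_total <= 0:
            raise ValidationError(f"probe_total must be > 0, got {self.probe_total}")


@dataclass(frozen=True)
class EquilibriumState:
    """Species concentrations (nM) at a two-ligand, one-site-class equilibrium."""

    free_sites: float
    bound_probe: float
    bound_competitor: float
    free_probe: float
    free_competitor: float

    @property
    def probe_total(self) -> float:
        return self.bound_probe + self.free_probe

    @property
    def competitor_total(self) -> float:
        return self.bound_competitor + self.free_competitor

    @property
    def site_total(self) -> float:
        return self.free_sites + self.bound_probe + self.bound_competitor

    def __post_init__(self):
        for name in (
            "free_sites",
            "bound_probe",
            "bound_competitor",
            "free_probe",
            "free_competitor",
        ):
            value = _require_finite(name, getattr(self, name))
            if value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value}")


@dataclass(frozen=True)
class ProtonationModel:
    """Single-proton (monoanion/dianion) ionization of the fluorophore."""

    pka: float
    signal_mono: float
    signal_di: float

    def __post_init__(self):
        _require_finite("pka", self.pka)
        _require_finite("signal_mono", self.signal_mono)
        _require_finite("signal_di", self.signal_di)
        if not 0.0 < self.pka < 14.0:
            raise ValidationError(f"pka must lie in (0, 14), got {self.pka}")
        if self.signal_di == self.signal_mono:
            raise ValidationError("signal_di must differ from signal_mono")


@dataclass(frozen=True)
class ElectrostaticResult:
    """Apparent electrostatic potential inferred from a probe pKa shift."""

    delta_pka: float
    phi_kt_per_e: float
    phi_volts: float
    temperature_k: float = DEFAULT_TEMPERATURE_K


def eq1_fluorescence(model: QuadraticBindingModel, psi):
    """Probe fluorescence at total binding-site concentration ``psi`` (nM).

    Evaluates the ligand-depletion ("tight-binding") quadratic isotherm

        F = F0 + (Fb - F0) / (2 P) * (S - sqrt(S^2 - 4 psi P)),

    with ``P = probe_total`` and ``S = psi + P + kd``. Accepts a scalar or
    array ``psi``; returns the matching shape.
    """

    psi_arr = np.asarray(psi, dtype=float)
    if not np.all(np.isfinite(psi_arr)):
        raise ValidationError("psi must be finite")
    if np.any(psi_arr < 0):
        raise ValidationError("psi must be >= 0")

    p = model.probe_total
    s = psi_arr + p + model.kd
    disc = s * s - 4.0 * psi_arr * p
    bad = disc < -_DISCRIMINANT_GUARD * s * s
    if np.any(bad):
        raise ValidationError("quadratic discriminant is negative beyond round-off")
    disc = np.clip(disc, 0.0, None)
    bound = 0.5 * (s - np.sqrt(disc))
    f = model.f0 + (model.fb - model.f0) * bound / p
    if np.isscalar(psi) or np.ndim(psi) == 0:
        return float(f)
    return f


def solve_competitive_equilibrium(
    site_total: float,
    probe_total: float,
    kd_probe: float,
    competitor_total: float,
    kd_competitor: float,
) -> EquilibriumState:
    """Solve the two-ligand, one-site-class competitive binding equilibrium.

    All binding sites are treated as equivalent. The mass-balance system is
    reduced to a single monotone equation in the free-site concentration
    ``s`` on ``[0, site_total]``:

        s + s*P/(Kp + s) + s*C/(Kc + s) = site_total,

    solved by bracketing root-find and polished by Newton steps. An infinite
    ``kd_competitor`` denotes an inert competitor.
    """

    for name, value in (
        ("site_total", site_total),
        ("probe_total", probe_total),
        ("competitor_total", competitor_total),
    ):
        value = float(value)
        if not math.isfinite(value) or value < 0:
            raise ValidationError(f"{name} must be finite and >= 0, got {value}")
    for name, value in (("kd_probe", kd_probe), ("kd_competitor", kd_competitor)):
        if not float(value) > 0:  # +inf allowed for kd_competitor
            raise ValidationError(f"{name} must be > 0, got {value}")
    if math.isinf(kd_probe):
        raise ValidationError("kd_probe must be finite")

    s_tot = float(site_total)
    p_tot = float(probe_total)
    c_tot = float(competitor_total)
    kp = float(kd_probe)
    kc = float(kd_competitor)
    if math.isinf(kc):
        c_tot_eff = 0.0
        kc = 1.0
    else:
        c_tot_eff = c_tot

    def balance(s: float) -> float:
        return s + s * p_tot / (kp + s) + s * c_tot_eff / (kc + s) - s_tot

    if s_tot == 0.0:
        s = 0.0
    else:
        s = brentq(balance, 0.0, s_tot, xtol=1e-14, rtol=8.9e-16, maxiter=200)
        # Newton polish to push the site balance to machine precision.
        for _ in range(3):
            deriv = (
                1.0
                + p_tot * kp / (kp + s) ** 2
                + c_tot_eff * kc / (kc + s) ** 2
            )
            step = balance(s) / deriv
            s = min(max(s - step, 0.0), s_tot)

    bound_probe = p_tot * s / (kp + s)
    bound_comp = c_tot_eff * s / (kc + s)
    state = EquilibriumState(
        free_sites=s,
        bound_probe=bound_probe,
        bound_competitor=bound_comp,
        free_probe=p_tot - bound_probe,
        free_competitor=c_tot - bound_comp,
    )
    residual = abs(balance(s)) / max(s_tot, 1.0)
    if residual > _RESIDUAL_TOL:
        raise ConvergenceError(
            f"site mass balance did not converge (relative residual {residual:.3e})",
            residual=residual,
        )
    return state


def dianion_fraction(ph: float, model: ProtonationModel) -> tuple[float, float]:
    """Dianion fraction and predicted signal at the given pH.

    Returns ``(fraction, signal)`` with ``fraction = 1/(1 + 10**(pKa - pH))``
    and the signal linearly interpolated between the monoanion and dianion
    asymptotes.
    """

    ph = _require_finite("ph", ph)
    fraction = 1.0 / (1.0 + 10.0 ** (model.pka - ph))
    signal = model.signal_mono + (model.signal_di - model.signal_mono) * fraction
    return fraction, signal


def electrostatic_potential(
    pka_free: float,
    pka_bound: float,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
) -> ElectrostaticResult:
    """Apparent potential of the probe binding site from the pKa shift.

    ``phi = -2.303 * (pKa_bound - pKa_free)`` in units of kT/e; also
    reported in volts at ``temperature_k`` using kB*T/e = R*T/(N_A*e).
    """

    for name, value in (("pka_free", pka_free), ("pka_bound", pka_bound)):
        value = _require_finite(name, value)
        if not 0.0 < value < 14.0:
            raise ValidationError(f"{name} must lie in (0, 14), got {value}")
    temperature_k = _require_finite("temperature_k", temperature_k)
    if temperature_k <= 0:
        raise ValidationError(f"temperature_k must be > 0, got {temperature_k}")

    delta = pka_bound - pka_free
    phi_kt = -LOG10_FACTOR * delta
    kt_over_e = GAS_CONSTANT * temperature_k / (AVOGADRO * ELEMENTARY_CHARGE)
    return ElectrostaticResult(
        delta_pka=delta,
        phi_kt_per_e=phi_kt,
        phi_volts=phi_kt * kt_over_e,
        temperature_k=temperature_k,
    )
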