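"""Seeded generators for every input the analysis pipeline consumes.

Forward-simulates probe titrations, displacement titrations, pH
titrations and full multi-plate single-point screens from the binding
models in :mod:`displaceq.equilibria`, with multiplicative Gaussian well
noise. Also provides the dot-bracket bulge/internal-loop counter used to
relate secondary structure to binding-site multiplicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .equilibria import (
    ProtonationModel,
    QuadraticBindingModel,
    dianion_fraction,
    eq1_fluorescence,
    solve_competitive_equilibrium,
)
from .errors import ParseError, ValidationError
from .fitting import TitrationSeries
from .preferences import AA_CODES, BETA_ALANINE, parse_compound_name
from .screening import PlateSet, Well

__all__ = [
    "AssayCondition",
    "NoiseModel",
    "LibraryTruth",
    "PRESETS",
    "DEFAULT_POS1_EFFECTS",
    "DEFAULT_POS2_EFFECTS",
    "default_roster",
    "simulate_fneo_titration",
    "simulate_displacement_titration",
    "simulate_ph_titration",
    "generate_ground_truth_library",
    "simulate_screen_plates",
    "simulate_control_plate",
    "noiseless_ic50",
    "competitor_kd_for_ic50",
    "count_bulge_regions",
]

#: Default fluorescence endpoints for simulated wells (arbitrary units):
#: free probe vs. fully bound (quenched) probe.
DEFAULT_F0 = 1000.0
DEFAULT_FB = 200.0


@dataclass(frozen=True)
class AssayCondition:
    """Fixed concentrations and site multiplicity of one screen format."""

    probe_total: float  # nM
    rna_total: float  # nM
    compound_conc: float  # nM, single-point screen concentration
    n_sites_per_rna: int
    kd_probe: float  # nM

    def __post_init__(self):
        for name in ("probe_total", "rna_total", "compound_conc", "kd_probe"):
            value = float(getattr(self, name))
            if not (math.isfinite(value) and value > 0):
                raise ValidationError(f"{name} must be finite and > 0, got {value}")
        if int(self.n_sites_per_rna) < 1:
            raise ValidationError(
                f"n_sites_per_rna must be >= 1, got {self.n_sites_per_rna}"
            )

    @property
    def site_total(self) -> float:
        return self.rna_total * self.n_sites_per_rna


#: Screen formats used in the source study: probe at 100 nM throughout;
#: two sites per mature miR-504 duplex, six per pre-miR-504 hairpin, one
#: per miR-142/miR-335 duplex; probe kd from the titration fits.
PRESETS: dict[str, AssayCondition] = {
    "mir504": AssayCondition(100.0, 50.0, 300.0, 2, 1.5),
    "premir504": AssayCondition(100.0, 16.7, 300.0, 6, 0.5),
    "mir142": AssayCondition(100.0, 100.0, 500.0, 1, 2.0),
    "mir335": AssayCondition(100.0, 100.0, 500.0, 1, 2.2),
}


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian well noise: signal *= N(1, cv)."""

    cv: float = 0.02
    seed: int | None = None

    def __post_init__(self):
        if self.cv < 0:
            raise ValidationError(f"cv must be >= 0, got {self.cv}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.cv == 0:
            return values.copy()
        return values * rng.normal(1.0, self.cv, size=values.shape)


def simulate_fneo_titration(
    model: QuadraticBindingModel,
    rna_concs,
    n_sites: int,
    noise: NoiseModel = NoiseModel(cv=0.0),
) -> TitrationSeries:
    """Simulate titrating RNA into the probe and reading fluorescence."""

    rna_concs = np.asarray(rna_concs, dtype=float)
    if rna_concs.size == 0:
        raise ValidationError("rna_concs must be non-empty")
    if np.any(rna_concs < 0):
        raise ValidationError("rna_concs must be >= 0")
    if int(n_sites) < 1:
        raise ValidationError(f"n_sites must be >= 1, got {n_sites}")
    y = eq1_fluorescence(model, int(n_sites) * rna_concs)
    y = noise.apply(np.atleast_1d(y), noise.rng())
    return TitrationSeries(x=rna_concs, y=y, meta=f"fneo_titration:n_sites={n_sites}")


def simulate_displacement_titration(
    cond: AssayCondition,
    kd_competitor: float,
    competitor_concs,
    f0: float = DEFAULT_F0,
    fb: float = DEFAULT_FB,
    noise: NoiseModel = NoiseModel(cv=0.0),
) -> TitrationSeries:
    """Simulate titrating a competitor into a pre-formed probe:RNA mix.

    Well signals come from the competitive mass-balance solver:
    ``y = f0 + (fb - f0) * bound_probe / probe_total`` plus well noise.
    """

    concs = np.asarray(competitor_concs, dtype=float)
    if concs.size == 0:
        raise ValidationError("competitor_concs must be non-empty")
    if np.any(concs < 0):
        raise ValidationError("competitor_concs must be >= 0")
    y = np.empty_like(concs)
    for i, c in enumerate(concs):
        state = solve_competitive_equilibrium(
            cond.site_total, cond.probe_total, cond.kd_probe, c, kd_competitor
        )
        y[i] = f0 + (fb - f0) * state.bound_probe / cond.probe_total
    y = noise.apply(y, noise.rng())
    return TitrationSeries(x=concs, y=y, meta=f"displacement:kd_comp={kd_competitor}")


def simulate_ph_titration(
    pka: float,
    signal_mono: float,
    signal_di: float,
    ph_grid,
    noise: NoiseModel = NoiseModel(cv=0.0),
) -> TitrationSeries:
    """Simulate a signal-vs-pH titration from the two-state ionization model."""

    ph_grid = np.asarray(ph_grid, dtype=float)
    if ph_grid.size == 0:
        raise ValidationError("ph_grid must be non-empty")
    model = ProtonationModel(pka=pka, signal_mono=signal_mono, signal_di=signal_di)
    y = np.array([dianion_fraction(ph, model)[1] for ph in ph_grid])
    y = noise.apply(y, noise.rng())
    return TitrationSeries(x=ph_grid, y=y, meta=f"ph_titration:pka={pka}")


# ---------------------------------------------------------------------------
# Ground-truth compound library


def default_roster() -> list[str]:
    """Default 215-compound conjugate roster.

    15 mono-conjugates (the 14 variable codes plus K), di-conjugates with
    position 2 in {S, T, Y, V} over all 15 position-1 codes, and
    di-conjugates with position 2 in {D, W, betaA, H, R, L, F, C, A, N}
    over the 14 position-1 codes without K.
    """

    pos1_with_k = ["A", "R", "N", "D", "H", "L", "F", "P", "S", "T", "Y", "V", "C", "W", "K"]
    pos1_no_k = pos1_with_k[:-1]
    roster = [f"Neo{c}" for c in pos1_with_k]
    for p2 in ["S", "T", "Y", "V"]:
        roster += [f"Neo{c}{p2}" for c in pos1_with_k]
    for p2 in ["D", "W", BETA_ALANINE, "H", "R", "L", "F", "C", "A", "N"]:
        roster += [f"Neo{c}{p2}" for c in pos1_no_k]
    return roster


#: Default additive effects on log10(kd). Negative means tighter binding
#: than the parent: arginine stabilizes, aspartate and tryptophan
#: destabilize, serine at position 2 stabilizes.
DEFAULT_POS1_EFFECTS: dict[str, float] = {
    "A": 0.05, "R": -0.35, "N": 0.00, "D": 0.40, "H": -0.10,
    "L": 0.10, "F": 0.10, "P": 0.10, "S": -0.05, "T": -0.05,
    "Y": 0.00, "V": 0.05, "C": 0.05, "W": 0.25, "K": -0.20,
}

DEFAULT_POS2_EFFECTS: dict[str, float] = {
    "S": -0.30, "T": -0.20, "Y": -0.15, "V": -0.10, "D": 0.45,
    "W": 0.25, BETA_ALANINE: 0.15, "H": 0.00, "R": -0.05, "L": 0.10,
    "F": 0.10, "C": 0.10, "A": 0.00, "N": 0.00,
}


@dataclass(frozen=True)
class LibraryTruth:
    """Deterministic per-compound true dissociation constants (nM)."""

    kd: dict  # compound name -> true kd, nM
    kd_neo: float
    alpha: dict = field(default_factory=dict)
    beta: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"compound": list(self.kd), "kd_nm": list(self.kd.values())}
        )


def generate_ground_truth_library(
    alpha: dict | None = None,
    beta: dict | None = None,
    roster: list[str] | None = None,
    kd_neo: float = 10.0,
    noise_sd: float = 0.05,
    seed: int | None = 0,
) -> LibraryTruth:
    """Generate true compound kds from additive positional effects.

    ``log10(kd) = log10(kd_neo) + alpha(pos1) + beta(pos2) + eps`` with
    ``eps ~ N(0, noise_sd)`` drawn once per compound from ``seed``.
    """

    alpha = dict(DEFAULT_POS1_EFFECTS if alpha is None else alpha)
    beta = dict(DEFAULT_POS2_EFFECTS if beta is None else beta)
    roster = list(default_roster() if roster is None else roster)
    if not roster:
        raise ValidationError("roster must be non-empty")
    if not kd_neo > 0:
        raise ValidationError(f"kd_neo must be > 0, got {kd_neo}")
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")

    rng = np.random.default_rng(seed)
    kd: dict[str, float] = {}
    for raw in roster:
        name = parse_compound_name(raw)
        log_kd = math.log10(kd_neo)
        for pos, table, label in ((name.pos1, alpha, "alpha"), (name.pos2, beta, "beta")):
            if pos is None:
                continue
            if pos not in table:
                raise ValidationError(
                    f"no {label} effect defined for amino-acid code {pos!r} "
                    f"(compound {raw})"
                )
            log_kd += table[pos]
        if noise_sd > 0:
            log_kd += rng.normal(0.0, noise_sd)
        kd[raw] = 10.0**log_kd
    return LibraryTruth(
        kd=kd, kd_neo=float(kd_neo), alpha=alpha, beta=beta,
        noise_sd=float(noise_sd), seed=seed,
    )


# ---------------------------------------------------------------------------
# Plate simulation

_ROWS = "ABCDEFGH"


def _well_positions():
    for row in _ROWS:
        for col in range(1, 13):
            yield f"{row}{col}"


def _signal_from_bound(bound: float, probe_total: float, f0: float, fb: float) -> float:
    return f0 + (fb - f0) * bound / probe_total


def simulate_screen_plates(
    truth: LibraryTruth,
    cond: AssayCondition,
    noise: NoiseModel = NoiseModel(),
    duplicates: int = 2,
    f0: float = DEFAULT_F0,
    fb: float = DEFAULT_FB,
) -> PlateSet:
    """Simulate a full single-point displacement screen of the library.

    Each 96-well plate carries two probe-only wells, two negative
    (probe+RNA) wells and two positive (probe+RNA+neomycin) wells,
    followed by library compounds in ``duplicates`` adjacent wells each.
    Compound well signals come from the competitive solver at the
    compound's true kd and the screen concentration of the condition.
    """

    if duplicates < 1:
        raise ValidationError(f"duplicates must be >= 1, got {duplicates}")
    per_plate = (96 - 6) // duplicates
    if per_plate < 1:
        raise ValidationError("too many duplicates for a 96-well plate")

    rng = noise.rng()
    state0 = solve_competitive_equilibrium(
        cond.site_total, cond.probe_total, cond.kd_probe, 0.0, 1.0
    )
    neg_signal = _signal_from_bound(state0.bound_probe, cond.probe_total, f0, fb)
    state_neo = solve_competitive_equilibrium(
        cond.site_total, cond.probe_total, cond.kd_probe,
        cond.compound_conc, truth.kd_neo,
    )
    pos_signal = _signal_from_bound(state_neo.bound_probe, cond.probe_total, f0, fb)
    compound_signal: dict[str, float] = {}
    for name, kd in truth.kd.items():
        state = solve_competitive_equilibrium(
            cond.site_total, cond.probe_total, cond.kd_probe, cond.compound_conc, kd
        )
        compound_signal[name] = _signal_from_bound(
            state.bound_probe, cond.probe_total, f0, fb
        )

    wells: list[Well] = []
    compounds = list(truth.kd)
    n_plates = max(1, math.ceil(len(compounds) / per_plate))
    for p in range(n_plates):
        plate_id = f"plate{p + 1}"
        positions = _well_positions()
        layout: list[tuple[str, str | None, float]] = [
            ("probe_only", None, f0),
            ("probe_only", None, f0),
            ("negative", None, neg_signal),
            ("negative", None, neg_signal),
            ("positive", "Neomycin", pos_signal),
            ("positive", "Neomycin", pos_signal),
        ]
        for name in compounds[p * per_plate : (p + 1) * per_plate]:
            layout += [("compound", name, compound_signal[name])] * duplicates
        for (role, name, clean), position in zip(layout, positions):
            signal = float(noise.apply(np.array([clean]), rng)[0])
            wells.append(
                Well(
                    plate_id=plate_id,
                    position=position,
                    role=role,
                    signal=max(signal, 0.0),
                    compound=name,
                )
            )
    return PlateSet(wells=wells)


def simulate_control_plate(
    cond: AssayCondition,
    kd_neo: float,
    noise: NoiseModel = NoiseModel(),
    n_pos: int = 48,
    n_neg: int = 48,
    f0: float = DEFAULT_F0,
    fb: float = DEFAULT_FB,
    plate_id: str = "controls",
) -> PlateSet:
    """Simulate a control-only plate for Z'-factor determination."""

    if n_pos + n_neg > 96:
        raise ValidationError("control plate cannot exceed 96 wells")
    rng = noise.rng()
    state0 = solve_competitive_equilibrium(
        cond.site_total, cond.probe_total, cond.kd_probe, 0.0, 1.0
    )
    neg_signal = _signal_from_bound(state0.bound_probe, cond.probe_total, f0, fb)
    state_neo = solve_competitive_equilibrium(
        cond.site_total, cond.probe_total, cond.kd_probe, cond.compound_conc, kd_neo
    )
    pos_signal = _signal_from_bound(state_neo.bound_probe, cond.probe_total, f0, fb)
    layout = [("positive", pos_signal)] * n_pos + [("negative", neg_signal)] * n_neg
    wells = []
    for (role, clean), position in zip(layout, _well_positions()):
        signal = float(noise.apply(np.array([clean]), rng)[0])
        wells.append(
            Well(
                plate_id=plate_id,
                position=position,
                role=role,
                signal=max(signal, 0.0),
                compound="Neomycin" if role == "positive" else None,
            )
        )
    return PlateSet(wells=wells)


# ---------------------------------------------------------------------------
# IC50 <-> kd helpers for designing simulations around printed IC50 values


def noiseless_ic50(
    cond: AssayCondition, kd_competitor: float, conc_hi: float | None = None
) -> float:
    """Competitor concentration displacing half the initially bound probe."""

    if conc_hi is None:
        conc_hi = 1e6 * max(kd_competitor, cond.site_total, cond.probe_total, 1.0)
    state0 = solve_competitive_equilibrium(
        cond.site_total, cond.probe_total, cond.kd_probe, 0.0, 1.0
    )
    half = 0.5 * state0.bound_probe

    def gap(conc: float) -> float:
        state = solve_competitive_equilibrium(
            cond.site_total, cond.probe_total, cond.kd_probe, conc, kd_competitor
        )
        return state.bound_probe - half

    return brentq(gap, 1e-9, conc_hi, xtol=1e-9, rtol=1e-12)


def competitor_kd_for_ic50(cond: AssayCondition, ic50_target: float) -> float:
    """Invert the displacement model: find the kd producing a target IC50."""

    if not ic50_target > 0:
        raise ValidationError(f"ic50_target must be > 0, got {ic50_target}")

    def gap(log_kd: float) -> float:
        return noiseless_ic50(cond, 10.0**log_kd) - ic50_target

    return 10.0 ** brentq(gap, -6.0, 9.0, xtol=1e-12)


# ---------------------------------------------------------------------------
# Dot-bracket bulge counting


def count_bulge_regions(structure: str) -> int:
    """Count bulge and internal-loop regions in a dot-bracket structure.

    Counts maximal unpaired regions enclosed within a helix. A two-sided
    internal loop counts once. Hairpin loops, exterior dangling ends and
    unpaired stretches adjacent to the ``&`` strand break of a two-strand
    duplex are excluded; ``&`` terminates a region and is never itself
    unpaired. Each unpaired stretch of a multibranch loop counts as one
    region.
    """

    n = len(structure)
    pair = [-1] * n
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ParseError(f"unmatched ')' at position {i}", position=i)
            j = stack.pop()
            pair[i], pair[j] = j, i
        elif ch not in ".&":
            raise ParseError(
                f"invalid character {ch!r} at position {i}", position=i
            )
    if stack:
        raise ParseError(
            f"unmatched '(' at position {stack[-1]}", position=stack[-1]
        )

    count = 0
    for i in range(n):
        j = pair[i]
        if j <= i:
            continue
        # walk the loop closed by pair (i, j)
        children = 0
        runs: list[int] = []
        current = 0
        broke_at_strand_gap = False
        k = i + 1
        while k < j:
            if pair[k] > k:
                if current:
                    runs.append(current)
                    current = 0
                children += 1
                k = pair[k] + 1
            elif structure[k] == "&":
                # strand break: terminate the run; flanking unpaired bases
                # are duplex overhangs, not loop bases
                current = 0
                broke_at_strand_gap = True
                k += 1
            else:
                current += 1
                k += 1
        if current and not (broke_at_strand_gap and children == 0):
            runs.append(current)
        if children == 0:
            continue  # hairpin loop or blunt duplex end: excluded
        if children == 1:
            if runs:
                count += 1
        else:
            count += len(runs)
    return count
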