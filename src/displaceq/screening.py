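"""Plate-level analysis of 96-well displacement screens.

Z'-factor assay quality control, per-plate percent-binding normalization
against the on-plate neomycin control, duplicate summarization, and hit
calling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from statistics import mean

import numpy as np

from .errors import DegenerateWindowError, PlateValidationError, ValidationError

__all__ = [
    "ROLES",
    "Well",
    "PlateSet",
    "ZFactorResult",
    "CompoundScreenRecord",
    "zfactor",
    "percent_binding",
    "summarize_screen",
    "call_hits",
]

ROLES = ("probe_only", "negative", "positive", "compound")

_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")

#: Name under which the positive-control wells are summarized.
POSITIVE_CONTROL_NAME = "Neomycin"


@dataclass(frozen=True)
class Well:
    """One well of a 96-well plate.

    Roles: ``probe_only`` (probe alone, total-window QC), ``negative``
    (probe + RNA, the quenched baseline), ``positive`` (probe + RNA +
    neomycin) and ``compound`` (probe + RNA + library compound).
    """

    plate_id: str
    position: str
    role: str
    signal: float
    compound: str | None = None

    def __post_init__(self):
        if not _WELL_RE.match(self.position):
            raise ValidationError(
                f"invalid 96-well position {self.position!r} (expected A1-H12)"
            )
        if self.role not in ROLES:
            raise ValidationError(
                f"unknown well role {self.role!r}; expected one of {ROLES}"
            )
        signal = float(self.signal)
        if not np.isfinite(signal) or signal < 0:
            raise ValidationError(
                f"signal must be finite and >= 0, got {signal!r} "
                f"(well {self.position} on {self.plate_id})"
            )
        if self.role == "compound" and not self.compound:
            raise ValidationError(
                f"compound well {self.position} on {self.plate_id} has no compound name"
            )


@dataclass
class PlateSet:
    """A collection of wells spanning one or more plates."""

    wells: list[Well] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.wells)

    def __iter__(self):
        return iter(self.wells)

    def plate_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.wells:
            seen.setdefault(w.plate_id, None)
        return list(seen)

    def plate(self, plate_id: str) -> list[Well]:
        return [w for w in self.wells if w.plate_id == plate_id]

    def by_role(self, plate_id: str, role: str) -> list[Well]:
        return [w for w in self.wells if w.plate_id == plate_id and w.role == role]


@dataclass(frozen=True)
class ZFactorResult:
    """Z'-factor statistic with the control summaries behind it."""

    z: float
    mu_p: float
    sigma_p: float
    mu_n: float
    sigma_n: float
    n_pos: int
    n_neg: int

    @property
    def verdict(self) -> str:
        if self.z > 0.5:
            return "excellent"
        if self.z >= 0.0:
            return "marginal"
        return "unacceptable"


@dataclass
class CompoundScreenRecord:
    """Per-compound screen summary on one plate."""

    compound_name: str
    percent_binding: float
    spread: float
    n_replicates: int
    plate_id: str
    hit: bool = False
    multi_plate: bool = False


def zfactor(positive_signals, negative_signals) -> ZFactorResult:
    """Z'-factor of a control plate: ``1 - 3*(sd_p + sd_n)/|mean_p - mean_n|``.

    Sample standard deviations (ddof=1) are used; each control group needs
    at least two wells.
    """

    pos = np.asarray(list(positive_signals), dtype=float)
    neg = np.asarray(list(negative_signals), dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError(
            f"need >= 2 wells per control group, got {len(pos)} positive "
            f"and {len(neg)} negative"
        )
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(neg))):
        raise ValidationError("control signals must be finite")
    mu_p, mu_n = float(np.mean(pos)), float(np.mean(neg))
    if mu_p == mu_n:
        raise DegenerateWindowError(
            "positive and negative control means are equal: no assay window"
        )
    sigma_p = float(np.std(pos, ddof=1))
    sigma_n = float(np.std(neg, ddof=1))
    z = 1.0 - 3.0 * (sigma_p + sigma_n) / abs(mu_p - mu_n)
    return ZFactorResult(z, mu_p, sigma_p, mu_n, sigma_n, len(pos), len(neg))


def percent_binding(
    compound_signal: float, neomycin_signal: float, baseline_signal: float
) -> float:
    """Displacement signal of a compound as a percentage of neomycin's.

    ``100 * (compound - baseline) / (neomycin - baseline)`` where the
    baseline is the probe+RNA (no displacer) mean on the same plate.
    Values may exceed 100% or be negative; no clipping is applied.
    """

    window = float(neomycin_signal) - float(baseline_signal)
    if window == 0.0:
        raise DegenerateWindowError(
            "neomycin signal equals the baseline: zero normalization window"
        )
    return 100.0 * (float(compound_signal) - float(baseline_signal)) / window


def summarize_screen(plates: PlateSet) -> list[CompoundScreenRecord]:
    """Summarize a multi-plate screen into per-compound records.

    For each plate the baseline and neomycin means are computed from that
    plate's own control wells. Replicate compound wells are converted to
    per-well percent binding; the record carries their mean and sample SD.
    The positive-control wells themselves are summarized under
    ``Neomycin`` (100% by construction). Compounds appearing on more than
    one plate keep one record per plate, flagged ``multi_plate``.
    """

    bad_plates = [
        pid
        for pid in plates.plate_ids()
        if not plates.by_role(pid, "negative") or not plates.by_role(pid, "positive")
    ]
    if bad_plates:
        raise PlateValidationError(
            f"plates missing negative or positive control wells: {bad_plates}"
        )

    records: list[CompoundScreenRecord] = []
    compound_plates: dict[str, list[int]] = {}
    for pid in plates.plate_ids():
        baseline = mean(w.signal for w in plates.by_role(pid, "negative"))
        neo = mean(w.signal for w in plates.by_role(pid, "positive"))
        if neo == baseline:
            raise DegenerateWindowError(
                f"plate {pid}: neomycin mean equals baseline mean"
            )

        groups: dict[str, list[float]] = {}
        pos_wells = plates.by_role(pid, "positive")
        groups[POSITIVE_CONTROL_NAME] = [w.signal for w in pos_wells]
        for w in plates.by_role(pid, "compound"):
            groups.setdefault(w.compound, []).append(w.signal)

        for name, signals in groups.items():
            percents = [percent_binding(s, neo, baseline) for s in signals]
            spread = float(np.std(percents, ddof=1)) if len(percents) > 1 else 0.0
            record = CompoundScreenRecord(
                compound_name=name,
                percent_binding=float(np.mean(percents)),
                spread=spread,
                n_replicates=len(percents),
                plate_id=pid,
            )
            compound_plates.setdefault(name, []).append(len(records))
            records.append(record)

    for name, idxs in compound_plates.items():
        if name != POSITIVE_CONTROL_NAME and len(idxs) > 1:
            for i in idxs:
                records[i].multi_plate = True
    return records


def call_hits(
    table: list[CompoundScreenRecord], threshold_percent: float = 110.0
) -> list[CompoundScreenRecord]:
    """Flag and return compounds at or above the percent-binding threshold.

    Records are flagged in place; the returned subset is sorted by
    descending percent binding. The default threshold of 110% corresponds
    to binding at least ten percent better than the parent neomycin.
    """

    if not threshold_percent > 0:
        raise ValidationError(f"threshold must be > 0, got {threshold_percent}")
    hits = []
    for record in table:
        record.hit = record.percent_binding >= threshold_percent
        if record.hit:
            hits.append(record)
    return sorted(hits, key=lambda r: r.percent_binding, reverse=True)
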