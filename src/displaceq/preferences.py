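"""Positional amino-acid preference statistics for conjugate libraries.

Converts per-compound percent-binding tables into library z-scores
("sigma deviations"), averages them over positional compound classes
(e.g. all conjugates with arginine at position 1), and compares a
compound's deviation across RNA targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .screening import POSITIVE_CONTROL_NAME, CompoundScreenRecord

__all__ = [
    "AA_CODES",
    "BETA_ALANINE",
    "CompoundName",
    "ClassSpec",
    "PreferenceScore",
    "ClassAverage",
    "parse_compound_name",
    "library_zscores",
    "class_average",
    "specificity_delta",
    "preference_table",
]

#: One-letter amino-acid codes usable at either conjugation position.
AA_CODES = frozenset("ARNDCHLKFPSTWYV")

#: Beta-alanine token, kept distinct from alanine. ``bA`` is the lossless
#: ASCII serialization.
BETA_ALANINE = "βA"
_BETA_ALANINE_ASCII = "bA"


@dataclass(frozen=True)
class CompoundName:
    """Parsed conjugate name: parent scaffold plus up to two amino acids."""

    raw: str
    pos1: str | None = None
    pos2: str | None = None

    @property
    def is_parent(self) -> bool:
        return self.pos1 is None and self.pos2 is None

    def __str__(self) -> str:
        return self.raw


def _tokenize(body: str, raw: str) -> list[str]:
    tokens: list[str] = []
    i = 0
    while i < len(body):
        if body.startswith(BETA_ALANINE, i):
            tokens.append(BETA_ALANINE)
            i += len(BETA_ALANINE)
        elif body.startswith(_BETA_ALANINE_ASCII, i):
            tokens.append(BETA_ALANINE)
            i += len(_BETA_ALANINE_ASCII)
        elif body[i] in AA_CODES:
            tokens.append(body[i])
            i += 1
        else:
            raise ParseError(
                f"unknown amino-acid token {body[i]!r} in compound name {raw!r}",
                position=raw.find(body) + i,
            )
    return tokens


def parse_compound_name(raw: str) -> CompoundName:
    """Parse a conjugate name such as ``NeoRS``, ``NeoR`` or ``NeoRβA``.

    ``Neomycin`` and bare ``Neo`` denote the unconjugated parent. Valid
    position tokens are the one-letter codes in :data:`AA_CODES` plus
    beta-alanine, written ``βA`` or ``bA``.
    """

    if not raw:
        raise ParseError("compound name must be a non-empty string")
    if raw == "Neomycin" or raw == "Neo":
        return CompoundName(raw=raw)
    if not raw.startswith("Neo"):
        raise ParseError(
            f"compound name {raw!r} must begin with 'Neo' or be 'Neomycin'"
        )
    tokens = _tokenize(raw[3:], raw)
    if len(tokens) > 2:
        raise ParseError(
            f"compound name {raw!r} has more than two amino-acid positions"
        )
    pos1 = tokens[0] if tokens else None
    pos2 = tokens[1] if len(tokens) > 1 else None
    return CompoundName(raw=raw, pos1=pos1, pos2=pos2)


@dataclass(frozen=True)
class ClassSpec:
    """Pattern over conjugation positions; ``X`` matches any amino acid.

    Supported forms: ``NeoX`` (mono-conjugates), ``NeoRX`` (fixed
    position 1, any amino acid at position 2), ``NeoXS`` (any position 1,
    fixed position 2), and exact single compounds like ``NeoRS`` or
    ``NeoR``.
    """

    raw: str
    pos1: str | None  # code, "X" wildcard, or None (absent)
    pos2: str | None

    @classmethod
    def parse(cls, spec: str) -> "ClassSpec":
        if not spec.startswith("Neo"):
            raise ParseError(f"class spec {spec!r} must begin with 'Neo'")
        body = spec[3:]
        tokens: list[str] = []
        i = 0
        while i < len(body):
            if body[i] == "X":
                tokens.append("X")
                i += 1
            elif body.startswith(BETA_ALANINE, i):
                tokens.append(BETA_ALANINE)
                i += len(BETA_ALANINE)
            elif body.startswith(_BETA_ALANINE_ASCII, i):
                tokens.append(BETA_ALANINE)
                i += len(_BETA_ALANINE_ASCII)
            elif body[i] in AA_CODES:
                tokens.append(body[i])
                i += 1
            else:
                raise ParseError(f"unknown token {body[i]!r} in class spec {spec!r}")
        if not 1 <= len(tokens) <= 2:
            raise ParseError(f"class spec {spec!r} must have one or two positions")
        pos1 = tokens[0]
        pos2 = tokens[1] if len(tokens) > 1 else None
        return cls(raw=spec, pos1=pos1, pos2=pos2)

    def matches(self, name: CompoundName) -> bool:
        if name.is_parent:
            return False

        def _match(pattern: str | None, token: str | None) -> bool:
            if pattern is None:
                return token is None
            if pattern == "X":
                return token is not None
            return token == pattern

        return _match(self.pos1, name.pos1) and _match(self.pos2, name.pos2)


@dataclass(frozen=True)
class PreferenceScore:
    """A compound's percent binding expressed in library standard deviations."""

    compound: CompoundName
    mirna_id: str
    percent_binding: float
    sigma_dev: float


@dataclass(frozen=True)
class ClassAverage:
    """Mean sigma deviation of a positional compound class for one target."""

    class_spec: str
    mirna_id: str
    mean_sigma: float
    n_members: int


def library_zscores(
    table: Sequence[CompoundScreenRecord], mirna_id: str = ""
) -> list[PreferenceScore]:
    """Standardize per-compound percent binding over one target's library.

    The parent neomycin is the normalization anchor (fixed at 100%) and is
    excluded from the library mean and SD and from the returned scores.
    Uses the sample standard deviation. A zero-SD library yields all-zero
    deviations with a warning.
    """

    names = []
    percents = []
    for record in table:
        name = parse_compound_name(record.compound_name)
        if name.is_parent or record.compound_name == POSITIVE_CONTROL_NAME:
            continue
        names.append(name)
        percents.append(record.percent_binding)
    if len(names) < 3:
        raise ValidationError(
            f"need at least 3 library compounds for z-scores, got {len(names)}"
        )
    values = np.asarray(percents, dtype=float)
    mu = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        warnings.warn(
            "degenerate library: all compounds have identical percent binding; "
            "sigma deviations set to 0",
            stacklevel=2,
        )
        sigmas = np.zeros_like(values)
    else:
        sigmas = (values - mu) / sd
    return [
        PreferenceScore(
            compound=name,
            mirna_id=mirna_id,
            percent_binding=float(b),
            sigma_dev=float(s),
        )
        for name, b, s in zip(names, values, sigmas)
    ]


def class_average(
    scores: Sequence[PreferenceScore],
    class_spec: str | ClassSpec | Iterable[str],
) -> ClassAverage:
    """Average sigma deviation over the members of a positional class.

    ``class_spec`` may be a pattern string (``NeoRX``, ``NeoXS``,
    ``NeoX``, exact compound), a parsed :class:`ClassSpec`, or an explicit
    iterable of compound names. Members are weighted equally.
    """

    if isinstance(class_spec, ClassSpec):
        spec = class_spec
        members = [s for s in scores if spec.matches(s.compound)]
        label = spec.raw
    elif isinstance(class_spec, str):
        spec = ClassSpec.parse(class_spec)
        members = [s for s in scores if spec.matches(s.compound)]
        label = class_spec
    else:
        wanted = set(class_spec)
        members = [s for s in scores if s.compound.raw in wanted]
        label = "{" + ",".join(sorted(wanted)) + "}"
    if not members:
        raise ValidationError(f"class {label} has no members in the score set")
    mirna_ids = {s.mirna_id for s in members}
    return ClassAverage(
        class_spec=label,
        mirna_id=mirna_ids.pop() if len(mirna_ids) == 1 else "mixed",
        mean_sigma=float(np.mean([s.sigma_dev for s in members])),
        n_members=len(members),
    )


def specificity_delta(
    scores_by_mirna: Mapping[str, Sequence[PreferenceScore]], compound: str
) -> pd.DataFrame:
    """Pairwise sigma-deviation differences of one compound across targets.

    Returns an antisymmetric matrix ``D`` with ``D[a, b] = sigma_a -
    sigma_b``; a positive entry means the compound deviates further above
    the library mean for target ``a`` than for target ``b``.
    """

    if len(scores_by_mirna) < 2:
        raise ValidationError("need score sets for at least 2 targets")
    sigma: dict[str, float] = {}
    for mirna_id, scores in scores_by_mirna.items():
        found = [s for s in scores if s.compound.raw == compound]
        if not found:
            raise ValidationError(
                f"compound {compound!r} missing from score set {mirna_id!r} "
                f"(searched: {list(scores_by_mirna)})"
            )
        sigma[mirna_id] = found[0].sigma_dev
    ids = list(sigma)
    data = [[sigma[a] - sigma[b] for b in ids] for a in ids]
    return pd.DataFrame(data, index=ids, columns=ids)


def preference_table(
    scores_by_mirna: Mapping[str, Sequence[PreferenceScore]],
    class_specs: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Class-average matrix: rows are class specs, columns are targets.

    When ``class_specs`` is omitted, every positional class present in the
    data is reported: the mono-conjugate class ``NeoX``, one ``Neo<c>X``
    row per observed position-1 code, and one ``NeoX<c>`` row per observed
    position-2 code.
    """

    if class_specs is None:
        pos1_codes: dict[str, None] = {}
        pos2_codes: dict[str, None] = {}
        for scores in scores_by_mirna.values():
            for s in scores:
                if s.compound.pos1 is not None and s.compound.pos2 is not None:
                    pos1_codes.setdefault(s.compound.pos1, None)
                    pos2_codes.setdefault(s.compound.pos2, None)
        class_specs = (
            ["NeoX"]
            + [f"Neo{c}X" for c in pos1_codes]
            + [f"NeoX{c}" for c in pos2_codes]
        )
    table: dict[str, dict[str, float]] = {}
    for mirna_id, scores in scores_by_mirna.items():
        column = {}
        for spec in class_specs:
            try:
                column[spec] = class_average(scores, spec).mean_sigma
            except ValidationError:
                column[spec] = float("nan")
        table[mirna_id] = column
    return pd.DataFrame(table).reindex(list(class_specs))
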