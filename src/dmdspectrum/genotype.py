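"""Variant calls and patient records; cohort table parsing.

A patient's genotype is one of three alternatives: an exon-level
rearrangement (deletion or duplication of a contiguous exon run, the MLPA
observable), a small sequence variant (carried as free text plus the two
structured fields the frame rule needs), or nothing detected. Patients
whose single-exon MLPA call was re-examined by PCR/sequencing carry the
outcome in ``validated_call``; :func:`effective_call` prefers it.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Union

import pandas as pd

from .errors import CohortLoadError, IntervalError, NotationParseError

__all__ = [
    "MutationKind",
    "RearrangementCall",
    "SmallVariant",
    "NoneDetected",
    "NONE_DETECTED",
    "VariantCall",
    "Phenotype",
    "IhcResult",
    "PatientRecord",
    "parse_mutation_notation",
    "format_mutation_notation",
    "effective_call",
    "load_cohort_table",
]

MAX_EXON = 79  # Dp427m exon count; notation parsing is bounded by it


class MutationKind(enum.Enum):
    DELETION = "deletion"
    DUPLICATION = "duplication"


@dataclass(frozen=True)
class RearrangementCall:
    """Deletion or duplication of exons ``first_exon..last_exon`` (inclusive)."""

    kind: MutationKind
    first_exon: int
    last_exon: int

    def __post_init__(self) -> None:
        if not 1 <= self.first_exon <= self.last_exon <= MAX_EXON:
            raise IntervalError(
                f"exon interval {self.first_exon}..{self.last_exon} outside 1..{MAX_EXON}"
            )

    @property
    def n_exons(self) -> int:
        return self.last_exon - self.first_exon + 1

    def contains(self, exon: int) -> bool:
        return self.first_exon <= exon <= self.last_exon

    def overlaps(self, interval: tuple[int, int]) -> bool:
        lo, hi = interval
        return self.first_exon <= hi and lo <= self.last_exon


@dataclass(frozen=True)
class SmallVariant:
    """Sub-exonic sequence variant.

    ``description`` is opaque text (e.g. cDNA notation). The frame rule
    only needs the signed net coding-length change and whether a premature
    stop codon is introduced.
    """

    description: str
    net_coding_change_nt: int
    introduces_premature_stop: bool
    affected_exon: int

    def __post_init__(self) -> None:
        if self.net_coding_change_nt == 0 and not self.introduces_premature_stop:
            raise NotationParseError(
                f"small variant {self.description!r}: a frame-neutral no-op "
                "(net 0 nt, no stop) is not a variant"
            )
        if not 1 <= self.affected_exon <= MAX_EXON:
            raise IntervalError(
                f"small variant exon {self.affected_exon} outside 1..{MAX_EXON}"
            )


class NoneDetected:
    """Singleton marker for 'no deletion / no duplication detected'."""

    _instance = None

    def __new__(cls) -> "NoneDetected":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NONE_DETECTED"


NONE_DETECTED = NoneDetected()

VariantCall = Union[RearrangementCall, SmallVariant, NoneDetected]


class Phenotype(enum.Enum):
    DMD = "DMD"
    BMD = "BMD"


class IhcResult(enum.Enum):
    NEGATIVE = "negative"
    FAINT = "faint"
    NOT_DONE = "not_done"


@dataclass(frozen=True)
class PatientRecord:
    """One cohort row: genotype plus the clinical fields the summaries use."""

    patient_id: str
    ck_iu_per_l: float | None
    onset_age_years: float | None
    wheelchair_age_years: float | None  # None while still ambulant
    current_age_years: float
    clinical_phenotype: Phenotype
    ihc_result: IhcResult
    mlpa_call: VariantCall
    validated_call: VariantCall | None = None

    @property
    def wheelchair_bound(self) -> bool:
        return self.wheelchair_age_years is not None


# "del 46-48", "dup 2-62", "del 51", en/em dashes and stray spaces tolerated
_REARR_RE = re.compile(
    r"^(?P<kind>del|dup)\s*(?P<first>\d+)\s*(?:[-–—]\s*(?P<last>\d+))?$",
    re.IGNORECASE,
)
_NONE_RE = re.compile(r"^no\s*del\s*/?\s*no\s*dup$", re.IGNORECASE)


def parse_mutation_notation(text: str) -> VariantCall:
    """Parse clinical shorthand into a :class:`VariantCall`.

    Accepted forms: ``del A-B``, ``del A``, ``dup A-B``, ``dup A``,
    ``no del/no dup``; case-insensitive, hyphen or en/em dash, whitespace
    tolerant. Single-exon forms yield ``first_exon == last_exon``.
    """
    if not isinstance(text, str):
        raise NotationParseError(f"expected a notation string, got {type(text).__name__}")
    stripped = text.strip()
    if _NONE_RE.match(stripped):
        return NONE_DETECTED
    m = _REARR_RE.match(stripped)
    if m is None:
        raise NotationParseError(f"cannot parse mutation notation {text!r}")
    kind = MutationKind.DELETION if m.group("kind").lower() == "del" else MutationKind.DUPLICATION
    first = int(m.group("first"))
    last = int(m.group("last") or first)
    if not 1 <= first <= MAX_EXON or not 1 <= last <= MAX_EXON:
        raise IntervalError(
            f"notation {text!r}: exon numbers must lie in 1..{MAX_EXON}"
        )
    if first > last:
        raise IntervalError(f"notation {text!r}: first exon exceeds last exon")
    return RearrangementCall(kind, first, last)


def format_mutation_notation(call: VariantCall) -> str:
    """Inverse of :func:`parse_mutation_notation` (hyphen output)."""
    if isinstance(call, NoneDetected):
        return "no del/no dup"
    if isinstance(call, RearrangementCall):
        word = "del" if call.kind is MutationKind.DELETION else "dup"
        if call.first_exon == call.last_exon:
            return f"{word} {call.first_exon}"
        return f"{word} {call.first_exon}-{call.last_exon}"
    if isinstance(call, SmallVariant):
        stop = 1 if call.introduces_premature_stop else 0
        return (
            f"small|{call.description}|net={call.net_coding_change_nt}"
            f"|stop={stop}|exon={call.affected_exon}"
        )
    raise NotationParseError(f"unknown call type {type(call).__name__}")


_SMALL_FIELD_RE = re.compile(r"^(net|stop|exon)=(-?\d+)$")


def _parse_small_variant(text: str) -> SmallVariant:
    parts = [p.strip() for p in text.split("|")]
    if parts[0].lower() != "small" or len(parts) < 2:
        raise NotationParseError(f"cannot parse small-variant field {text!r}")
    description = parts[1]
    fields: dict[str, int] = {}
    for token in parts[2:]:
        m = _SMALL_FIELD_RE.match(token)
        if m is None:
            raise NotationParseError(
                f"small-variant token {token!r} in {text!r} is malformed"
            )
        fields[m.group(1)] = int(m.group(2))
    missing = {"net", "stop", "exon"} - fields.keys()
    if missing:
        raise NotationParseError(f"small-variant {text!r} missing {sorted(missing)}")
    return SmallVariant(
        description=description,
        net_coding_change_nt=fields["net"],
        introduces_premature_stop=bool(fields["stop"]),
        affected_exon=fields["exon"],
    )


def _parse_call_field(text: str) -> VariantCall:
    if text.lower().startswith("small"):
        return _parse_small_variant(text)
    return parse_mutation_notation(text)


def effective_call(patient: PatientRecord) -> VariantCall:
    """The validated call when present, else the initial MLPA call."""
    return patient.validated_call if patient.validated_call is not None else patient.mlpa_call


_MISSING = {"", "na", "n/a", "no data", "nan"}
_AMBULANT = {"ambulant", "still ambulant", "not yet"}

COHORT_COLUMNS = [
    "patient_id",
    "ck",
    "onset_age",
    "wheelchair_age",
    "current_age",
    "phenotype",
    "ihc",
    "mlpa_call",
    "validated_call",
]


def _optional_number(raw: str, row: int, column: str, errors: list[str]) -> float | None:
    text = raw.strip().lower()
    if text in _MISSING:
        return None
    try:
        value = float(text)
    except ValueError:
        errors.append(f"row {row}: column {column!r} value {raw!r} is not numeric")
        return None
    if math.isnan(value):
        return None
    return value


def load_cohort_table(source: str | Path = "default") -> list[PatientRecord]:
    """Load patient records from a cohort TSV (see ``docs/format.md``).

    ``"default"`` loads the packaged 43-patient table. Missing values are
    ``NA``; still-ambulant patients carry ``ambulant`` (or ``not yet``) in
    the wheelchair-age column. All row-level problems are collected and
    reported together in a single :class:`CohortLoadError`.
    """
    if isinstance(source, str) and source == "default":
        path = Path(str(resources.files("dmdspectrum").joinpath("data/cohort_table1.tsv")))
    else:
        path = Path(source)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(table.columns) != COHORT_COLUMNS:
        raise CohortLoadError(
            f"cohort table {path} must have columns {COHORT_COLUMNS}, "
            f"got {list(table.columns)}"
        )
    errors: list[str] = []
    records: list[PatientRecord] = []
    seen: set[str] = set()
    for idx, row in table.iterrows():
        rownum = int(idx) + 2  # 1-based, plus header line
        patient_id = row["patient_id"].strip()
        if not patient_id:
            errors.append(f"row {rownum}: empty patient_id")
            continue
        if patient_id in seen:
            errors.append(f"row {rownum}: duplicate patient_id {patient_id!r}")
            continue
        seen.add(patient_id)

        ck = _optional_number(row["ck"], rownum, "ck", errors)
        if ck is not None and ck < 0:
            errors.append(f"row {rownum}: negative CK {ck}")
            continue
        onset = _optional_number(row["onset_age"], rownum, "onset_age", errors)
        wc_raw = row["wheelchair_age"].strip().lower()
        if wc_raw in _AMBULANT:
            wheelchair = None
        else:
            wheelchair = _optional_number(row["wheelchair_age"], rownum, "wheelchair_age", errors)
        current = _optional_number(row["current_age"], rownum, "current_age", errors)
        if current is None:
            errors.append(f"row {rownum}: current_age is required")
            continue

        try:
            phenotype = Phenotype(row["phenotype"].strip().upper())
        except ValueError:
            errors.append(f"row {rownum}: unknown phenotype {row['phenotype']!r}")
            continue
        ihc_raw = row["ihc"].strip().lower()
        if ihc_raw in _MISSING:
            ihc = IhcResult.NOT_DONE
        else:
            try:
                ihc = IhcResult(ihc_raw)
            except ValueError:
                errors.append(f"row {rownum}: unknown IHC value {row['ihc']!r}")
                continue

        try:
            mlpa = _parse_call_field(row["mlpa_call"].strip())
        except (NotationParseError, IntervalError) as exc:
            errors.append(f"row {rownum}: {exc}")
            continue
        validated_raw = row["validated_call"].strip()
        validated = None
        if validated_raw.lower() not in _MISSING:
            try:
                validated = _parse_call_field(validated_raw)
            except (NotationParseError, IntervalError) as exc:
                errors.append(f"row {rownum}: {exc}")
                continue

        records.append(
            PatientRecord(
                patient_id=patient_id,
                ck_iu_per_l=ck,
                onset_age_years=onset,
                wheelchair_age_years=wheelchair,
                current_age_years=current,
                clinical_phenotype=phenotype,
                ihc_result=ihc,
                mlpa_call=mlpa,
                validated_call=validated,
            )
        )
    if errors:
        raise CohortLoadError(
            f"cohort table {path} failed validation:\n  " + "\n  ".join(errors)
        )
    if isinstance(source, str) and source == "default":
        _check_default_fixture(records)
    return records


def _check_default_fixture(records: list[PatientRecord]) -> None:
    """Load-time guard on the packaged table's headline composition."""
    kinds = {"deletion": 0, "duplication": 0, "none": 0}
    for rec in records:
        call = rec.mlpa_call
        if isinstance(call, RearrangementCall):
            kinds[call.kind.value] += 1
        else:
            kinds["none"] += 1
    expected = {"deletion": 30, "duplication": 5, "none": 8}
    if len(records) != 43 or kinds != expected:
        raise CohortLoadError(
            f"packaged cohort fixture corrupt: n={len(records)}, composition {kinds}, "
            f"expected n=43 with {expected}"
        )
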