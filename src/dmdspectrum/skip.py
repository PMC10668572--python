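"""Single-exon skip advisor and read-through eligibility.

Antisense-oligonucleotide exon skipping removes one additional exon from
the mature transcript of an out-of-frame deletion; if the deleted span
plus the skipped flanking exon totals a codon multiple, the frame is
restored and a Becker-like internally deleted dystrophin can be made.
Only the two exons flanking the deletion are candidates (single-exon
skipping); when both flanks restore the frame the 5' flank is reported as
the primary therapeutic target. Nonsense small variants are instead
candidates for stop-codon read-through compounds (e.g. ataluren).

Static drug context: exon 51 -> eteplirsen, exon 53 -> golodirsen
(approved antisense drugs); all other targets are investigational.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import UsageError
from .frame import FrameClass, classify_rearrangement_frame, classify_small_variant_frame
from .genotype import (
    MutationKind,
    PatientRecord,
    RearrangementCall,
    SmallVariant,
    effective_call,
    format_mutation_notation,
)
from .reference import GeneModel

__all__ = [
    "SkipRecommendation",
    "candidate_single_exon_skips",
    "primary_skip_target",
    "readthrough_eligible",
    "multi_exon_skips",
    "AmenabilitySummary",
    "cohort_amenability",
    "APPROVED_SKIP_DRUGS",
]

APPROVED_SKIP_DRUGS: dict[int, str] = {51: "eteplirsen", 53: "golodirsen"}


@dataclass(frozen=True)
class SkipRecommendation:
    """Which flanking-exon skips restore the frame for one deletion."""

    variant: RearrangementCall
    restoring_skips: frozenset[int]
    primary_target: int | None
    amenable: bool

    def __post_init__(self) -> None:
        assert self.amenable == bool(self.restoring_skips)
        assert self.primary_target is None or self.primary_target in self.restoring_skips


def candidate_single_exon_skips(
    deletion: RearrangementCall, model: GeneModel
) -> SkipRecommendation:
    """Evaluate both flanks of an out-of-frame deletion.

    Flank exon ``e`` (in ``2..N-1``; the terminal exons hold the start and
    stop codons and cannot be skipped) restores the frame iff
    ``span(first, last) + length(e)`` is divisible by 3. Calling this on
    an in-frame deletion is a usage error: there is no frame to restore.
    """
    if deletion.kind is not MutationKind.DELETION:
        raise UsageError("skip candidates are defined for deletions only")
    frame = classify_rearrangement_frame(deletion, model)
    if frame is not FrameClass.OUT_OF_FRAME:
        raise UsageError(
            f"deletion {format_mutation_notation(deletion)} is {frame.value}; "
            "exon skipping applies to out-of-frame deletions"
        )
    span = model.coding_span_length(deletion.first_exon, deletion.last_exon)
    restoring = set()
    for flank in (deletion.first_exon - 1, deletion.last_exon + 1):
        if not 2 <= flank <= model.n_exons - 1:
            continue
        if (span + model.exon(flank).coding_length_nt) % 3 == 0:
            restoring.add(flank)
    rec = SkipRecommendation(
        variant=deletion,
        restoring_skips=frozenset(restoring),
        primary_target=None,
        amenable=bool(restoring),
    )
    return SkipRecommendation(
        variant=deletion,
        restoring_skips=rec.restoring_skips,
        primary_target=primary_skip_target(rec),
        amenable=rec.amenable,
    )


def primary_skip_target(rec: SkipRecommendation) -> int | None:
    """Pick one target: the 5' flank when both flanks restore the frame."""
    if not rec.restoring_skips:
        return None
    five_prime = rec.variant.first_exon - 1
    if five_prime in rec.restoring_skips:
        return five_prime
    return min(rec.restoring_skips)


def readthrough_eligible(variant: SmallVariant) -> bool:
    """Stop-codon read-through applies exactly to nonsense variants."""
    return variant.introduces_premature_stop


def multi_exon_skips(deletion: RearrangementCall, model: GeneModel):
    """Multi-exon skipping is out of scope; reserved extension point."""
    raise NotImplementedError(
        "multi-exon skipping is not implemented; only single flanking-exon "
        "skips are evaluated"
    )


@dataclass(frozen=True)
class AmenabilitySummary:
    """Cohort-level therapy amenability, grouped by primary skip target."""

    by_target: dict[int, tuple[str, ...]]  # target exon -> patient ids
    n_total: int  # whole-cohort denominator for percentages
    n_amenable: int
    amenable_ids: tuple[str, ...]
    n_readthrough: int
    readthrough_ids: tuple[str, ...]
    recommendations: dict[str, SkipRecommendation]

    @property
    def percent_amenable(self) -> float:
        return 100.0 * self.n_amenable / self.n_total if self.n_total else float("nan")

    def target_counts(self) -> dict[int, int]:
        return {exon: len(ids) for exon, ids in self.by_target.items()}

    def to_frame(self) -> pd.DataFrame:
        """Amenability grouping as a table (one row per target exon)."""
        rows = []
        for exon, ids in sorted(
            self.by_target.items(), key=lambda kv: (-len(kv[1]), kv[0])
        ):
            rows.append(
                {
                    "target_exon": exon,
                    "drug": APPROVED_SKIP_DRUGS.get(exon, ""),
                    "mutations": ", ".join(
                        format_mutation_notation(self.recommendations[pid].variant)
                        for pid in ids
                    ),
                    "n_cases": len(ids),
                    "percent_of_cohort": round(100.0 * len(ids) / self.n_total, 2),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["target_exon", "drug", "mutations", "n_cases", "percent_of_cohort"],
        )


def cohort_amenability(cohort: list[PatientRecord], model: GeneModel) -> AmenabilitySummary:
    """Group patients by primary skip target; count read-through cases.

    Operates on the validated view: only out-of-frame exon deletions are
    evaluated for skipping, and nonsense small variants count as
    read-through eligible. Percentages use the whole cohort as the
    denominator.
    """
    by_target: dict[int, list[str]] = {}
    recommendations: dict[str, SkipRecommendation] = {}
    amenable: list[str] = []
    readthrough: list[str] = []
    for patient in cohort:
        call = effective_call(patient)
        if isinstance(call, SmallVariant):
            if readthrough_eligible(call):
                readthrough.append(patient.patient_id)
            continue
        if not isinstance(call, RearrangementCall) or call.kind is not MutationKind.DELETION:
            continue
        if classify_rearrangement_frame(call, model) is not FrameClass.OUT_OF_FRAME:
            continue
        rec = candidate_single_exon_skips(call, model)
        recommendations[patient.patient_id] = rec
        if rec.amenable:
            amenable.append(patient.patient_id)
            assert rec.primary_target is not None
            by_target.setdefault(rec.primary_target, []).append(patient.patient_id)
    return AmenabilitySummary(
        by_target={exon: tuple(ids) for exon, ids in by_target.items()},
        n_total=len(cohort),
        n_amenable=len(amenable),
        amenable_ids=tuple(amenable),
        n_readthrough=len(readthrough),
        readthrough_ids=tuple(readthrough),
        recommendations=recommendations,
    )
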