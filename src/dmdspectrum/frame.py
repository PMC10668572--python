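"""Reading-frame rule and genotype-phenotype concordance.

The rule: an exon deletion (or tandem duplication) whose summed coding
length is divisible by 3 leaves the downstream frame intact and predicts
the milder Becker phenotype (BMD); a frame-disrupting lesion, or any
variant introducing a premature stop, predicts Duchenne (DMD). The
classification here is pure length arithmetic — possible stop codons
formed at novel junctions are deliberately not modelled, matching how the
standard exonic deletion/duplication frame checkers operate.

Rearrangements touching the first or last exon are NOT_ASSESSABLE: they
remove or displace the start/stop codon and UTRs, so the mod-3 rule does
not apply.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .errors import IntervalError
from .genotype import (
    NoneDetected,
    PatientRecord,
    RearrangementCall,
    SmallVariant,
    VariantCall,
    effective_call,
)
from .reference import GeneModel, coding_span_length

__all__ = [
    "FrameClass",
    "PhenotypePrediction",
    "classify_rearrangement_frame",
    "classify_small_variant_frame",
    "classify_call",
    "predict_phenotype",
    "ConcordanceSummary",
    "concordance_summary",
]


class FrameClass(enum.Enum):
    IN_FRAME = "in-frame"
    OUT_OF_FRAME = "out-of-frame"
    NOT_ASSESSABLE = "not-assessable"


class PhenotypePrediction(enum.Enum):
    DMD = "DMD"
    BMD = "BMD"
    UNKNOWN = "UNKNOWN"


def classify_rearrangement_frame(call: RearrangementCall, model: GeneModel) -> FrameClass:
    """Frame class of an exon deletion or (assumed tandem) duplication.

    Both kinds reduce to the same test — is the coding length of the
    affected span a multiple of 3? A tandem, fully intragenic duplication
    inserts exactly one extra copy of the span into the mature transcript,
    so the inserted length equals the deleted length of the corresponding
    deletion.
    """
    if not model.contains_interval(call.first_exon, call.last_exon):
        raise IntervalError(
            f"call {call.first_exon}..{call.last_exon} outside the "
            f"{model.n_exons}-exon model"
        )
    if call.first_exon == 1 or call.last_exon == model.n_exons:
        return FrameClass.NOT_ASSESSABLE
    span = coding_span_length(model, call.first_exon, call.last_exon)
    return FrameClass.IN_FRAME if span % 3 == 0 else FrameClass.OUT_OF_FRAME


def classify_small_variant_frame(variant: SmallVariant) -> FrameClass:
    """A small variant is in-frame iff codon-multiple and stop-free."""
    if variant.introduces_premature_stop:
        return FrameClass.OUT_OF_FRAME
    return (
        FrameClass.IN_FRAME
        if variant.net_coding_change_nt % 3 == 0
        else FrameClass.OUT_OF_FRAME
    )


def classify_call(call: VariantCall, model: GeneModel) -> FrameClass:
    """Dispatch over the three call alternatives."""
    if isinstance(call, RearrangementCall):
        return classify_rearrangement_frame(call, model)
    if isinstance(call, SmallVariant):
        return classify_small_variant_frame(call)
    if isinstance(call, NoneDetected):
        return FrameClass.NOT_ASSESSABLE
    raise IntervalError(f"unknown call type {type(call).__name__}")


def predict_phenotype(frame: FrameClass) -> PhenotypePrediction:
    """OUT_OF_FRAME -> DMD, IN_FRAME -> BMD, NOT_ASSESSABLE -> UNKNOWN."""
    if frame is FrameClass.OUT_OF_FRAME:
        return PhenotypePrediction.DMD
    if frame is FrameClass.IN_FRAME:
        return PhenotypePrediction.BMD
    return PhenotypePrediction.UNKNOWN


@dataclass(frozen=True)
class ConcordanceSummary:
    """Frame-rule prediction vs clinical phenotype over a cohort."""

    table: pd.DataFrame  # per-patient: id, call, frame, predicted, clinical, concordant
    n_assessed: int
    n_concordant: int
    n_discordant: int
    discordant_ids: tuple[str, ...]

    @property
    def percent_concordant(self) -> float:
        return 100.0 * self.n_concordant / self.n_assessed if self.n_assessed else float("nan")


def concordance_summary(cohort: list[PatientRecord], model: GeneModel) -> ConcordanceSummary:
    """Per-patient frame predictions and their agreement with the clinic.

    Uses the validated view (:func:`effective_call`); patients with no
    detected variant are excluded from the denominator.
    """
    from .genotype import format_mutation_notation  # local import avoids cycle at module load

    rows = []
    for patient in cohort:
        call = effective_call(patient)
        if isinstance(call, NoneDetected):
            continue
        frame = classify_call(call, model)
        predicted = predict_phenotype(frame)
        clinical = patient.clinical_phenotype.value
        concordant = predicted.value == clinical
        rows.append(
            {
                "patient_id": patient.patient_id,
                "variant": format_mutation_notation(call),
                "frame_class": frame.value,
                "predicted_phenotype": predicted.value,
                "clinical_phenotype": clinical,
                "concordant": concordant,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "variant",
            "frame_class",
            "predicted_phenotype",
            "clinical_phenotype",
            "concordant",
        ],
    )
    discordant = tuple(table.loc[~table["concordant"], "patient_id"])
    return ConcordanceSummary(
        table=table,
        n_assessed=len(table),
        n_concordant=int(table["concordant"].sum()),
        n_discordant=len(discordant),
        discordant_ids=discordant,
    )
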