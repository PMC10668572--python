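"""Coding-exon model of the dystrophin Dp427m transcript.

The reading-frame rule for *DMD* exon rearrangements is pure modular
arithmetic over coding-exon lengths: a deletion or duplication of exons
``a..b`` preserves the translational frame iff the summed coding length of
the span is divisible by 3. This module supplies the substrate for that
arithmetic: an immutable :class:`GeneModel` holding the 79 coding-exon
lengths of Dp427m (NM_004006) with per-exon phases, plus loaders and a
synthetic-model factory for property tests.

Conventions
-----------
Exon numbers are 1-based and intervals are inclusive on both ends, matching
clinical notation such as "del 46-48". Lengths are coding nucleotides only:
UTR portions of the terminal exons are excluded, so the total length of the
default model is the 11,058 nt CDS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import GeneModelError, IntervalError

__all__ = [
    "ExonRecord",
    "GeneModel",
    "load_gene_model",
    "load_gene_model_from_bed",
    "make_synthetic_model",
    "DEFAULT_PROXIMAL_HOTSPOT",
    "DEFAULT_DISTAL_HOTSPOT",
]

#: Deletion/duplication hotspot intervals (inclusive exon ranges) commonly
#: used for the dystrophin gene; configurable on :class:`GeneModel`.
DEFAULT_PROXIMAL_HOTSPOT: tuple[int, int] = (2, 20)
DEFAULT_DISTAL_HOTSPOT: tuple[int, int] = (45, 55)


@dataclass(frozen=True)
class ExonRecord:
    """One coding exon.

    Parameters
    ----------
    exon_number:
        1-based position of the exon in the transcript.
    coding_length_nt:
        Number of coding (CDS) nucleotides contained in the exon.
    phase_start:
        Cumulative coding length of all preceding exons, mod 3. An exon
        with ``phase_start == 0`` begins on a codon boundary.
    phase_end:
        ``(phase_start + coding_length_nt) mod 3``.
    """

    exon_number: int
    coding_length_nt: int
    phase_start: int
    phase_end: int

    def __post_init__(self) -> None:
        if self.exon_number < 1:
            raise GeneModelError(f"exon_number must be >= 1, got {self.exon_number}")
        if self.coding_length_nt <= 0:
            raise GeneModelError(
                f"exon {self.exon_number}: coding_length_nt must be positive, "
                f"got {self.coding_length_nt}"
            )
        expected = (self.phase_start + self.coding_length_nt) % 3
        if self.phase_end != expected:
            raise GeneModelError(
                f"exon {self.exon_number}: phase_end {self.phase_end} != "
                f"(phase_start + length) mod 3 = {expected}"
            )


@dataclass(frozen=True)
class GeneModel:
    """Ordered, validated set of coding exons with hotspot annotations."""

    transcript_label: str
    exons: tuple[ExonRecord, ...]
    hotspot_proximal: tuple[int, int] = DEFAULT_PROXIMAL_HOTSPOT
    hotspot_distal: tuple[int, int] = DEFAULT_DISTAL_HOTSPOT
    _lengths: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.exons) < 2:
            raise GeneModelError("a gene model needs at least 2 exons")
        numbers = [e.exon_number for e in self.exons]
        if numbers != list(range(1, len(self.exons) + 1)):
            missing = sorted(set(range(1, max(numbers) + 1)) - set(numbers))
            raise GeneModelError(
                f"exon numbers must be contiguous 1..N; missing/misordered: {missing or numbers}"
            )
        if self.exons[0].phase_start != 0:
            raise GeneModelError("exon 1 must start in phase 0")
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.phase_start != prev.phase_end:
                raise GeneModelError(
                    f"phase chain broken between exons {prev.exon_number} and "
                    f"{cur.exon_number}"
                )
        if self.total_coding_length % 3 != 0:
            raise GeneModelError(
                f"total coding length {self.total_coding_length} is not divisible "
                "by 3: incomplete CDS"
            )
        for name in ("hotspot_proximal", "hotspot_distal"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise GeneModelError(f"{name} interval ({lo}, {hi}) is malformed")
        lengths = np.array([e.coding_length_nt for e in self.exons], dtype=np.int64)
        object.__setattr__(self, "_lengths", lengths)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def total_coding_length(self) -> int:
        return int(sum(e.coding_length_nt for e in self.exons))

    def exon(self, number: int) -> ExonRecord:
        if not 1 <= number <= self.n_exons:
            raise IntervalError(f"exon {number} outside 1..{self.n_exons}")
        return self.exons[number - 1]

    def coding_span_length(self, first: int, last: int) -> int:
        """Summed coding length of exons ``first..last`` (inclusive)."""
        return coding_span_length(self, first, last)

    def contains_interval(self, first: int, last: int) -> bool:
        return 1 <= first <= last <= self.n_exons


def _build_model(
    lengths: Sequence[int],
    transcript_label: str,
    hotspot_proximal: tuple[int, int] = DEFAULT_PROXIMAL_HOTSPOT,
    hotspot_distal: tuple[int, int] = DEFAULT_DISTAL_HOTSPOT,
) -> GeneModel:
    exons = []
    phase = 0
    for i, length in enumerate(lengths, start=1):
        length = int(length)
        if length <= 0:
            raise GeneModelError(f"exon {i}: non-positive coding length {length}")
        end = (phase + length) % 3
        exons.append(ExonRecord(i, length, phase, end))
        phase = end
    return GeneModel(
        transcript_label=transcript_label,
        exons=tuple(exons),
        hotspot_proximal=hotspot_proximal,
        hotspot_distal=hotspot_distal,
    )


def _default_table_path() -> Path:
    return Path(str(resources.files("dmdspectrum").joinpath("data/dp427m_exons.tsv")))


def load_gene_model(source: str | Path = "default") -> GeneModel:
    """Load a gene model from a two-column exon table.

    Parameters
    ----------
    source:
        ``"default"`` for the packaged Dp427m table, or a path to a
        tab-separated file with header ``exon<TAB>coding_length_nt``.

    Raises
    ------
    GeneModelError
        Missing exon numbers, non-positive lengths, or a total coding
        length not divisible by 3.
    """
    label = "Dp427m"
    if isinstance(source, str) and source == "default":
        path = _default_table_path()
    else:
        path = Path(source)
        label = path.stem
    try:
        table = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - surface as a data error
        raise GeneModelError(f"cannot read exon table {path}: {exc}") from exc
    required = {"exon", "coding_length_nt"}
    if not required.issubset(table.columns):
        raise GeneModelError(
            f"exon table {path} must have columns {sorted(required)}, "
            f"got {list(table.columns)}"
        )
    table = table.sort_values("exon")
    numbers = table["exon"].to_list()
    if numbers != list(range(1, len(numbers) + 1)):
        raise GeneModelError(f"exon table {path}: exon numbers are not contiguous 1..N")
    return _build_model(table["coding_length_nt"].to_list(), label)


def load_gene_model_from_bed(path: str | Path, transcript_label: str | None = None) -> GeneModel:
    """Load a gene model from a BED-like table of coding-exon intervals.

    Accepts a headerless tab-separated file whose first four columns are
    ``chrom, start, end, exon_number`` with 0-based half-open coordinates
    (the usual BED convention). Coding lengths are ``end - start``; exon
    numbers must cover 1..N. The packaged TSV remains the canonical format;
    this loader exists so genome-browser exports can be used directly.
    """
    path = Path(path)
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    if bed.shape[1] < 4:
        raise GeneModelError(f"BED file {path} needs >= 4 columns (chrom,start,end,exon)")
    bed = bed.iloc[:, :4]
    bed.columns = ["chrom", "start", "end", "exon"]
    if (bed["end"] <= bed["start"]).any():
        bad = bed.index[bed["end"] <= bed["start"]].tolist()
        raise GeneModelError(f"BED file {path}: empty/negative intervals at rows {bad}")
    bed = bed.sort_values("exon")
    if bed["exon"].to_list() != list(range(1, len(bed) + 1)):
        raise GeneModelError(f"BED file {path}: exon numbers are not contiguous 1..N")
    lengths = (bed["end"] - bed["start"]).to_list()
    return _build_model(lengths, transcript_label or path.stem)


def coding_span_length(model: GeneModel, first: int, last: int) -> int:
    """Summed coding length (nt) of exons ``first..last`` inclusive.

    Additive by construction: ``span(a, c) == span(a, b) + span(b+1, c)``.
    """
    if not model.contains_interval(first, last):
        raise IntervalError(
            f"interval {first}..{last} invalid for a {model.n_exons}-exon model"
        )
    return int(model._lengths[first - 1 : last].sum())


def make_synthetic_model(
    n_exons: int,
    lengths: Iterable[int] | None = None,
    *,
    seed: int | None = None,
    length_range: tuple[int, int] = (30, 250),
    transcript_label: str = "synthetic",
) -> GeneModel:
    """Build a valid synthetic gene model for tests.

    Either pass explicit ``lengths`` (their total must be divisible by 3),
    or a ``seed``: lengths are then drawn uniformly from ``length_range``
    and the last exon is padded by 0-2 nt so the CDS total is a multiple
    of 3. Same seed, same model.
    """
    if n_exons < 2:
        raise GeneModelError("a synthetic model needs n_exons >= 2")
    if lengths is not None:
        lengths = [int(x) for x in lengths]
        if len(lengths) != n_exons:
            raise GeneModelError(
                f"expected {n_exons} lengths, got {len(lengths)}"
            )
        return _build_model(lengths, transcript_label)
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    if not 0 < lo <= hi:
        raise GeneModelError(f"invalid length_range {length_range}")
    drawn = rng.integers(lo, hi + 1, size=n_exons).tolist()
    pad = (-sum(drawn)) % 3
    drawn[-1] += pad
    return _build_model(drawn, transcript_label)
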