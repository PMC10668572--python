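"""MLPA peak simulation, dosage-quotient normalization and CN calling.

Multiplex ligation-dependent probe amplification measures per-exon copy
number through relative peak heights. The simulator emulates a two-panel
79-probe dystrophin kit plus a set of autosomal control (reference)
probes, capillary peak heights proportional to copy number with
multiplicative Gaussian noise, and ligation-site artifacts: a sequence
variant under a probe's ligation site abolishes that probe's signal and
mimics a single-exon deletion. The transparent threshold caller that
replaces vendor software therefore *always* flags single-exon calls for
orthogonal confirmation — in screening practice a sizeable fraction of
such calls are ligation-site false positives.

Normalization follows the dosage-quotient convention: each probe's peak is
expressed relative to the control-probe mass of its own sample, then
divided by the same quantity in a reference sample. When a peak table
carries no control probes the fallback is relative-to-total-sum
normalization, which exhibits the classic renormalization effect (a
deletion inflates all remaining ratios by ``total/(total - deleted
mass)``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import QCError, ThresholdConfigError, UsageError
from .genotype import MutationKind, RearrangementCall

__all__ = [
    "PEAK_TABLE_COLUMNS",
    "ProbeRatioProfile",
    "CopyNumberCallSet",
    "CarrierStatus",
    "ThresholdBin",
    "CallingThresholds",
    "simulate_peak_table",
    "normalize_peaks",
    "call_copy_number",
    "call_carrier",
    "genotype_from_call",
    "default_panel_assignment",
    "read_peak_table",
    "write_peak_table",
]

PEAK_TABLE_COLUMNS = ["probe_id", "probe_exon", "panel", "peak_height"]

#: exon number used for autosomal control probes in peak tables
CONTROL_EXON = 0
CONTROL_PANEL = "REF"

_BASELINE = {"male": 1, "female": 2}
_MAX_CN = {"male": 3, "female": 4}


def default_panel_assignment(n_exons: int = 79) -> dict[int, str]:
    """Stand-in two-panel split: odd exons P034, even exons P035.

    The true vendor layout is a bookkeeping detail that does not affect
    calls; a custom mapping can be passed to :func:`simulate_peak_table`.
    """
    return {e: ("P034" if e % 2 else "P035") for e in range(1, n_exons + 1)}


def _base_intensities(n_exons: int, n_controls: int) -> tuple[np.ndarray, np.ndarray]:
    # deterministic, probe-specific intensities so normalization is non-trivial
    gene = 900.0 + 30.0 * ((53 * np.arange(1, n_exons + 1)) % 11)
    ctrl = 1000.0 + 40.0 * ((31 * np.arange(1, n_controls + 1)) % 7)
    return gene, ctrl


def simulate_peak_table(
    genotype: Mapping[int, int],
    sex: str = "male",
    noise_sd: float = 0.0,
    artifact_exons: Iterable[int] = (),
    seed: int | None = None,
    *,
    n_exons: int = 79,
    n_control_probes: int = 13,
    panel_of: Mapping[int, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one MLPA run: a test sample and a same-sex reference.

    Parameters
    ----------
    genotype:
        Per-exon copy number of the test sample; exons not listed sit at
        the sex baseline (1 hemizygous male / 2 female). Copy numbers are
        bounded by 0..3 (male) or 0..4 (female).
    sex:
        ``"male"`` or ``"female"``; fixes baselines of both samples.
    noise_sd:
        Standard deviation of the multiplicative noise term: each peak is
        ``base_intensity * copy_number * (1 + eps)``, ``eps ~ N(0, sd)``.
    artifact_exons:
        Exons whose test-sample probe suffers a ligation-site sequence
        variant: the probe's effective copy contribution is forced to 0
        regardless of the true copy number.
    seed:
        Seed for the noise generator; same seed, same tables.
    n_control_probes:
        Autosomal reference probes (copy number 2 in every sample) added
        to both panels' mixes; they carry the normalization.

    Returns
    -------
    (test, reference):
        Two peak tables with columns ``probe_id, probe_exon, panel,
        peak_height``; control probes have ``probe_exon == 0`` and panel
        ``REF``.
    """
    if sex not in _BASELINE:
        raise UsageError(f"sex must be 'male' or 'female', got {sex!r}")
    if noise_sd < 0:
        raise UsageError(f"noise_sd must be >= 0, got {noise_sd}")
    baseline = _BASELINE[sex]
    cn = np.full(n_exons, baseline, dtype=float)
    for exon, copies in genotype.items():
        if not 1 <= int(exon) <= n_exons:
            raise KeyError(f"genotype exon {exon} outside 1..{n_exons}")
        if not 0 <= int(copies) <= _MAX_CN[sex]:
            raise UsageError(
                f"copy number {copies} at exon {exon} outside 0..{_MAX_CN[sex]} for {sex}"
            )
        cn[int(exon) - 1] = int(copies)
    artifacts = set()
    for exon in artifact_exons:
        if not 1 <= int(exon) <= n_exons:
            raise KeyError(f"artifact exon {exon} outside 1..{n_exons}")
        artifacts.add(int(exon))

    panels = dict(panel_of) if panel_of is not None else default_panel_assignment(n_exons)
    gene_base, ctrl_base = _base_intensities(n_exons, n_control_probes)
    rng = np.random.default_rng(seed)

    def _noise(size: int) -> np.ndarray:
        if noise_sd == 0.0:
            return np.ones(size)
        return 1.0 + rng.normal(0.0, noise_sd, size=size)

    test_cn = cn.copy()
    for exon in artifacts:
        test_cn[exon - 1] = 0.0  # probe dropout: complete signal loss
    ref_cn = np.full(n_exons, baseline, dtype=float)

    def _table(gene_copy: np.ndarray) -> pd.DataFrame:
        gene_peaks = gene_base * gene_copy * _noise(n_exons)
        ctrl_peaks = ctrl_base * 2.0 * _noise(n_control_probes)
        return pd.DataFrame(
            {
                "probe_id": [f"ex{e:02d}" for e in range(1, n_exons + 1)]
                + [f"ctrl{j:02d}" for j in range(1, n_control_probes + 1)],
                "probe_exon": list(range(1, n_exons + 1)) + [CONTROL_EXON] * n_control_probes,
                "panel": [panels[e] for e in range(1, n_exons + 1)]
                + [CONTROL_PANEL] * n_control_probes,
                "peak_height": np.concatenate([gene_peaks, ctrl_peaks]),
            }
        )

    return _table(test_cn), _table(ref_cn)


@dataclass(frozen=True)
class ProbeRatioProfile:
    """Per-exon dosage quotients of one sample against a reference."""

    sample_id: str
    expected_baseline_copies: int  # 1 male, 2 female
    ratios: dict[int, float]
    panel_of: dict[int, str]

    def __post_init__(self) -> None:
        if set(self.ratios) != set(self.panel_of):
            raise QCError("ratio and panel maps must cover the same exons")

    @property
    def exons(self) -> list[int]:
        return sorted(self.ratios)


def normalize_peaks(
    test: pd.DataFrame,
    reference: pd.DataFrame,
    *,
    sex: str = "male",
    sample_id: str = "sample",
) -> ProbeRatioProfile:
    """Dosage-quotient normalization of a test sample against a reference.

    ``ratio_e = (test_e / N_test) / (ref_e / N_ref)`` where the
    normalizer ``N`` is the control-probe sum when control probes
    (``probe_exon == 0``) are present in both tables, and the total peak
    sum otherwise.
    """
    if sex not in _BASELINE:
        raise UsageError(f"sex must be 'male' or 'female', got {sex!r}")
    for name, table in (("test", test), ("reference", reference)):
        missing = set(PEAK_TABLE_COLUMNS) - set(table.columns)
        if missing:
            raise QCError(f"{name} peak table lacks columns {sorted(missing)}")
    test = test.sort_values("probe_id").reset_index(drop=True)
    reference = reference.sort_values("probe_id").reset_index(drop=True)
    if list(test["probe_id"]) != list(reference["probe_id"]):
        raise QCError("test and reference tables carry different probe sets")

    gene_mask = test["probe_exon"].to_numpy() != CONTROL_EXON
    ctrl_mask = ~gene_mask
    ref_peaks = reference["peak_height"].to_numpy(dtype=float)
    test_peaks = test["peak_height"].to_numpy(dtype=float)
    zero_ref = reference.loc[(ref_peaks <= 0) & gene_mask, "probe_id"].tolist()
    if zero_ref:
        raise QCError(f"reference sample has zero peaks at probes {zero_ref}")

    if ctrl_mask.any():
        n_test = float(test_peaks[ctrl_mask].sum())
        n_ref = float(ref_peaks[ctrl_mask].sum())
        scheme = "control-probe sum"
    else:
        n_test = float(test_peaks.sum())
        n_ref = float(ref_peaks.sum())
        scheme = "total sum"
    if n_test <= 0 or n_ref <= 0:
        raise QCError(f"non-positive {scheme} normalizer (test {n_test}, ref {n_ref})")

    ratios: dict[int, float] = {}
    panel_of: dict[int, str] = {}
    for i in np.flatnonzero(gene_mask):
        exon = int(test.at[i, "probe_exon"])
        ratios[exon] = (test_peaks[i] / n_test) / (ref_peaks[i] / n_ref)
        panel_of[exon] = str(test.at[i, "panel"])
    return ProbeRatioProfile(
        sample_id=sample_id,
        expected_baseline_copies=_BASELINE[sex],
        ratios=ratios,
        panel_of=panel_of,
    )


@dataclass(frozen=True)
class ThresholdBin:
    """One copy-number bin: ``lo <= ratio <= hi`` with optional open ends."""

    cn: int
    lo: float
    hi: float
    lo_open: bool = False
    hi_open: bool = False

    def contains(self, ratio: float) -> bool:
        above = ratio > self.lo if self.lo_open else ratio >= self.lo
        below = ratio < self.hi if self.hi_open else ratio <= self.hi
        return above and below

    def numeric_overlap(self, other: "ThresholdBin") -> bool:
        lo, hi = max(self.lo, other.lo), min(self.hi, other.hi)
        if lo > hi:
            return False
        if lo < hi:
            return True
        # touching at a single point: only a clash if both ends are closed
        left, right = (self, other) if self.lo <= other.lo else (other, self)
        return not (left.hi_open or right.lo_open)


@dataclass(frozen=True)
class CallingThresholds:
    """Ordered ratio bins mapping dosage quotients to copy numbers.

    The defaults are midpoints between the dosage levels expected for a
    hemizygous male (0, 1, 2 copies against a 1-copy baseline) and a
    female (0..3 copies against 2); they are deliberately wide no-call
    margins rather than vendor values.
    """

    bins: tuple[ThresholdBin, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.bins, self.bins[1:]):
            if a.cn == b.cn:
                raise ThresholdConfigError(f"duplicate bin for CN {a.cn}")
        for i, a in enumerate(self.bins):
            for b in self.bins[i + 1 :]:
                if a.numeric_overlap(b):
                    raise ThresholdConfigError(
                        f"threshold bins overlap: CN {a.cn} [{a.lo}, {a.hi}] and "
                        f"CN {b.cn} [{b.lo}, {b.hi}]"
                    )

    def classify(self, ratio: float) -> int | None:
        for bin_ in self.bins:
            if bin_.contains(ratio):
                return bin_.cn
        return None

    @classmethod
    def default_male(cls) -> "CallingThresholds":
        return cls(
            bins=(
                ThresholdBin(0, 0.0, 0.30, hi_open=True),
                ThresholdBin(1, 0.70, 1.30),
                ThresholdBin(2, 1.70, float("inf"), lo_open=True),
            )
        )

    @classmethod
    def default_female(cls) -> "CallingThresholds":
        return cls(
            bins=(
                ThresholdBin(0, 0.0, 0.30, hi_open=True),
                ThresholdBin(1, 0.35, 0.65),
                ThresholdBin(2, 0.80, 1.20),
                ThresholdBin(3, 1.30, 1.70),
            )
        )

    @classmethod
    def default_for_baseline(cls, baseline_copies: int) -> "CallingThresholds":
        return cls.default_male() if baseline_copies == 1 else cls.default_female()

    @classmethod
    def from_file(cls, path: str | Path) -> "CallingThresholds":
        """Load bins from a YAML/JSON file: ``bins: [{cn, lo, hi, ...}]``."""
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict) or "bins" not in payload:
            raise ThresholdConfigError(f"{path}: expected a mapping with a 'bins' list")
        bins = []
        for entry in payload["bins"]:
            try:
                bins.append(
                    ThresholdBin(
                        cn=int(entry["cn"]),
                        lo=float(entry["lo"]),
                        hi=float(entry.get("hi", float("inf"))),
                        lo_open=bool(entry.get("lo_open", False)),
                        hi_open=bool(entry.get("hi_open", False)),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ThresholdConfigError(f"{path}: malformed bin {entry!r}") from exc
        return cls(bins=tuple(bins))


@dataclass(frozen=True)
class CopyNumberCallSet:
    """Per-exon integer calls plus derived rearrangements and QC notes.

    ``derived_calls`` are maximal runs of consecutive exons sharing the
    same non-baseline copy number; ``confirmation_required`` is parallel
    to it, and is always True for single-exon calls (ligation-site
    artifact safeguard).
    """

    per_exon_cn: dict[int, int | None]
    derived_calls: tuple[RearrangementCall, ...]
    confirmation_required: tuple[bool, ...]
    qc_notes: tuple[str, ...]
    baseline_copies: int

    def no_calls(self) -> list[int]:
        return [e for e, cn in sorted(self.per_exon_cn.items()) if cn is None]


def call_copy_number(
    profile: ProbeRatioProfile,
    thresholds: CallingThresholds | None = None,
) -> CopyNumberCallSet:
    """Threshold each exon's dosage quotient and segment into calls."""
    baseline = profile.expected_baseline_copies
    if thresholds is None:
        thresholds = CallingThresholds.default_for_baseline(baseline)
    per_exon: dict[int, int | None] = {}
    notes: list[str] = []
    for exon in profile.exons:
        ratio = profile.ratios[exon]
        cn = thresholds.classify(ratio)
        per_exon[exon] = cn
        if cn is None:
            notes.append(
                f"exon {exon}: ratio {ratio:.3f} falls in no copy-number bin (NO_CALL)"
            )

    derived: list[RearrangementCall] = []
    confirm: list[bool] = []
    exons = profile.exons
    i = 0
    while i < len(exons):
        exon, cn = exons[i], per_exon[exons[i]]
        if cn is None or cn == baseline:
            i += 1
            continue
        j = i
        while (
            j + 1 < len(exons)
            and exons[j + 1] == exons[j] + 1
            and per_exon[exons[j + 1]] == cn
        ):
            j += 1
        kind = MutationKind.DELETION if cn < baseline else MutationKind.DUPLICATION
        call = RearrangementCall(kind, exons[i], exons[j])
        derived.append(call)
        single = call.n_exons == 1
        confirm.append(single)
        if single:
            notes.append(
                f"single-exon {kind.value} at exon {call.first_exon}: requires "
                "PCR/sequencing confirmation (possible ligation-site artifact)"
            )
        i = j + 1
    return CopyNumberCallSet(
        per_exon_cn=per_exon,
        derived_calls=tuple(derived),
        confirmation_required=tuple(confirm),
        qc_notes=tuple(notes),
        baseline_copies=baseline,
    )


class CarrierStatus(enum.Enum):
    CARRIER = "carrier"
    NON_CARRIER = "non-carrier"
    INCONCLUSIVE = "inconclusive"


def call_carrier(
    female_profile: ProbeRatioProfile,
    proband_call: RearrangementCall,
    thresholds: CallingThresholds | None = None,
) -> CarrierStatus:
    """Heterozygous-dosage test of a female relative at the proband's lesion.

    CARRIER iff every exon of the proband interval is called at the
    heterozygous level (CN 1 for a deletion, CN 3 for a duplication);
    NON_CARRIER iff all sit at the normal CN 2; anything mixed or
    uncallable is INCONCLUSIVE.
    """
    if female_profile.expected_baseline_copies != 2:
        raise UsageError("carrier analysis expects a female (2-copy baseline) profile")
    calls = call_copy_number(female_profile, thresholds)
    want = 1 if proband_call.kind is MutationKind.DELETION else 3
    states = [
        calls.per_exon_cn.get(exon)
        for exon in range(proband_call.first_exon, proband_call.last_exon + 1)
    ]
    if all(cn == want for cn in states):
        return CarrierStatus.CARRIER
    if all(cn == 2 for cn in states):
        return CarrierStatus.NON_CARRIER
    return CarrierStatus.INCONCLUSIVE


def genotype_from_call(
    call: RearrangementCall, sex: str = "male", *, heterozygous: bool = False
) -> dict[int, int]:
    """Per-exon copy numbers implied by a rearrangement call.

    ``heterozygous=True`` models a female carrier (CN 1 or 3 over the
    interval); otherwise the lesion is hemizygous/homozygous for the
    given sex baseline.
    """
    if sex not in _BASELINE:
        raise UsageError(f"sex must be 'male' or 'female', got {sex!r}")
    baseline = _BASELINE[sex]
    if call.kind is MutationKind.DELETION:
        cn = baseline - 1 if heterozygous else 0
    else:
        cn = baseline + 1 if heterozygous else 2 * baseline
    return {exon: cn for exon in range(call.first_exon, call.last_exon + 1)}


def write_peak_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=PEAK_TABLE_COLUMNS)


def read_peak_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(PEAK_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise QCError(f"peak table {path} lacks columns {sorted(missing)}")
    return table
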