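"""MLPA simulation, dosage-quotient normalization and copy-number calling."""

import numpy as np
import pytest

from dmdspectrum import (
    CallingThresholds,
    CarrierStatus,
    MutationKind,
    RearrangementCall,
    call_carrier,
    call_copy_number,
    genotype_from_call,
    normalize_peaks,
    simulate_peak_table,
)
from dmdspectrum.errors import QCError, ThresholdConfigError, UsageError
from dmdspectrum.mlpa import ThresholdBin

DEL = MutationKind.DELETION
DUP = MutationKind.DUPLICATION
DEL_46_48 = RearrangementCall(DEL, 46, 48)


def _profile(genotype, sex="male", noise_sd=0.0, artifacts=(), seed=0, **kw):
    test, ref = simulate_peak_table(
        genotype, sex=sex, noise_sd=noise_sd, artifact_exons=artifacts, seed=seed, **kw
    )
    return normalize_peaks(test, ref, sex=sex)


def test_noiseless_baseline_is_identity():
    test, ref = simulate_peak_table({}, "male", 0.0, (), seed=1)
    assert np.allclose(test["peak_height"], ref["peak_height"])
    profile = normalize_peaks(test, ref)
    assert all(r == pytest.approx(1.0) for r in profile.ratios.values())
    assert call_copy_number(profile).derived_calls == ()


def test_deleted_probes_have_zero_peaks_only_there():
    test, _ = simulate_peak_table(genotype_from_call(DEL_46_48), "male", 0.0, (), seed=1)
    gene = test[test.probe_exon > 0].set_index("probe_exon")["peak_height"]
    assert (gene.loc[[46, 47, 48]] == 0).all()
    assert (gene.drop([46, 47, 48]) > 0).all()


def test_simulation_determinism():
    a = simulate_peak_table(genotype_from_call(DEL_46_48), "male", 0.08, {12}, seed=99)
    b = simulate_peak_table(genotype_from_call(DEL_46_48), "male", 0.08, {12}, seed=99)
    for x, y in zip(a, b):
        assert np.array_equal(x["peak_height"], y["peak_height"])


def test_simulation_rejects_bad_inputs():
    with pytest.raises(KeyError):
        simulate_peak_table({80: 0}, "male")
    with pytest.raises(KeyError):
        simulate_peak_table({}, "male", artifact_exons={0})
    with pytest.raises(UsageError):
        simulate_peak_table({}, "other")
    with pytest.raises(UsageError):
        simulate_peak_table({10: 9}, "male")


def test_normalization_scale_invariance():
    """Multiplying either sample by a positive constant changes nothing."""
    test, ref = simulate_peak_table(genotype_from_call(DEL_46_48), "male", 0.05, (), seed=3)
    base = normalize_peaks(test, ref)
    test2, ref2 = test.copy(), ref.copy()
    test2["peak_height"] *= 3.7
    ref2["peak_height"] *= 0.41
    scaled = normalize_peaks(test2, ref2)
    assert base.ratios == pytest.approx(scaled.ratios)


def test_total_sum_fallback_renormalization_factor():
    """Without control probes, non-deleted ratios all equal the closed-form
    inflation factor total/(total - deleted mass)."""
    test, ref = simulate_peak_table(
        genotype_from_call(DEL_46_48), "male", 0.0, (), seed=5, n_control_probes=0
    )
    profile = normalize_peaks(test, ref)
    total = ref["peak_height"].sum()
    mass = ref.loc[ref.probe_exon.isin([46, 47, 48]), "peak_height"].sum()
    factor = total / (total - mass)
    assert factor > 1
    for exon, ratio in profile.ratios.items():
        expected = 0.0 if 46 <= exon <= 48 else factor
        assert ratio == pytest.approx(expected)


def test_zero_reference_peak_is_a_qc_error_naming_the_probe():
    test, ref = simulate_peak_table({}, "male", 0.0, (), seed=6)
    ref.loc[ref.probe_id == "ex23", "peak_height"] = 0.0
    with pytest.raises(QCError, match="ex23"):
        normalize_peaks(test, ref)


def test_overlapping_threshold_bins_rejected():
    with pytest.raises(ThresholdConfigError):
        CallingThresholds(bins=(ThresholdBin(0, 0.0, 0.5), ThresholdBin(1, 0.4, 1.2)))
    # touching endpoints are fine when one side is open
    CallingThresholds(bins=(ThresholdBin(0, 0.0, 0.5, hi_open=True), ThresholdBin(1, 0.5, 1.2)))


def test_thresholds_from_file(tmp_path):
    cfg = tmp_path / "thresholds.yaml"
    cfg.write_text(
        "bins:\n"
        "  - {cn: 0, lo: 0.0, hi: 0.25, hi_open: true}\n"
        "  - {cn: 1, lo: 0.75, hi: 1.25}\n"
        "  - {cn: 2, lo: 1.75, lo_open: true}\n"
    )
    thresholds = CallingThresholds.from_file(cfg)
    assert thresholds.classify(1.0) == 1
    assert thresholds.classify(0.5) is None
    assert thresholds.classify(2.4) == 2
    bad = tmp_path / "bad.yaml"
    bad.write_text("bins:\n  - {cn: 0}\n")
    with pytest.raises(ThresholdConfigError):
        CallingThresholds.from_file(bad)


def test_exact_recovery_of_multi_exon_deletion():
    calls = call_copy_number(_profile(genotype_from_call(DEL_46_48)))
    assert calls.derived_calls == (DEL_46_48,)
    assert calls.confirmation_required == (False,)
    assert calls.qc_notes == ()


def test_artifact_mimics_single_exon_deletion_and_is_flagged():
    """A ligation-site dropout on a normal genotype must surface as a
    single-exon deletion call carrying confirmation_required."""
    calls = call_copy_number(_profile({}, artifacts={47}))
    assert calls.derived_calls == (RearrangementCall(DEL, 47, 47),)
    assert calls.confirmation_required == (True,)
    assert any("confirmation" in note for note in calls.qc_notes)


def test_every_single_exon_artifact_is_flagged_noiseless():
    """Property over all 79 probes: artifact -> flagged single-exon call."""
    for exon in range(1, 80):
        calls = call_copy_number(_profile({}, artifacts={exon}))
        assert calls.derived_calls == (RearrangementCall(DEL, exon, exon),)
        assert calls.confirmation_required == (True,)


def test_exhaustive_recovery_of_contiguous_events_at_zero_noise():
    """Every >=2-exon single-interval deletion and duplication over the 79
    probes is recovered exactly (control-probe dosage quotients)."""
    for first in range(1, 80):
        for last in range(first + 1, 80):
            for kind, cn in ((DEL, 0), (DUP, 2)):
                genotype = {e: cn for e in range(first, last + 1)}
                calls = call_copy_number(_profile(genotype))
                assert calls.derived_calls == (RearrangementCall(kind, first, last),), (
                    kind,
                    first,
                    last,
                )
                assert calls.qc_notes == ()


def test_noisy_monte_carlo_recovery_rate():
    """del 46-48 at noise_sd 0.05: at least 95 of 100 seeded replicates
    recover the exact call."""
    genotype = genotype_from_call(DEL_46_48)
    recovered = sum(
        call_copy_number(_profile(genotype, noise_sd=0.05, seed=seed)).derived_calls
        == (DEL_46_48,)
        for seed in range(100)
    )
    assert recovered >= 95


def test_carrier_classification():
    het = _profile(genotype_from_call(DEL_46_48, "female", heterozygous=True), sex="female")
    assert call_carrier(het, DEL_46_48) is CarrierStatus.CARRIER
    normal = _profile({}, sex="female")
    assert call_carrier(normal, DEL_46_48) is CarrierStatus.NON_CARRIER
    # heterozygous over only part of the proband interval: mixed evidence
    partial = _profile({46: 1, 47: 1}, sex="female")
    assert call_carrier(partial, DEL_46_48) is CarrierStatus.INCONCLUSIVE
    dup = RearrangementCall(DUP, 14, 17)
    het_dup = _profile(genotype_from_call(dup, "female", heterozygous=True), sex="female")
    assert call_carrier(het_dup, dup) is CarrierStatus.CARRIER
    with pytest.raises(UsageError):
        call_carrier(_profile({}), DEL_46_48)  # male profile
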