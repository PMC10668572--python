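"""Female carrier detection from heterozygous dosage ratios.

A carrier mother shows ~0.5 dosage over a deleted interval (one of two X
copies lost); carrier/de novo rates aggregate over tested relatives.
"""

from dmdspectrum import (
    call_carrier,
    carrier_summary,
    genotype_from_call,
    normalize_peaks,
    parse_mutation_notation,
    simulate_peak_table,
)

proband = parse_mutation_notation("del 46-48")

# mother heterozygous for the proband's deletion
test, ref = simulate_peak_table(
    genotype_from_call(proband, "female", heterozygous=True),
    sex="female", noise_sd=0.04, seed=8,
)
mother = normalize_peaks(test, ref, sex="female", sample_id="mother")
print("mother:", call_carrier(mother, proband).value)
print("  ratios over interval:",
      {e: round(float(mother.ratios[e]), 2) for e in (46, 47, 48)})

# non-carrier sister
test, ref = simulate_peak_table({}, sex="female", noise_sd=0.04, seed=9)
sister = normalize_peaks(test, ref, sex="female", sample_id="sister")
print("sister:", call_carrier(sister, proband).value)

# study-style aggregation: 14 carriers among 27 tested mothers
maternal = [(f"mother{i}", "carrier") for i in range(14)] + [
    (f"mother{i}", "non-carrier") for i in range(14, 27)
]
rates = carrier_summary(maternal)
print(
    f"\n{rates.n_carrier}/{rates.n_tested} mothers carry the proband lesion "
    f"({rates.percent_carrier}% inherited, {rates.percent_de_novo}% apparently de novo)"
)
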