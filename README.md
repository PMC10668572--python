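# dmdspectrum

Reading-frame, exon-skipping, MLPA copy-number and cohort-spectrum
analysis for dystrophin (*DMD* gene) exon rearrangements.

Duchenne and Becker muscular dystrophy (DMD/BMD) are X-linked
dystrophinopathies caused mostly by multi-exon deletions and duplications
of the *DMD* gene. Diagnosis and therapy selection hinge on a small set
of computations that this package implements end to end for genetics
labs and genotype–phenotype researchers:

- the **reading-frame rule**: a rearrangement of exons `a..b` is
  in-frame iff `Σ len(a..b) ≡ 0 (mod 3)` over coding exon lengths —
  in-frame predicts the milder BMD, out-of-frame predicts DMD;
- **exon-skipping amenability**: flank exon `e ∈ {a−1, b+1}` rescues an
  out-of-frame deletion iff `Σ len(a..b) + len(e) ≡ 0 (mod 3)` (exon 51
  → eteplirsen, exon 53 → golodirsen), plus stop-codon read-through
  eligibility for nonsense variants;
- **MLPA simulation and calling**: per-exon dosage quotients
  `DQ_e = (test_e/N_test)/(ref_e/N_ref)`, threshold-based copy-number
  calls, female-carrier dosage (DQ ≈ 0.5 / 1.5), and the single-exon
  false-positive safeguard for ligation-site artifacts;
- **cohort reporting**: mutation spectrum, proximal (exons 2–20) /
  distal (exons 45–55) hotspot partition, per-exon involvement,
  frame-rule concordance, clinical and carrier summaries.

It ships the 79-exon coding table of the Dp427m transcript (NM_004006)
and a transcription of a published 43-patient Indonesian DMD/BMD cohort
as fixtures (`src/dmdspectrum/data/README.md`).

## Worked example

```python
>>> from dmdspectrum import (load_gene_model, parse_mutation_notation,
...     classify_call, predict_phenotype, candidate_single_exon_skips)
>>> model = load_gene_model()
>>> call = parse_mutation_notation("del 48-50")
>>> model.coding_span_length(48, 50)
397
>>> classify_call(call, model).value
'out-of-frame'
>>> predict_phenotype(classify_call(call, model)).value
'DMD'
>>> rec = candidate_single_exon_skips(call, model)
>>> sorted(rec.restoring_skips), rec.primary_target
([51], 51)
```

397 nt is not a codon multiple, so del 48–50 shifts the frame and
predicts Duchenne; adding exon 51 (233 nt) gives 630 ≡ 0 (mod 3), so the
patient is amenable to exon-51 skipping (eteplirsen's target).

Each capability has a narrative script under `examples/`
(`python examples/01_reading_frame.py`, …): frame classification, skip
advice, MLPA simulation with the artifact safeguard, carrier analysis,
and the full cohort report. The same operations are available from a
shell via the `dmdspectrum` CLI (`annotate`, `skip`, `cohort`,
`simulate`, `call`, `carrier`; see `dmdspectrum --help`).

Running the cohort report on the packaged table prints, among others:

```
- Deletions: 30 (69.77%)
- Duplications: 5 (11.63%)
- Distal (exons 45-55): 20 (66.67%)
- Proximal (exons 2-20): 8 (26.67%)
- Concordance with clinical phenotype: 31/35 (88.57%)
- Amenable to single-exon skipping: 21 (48.84%)
```

i.e. deletions dominate the spectrum and cluster distally; the frame
rule predicts the clinical phenotype in about nine of ten
variant-positive patients; and roughly half the cohort is a candidate
for single-exon skipping therapy.

## Layout

- `src/dmdspectrum/` — library (`reference`, `genotype`, `frame`,
  `skip`, `mlpa`, `cohort`, `cli`)
- `src/dmdspectrum/data/` — bundled exon reference and cohort fixtures
- `examples/` — one runnable script per capability
- `docs/methods.md` — models, assumptions, thresholds, limitations
- `docs/format.md` — file formats
- `tests/` — unit, property and end-to-end suites
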