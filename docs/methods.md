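# Methods

## Scope and model

`dmdspectrum` analyses exon-level rearrangements of the dystrophin gene
(*DMD*, Xp21) as observed by MLPA screening of dystrophinopathy patients.
Its four computational layers are:

1. **Gene model.** The muscle isoform Dp427m (NM_004006) has 79 exons and
   an 11,058 nt CDS. All frame arithmetic runs on *coding* exon lengths
   (UTR portions of exons 1 and 79 excluded), because the reading-frame
   rule is defined on the translated sequence. Exon coordinates are
   1-based, intervals inclusive, matching clinical notation ("del 46-48").
2. **Reading-frame rule.** A deletion of exons `a..b` is in-frame iff
   `sum(len[a..b]) mod 3 == 0`; in-frame predicts BMD, out-of-frame DMD.
   Duplications are assumed tandem and fully intragenic, so the inserted
   length equals the span length and the same test applies — this
   assumption reproduces the out-of-frame verdicts of all five
   duplications in the bundled cohort. Small variants are in-frame iff
   their net coding change is a codon multiple and no premature stop is
   introduced. Junction effects (stop codons created at novel exon-exon
   boundaries) are *not* modelled; the classification is pure length
   arithmetic, which is what the widely used exonic del/dup frame
   checkers implement. Rearrangements touching exon 1 or exon 79 return
   NOT_ASSESSABLE rather than a guess (start/stop codon and UTR effects
   dominate there); none occur in the bundled cohort.
3. **Skip advisor.** For an out-of-frame deletion, skipping flank exon
   `e ∈ {a-1, b+1}` (restricted to 2..78) restores the frame iff
   `span + len[e] ≡ 0 (mod 3)`. Only single flanking-exon skips are
   evaluated; multi-exon skipping is a stub raising `NotImplementedError`.
   When both flanks restore the frame the 5' flank is the primary target —
   the only tie-break consistent with the bundled cohort's published
   grouping (del 51 → exon 50, del 52 → exon 51). Both options remain in
   `restoring_skips`. Nonsense small variants are read-through eligible.
4. **MLPA simulator and caller.** Peak height = base intensity × copy
   number × (1 + ε), ε ~ N(0, `noise_sd`), seeded and probe-specific.
   Thirteen autosomal control probes (copy number 2 in all samples)
   accompany the 79 gene probes. A ligation-site artifact forces one test
   probe's contribution to zero — a perfect mimic of a single-exon
   deletion, which is why the caller marks *every* single-exon call
   `confirmation_required`.

## Normalization

The dosage quotient of probe *e* is
`(test_e / N_test) / (ref_e / N_ref)`. `N` is the control-probe sum when
control probes are present (the field-standard reference-probe
normalization), and the total probe sum otherwise. The fallback exhibits
the classic renormalization effect — deleting mass *d* inflates all
remaining ratios by `N_ref / (N_ref − d)` — which is asserted in the
tests in closed form. Control-probe normalization is the default for a
reason: with only gene probes, events covering ≳a third of the panel push
unaffected ratios out of the calling bins (a 42-exon deletion inflates
the rest to ~1.9, a ≥14-exon duplication dilutes itself below 1.7), so
total-sum normalization cannot support exact recovery of large
single-interval events, whereas control-referenced quotients recover
every contiguous event exactly at zero noise (verified exhaustively for
all ≥2-exon intervals over 79 exons). Normalization is scale-invariant in
both schemes.

## Calling thresholds

Transparent threshold bins replace vendor software; values are package
defaults chosen as midpoints between expected dosage levels, not vendor
or study values, and are configurable (YAML, `--thresholds`):

| baseline | CN 0 | CN 1 | CN 2 | CN 3 |
|---|---|---|---|---|
| male (1 copy) | < 0.30 | 0.70–1.30 | > 1.70 | — |
| female (2 copies) | < 0.30 | 0.35–0.65 | 0.80–1.20 | 1.30–1.70 |

Ratios outside all bins yield NO_CALL with a QC note; NO_CALL exons break
runs. Derived calls are maximal runs of consecutive exons at the same
non-baseline copy number. Carrier classification requires the *entire*
proband interval at the heterozygous level (CN 1 del / CN 3 dup);
anything mixed is INCONCLUSIVE.

At `noise_sd = 0.05` (a generous value for a clean capillary run) the
3-exon deletion benchmark is recovered in ≥95 of 100 seeded replicates;
the no-call margins (0.30–0.70 etc.) make miscalls rare rather than
wrong.

## The bundled cohort and what the synthetic data emulate

The packaged table transcribes a published 43-patient Indonesian
DMD/BMD cohort (males, MLPA-screened with the P034/P035 panels;
single-exon calls re-examined by PCR/Sanger). The two refuted single-exon
calls are stored as *both* the initial MLPA call and the validated small
variant, so statistics can run on the initial view (n=43; 30 deletions)
or the validated view (n=35 variant-positive: 28 exon deletions + 2 small
variants + 5 duplications). Each summary records its view; hotspot
statistics deliberately use the initial view (the published denominators
include the refuted calls).

Hotspot classification is overlap-based with distal precedence
(distal = exons 45–55, proximal = 2–20, both configurable). The
precedence is a derived reconciliation, not a published rule: it is the
only partition of the 30 initial deletion calls that reproduces the
published 20/8/2 split (del 18–47 overlaps both regions and counts as
distal; del 65 and del 56–74 as neither).

The simulator emulates relative peak heights, dosage renormalization,
heterozygous-carrier dosage and ligation-site dropout. It does **not**
emulate fragment sizing, inter-capillary drift, partial hybridization,
GC-dependent amplification bias or mosaicism — passing the recovery tests
therefore demonstrates the caller's arithmetic, not robustness to every
real-world MLPA failure mode.

## Documented inconsistencies in the source cohort's summary statistics

Three published headline numbers cannot be reproduced from the cohort's
own genotype table plus Dp427m arithmetic. They are reported as computed
and flagged in report notes; the corresponding end-to-end tests assert
the published values and are expected to fail:

1. **del 56–74 (dmd37).** The span is 2,337 coding nt, divisible by 3 —
   in-frame — though the source annotates it out-of-frame. Every other
   printed frame verdict (26 rearrangements) and all 15 published skip
   assignments agree with the same exon table, and the table is anchored
   by the source's own cDNA coordinates (c.6808 in exon 47, c.9540–9551
   in exon 65). With dmd37 discordant (predicted BMD, clinical DMD),
   frame-rule concordance is 31/35 = 88.57% rather than the published
   32/35 = 91.43%, and in-frame deletion-carriers number 5, not 4.
2. **Amenable total.** del 3–17 spans 2,075 nt (≡ 2 mod 3); adding exon
   18 (124 nt) gives 2,199 ≡ 0, so it is rescued by an exon-18 skip —
   derivable entirely from spans pinned by the source's other published
   assignments, and consistent with the source's own cross-country table
   listing exon 18. The amenable total is therefore 21/43 (48.84%), not
   the published 20 (46.51%); the eight published per-target rows
   (51:5, 53:5, 45:2, 50:2, 17:2, 2:2, 44:1, 8:1) reproduce exactly.
3. **CK statistics.** The table's minimum CK is 1,368 IU/L (dmd42),
   below the published range minimum of 1,734. That 1,368 belongs to the
   source's own dataset is provable from its mean: the 41 available
   values sum to 383,111, and 383,111/42 = 9,121.69 matches the published
   mean of 9,121.7 (an apparent denominator slip — 41 values divided
   by 42). This package reports mean = sum/41 = 9,344.2 and
   min = 1,368, with the published figures quoted in the report notes.

Separately, the source's abstract claims 60.47% (n=26) amenability
against its results section's 46.51% (n=20); the per-target computation
here is the internally consistent one and no attempt is made to
reconstruct the 26.

## Numerical and design choices

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); no global state.
- Percentages are computed at full precision and rounded to 2 decimals
  for display; stored percentages re-derive from their counts within
  ±0.02 in tests (the source mixes rounding and truncation).
- The P034/P035 panel split defaults to odd/even exons — a stand-in,
  since panel identity affects bookkeeping only; the real layout can be
  supplied as a mapping.
- Degenerate inputs: an empty cohort file (header only) is a valid empty
  cohort; a deletion abutting exon 2 simply has no 5' skip candidate;
  zero reference peaks are QC errors naming the probe.
- Problem sizes in the test suite — exhaustive single-interval recovery
  (2 × 3,081 events), 500 random synthetic skip checks, 100-replicate
  noise Monte-Carlo — were chosen to cover the full combinatorial space
  where feasible and seeded sampling elsewhere.

## Limitations

- Frame classification ignores junction-encoded stop codons and splice
  re-arrangements; discordant patients (e.g. in-frame genotypes with
  severe phenotypes) are expected biologically and surface in the
  concordance report rather than being "corrected".
- Only the Dp427m transcript is modelled; no genomic coordinates,
  introns, or shorter isoform promoters.
- The MLPA caller is a deliberately transparent reimplementation, not a
  reproduction of any vendor algorithm.
- Carrier analysis assumes germline heterozygosity; somatic or germline
  mosaicism is out of scope.
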