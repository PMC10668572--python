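# Bundled reference data

## `dp427m_exons.tsv`

Coding length, in nucleotides, of each of the 79 exons of the muscle-isoform
dystrophin transcript Dp427m (RefSeq NM_004006). Lengths cover the coding
sequence only: the 5'UTR portion of exon 1 and the 3'UTR portion of exon 79
are excluded, so the column sums to the full CDS of 11,058 nt
(3,685 codons plus the stop). The table was transcribed from the canonical
NM_004006 cDNA exon boundaries (exon *i* spans c.(end(i-1)+1)..end(i)); a
few well-known anchors, e.g. exon 44 ending at c.6438 and exon 51 at
c.7542, pin the transcription, and `tests/test_reference.py` re-derives all
phases from the column by brute force.

Format: tab-separated, header `exon<TAB>coding_length_nt`, one row per exon,
ascending.

## `cohort_table1.tsv`

Transcription of the genotype/clinical table of a published Indonesian
dystrophinopathy cohort: 43 male patients screened by MLPA (SALSA P034/P035),
with single-exon deletion calls re-examined by PCR and Sanger sequencing.
Columns are documented in `docs/format.md`. The two sequencing-corrected
cases keep both their initial MLPA call and the validated small variant
(`dmd28`: c.6808delT, net -1 nt, premature stop; `dmd18`:
c.9540-9551delCTGGCTGCTGAA, net -12 nt, no stop), so analyses can run on the
initial-MLPA view or the validated view.

Values are transcribed verbatim, including entries that conflict with the
source study's own narrative statistics (e.g. CK 1,368 IU/L for `dmd42`,
below the narrative range minimum of 1,734); see `docs/methods.md` for the
full list of documented discrepancies.
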