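# File formats

## Exon reference table (canonical)

Tab-separated, UTF-8, header row, exons ascending:

```
exon	coding_length_nt
1	31
2	62
...
79	12
```

`coding_length_nt` is the number of CDS nucleotides in the exon (UTR
excluded for terminal exons). Loader: `load_gene_model(path)`; validation
enforces contiguous exon numbers, positive lengths, an intact phase chain
and a total divisible by 3.

A BED-like alternative is accepted by `load_gene_model_from_bed`:
headerless TSV whose first four columns are `chrom, start, end,
exon_number` in 0-based half-open coordinates; lengths are `end - start`.
The TSV above remains canonical.

## Cohort table

Tab-separated, UTF-8, exactly these columns:

```
patient_id	ck	onset_age	wheelchair_age	current_age	phenotype	ihc	mlpa_call	validated_call
```

- `ck`: serum creatine kinase in IU/L; `NA` when unavailable.
- `onset_age`, `current_age`: years.
- `wheelchair_age`: years at loss of ambulation, or `ambulant` /
  `not yet` / `still ambulant` for patients who still walk.
- `phenotype`: clinical label, `DMD` or `BMD`.
- `ihc`: Dys-2 immunostaining result, `negative`, `faint`, or `NA` (no
  biopsy).
- `mlpa_call`: rearrangement notation (below) or `no del/no dup`.
- `validated_call`: `NA`, a rearrangement notation (single-exon call
  confirmed by PCR), or a small-variant field (below) when sequencing
  refuted the MLPA call.

### Rearrangement notation

`del A-B`, `del A`, `dup A-B`, `dup A`, `no del/no dup` —
case-insensitive; hyphen, en dash or em dash; exons must lie in 1..79.
Output always uses a hyphen.

### Small-variant field

Pipe-separated: `small|<description>|net=<int>|stop=<0|1>|exon=<int>`,
e.g. `small|c.6808delT|net=-1|stop=1|exon=47`. `net` is the signed change
in coding length (deletions negative), `stop` marks a premature stop
codon, `exon` locates the variant. The description is opaque text.

## MLPA peak tables

Tab-separated with header `probe_id, probe_exon, panel, peak_height`.
Gene probes have `probe_exon` 1..79 and panel `P034`/`P035`; autosomal
control probes have `probe_exon` 0 and panel `REF`. Peak heights are
arbitrary fluorescence units (only ratios matter).

## Threshold configuration

YAML (JSON also parses):

```yaml
bins:
  - {cn: 0, lo: 0.0, hi: 0.30, hi_open: true}
  - {cn: 1, lo: 0.70, hi: 1.30}
  - {cn: 2, lo: 1.70, lo_open: true}
```

Each bin maps a dosage-quotient interval to an integer copy number;
`lo_open`/`hi_open` exclude an endpoint; a missing `hi` means unbounded.
Overlapping bins are rejected.
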