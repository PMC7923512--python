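# vcf2report

Convert VCF variant calls into an HL7 FHIR Genomics **Diagnostic Report**
(JSON) — the bridge between the file format sequencing labs produce and the
resource format electronic health records consume.

The converter is for bioinformaticians and clinical-informatics engineers
wiring sequencing output into FHIR-based pipelines: it takes a single-sample
VCF (plain text or bgzipped) plus a genome build (`GRCh37`/`GRCh38`) and
emits one JSON DiagnosticReport containing

* **variant observations** (LOINC 69548-6) — one per simple variant (SNV,
  MNV, indel), mirroring the VCF row verbatim (same POS/REF/ALT, 1-based
  coordinates, no left-alignment or trimming: syntactic, not semantic,
  normalization);
* **region-studied observations** (LOINC 53041-0) — which requested ranges
  the assay actually examined and, on request, which examined subranges were
  uncallable;
* **sequence-phase-relationship observations** (LOINC 82120-7) — Cis/Trans
  assertions between phased heterozygous variants sharing a phase set.

## Genotype → allelic state

The sample's `FORMAT.GT` decides the zygosity recorded in each variant
observation:

| GT                  | allelic state                  |
|---------------------|--------------------------------|
| `0/1`, `1|0`, `0/2` | heterozygous                   |
| `1/1`, `2/2`        | homozygous                     |
| `1/2` (two alts)    | two heterozygous variants      |
| `0/0`               | absent (ALT set equal to REF)  |
| haploid `1` (X/Y)   | hemizygous                     |
| MT haploid `1`      | homoplasmic if AD/DP > 0.99, else heteroplasmic |

Phased heterozygous calls that share a `FORMAT.PS` phase set are compared by
haplotype slot: `1|0` with `1|0` is **Cis** (same chromosome copy), `1|0`
with `0|1` is **Trans**. Rows with `INFO.SVTYPE` (structural variants),
non-PASS filters, missing genotypes or unrecognized contigs are skipped,
never fatal, and every skip is enumerated with a reason code in a
`*.skips.tsv` log beside the report.

Region inputs are BED files; internally all coordinates are 1-based fully
closed (the VCF convention). The examined ranges are
`conversion ∩ studied`; the uncallable subranges are
`non-callable ∩ studied ∩ conversion`.

## Worked example

Generate the built-in three-region demo scenario and convert it:

```bash
vcf2report make-fixture fig2 --out-dir .
vcf2report convert fig2.vcf --ref-build GRCh37 --out report.json \
  --conv-region fig2.conversion.bed --region-studied fig2.studied.bed \
  --nocall-region fig2.noncallable.bed --include-uncallable \
  --fixed-timestamp 2021-03-02T00:00:00Z
```

which prints

```
4 rows: 3 converted (3 variants, 0 phase relationships), 1 skipped -> report.json
```

The conversion region requests 10,000–12,000, 20,000–22,000, 41,000–43,000,
68,000–73,000 and 75,000–80,000; the lab studied 18,000–37,000,
46,000–58,000 and 71,000–83,000 and could not call 30,000–36,000 and
71,500–72,000. The report's single region-studied observation therefore
lists examined ranges **20,000–22,000, 71,000–73,000, 75,000–80,000** and
uncallable subregion **71,500–72,000** (30,000–36,000 is dropped because it
was never requested for conversion). A consumer can tell that a missing
call at position 11,000 means *not studied*, while a missing call at
76,000 means *homozygous reference*. The row at 55,000 sits outside the
conversion region, so `report.skips.tsv` reads:

```
row	reason
3	outside conversion region
```

## Scope

Single tested sample per run (selectable with `--sample`); structural
variants, HGVS/transcript annotation, variant normalization and any HTTP
serving are out of scope. See `docs/methods.md` for the conversion rules,
their edge cases and known limitations.
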