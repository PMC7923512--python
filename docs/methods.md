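# Methods

## Conversion model

The converter maps one single-sample VCF onto one FHIR Genomics
DiagnosticReport. The unit of translation is the VCF data row: each
convertible row yields exactly one variant observation, except a row whose
diploid genotype names two distinct alternate alleles (e.g. `GT 1/2`), which
yields two heterozygous observations. The mapping is *syntactic*: POS, REF
and ALT are copied verbatim (1-based, fully closed coordinates, declared
explicitly in every variant observation via LOINC 92822-6), with no
left-alignment, trimming or other semantic normalization — a deliberate
property, since consumers matching against knowledge bases must see exactly
what the caller wrote.

### Convertibility gate

A row converts only if all of the following hold; otherwise it is skipped
with a stable reason code written to the skip log:

* no `INFO.SVTYPE` key (structural variants are out of scope);
* all ALT alleles are plain nucleotide strings (no symbolic `<DEL>` or
  breakend notation);
* FILTER is `PASS` or `.` — the conservative clinical gate; rows the caller
  itself flagged are not propagated into a clinical document;
* the genotype is fully called (`./.` and half-calls like `1/.` are
  skipped) with ploidy 1 or 2, and every allele index resolves into the ALT
  list;
* the contig normalizes into {1..22, X, Y, MT} (both `chr1` and `1`
  dialects accepted); anything else — alt loci, unplaced scaffolds — is
  skipped, never fatal;
* mitochondrial rows must be haploid (the mitochondrial model below assumes
  haploid calls); diploid MT rows are skipped with a warning.

The gate is a total function: `converted + skipped = rows in` holds on any
input, and the stress-test suite asserts it on a 1,000-row mixed fixture.

### Allelic state

Diploid `i/j`: both zero → absent (ALT set equal to REF, the observation
valued *Absent*); equal nonzero → homozygous; one zero → heterozygous;
distinct nonzero → two heterozygous variants. Haploid: nonzero →
hemizygous, zero → absent. Sex-chromosome calls are translated exactly as
they appear — diploid X calls (common in the pseudoautosomal regions) map
through the diploid rules, haploid X/Y calls are hemizygous; no
PAR-coordinate special-casing is done because calling pipelines apply that
masking upstream.

Mitochondrial state is a function of the alt-allele fraction
`AD[called alt] / DP`: strictly greater than 0.99 → homoplasmic, otherwise
heteroplasmic. The strict inequality makes a fraction of exactly 0.99
heteroplasmic; the suite pins this boundary and the monotonicity of the
gate in AD. On multi-allelic MT rows the called allele's AD entry feeds the
ratio. When AD or DP is missing (or DP = 0) the fraction is undefined: the
variant is still emitted, with no allelic-state component, and a warning is
logged.

## Phase relationships

Only phased heterozygous variants carrying a `FORMAT.PS` value participate.
Within each (contig, phase set) group, members are ordered by position and
one relationship observation is emitted per consecutive pair — n members
give n−1 relationships, which encode the complete phasing (any other
pair's relation follows by composing the chain) without the quadratic
all-pairs blow-up. The relation is **Cis** when both variants' alternate
alleles occupy the same haplotype slot of the phased GT (`1|0` with `1|0`)
and **Trans** otherwise. Homozygous phased calls (`1|1`) never participate.
A phased compound-heterozygous row (`1|2`) contributes its two split
variants with their respective slots when a PS is present; without a PS the
two are still reported Trans to each other, since they occupy opposite
haplotypes of their own row by construction.

## Region algebra

The three optional region inputs (conversion, studied, non-callable) are
BED files (0-based half-open, shifted to 1-based closed on read; overlapping
or adjacent lines merged). Examined ranges are `conversion ∩ studied`;
uncallable subranges are `non-callable ∩ studied ∩ conversion` — a
non-callable stretch matters only where it was both requested and examined.
With no conversion region the whole file converts and the studied ranges
are reported as examined unchanged. One region-studied observation is
emitted per contig with a non-empty examined set; uncallable components are
included only when requested (`--include-uncallable`). The implementation
is a sorted-merged-interval list; the test suite checks it exactly against
a per-base membership oracle on 500 random region-set triples, plus the
commutativity/associativity/idempotence laws and the containment chain
`uncallable ⊆ examined ⊆ conversion`.

Interval endpoints are interpreted inclusively. In the shipped worked
example every expected boundary coincides under inclusive or exclusive
reading, so the convention cannot silently corrupt that scenario.

## Report document

Observations are coded from a reviewable table
(`src/vcf2report/data/loinc_codes.json`): variant observations LOINC
69548-6 with components for reference sequence (48013-7, RefSeq chromosome
accession from the build-specific table in `data/refseq_accessions.json`),
ref/alt alleles (69547-8/69551-0), exact position (81254-5), coordinate
system (92822-6), genomic source class (48002-0, germline) and allelic
state (53034-5); region-studied observations LOINC 53041-0 with 51959-5
range components; phase observations LOINC 82120-7 valued Cis/Trans and
`derivedFrom` references to the two variant observations.

Identifier assignment is deterministic (variants sorted by contig, position,
alt allele; then regions; then relationships) and serialization uses sorted
keys, so two runs on the same input are byte-identical once the issued
timestamp is pinned with `--fixed-timestamp`; by default the timestamp is
wall-clock UTC. Before writing, every document is validated against the
structural JSON-Schema shipped at `src/vcf2report/data/report.schema.json`;
validation is performed by a small in-package checker implementing exactly
the schema subset used (`type`, `enum`, `required`, `properties`, `items`,
`pattern`, local `$ref`). Identifier uniqueness and phase-reference
resolution are checked separately and refuse the write on failure.

## Synthetic fixtures

`vcf2report.fixtures` generates the test scenarios programmatically:
the three-region worked example, the two-phase-set truth table, compound
heterozygotes, sex chromosomes, mitochondrial plasmy boundaries,
absent-variant rows, structural-variant skipping, and a 1,000-row mixed
stress file drawn from a seeded RNG (fixed category weights: ~45% simple
SNVs, 12% indels, 8% compound hets, 10% homozygous-reference, and ~25%
rows that must be skipped — SVs, non-PASS, missing genotypes, unknown
contigs). The fixtures emulate genotype/region structure, not realistic
allele-frequency spectra, linkage or error profiles: passing tests
demonstrate correct translation semantics, not variant-calling accuracy on
real data. Multi-sample selection is exercised only through the
first-column default.

## Known limitations

* One tested sample per run; no joint multi-sample conversion.
* No structural variants, no HGVS or transcript-level representation, no
  annotation lookups, no VCF writing, no HTTP service.
* Half-called diploid genotypes are skipped rather than converted as
  haploid — the more conservative reading.
* Whether non-PASS rows should convert is a policy choice; the PASS-only
  gate is deliberate and logged, not configurable.
* The phasing output encodes consecutive-pair relations only; consumers
  wanting all pairs must compose the chain.
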