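"""Deterministic synthetic VCF/BED fixtures for tests and demos.

Each named scenario exercises one conversion behaviour: the worked
region-studied example (``fig2``), the published phasing truth table
(``table1_phasing``), compound heterozygotes, sex chromosomes, mitochondrial
plasmy, absent-variant rows, structural-variant skipping, and a large mixed
stress file.  Files are plain text and byte-identical for a given seed.
"""

from __future__ import annotations

import random
from pathlib import Path

SCENARIOS = (
    "fig2",
    "table1_phasing",
    "compound_het",
    "sex_chromosomes",
    "mito_plasmy",
    "absent_variant",
    "sv_skip",
    "mixed_stress",
)

_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##FILTER=<ID=q10,Description="Quality below 10">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""

# Region-studied worked example: conversion (C), studied (S) and
# uncallable (U) ranges, 1-based fully closed, all on chromosome 1.
FIG2_CONVERSION = [(10_000, 12_000), (20_000, 22_000), (41_000, 43_000),
                   (68_000, 73_000), (75_000, 80_000)]
FIG2_STUDIED = [(18_000, 37_000), (46_000, 58_000), (71_000, 83_000)]
FIG2_NONCALLABLE = [(30_000, 36_000), (71_500, 72_000)]
FIG2_EXPECTED_EXAMINED = [(20_000, 22_000), (71_000, 73_000), (75_000, 80_000)]
FIG2_EXPECTED_UNCALLABLE = [(71_500, 72_000)]

# Published phase-relationship truth table: two phase sets on chromosome 6;
# the PS-18142205 pair is TRANS (opposite haplotype slots), the PS-18142289
# pair is CIS (same slot).
TABLE1_ROWS = [
    ("6", 18142205, "C", "T", "GT:PS", "1|0:18142205"),
    ("6", 18142289, "A", "G", "GT:PS", "1|0:18142289"),
    ("6", 18142308, "A", "G", "GT:PS", "1|0:18142289"),
    ("6", 18142422, "A", "C", "GT:PS", "0|1:18142205"),
]


def _write_vcf(path: Path, rows: list[tuple], contigs: list[str],
               sample: str = "NA12878") -> None:
    contig_lines = "".join(f"##contig=<ID={c}>\n" for c in contigs)
    lines = [_HEADER.format(contigs=contig_lines, sample=sample)]
    for chrom, pos, ref, alt, fmt, call, *info in rows:
        info_text = info[0] if info else "."
        filt = info[1] if len(info) > 1 else "PASS"
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t50\t{filt}\t{info_text}\t{fmt}\t{call}\n")
    path.write_text("".join(lines))


def _write_bed(path: Path, intervals: list[tuple[int, int]], contig: str = "1") -> None:
    # internal 1-based closed -> BED 0-based half-open
    path.write_text("".join(f"{contig}\t{start - 1}\t{end}\n" for start, end in intervals))


def _fig2(out: Path, rng: random.Random) -> dict[str, Path]:
    # SNP1 (11,000) and SNP5 (76,000) have no call; SNP2/SNP3/SNP4 do.
    # The 55,000 row sits outside the conversion region and is not converted.
    rows = [
        ("1", 21_000, "G", "A", "GT", "0/1"),
        ("1", 42_000, "T", "C", "GT", "1/1"),
        ("1", 55_000, "A", "G", "GT", "0/1"),
        ("1", 71_700, "C", "T", "GT", "0/1"),
    ]
    paths = {
        "vcf": out / "fig2.vcf",
        "conversion_bed": out / "fig2.conversion.bed",
        "studied_bed": out / "fig2.studied.bed",
        "noncallable_bed": out / "fig2.noncallable.bed",
    }
    _write_vcf(paths["vcf"], rows, ["1"])
    _write_bed(paths["conversion_bed"], FIG2_CONVERSION)
    _write_bed(paths["studied_bed"], FIG2_STUDIED)
    _write_bed(paths["noncallable_bed"], FIG2_NONCALLABLE)
    return paths


def _table1_phasing(out: Path, rng: random.Random) -> dict[str, Path]:
    paths = {"vcf": out / "table1_phasing.vcf"}
    _write_vcf(paths["vcf"], TABLE1_ROWS, ["6"])
    return paths


def _compound_het(out: Path, rng: random.Random) -> dict[str, Path]:
    rows = [
        ("2", 100, "C", "T,G", "GT", "1/2"),          # unphased compound het
        ("2", 500, "A", "G,T", "GT:PS", "1|2:500"),   # phased -> row-local TRANS
        ("2", 900, "G", "A", "GT", "0/1"),            # ordinary het
    ]
    paths = {"vcf": out / "compound_het.vcf"}
    _write_vcf(paths["vcf"], rows, ["2"])
    return paths


def _sex_chromosomes(out: Path, rng: random.Random) -> dict[str, Path]:
    rows = [
        ("X", 2_700_000, "A", "G", "GT", "0/1"),   # PAR diploid -> heterozygous
        ("X", 31_220_000, "C", "T", "GT", "1"),    # non-PAR haploid -> hemizygous
        ("X", 31_230_000, "G", "A", "GT", "0"),    # haploid reference -> absent
        ("Y", 2_800_000, "T", "C", "GT", "1"),     # haploid -> hemizygous
    ]
    paths = {"vcf": out / "sex_chromosomes.vcf"}
    _write_vcf(paths["vcf"], rows, ["X", "Y"])
    return paths


def _mito_plasmy(out: Path, rng: random.Random) -> dict[str, Path]:
    rows = [
        ("MT", 73, "A", "G", "GT:AD:DP", "1:0,1000:1000"),   # 1.00 -> homoplasmic
        ("MT", 146, "T", "C", "GT:AD:DP", "1:10,990:1000"),  # 0.99 -> heteroplasmic
        ("MT", 310, "T", "C", "GT:AD:DP", "1:500,500:1000"),  # 0.50 -> heteroplasmic
        ("MT", 750, "A", "G", "GT", "1"),                     # no AD/DP -> state omitted
        ("MT", 1438, "A", "G", "GT", "0/1"),                  # diploid MT -> skipped
    ]
    paths = {"vcf": out / "mito_plasmy.vcf"}
    _write_vcf(paths["vcf"], rows, ["MT"])
    return paths


def _absent_variant(out: Path, rng: random.Random) -> dict[str, Path]:
    rows = [
        ("3", 500, "G", ".", "GT", "0/0"),
        ("3", 900, "C", "T", "GT", "0/0"),
        ("3", 1_300, "A", "C", "GT", "0/1"),
    ]
    paths = {"vcf": out / "absent_variant.vcf"}
    _write_vcf(paths["vcf"], rows, ["3"])
    return paths


def _sv_skip(out: Path, rng: random.Random) -> dict[str, Path]:
    rows = [
        ("4", 1_000, "A", "<DEL>", "GT", "0/1", "SVTYPE=DEL"),
        ("4", 2_000, "T", "TACGT", "GT", "0/1", "SVTYPE=INS"),
        ("4", 3_000, "G", "A", "GT", "0/1"),
    ]
    paths = {"vcf": out / "sv_skip.vcf"}
    _write_vcf(paths["vcf"], rows, ["4"])
    return paths


def _mixed_stress(out: Path, rng: random.Random, n_rows: int = 1000) -> dict[str, Path]:
    """A large file mixing every row category the converter must handle."""
    bases = "ACGT"
    contig_pool = [str(c) for c in range(1, 23)]
    rows: list[tuple] = []
    pos_by_contig: dict[str, int] = {}
    for _ in range(n_rows):
        kind = rng.choices(
            ["snv_het", "snv_hom", "indel", "compound", "absent", "sv",
             "nonpass", "missing_gt", "unknown_chrom", "x_haploid", "mito"],
            weights=[30, 15, 12, 8, 10, 5, 6, 5, 3, 3, 3],
        )[0]
        chrom = rng.choice(contig_pool)
        if kind == "unknown_chrom":
            chrom = "chrUn_gl000220"
        elif kind == "x_haploid":
            chrom = "X"
        elif kind == "mito":
            chrom = "MT"
        pos = pos_by_contig.get(chrom, 0) + rng.randint(50, 5_000)
        pos_by_contig[chrom] = pos
        ref = rng.choice(bases)
        alt = rng.choice([b for b in bases if b != ref])
        if kind in ("snv_het", "unknown_chrom"):
            rows.append((chrom, pos, ref, alt, "GT", rng.choice(["0/1", "1/0"])))
        elif kind == "snv_hom":
            rows.append((chrom, pos, ref, alt, "GT", "1/1"))
        elif kind == "indel":
            ins = ref + "".join(rng.choices(bases, k=rng.randint(1, 4)))
            if rng.random() < 0.5:
                rows.append((chrom, pos, ref, ins, "GT", "0/1"))
            else:
                rows.append((chrom, pos, ins, ref, "GT", "0/1"))
        elif kind == "compound":
            alt2 = rng.choice([b for b in bases if b not in (ref, alt)])
            rows.append((chrom, pos, ref, f"{alt},{alt2}", "GT", "1/2"))
        elif kind == "absent":
            rows.append((chrom, pos, ref, alt, "GT", "0/0"))
        elif kind == "sv":
            rows.append((chrom, pos, ref, "<DEL>", "GT", "0/1", "SVTYPE=DEL"))
        elif kind == "nonpass":
            rows.append((chrom, pos, ref, alt, "GT", "0/1", ".", "q10"))
        elif kind == "missing_gt":
            rows.append((chrom, pos, ref, alt, "GT", rng.choice(["./.", "1/."])))
        elif kind == "x_haploid":
            rows.append((chrom, pos, ref, alt, "GT", "1"))
        elif kind == "mito":
            dp = 1000
            ad_alt = rng.choice([1000, 995, 990, 700, 500])
            rows.append((chrom, pos, ref, alt, "GT:AD:DP", f"1:{dp - ad_alt},{ad_alt}:{dp}"))
    contig_order = {c: i for i, c in enumerate(contig_pool + ["X", "MT", "chrUn_gl000220"])}
    rows.sort(key=lambda r: (contig_order[r[0]], r[1]))
    paths = {"vcf": out / "mixed_stress.vcf"}
    _write_vcf(paths["vcf"], rows, sorted({r[0] for r in rows}, key=contig_order.get))
    return paths


_GENERATORS = {
    "fig2": _fig2,
    "table1_phasing": _table1_phasing,
    "compound_het": _compound_het,
    "sex_chromosomes": _sex_chromosomes,
    "mito_plasmy": _mito_plasmy,
    "absent_variant": _absent_variant,
    "sv_skip": _sv_skip,
    "mixed_stress": _mixed_stress,
}


def generate_fixture(scenario: str, seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write the files of a named scenario; returns a name->path mapping.

    Output is deterministic for a given (scenario, seed) pair.
    """
    if scenario not in _GENERATORS:
        raise ValueError(
            f"unknown scenario {scenario!r}; choose from: {', '.join(SCENARIOS)}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return _GENERATORS[scenario](out, random.Random(seed))
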