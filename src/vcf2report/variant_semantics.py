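"""Translate one convertible VCF row into converted variants with allelic state.

The conversion mirrors the VCF representation — same position, reference and
alternate alleles, no left-alignment or trimming ("syntactic", not semantic,
normalization).  The row's genotype decides the allelic state:

* diploid ref/alt (0/1, 1/0, 0/2 ...)  -> heterozygous
* diploid alt/alt with equal indices   -> homozygous
* diploid 0/0                          -> absent-variant (alt set equal to ref)
* diploid with two distinct alt indices (1/2) -> two heterozygous variants
* haploid non-reference                -> hemizygous
* haploid 0                            -> absent-variant
* mitochondrial haploid non-reference  -> homoplasmic / heteroplasmic by the
  alt-allele fraction AD/DP (strictly > 0.99 is homoplasmic)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .contigs import accession_for, normalize_contig
from .vcf_ingest import SampleCall, VcfRecord

log = logging.getLogger(__name__)

# allelic-state labels
HETEROZYGOUS = "heterozygous"
HOMOZYGOUS = "homozygous"
HEMIZYGOUS = "hemizygous"
HOMOPLASMIC = "homoplasmic"
HETEROPLASMIC = "heteroplasmic"
ABSENT = "absent-variant"

HOMOPLASMY_FRACTION = 0.99  # alt fraction must strictly exceed this


class SkipRecord(Exception):
    """Raised when a nominally convertible record must be skipped after all."""

    def __init__(self, reason: str) -> None:
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class ConvertedVariant:
    """One syntactically-normalized variant destined for the report."""

    contig: str
    accession: str
    pos: int
    ref_allele: str
    alt_allele: str
    allelic_state: str | None
    source_record_index: int
    phase_set: int | None = None

    @property
    def is_absent(self) -> bool:
        return self.allelic_state == ABSENT


def allelic_state_from_genotype(call: SampleCall, contig: str) -> str:
    """Allelic state of a non-mitochondrial, non-compound genotype."""
    idx = call.gt_allele_indices
    if call.is_haploid:
        return ABSENT if idx[0] == 0 else HEMIZYGOUS
    i, j = idx
    if i == 0 and j == 0:
        return ABSENT
    if i == j:
        return HOMOZYGOUS
    return HETEROZYGOUS


def mito_plasmy_state(call: SampleCall) -> str | None:
    """Homoplasmic/heteroplasmic from the called alt allele's depth fraction.

    Returns ``None`` (state omitted, variant still emitted) when AD or DP is
    missing or DP is zero — the fraction is then undefined.
    """
    allele = call.gt_allele_indices[0]
    if allele is None or allele < 1:
        raise ValueError("plasmy state requires a haploid non-reference call")
    if call.allelic_depths is None or call.read_depth is None or call.read_depth <= 0:
        log.warning("mitochondrial call lacks usable AD/DP; omitting allelic state")
        return None
    if allele >= len(call.allelic_depths):
        log.warning("AD has no entry for allele index %d; omitting allelic state", allele)
        return None
    fraction = call.allelic_depths[allele] / call.read_depth
    return HOMOPLASMIC if fraction > HOMOPLASMY_FRACTION else HETEROPLASMIC


def build_variant(
    record: VcfRecord,
    state: str | None,
    alt: str,
    build: str,
    phase_set: int | None = None,
) -> ConvertedVariant:
    """Assemble one ConvertedVariant, copying pos/ref/alt verbatim."""
    contig = normalize_contig(record.chrom)
    if contig is None:
        raise SkipRecord("unknown chromosome")
    accession = accession_for(contig, build)
    if accession is None:
        raise SkipRecord(f"no {build} accession for contig {contig}")
    return ConvertedVariant(
        contig=contig,
        accession=accession,
        pos=record.pos,
        ref_allele=record.ref_allele,
        alt_allele=alt,
        allelic_state=state,
        source_record_index=record.row_index,
        phase_set=phase_set,
    )


def split_compound_heterozygote(record: VcfRecord, build: str) -> list[ConvertedVariant]:
    """Two heterozygous variants from a diploid GT naming two alt alleles."""
    call = record.sample_call
    assert call is not None and call.is_diploid
    variants = []
    for allele in call.gt_allele_indices:
        assert allele is not None and allele >= 1
        if allele > len(record.alt_alleles):
            raise SkipRecord("GT allele index beyond ALT list")
        variants.append(
            build_variant(
                record, HETEROZYGOUS, record.alt_alleles[allele - 1], build,
                phase_set=call.phase_set,
            )
        )
    return variants


def convert_record(record: VcfRecord, build: str) -> list[ConvertedVariant]:
    """Full genotype-to-variant translation for one convertible record.

    Returns one variant, or two for a compound-heterozygous row.  Raises
    :class:`SkipRecord` for rows that turn out non-convertible here
    (allele index out of range, missing accession).
    """
    call = record.sample_call
    assert call is not None
    idx = call.gt_allele_indices
    contig = normalize_contig(record.chrom)
    if contig is None:
        raise SkipRecord("unknown chromosome")

    if any(i is not None and i > len(record.alt_alleles) for i in idx):
        raise SkipRecord("GT allele index beyond ALT list")

    if contig == "MT":
        allele = idx[0]
        if allele == 0:
            return [build_variant(record, ABSENT, record.ref_allele, build)]
        state = mito_plasmy_state(call)
        return [
            build_variant(record, state, record.alt_alleles[allele - 1], build)  # type: ignore[index]
        ]

    if call.is_diploid:
        i, j = idx
        if i != j and i != 0 and j != 0:
            return split_compound_heterozygote(record, build)

    state = allelic_state_from_genotype(call, contig)
    if state == ABSENT:
        return [
            build_variant(record, ABSENT, record.ref_allele, build, phase_set=call.phase_set)
        ]
    called_alt = max(i for i in idx if i is not None)
    return [
        build_variant(
            record, state, record.alt_alleles[called_alt - 1], build,
            phase_set=call.phase_set,
        )
    ]
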