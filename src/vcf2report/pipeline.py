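"""End-to-end conversion: VCF + BED regions -> genomics report JSON.

Every input data row is accounted for: it either contributes converted
variants or appears in the skip log with a stable reason code, so
``rows in == rows converted + rows skipped`` holds on any input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import phasing, report_builder, vcf_ingest
from .contigs import SUPPORTED_BUILDS, normalize_contig
from .phasing import PhasedMember, PhaseRelationship
from .region_algebra import RegionSet, read_regions
from .variant_semantics import (
    ConvertedVariant,
    HETEROZYGOUS,
    SkipRecord,
    convert_record,
)

log = logging.getLogger(__name__)

REASON_OUTSIDE_REGION = "outside conversion region"


@dataclass(frozen=True)
class ConversionConfig:
    """Validated parameters of one conversion run."""

    vcf_path: Path
    build: str
    output_path: Path
    conversion_bed: Path | None = None
    studied_bed: Path | None = None
    noncallable_bed: Path | None = None
    include_uncallable: bool = False
    sample_name: str | None = None
    patient_id: str | None = None
    fixed_timestamp: str | None = None

    def __post_init__(self) -> None:
        if self.build not in SUPPORTED_BUILDS:
            raise ValueError(
                f"unknown genome build {self.build!r}; "
                f"allowed values: {', '.join(SUPPORTED_BUILDS)}"
            )
        if self.noncallable_bed is not None and self.studied_bed is None:
            raise ValueError(
                "a non-callable region requires a studied region "
                "(uncallable ranges are subsets of studied ranges)"
            )


@dataclass
class ConversionOutcome:
    """What one run produced, for callers and the skip log."""

    report: report_builder.GenomicsReport
    document: str
    variants: list[ConvertedVariant]
    relationships: list[PhaseRelationship]
    rows_total: int = 0
    rows_converted: int = 0
    skips: list[tuple[int, str]] = field(default_factory=list)


def _phased_members(
    variants: list[ConvertedVariant], record: vcf_ingest.VcfRecord
) -> tuple[list[PhasedMember], list[PhaseRelationship]]:
    """Phase-set members (and PS-less row-local relations) for one row."""
    call = record.sample_call
    assert call is not None
    if not call.gt_phased or not call.is_diploid:
        return [], []
    het = [v for v in variants if v.allelic_state == HETEROZYGOUS]
    members: list[PhasedMember] = []
    locals_: list[PhaseRelationship] = []
    if call.phase_set is not None:
        for variant in het:
            # GT allele index (1-based into ALT) that produced this variant,
            # then the haplotype slot that carries it
            allele = record.alt_alleles.index(variant.alt_allele) + 1
            members.append(
                PhasedMember(
                    variant=variant,
                    haplotype_slot=call.gt_allele_indices.index(allele),
                    phase_set=call.phase_set,
                )
            )
    elif len(het) == 2:
        # phased compound het with no PS: the two alleles are on opposite
        # haplotypes of this row by construction
        locals_.append(
            PhaseRelationship(first=het[0], second=het[1],
                              relation=phasing.TRANS, phase_set=None)
        )
    return members, locals_


def convert(config: ConversionConfig) -> ConversionOutcome:
    """Run the full conversion and return the outcome (nothing written)."""
    conversion = read_regions(config.conversion_bed) if config.conversion_bed else None
    studied = read_regions(config.studied_bed) if config.studied_bed else None
    noncallable = (
        read_regions(config.noncallable_bed) if config.noncallable_bed else RegionSet()
    )

    meta, records = vcf_ingest.open_vcf(
        config.vcf_path, config.build, config.sample_name
    )
    patient_id = config.patient_id or config.sample_name or (
        meta.sample_names[0] if meta.sample_names else "unknown"
    )

    variants: list[ConvertedVariant] = []
    members: list[PhasedMember] = []
    relationships: list[PhaseRelationship] = []
    skips: list[tuple[int, str]] = []
    rows = converted = 0

    for record in records:
        rows += 1
        ok, reason = vcf_ingest.is_convertible(record)
        if not ok:
            skips.append((record.row_index, reason or "not convertible"))
            continue
        if conversion is not None and not conversion.contains(
            normalize_contig(record.chrom), record.pos
        ):
            skips.append((record.row_index, REASON_OUTSIDE_REGION))
            continue
        try:
            row_variants = convert_record(record, config.build)
        except SkipRecord as exc:
            log.warning("row %d skipped: %s", record.row_index, exc.reason)
            skips.append((record.row_index, exc.reason))
            continue
        converted += 1
        variants.extend(row_variants)
        row_members, row_locals = _phased_members(row_variants, record)
        members.extend(row_members)
        relationships.extend(row_locals)

    groups = phasing.group_by_phase_set(members)
    relationships.extend(phasing.emit_phase_relationships(groups))

    region_obs: list[report_builder.RegionStudiedResult] = []
    if studied is not None and studied:
        region_obs = report_builder.build_region_studied(
            conversion, studied, noncallable, config.include_uncallable, config.build
        )

    report = report_builder.assemble_report(
        variants, relationships, region_obs, patient_id,
        issued=config.fixed_timestamp,
    )
    document = report_builder.serialize(report)
    return ConversionOutcome(
        report=report,
        document=document,
        variants=report.variants,
        relationships=report.relationships,
        rows_total=rows,
        rows_converted=converted,
        skips=skips,
    )


def run_conversion(config: ConversionConfig) -> ConversionOutcome:
    """Convert and write the report plus a per-row skip log beside it."""
    outcome = convert(config)
    config.output_path.parent.mkdir(parents=True, exist_ok=True)
    config.output_path.write_text(outcome.document)
    log_path = config.output_path.with_suffix(".skips.tsv")
    with open(log_path, "w") as handle:
        handle.write("row\treason\n")
        for row_index, reason in outcome.skips:
            handle.write(f"{row_index}\t{reason}\n")
    log.info(
        "%d rows: %d converted (%d variants), %d skipped",
        outcome.rows_total, outcome.rows_converted,
        len(outcome.variants), len(outcome.skips),
    )
    return outcome
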