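"""Cis/trans sequence-phase relationships between phased heterozygous variants.

Two heterozygous variants in the same phase set (FORMAT.PS) are *cis* when
their alternate alleles sit on the same haplotype — the non-reference allele
occupies the same slot of the phased GT vector in both rows (1|0 with 1|0) —
and *trans* when they sit on opposite haplotypes (1|0 with 0|1).

Within each (contig, phase set) group the converter emits one relationship
per consecutive position-ordered pair: n phased members give n-1
relationships, which convey the complete phasing (any other pair's relation
is derivable by composing the chain).
"""

from __future__ import annotations

from dataclasses import dataclass

from .variant_semantics import ConvertedVariant, HETEROZYGOUS
from .vcf_ingest import SampleCall

CIS = "CIS"
TRANS = "TRANS"


@dataclass(frozen=True)
class PhasedMember:
    """A heterozygous variant's seat in a phase set."""

    variant: ConvertedVariant
    haplotype_slot: int  # index of the variant's alt allele in the phased GT
    phase_set: int


@dataclass(frozen=True)
class PhaseRelationship:
    first: ConvertedVariant
    second: ConvertedVariant
    relation: str  # CIS or TRANS
    phase_set: int | None


def haplotype_slot(call: SampleCall) -> int:
    """Slot (0 or 1) carrying the non-reference allele of a phased het call."""
    nonzero = [k for k, allele in enumerate(call.gt_allele_indices) if allele]
    if len(nonzero) != 1:
        raise ValueError("haplotype slot requires exactly one non-reference allele")
    return nonzero[0]


def phase_relation(call_a: SampleCall, call_b: SampleCall) -> str:
    """CIS when both alt alleles share a haplotype slot, TRANS otherwise."""
    return CIS if haplotype_slot(call_a) == haplotype_slot(call_b) else TRANS


def group_by_phase_set(
    members: list[PhasedMember],
) -> dict[tuple[str, int], list[PhasedMember]]:
    """Group phased heterozygous variants by (contig, phase set).

    Only heterozygous members belong here (homozygous phased calls such as
    1|1 never participate); each group comes out position-sorted.
    """
    groups: dict[tuple[str, int], list[PhasedMember]] = {}
    for member in members:
        if member.variant.allelic_state != HETEROZYGOUS:
            continue
        key = (member.variant.contig, member.phase_set)
        groups.setdefault(key, []).append(member)
    for key in groups:
        groups[key].sort(key=lambda m: (m.variant.pos, m.variant.alt_allele))
    return dict(sorted(groups.items()))


def emit_phase_relationships(
    groups: dict[tuple[str, int], list[PhasedMember]],
) -> list[PhaseRelationship]:
    """One relationship per consecutive position-ordered pair in each group."""
    relationships: list[PhaseRelationship] = []
    for (_contig, phase_set), members in groups.items():
        for left, right in zip(members, members[1:]):
            relation = CIS if left.haplotype_slot == right.haplotype_slot else TRANS
            relationships.append(
                PhaseRelationship(
                    first=left.variant,
                    second=right.variant,
                    relation=relation,
                    phase_set=phase_set,
                )
            )
    return relationships
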