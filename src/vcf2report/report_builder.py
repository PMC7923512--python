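"""Assemble converted variants, phase relationships and region-studied
results into one genomics diagnostic report and serialize it as JSON.

The document follows the HL7 FHIR Genomics reporting shapes: a
DiagnosticReport containing Observation resources for variants
(LOINC 69548-6), regions studied (LOINC 53041-0) and sequence-phase
relationships (LOINC 82120-7).  Observation components are labeled by LOINC
codes drawn from a reviewable code table shipped with the package
(``data/loinc_codes.json``) rather than hard-coded strings.

Serialization is deterministic (sorted keys, fixed identifier assignment) so
two runs on identical input produce byte-identical files once the issued
timestamp is pinned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from functools import lru_cache
from importlib import resources
from pathlib import Path

from .phasing import PhaseRelationship
from .region_algebra import GenomicInterval, RegionSet, intersect, uncallable_within
from .contigs import accession_for
from .variant_semantics import ConvertedVariant
from . import schema as _schema

_CONTIG_ORDER = {c: i for i, c in enumerate([str(n) for n in range(1, 23)] + ["X", "Y", "MT"])}


@lru_cache(maxsize=None)
def code_table() -> dict:
    text = resources.files("vcf2report").joinpath("data/loinc_codes.json").read_text()
    return json.loads(text)


class ReportConsistencyError(ValueError):
    """Internal inconsistency (dangling reference, duplicate id) — a pipeline bug."""


@dataclass(frozen=True)
class RegionStudiedResult:
    """Per-contig examined ranges and their uncallable subranges."""

    contig: str
    accession: str
    ranges_examined: tuple[GenomicInterval, ...]
    uncallable_subregions: tuple[GenomicInterval, ...]


@dataclass
class GenomicsReport:
    """The assembled diagnostic report prior to serialization."""

    patient_id: str
    issued: str
    variants: list[ConvertedVariant] = field(default_factory=list)
    relationships: list[PhaseRelationship] = field(default_factory=list)
    region_studied: list[RegionStudiedResult] = field(default_factory=list)


def build_region_studied(
    conversion: RegionSet | None,
    studied: RegionSet,
    noncallable: RegionSet,
    include_uncallable: bool,
    build: str,
) -> list[RegionStudiedResult]:
    """One observation per contig with a non-empty studied∩conversion.

    With no conversion region the whole genome is in scope, so the examined
    ranges are the studied ranges themselves.
    """
    if conversion is None:
        examined = studied
        uncallable = noncallable.intersect(studied)
    else:
        examined = intersect(conversion, studied)
        uncallable = uncallable_within(conversion, studied, noncallable)

    results: list[RegionStudiedResult] = []
    for contig in examined.contigs:
        accession = accession_for(contig, build)
        if accession is None:
            continue
        results.append(
            RegionStudiedResult(
                contig=contig,
                accession=accession,
                ranges_examined=tuple(examined.intervals(contig)),
                uncallable_subregions=(
                    tuple(uncallable.intervals(contig)) if include_uncallable else ()
                ),
            )
        )
    return results


def assemble_report(
    variants: list[ConvertedVariant],
    relationships: list[PhaseRelationship],
    region_obs: list[RegionStudiedResult],
    patient_id: str,
    issued: str | None = None,
) -> GenomicsReport:
    """Order the inputs deterministically and check internal consistency."""
    ordered = sorted(
        variants,
        key=lambda v: (_CONTIG_ORDER.get(v.contig, 99), v.pos, v.alt_allele,
                       v.source_record_index),
    )
    known = set(id(v) for v in ordered)
    for rel in relationships:
        if id(rel.first) not in known or id(rel.second) not in known:
            raise ReportConsistencyError(
                "phase relationship references a variant not in the report"
            )
    ordered_regions = sorted(region_obs, key=lambda r: _CONTIG_ORDER.get(r.contig, 99))
    ordered_rels = sorted(
        relationships,
        key=lambda r: (_CONTIG_ORDER.get(r.first.contig, 99), r.first.pos,
                       r.second.pos, r.first.alt_allele, r.second.alt_allele),
    )
    if issued is None:
        issued = datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
    return GenomicsReport(
        patient_id=patient_id,
        issued=issued,
        variants=ordered,
        relationships=ordered_rels,
        region_studied=ordered_regions,
    )


# ---------------------------------------------------------------------------
# JSON rendering


def _concept(entry: dict, system_key: str = "loinc") -> dict:
    codes = code_table()
    system = codes["systems"][entry.get("system", system_key)]
    return {
        "coding": [{"system": system, "code": entry["code"], "display": entry["display"]}]
    }


def _component(kind: str, value: dict) -> dict:
    codes = code_table()
    return {"code": _concept(codes["components"][kind]), **value}


def variant_observation(variant: ConvertedVariant, obs_id: str) -> dict:
    codes = code_table()
    components = [
        _component("reference_sequence", {
            "valueCodeableConcept": {"coding": [{
                "system": "http://www.ncbi.nlm.nih.gov/nuccore",
                "code": variant.accession,
                "display": variant.accession,
            }]}
        }),
        _component("reference_allele", {"valueString": variant.ref_allele}),
        _component("alternate_allele", {"valueString": variant.alt_allele}),
        _component("exact_position", {
            "valueRange": {"low": {"value": variant.pos}}
        }),
        _component("coordinate_system", {
            "valueCodeableConcept": _concept(codes["coordinate_system_1_based"])
        }),
        _component("genomic_source_class", {
            "valueCodeableConcept": _concept(codes["genomic_source_germline"])
        }),
    ]
    if variant.allelic_state is not None and not variant.is_absent:
        components.append(_component("allelic_state", {
            "valueCodeableConcept": _concept(codes["allelic_states"][variant.allelic_state])
        }))
    presence = codes["variant_absent"] if variant.is_absent else codes["variant_present"]
    return {
        "resourceType": "Observation",
        "id": obs_id,
        "status": "final",
        "category": [{"coding": [{
            "system": codes["systems"]["observation_category"],
            "code": "laboratory",
        }]}],
        "code": _concept(codes["variant_code"]),
        "valueCodeableConcept": _concept(presence),
        "component": components,
    }


def region_studied_observation(region: RegionStudiedResult, obs_id: str) -> dict:
    codes = code_table()
    components = [
        _component("reference_sequence", {
            "valueCodeableConcept": {"coding": [{
                "system": "http://www.ncbi.nlm.nih.gov/nuccore",
                "code": region.accession,
                "display": region.accession,
            }]}
        }),
    ]
    for iv in region.ranges_examined:
        components.append(_component("ranges_examined", {
            "valueRange": {"low": {"value": iv.start}, "high": {"value": iv.end}}
        }))
    for iv in region.uncallable_subregions:
        components.append(_component("uncallable_region", {
            "valueRange": {"low": {"value": iv.start}, "high": {"value": iv.end}}
        }))
    return {
        "resourceType": "Observation",
        "id": obs_id,
        "status": "final",
        "category": [{"coding": [{
            "system": codes["systems"]["observation_category"],
            "code": "laboratory",
        }]}],
        "code": _concept(codes["region_studied_code"]),
        "component": components,
    }


def phase_observation(rel: PhaseRelationship, obs_id: str,
                      first_id: str, second_id: str) -> dict:
    codes = code_table()
    return {
        "resourceType": "Observation",
        "id": obs_id,
        "status": "final",
        "category": [{"coding": [{
            "system": codes["systems"]["observation_category"],
            "code": "laboratory",
        }]}],
        "code": _concept(codes["phase_code"]),
        "valueCodeableConcept": _concept(codes["phase_relations"][rel.relation]),
        "derivedFrom": [{"reference": f"#{first_id}"}, {"reference": f"#{second_id}"}],
    }


def render(report: GenomicsReport) -> dict:
    """Render the report as a FHIR DiagnosticReport JSON document."""
    codes = code_table()
    variant_ids: dict[int, str] = {}
    contained: list[dict] = []
    for n, variant in enumerate(report.variants, start=1):
        obs_id = f"variant-{n}"
        variant_ids[id(variant)] = obs_id
        contained.append(variant_observation(variant, obs_id))
    for n, region in enumerate(report.region_studied, start=1):
        contained.append(region_studied_observation(region, f"region-studied-{n}"))
    for n, rel in enumerate(report.relationships, start=1):
        try:
            first_id = variant_ids[id(rel.first)]
            second_id = variant_ids[id(rel.second)]
        except KeyError as exc:
            raise ReportConsistencyError(
                "phase relationship references a variant not in the report"
            ) from exc
        contained.append(phase_observation(rel, f"phase-{n}", first_id, second_id))

    ids = [obs["id"] for obs in contained]
    if len(ids) != len(set(ids)):
        raise ReportConsistencyError("observation identifiers are not unique")

    return {
        "resourceType": "DiagnosticReport",
        "status": "final",
        "code": _concept(codes["report_code"]),
        "subject": {"reference": f"Patient/{report.patient_id}"},
        "issued": report.issued,
        "contained": contained,
        "result": [{"reference": f"#{obs_id}"} for obs_id in ids],
    }


def serialize(report: GenomicsReport, path: str | Path | None = None) -> str:
    """Render, validate against the shipped schema, and optionally write.

    Key order is sorted so the output is byte-stable; an invalid report is
    refused before anything is written.
    """
    document = render(report)
    _schema.validate_report(document)
    text = json.dumps(document, indent=2, sort_keys=True) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
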