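"""Canonical contig vocabulary and build-specific RefSeq accession lookup.

Chromosome names arrive in two common dialects (``chr1`` vs ``1``,
``chrM``/``M`` vs ``MT``).  Everything downstream of ingestion works with a
canonical vocabulary {1..22, X, Y, MT}; the per-build accession table maps a
canonical contig to the RefSeq chromosome accession embedded in the report.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

SUPPORTED_BUILDS = ("GRCh37", "GRCh38")

CANONICAL_CONTIGS: frozenset[str] = frozenset(
    [str(i) for i in range(1, 23)] + ["X", "Y", "MT"]
)


def normalize_contig(chrom: str) -> str | None:
    """Map a VCF CHROM value onto the canonical vocabulary.

    Returns ``None`` for contigs outside {1..22, X, Y, MT} (alt loci,
    unplaced scaffolds, decoys ...); callers skip such rows rather than fail.
    """
    name = chrom.strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    name = name.upper()
    if name == "M":
        name = "MT"
    return name if name in CANONICAL_CONTIGS else None


@lru_cache(maxsize=None)
def _accession_table() -> dict[str, dict[str, str]]:
    text = resources.files("vcf2report").joinpath("data/refseq_accessions.json").read_text()
    return json.loads(text)


def accession_for(contig: str, build: str) -> str | None:
    """RefSeq accession of a canonical contig under a genome build."""
    if build not in SUPPORTED_BUILDS:
        raise ValueError(
            f"unsupported genome build {build!r}; allowed: {', '.join(SUPPORTED_BUILDS)}"
        )
    return _accession_table()[build].get(contig)
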