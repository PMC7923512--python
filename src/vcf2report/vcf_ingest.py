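"""Read plain-text or bgzipped VCF files into validated records.

pysam (htslib) does the heavy lifting — header parsing, BGZF decompression,
iteration.  The fields the conversion consumes (CHROM, POS, REF, ALT, FILTER,
INFO keys, and the tested sample's GT/PS/AD/DP) are re-split from the raw
record text so they mirror the file byte-for-byte: the converter mirrors the
VCF representation and must not inherit any library-side re-formatting.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pysam

from .contigs import SUPPORTED_BUILDS, normalize_contig

log = logging.getLogger(__name__)

_NUCLEOTIDES = re.compile(r"^[ACGTNacgtn]+$")


class VcfParseError(ValueError):
    """Malformed VCF content that prevents any conversion."""


@dataclass(frozen=True)
class VcfMeta:
    """Header facts the pipeline needs before the first data line."""

    fileformat_version: str
    contig_names: tuple[str, ...]
    sample_names: tuple[str, ...]


@dataclass(frozen=True)
class SampleCall:
    """The tested sample's genotype fields for one row.

    ``gt_allele_indices`` holds ``None`` for missing alleles ('.').
    """

    gt_allele_indices: tuple[int | None, ...]
    gt_phased: bool
    phase_set: int | None = None
    allelic_depths: tuple[int, ...] | None = None
    read_depth: int | None = None

    @property
    def is_haploid(self) -> bool:
        return len(self.gt_allele_indices) == 1

    @property
    def is_diploid(self) -> bool:
        return len(self.gt_allele_indices) == 2


@dataclass(frozen=True)
class VcfRecord:
    """One VCF data line plus the tested sample's call, mirrored verbatim."""

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    filter_status: str
    info_keys: frozenset[str]
    sample_call: SampleCall | None
    row_index: int  # 1-based data-line ordinal in the source file


# ---------------------------------------------------------------------------
# reason codes for skipped rows (is_convertible is total: it never raises)

REASON_STRUCTURAL = "structural-variant row"
REASON_SYMBOLIC_ALT = "symbolic or breakend ALT allele"
REASON_MISSING_GT = "missing genotype"
REASON_FILTER = "FILTER not PASS"
REASON_UNKNOWN_CHROM = "unknown chromosome"
REASON_BAD_REF = "REF not a nucleotide string"
REASON_BAD_PLOIDY = "genotype ploidy not 1 or 2"
REASON_ALLELE_RANGE = "GT allele index beyond ALT list"
REASON_MITO_DIPLOID = "diploid call on mitochondrial contig"
REASON_MALFORMED_CALL = "unparseable sample FORMAT fields"


def parse_sample_call(
    gt_text: str,
    ps_text: str | None = None,
    ad_text: str | None = None,
    dp_text: str | None = None,
) -> SampleCall:
    """Parse the tested sample's GT (plus optional PS/AD/DP) strings.

    Raises :class:`VcfParseError` on syntax the VCF spec does not allow;
    callers treat that as a skippable row, never a crash.
    """
    gt_text = gt_text.strip()
    if not gt_text:
        raise VcfParseError("empty GT field")
    phased = "|" in gt_text
    parts = re.split(r"[/|]", gt_text)
    indices: list[int | None] = []
    for part in parts:
        if part == ".":
            indices.append(None)
        elif part.isdigit():
            indices.append(int(part))
        else:
            raise VcfParseError(f"unparseable GT {gt_text!r}")

    phase_set: int | None = None
    if ps_text not in (None, "", "."):
        try:
            phase_set = int(ps_text)
        except ValueError as exc:
            raise VcfParseError(f"unparseable PS {ps_text!r}") from exc

    depths: tuple[int, ...] | None = None
    if ad_text not in (None, "", "."):
        try:
            depths = tuple(0 if tok == "." else int(tok) for tok in ad_text.split(","))
        except ValueError as exc:
            raise VcfParseError(f"unparseable AD {ad_text!r}") from exc

    read_depth: int | None = None
    if dp_text not in (None, "", "."):
        try:
            read_depth = int(dp_text)
        except ValueError as exc:
            raise VcfParseError(f"unparseable DP {dp_text!r}") from exc

    return SampleCall(
        gt_allele_indices=tuple(indices),
        gt_phased=phased,
        phase_set=phase_set,
        allelic_depths=depths,
        read_depth=read_depth,
    )


def _parse_info_keys(info_text: str) -> frozenset[str]:
    if info_text in (".", ""):
        return frozenset()
    return frozenset(item.split("=", 1)[0] for item in info_text.split(";") if item)


def _record_from_line(line: str, sample_column: int, row_index: int) -> VcfRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 8:
        raise VcfParseError(f"data line {row_index}: fewer than 8 columns")
    chrom, pos_text, _id, ref, alt, _qual, filt, info = fields[:8]
    try:
        pos = int(pos_text)
    except ValueError as exc:
        raise VcfParseError(f"data line {row_index}: non-integer POS {pos_text!r}") from exc
    alts: tuple[str, ...] = () if alt == "." else tuple(alt.split(","))

    call: SampleCall | None = None
    if len(fields) > sample_column and len(fields) > 8:
        fmt_keys = fields[8].split(":")
        sample_values = fields[sample_column].split(":")
        sample = dict(zip(fmt_keys, sample_values))
        gt = sample.get("GT")
        if gt is not None:
            call = parse_sample_call(gt, sample.get("PS"), sample.get("AD"), sample.get("DP"))

    return VcfRecord(
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_alleles=alts,
        filter_status=filt,
        info_keys=_parse_info_keys(info),
        sample_call=call,
        row_index=row_index,
    )


def read_meta(path: str | Path) -> VcfMeta:
    """Header-only read; validates the fileformat version."""
    with pysam.VariantFile(str(path)) as vf:
        version = vf.header.version
        meta = VcfMeta(
            fileformat_version=version,
            contig_names=tuple(vf.header.contigs),
            sample_names=tuple(vf.header.samples),
        )
    if not meta.fileformat_version.startswith("VCFv4"):
        raise VcfParseError(
            f"unsupported fileformat {meta.fileformat_version!r} (need VCFv4.x)"
        )
    return meta


def open_vcf(
    path: str | Path,
    build: str,
    sample_name: str | None = None,
) -> tuple[VcfMeta, Iterator[VcfRecord]]:
    """Open a plain or bgzipped VCF and stream records in file order.

    ``build`` must be one of the supported genome builds; it is validated
    here so a bad build fails before any parsing work.  ``sample_name``
    selects the tested sample among the header's sample columns (default:
    the first one).
    """
    if build not in SUPPORTED_BUILDS:
        raise ValueError(
            f"unknown genome build {build!r}; allowed values: {', '.join(SUPPORTED_BUILDS)}"
        )
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF file not found: {path}")
    meta = read_meta(path)

    if sample_name is None:
        sample_index = 0
    else:
        if sample_name not in meta.sample_names:
            raise ValueError(
                f"sample {sample_name!r} not in VCF samples {list(meta.sample_names)}"
            )
        sample_index = meta.sample_names.index(sample_name)
    sample_column = 9 + sample_index

    def records() -> Iterator[VcfRecord]:
        with pysam.VariantFile(str(path)) as vf:
            for row_index, rec in enumerate(vf, start=1):
                try:
                    yield _record_from_line(str(rec), sample_column, row_index)
                except VcfParseError as exc:
                    log.warning("skipping row %d: %s", row_index, exc)
                    # surfaced as a non-convertible placeholder so callers
                    # can account for every input row
                    yield VcfRecord(
                        chrom="?", pos=0, ref_allele="", alt_alleles=(),
                        filter_status=".", info_keys=frozenset(),
                        sample_call=None, row_index=row_index,
                    )

    return meta, records()


def is_convertible(record: VcfRecord) -> tuple[bool, str | None]:
    """Decide whether a row can be converted; total, never raises.

    Returns ``(True, None)`` or ``(False, reason)`` with a stable,
    machine-readable reason code.
    """
    if "SVTYPE" in record.info_keys:
        return False, REASON_STRUCTURAL
    if normalize_contig(record.chrom) is None:
        return False, REASON_UNKNOWN_CHROM
    for alt in record.alt_alleles:
        if not _NUCLEOTIDES.match(alt):
            return False, REASON_SYMBOLIC_ALT
    if record.pos < 1 or not _NUCLEOTIDES.match(record.ref_allele or ""):
        return False, REASON_BAD_REF
    if record.filter_status not in ("PASS", "."):
        return False, REASON_FILTER
    call = record.sample_call
    if call is None:
        return False, REASON_MALFORMED_CALL
    if len(call.gt_allele_indices) not in (1, 2):
        return False, REASON_BAD_PLOIDY
    if any(idx is None for idx in call.gt_allele_indices):
        # wholly missing (./.) and half-calls (1/.) alike are skipped
        return False, REASON_MISSING_GT
    if any(idx > len(record.alt_alleles) for idx in call.gt_allele_indices):  # type: ignore[operator]
        return False, REASON_ALLELE_RANGE
    if normalize_contig(record.chrom) == "MT" and call.is_diploid:
        return False, REASON_MITO_DIPLOID
    return True, None
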