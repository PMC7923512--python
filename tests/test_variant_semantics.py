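"""Genotype -> allelic state translation, compound-het splitting, plasmy."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from vcf2report import (
    ABSENT,
    HEMIZYGOUS,
    HETEROPLASMIC,
    HETEROZYGOUS,
    HOMOPLASMIC,
    HOMOZYGOUS,
    allelic_state_from_genotype,
    convert_record,
    mito_plasmy_state,
    split_compound_heterozygote,
)
from vcf2report.variant_semantics import SkipRecord
from vcf2report.vcf_ingest import SampleCall, VcfRecord


def record(chrom="7", pos=100, ref="C", alts=("T", "G"), gt=(0, 1), phased=False,
           ps=None, ad=None, dp=None):
    return VcfRecord(
        chrom=chrom, pos=pos, ref_allele=ref, alt_alleles=alts,
        filter_status="PASS", info_keys=frozenset(),
        sample_call=SampleCall(gt, phased, phase_set=ps, allelic_depths=ad,
                               read_depth=dp),
        row_index=1,
    )


# -- exhaustive genotype truth table -----------------------------------------

def oracle_state(indices):
    """Independent statement of the zygosity rules, written directly from them."""
    if len(indices) == 1:
        return ABSENT if indices[0] == 0 else HEMIZYGOUS
    i, j = indices
    if i == 0 and j == 0:
        return ABSENT
    if i == j:
        return HOMOZYGOUS
    return HETEROZYGOUS


@pytest.mark.parametrize(
    "indices",
    [(i, j) for i, j in itertools.product(range(3), range(3))] + [(0,), (1,), (2,)],
)
def test_allelic_state_matches_truth_table(indices):
    call = SampleCall(indices, False)
    assert allelic_state_from_genotype(call, "7") == oracle_state(indices)


@pytest.mark.parametrize(
    "indices",
    [(i, j) for i, j in itertools.product(range(3), range(3))] + [(0,), (1,), (2,)],
)
def test_emitted_variant_count_over_all_genotypes(indices):
    """Two variants iff the diploid GT names two distinct alt alleles."""
    rec = record(gt=indices)
    variants = convert_record(rec, "GRCh37")
    compound = len(indices) == 2 and indices[0] != indices[1] and 0 not in indices
    assert len(variants) == (2 if compound else 1)
    for v in variants:
        # mirror property: pos/ref verbatim, alt from the row (or ref when absent)
        assert v.pos == rec.pos and v.ref_allele == rec.ref_allele
        assert v.alt_allele in rec.alt_alleles or v.alt_allele == rec.ref_allele
        assert (v.alt_allele == v.ref_allele) == (v.allelic_state == ABSENT)


def test_compound_het_splits_into_two_heterozygous_variants():
    variants = split_compound_heterozygote(record(gt=(1, 2)), "GRCh37")
    assert [(v.ref_allele, v.alt_allele, v.allelic_state, v.pos) for v in variants] == [
        ("C", "T", HETEROZYGOUS, 100),
        ("C", "G", HETEROZYGOUS, 100),
    ]
    assert variants[0].source_record_index == variants[1].source_record_index


def test_allele_index_beyond_alt_list_is_skipped():
    with pytest.raises(SkipRecord, match="beyond ALT"):
        convert_record(record(alts=("T",), gt=(1, 2)), "GRCh37")


def test_haploid_calls_on_sex_chromosomes():
    assert convert_record(record(chrom="X", gt=(1,)), "GRCh37")[0].allelic_state == HEMIZYGOUS
    assert convert_record(record(chrom="Y", gt=(1,)), "GRCh37")[0].allelic_state == HEMIZYGOUS
    absent = convert_record(record(chrom="X", gt=(0,)), "GRCh37")[0]
    assert absent.allelic_state == ABSENT
    assert absent.alt_allele == absent.ref_allele


def test_absent_variant_sets_alt_equal_to_ref():
    variant = convert_record(record(gt=(0, 0), ref="G", alts=("A",)), "GRCh37")[0]
    assert variant.allelic_state == ABSENT
    assert variant.alt_allele == variant.ref_allele == "G"


def test_padded_indel_is_mirrored_not_normalized():
    variant = convert_record(record(ref="AT", alts=("A",), gt=(0, 1)), "GRCh37")[0]
    assert (variant.ref_allele, variant.alt_allele, variant.pos) == ("AT", "A", 100)


def test_accession_follows_build():
    rec = record(chrom="chr6", pos=18142205, ref="C", alts=("T",), gt=(0, 1))
    assert convert_record(rec, "GRCh37")[0].accession == "NC_000006.11"
    assert convert_record(rec, "GRCh38")[0].accession == "NC_000006.12"


# -- mitochondrial plasmy ----------------------------------------------------

@pytest.mark.parametrize(
    "ad, dp, expected",
    [
        ((0, 1000), 1000, HOMOPLASMIC),    # fraction 1.0
        ((10, 990), 1000, HETEROPLASMIC),  # exactly 0.99: not strictly greater
        ((9, 991), 1000, HOMOPLASMIC),     # just above the gate
        ((500, 500), 1000, HETEROPLASMIC),
    ],
)
def test_plasmy_threshold_boundary(ad, dp, expected):
    call = SampleCall((1,), False, allelic_depths=ad, read_depth=dp)
    assert mito_plasmy_state(call) == expected


def test_plasmy_state_omitted_without_depths():
    call = SampleCall((1,), False)
    assert mito_plasmy_state(call) is None
    variant = convert_record(record(chrom="MT", gt=(1,)), "GRCh37")[0]
    assert variant.allelic_state is None  # variant still emitted


def test_plasmy_uses_called_alt_depth_on_multiallelic_rows():
    call = SampleCall((2,), False, allelic_depths=(0, 5, 995), read_depth=1000)
    assert mito_plasmy_state(call) == HOMOPLASMIC


@settings(max_examples=200, deadline=None, derandomize=True)
@given(dp=st.integers(1, 10_000), ad=st.integers(0, 10_000), bump=st.integers(0, 500))
def test_plasmy_monotone_in_alt_depth(dp, ad, bump):
    """Raising AD at fixed DP never moves homoplasmic back to heteroplasmic."""
    low = SampleCall((1,), False, allelic_depths=(0, min(ad, dp)), read_depth=dp)
    high = SampleCall((1,), False, allelic_depths=(0, min(ad + bump, dp)), read_depth=dp)
    if mito_plasmy_state(low) == HOMOPLASMIC:
        assert mito_plasmy_state(high) == HOMOPLASMIC
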