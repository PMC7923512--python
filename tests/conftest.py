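from pathlib import Path

import pytest

from vcf2report import ConversionConfig, generate_fixture, run_conversion

FIXED_TS = "2021-03-02T00:00:00Z"


@pytest.fixture
def scenario_runner(tmp_path):
    """Generate a named scenario and run the full conversion on it."""

    def run(scenario: str, seed: int = 0, build: str = "GRCh37", **overrides):
        paths = generate_fixture(scenario, seed, tmp_path / scenario)
        config = ConversionConfig(
            vcf_path=paths["vcf"],
            build=build,
            output_path=tmp_path / scenario / "report.json",
            conversion_bed=paths.get("conversion_bed"),
            studied_bed=paths.get("studied_bed"),
            noncallable_bed=paths.get("noncallable_bed"),
            include_uncallable="noncallable_bed" in paths,
            fixed_timestamp=FIXED_TS,
            **overrides,
        )
        return run_conversion(config)

    return run


@pytest.fixture
def write_vcf(tmp_path):
    """Write a minimal single-sample VCF from (chrom, pos, ref, alt, fmt, call[, info[, filter]]) rows."""

    header = (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n'
        '##FILTER=<ID=q10,Description="low qual">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE1\n"
    )

    def write(rows, name="test.vcf") -> Path:
        lines = [header]
        for chrom, pos, ref, alt, fmt, call, *rest in rows:
            info = rest[0] if rest else "."
            filt = rest[1] if len(rest) > 1 else "PASS"
            lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t50\t{filt}\t{info}\t{fmt}\t{call}\n")
        path = tmp_path / name
        path.write_text("".join(lines))
        return path

    return write
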