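"""Shared fixtures: small hand-written VCFs and phenotype maps."""

from __future__ import annotations

from pathlib import Path

import pytest

from abdmap.vcfio import PhenotypeMap

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=100000000>
##contig=<ID=2,length=100000000>
##contig=<ID=4,length=120000601>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations \
from Ensembl VEP. Format: Allele|Consequence|IMPACT|SYMBOL|Feature|SIFT">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(path: Path, lines: list[str], samples: list[str]) -> Path:
    """Write a VCF from pre-formatted data lines (tab-joined columns)."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for line in lines:
            fh.write(line + "\n")
    return path


def gt_line(
    chrom: str,
    pos: int,
    gts: list[str],
    vid: str = ".",
    ref: str = "A",
    alt: str = "T",
    qual: str = "3000",
    info: str = "DP=250",
    gq: int = 99,
    dp: int = 30,
) -> str:
    """One VCF data line; plain GT strings get :GQ:DP appended."""
    cells = [g if ":" in g else f"{g}:{gq}:{dp}" for g in gts]
    return "\t".join(
        [chrom, str(pos), vid, ref, alt, qual, "PASS", info, "GT:GQ:DP"] + cells
    )


@pytest.fixture
def samples9() -> list[str]:
    return [f"case_{i}" for i in range(1, 4)] + [
        f"carrier_{i}" for i in range(1, 7)
    ]


@pytest.fixture
def phen9(samples9) -> PhenotypeMap:
    """The three-case / six-carrier design."""
    return PhenotypeMap(cases=samples9[:3], controls=samples9[3:])


@pytest.fixture
def vcf_factory(tmp_path):
    counter = {"n": 0}

    def make(lines: list[str], samples: list[str]) -> Path:
        counter["n"] += 1
        return write_vcf(tmp_path / f"fixture{counter['n']}.vcf", lines, samples)

    return make
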