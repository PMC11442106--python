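"""Shared fixtures: handcrafted variant records, tiny VCFs, window builders."""

from __future__ import annotations

import pytest

from polybsa.scan import WindowStat
from polybsa.vcf_io import VariantRecord

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##contig=<ID=chr2,length=500000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\tBL\tBH
"""


def make_record(
    chrom: str = "chr1",
    pos: int = 100,
    ref: str = "A",
    alt: str = "T",
    p1: tuple[int, int] = (50, 10),
    p2: tuple[int, int] = (60, 0),
    low: tuple[int, int] = (55, 5),
    high: tuple[int, int] = (50, 8),
) -> VariantRecord:
    return VariantRecord(
        chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
        depths={"P1": p1, "P2": p2, "BULK_LOW": low, "BULK_HIGH": high},
    )


def make_window(
    start: int,
    end: int,
    chrom: str = "chr1",
    n: int = 30,
    up95: int = 0,
    down95: int = 0,
    up99: int = 0,
    down99: int = 0,
    zeros_low: int = 0,
    zeros_high: int = 0,
    mean_delta: float = 0.0,
) -> WindowStat:
    return WindowStat(
        chrom=chrom, start=start, end=end, n_variants=n,
        mean_idx_low=0.08, mean_idx_high=0.08 + mean_delta,
        mean_delta=mean_delta, mean_neglog10p=0.5,
        count95_up=up95, count95_down=down95,
        count99_up=up99, count99_down=down99,
        zeros_low=zeros_low, zeros_high=zeros_high,
    )


@pytest.fixture
def sample_map():
    return {"P1": "P1", "P2": "P2", "BULK_LOW": "BL", "BULK_HIGH": "BH"}


@pytest.fixture
def tiny_vcf(tmp_path):
    """Three biallelic sites on two chromosomes, all four samples present."""
    body = [
        "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT:AD\t./.:50,10\t./.:60,0\t./.:55,5\t./.:50,8",
        "chr1\t250\t.\tA\tACG\t.\tPASS\t.\tGT:AD\t./.:40,12\t./.:70,0\t./.:52,4\t./.:48,9",
        "chr2\t50\t.\tG\tC\t.\tPASS\t.\tGT:AD\t./.:45,11\t./.:66,0\t./.:60,6\t./.:55,7",
    ]
    path = tmp_path / "tiny.vcf"
    path.write_text(VCF_HEADER + "\n".join(body) + "\n")
    return path


@pytest.fixture
def multiallelic_vcf(tmp_path):
    """One biallelic and one triallelic site for split/drop policies."""
    body = [
        "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT:AD\t./.:50,10\t./.:60,0\t./.:55,5\t./.:50,8",
        "chr1\t300\t.\tA\tT,G\t.\tPASS\t.\tGT:AD\t./.:40,12,3\t./.:70,0,1\t./.:52,4,2\t./.:48,9,5",
    ]
    path = tmp_path / "multi.vcf"
    path.write_text(VCF_HEADER + "\n".join(body) + "\n")
    return path
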