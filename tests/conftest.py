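import numpy as np
import pytest

from pavpop.dataio import HaplotypeSet


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_926 % 2**31)


@pytest.fixture
def small_vcf(tmp_path):
    """Two diploid samples, three phased biallelic SNPs, one multiallelic and
    one indel record to be skipped."""
    text = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|1
chr1\t200\t.\tC\tG\t.\tPASS\t.\tGT\t0|0\t0|1
chr1\t250\t.\tA\tT,G\t.\tPASS\t.\tGT\t0|1\t0|2
chr1\t300\t.\tG\tGA\t.\tPASS\t.\tGT\t0|0\t0|1
chr1\t400\t.\tT\tC\t.\tPASS\t.\tGT\t1|0\t0|0
"""
    path = tmp_path / "small.vcf"
    path.write_text(text)
    return path


def make_haps(alleles, positions=None):
    alleles = np.asarray(alleles, dtype=np.uint8)
    if positions is None:
        positions = np.arange(1, alleles.shape[1] + 1) * 100
    return HaplotypeSet(
        positions=np.asarray(positions),
        alleles=alleles,
        sample_of_origin=[f"h{i}" for i in range(alleles.shape[0])],
    )
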