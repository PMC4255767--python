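import numpy as np
import pytest

from sweepscan.genomic_io import HaplotypeMatrix, VariantSite


def make_matrix(columns, polarized=True, chrom="chr1", start_pos=100, spacing=10):
    """Build a HaplotypeMatrix from a row-per-haplotype 0/1 nested list."""
    data = np.array(columns, dtype=np.uint8)
    n_hap, n_site = data.shape
    sites = [
        VariantSite(
            chrom=chrom,
            pos=start_pos + j * spacing,
            id=f"v{j}",
            ref_allele="A",
            alt_allele="G",
            ancestral="ref" if polarized else "unresolved",
        )
        for j in range(n_site)
    ]
    hap_ids = [f"s{i // 2:03d}_{i % 2}" for i in range(n_hap)]
    return HaplotypeMatrix(
        sites=sites, hap_ids=hap_ids, data=data, polarized=polarized
    )


@pytest.fixture
def three_singletons():
    """n=4 haplotypes, three singleton sites (the worked oracle case)."""
    return make_matrix(
        [
            [1, 0, 0],
            [0, 1, 0],
            [0, 0, 1],
            [0, 0, 0],
        ]
    )


@pytest.fixture
def one_high_freq_site():
    """n=4, a single site at derived count 3."""
    return make_matrix([[1], [1], [1], [0]])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_matrix(rng, n_hap=20, n_site=50, polarized=True):
    data = rng.integers(0, 2, size=(n_hap, n_site), dtype=np.uint8)
    return make_matrix(data.tolist(), polarized=polarized)


TINY_VCF = """\
##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampA\tsampB\tsampC
chr1\t101\trs1\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t0|0\t1|1
chr1\t205\trs2\tC\tT\t.\tPASS\tAA=T\tGT\t0|0\t0|1\t0|0
chr1\t300\trs3\tG\tA\t.\tPASS\tAA=G\tGT\t1|0\t0|0\t0|1
chr1\t412\trs4\tT\tC\t.\tPASS\tAA=C\tGT\t1|1\t1|0\t0|0
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(TINY_VCF)
    return path


@pytest.fixture
def tiny_panel(tmp_path):
    path = tmp_path / "panel.tsv"
    path.write_text(
        "sample\tpopulation\nsampA\tPOP1\nsampB\tPOP1\nsampC\tPOP2\n"
    )
    return path
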