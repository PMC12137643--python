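import numpy as np
import pandas as pd
import pytest

from orchardpop.datatypes import GenotypeMatrix, PedigreeTable, VariantTable


@pytest.fixture
def tiny_vcf(tmp_path):
    """3-sample, 3-record VCF: two biallelic SNPs (one ./. call) and one
    multiallelic record that readers must skip."""
    text = """##fileformat=VCFv4.2
##contig=<ID=Chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
Chr1\t101\t.\tA\tG\t60\tPASS\t.\tGT:DP:GQ\t0/0:12:40\t0/1:9:35\t1/1:20:50
Chr1\t202\t.\tC\tT\t80\tPASS\t.\tGT:DP:GQ\t./.:.:.\t0/1:15:45\t0/0:11:38
Chr1\t303\t.\tG\tA,T\t50\tPASS\t.\tGT:DP:GQ\t0/1:9:30\t0/2:8:31\t1/2:7:29
"""
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    return path


@pytest.fixture
def trio_pedigree():
    df = pd.DataFrame(
        dict(
            individual=["A", "B", "C"],
            sire=[None, None, "A"],
            dam=[None, None, "B"],
            relation_type=["cross", "cross", "cross"],
        )
    )
    return PedigreeTable(df)


def make_genotypes(dosages, samples=None, phased=None):
    dosages = np.asarray(dosages, dtype=float)
    if samples is None:
        samples = [f"S{i}" for i in range(dosages.shape[0])]
    return GenotypeMatrix(samples=samples, dosages=dosages, phased=phased)


def make_variants(m, chrom="Chr1", spacing=1000, **kw):
    return VariantTable(
        chrom=np.array([chrom] * m, dtype=object),
        pos=np.arange(m, dtype=np.int64) * spacing + 100,
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["G"] * m, dtype=object),
        **kw,
    )
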