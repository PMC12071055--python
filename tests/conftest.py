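import numpy as np
import pytest

from snppanel.genotype import GenotypeMatrix, SampleInfo, VariantSite

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=2>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""

# 5 biallelic sites, 3 samples; includes phased, missing and half-missing calls
VCF_BODY = """\
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0|1\t1|1\t0/0
1\t300\trs3\tG\tA\t.\tPASS\t.\tGT\t./.\t0/0\t0/1
2\t150\trs4\tT\tC\t.\tPASS\t.\tGT\t1/1\t0/.\t0/0
2\t250\trs5\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0
"""

SAMPLE_TABLE = "sample_id\tbreed\tsex\nS1\tES\tF\nS2\tES\tM\nS3\tHP\tF\n"


@pytest.fixture
def tiny_vcf(tmp_path):
    vcf = tmp_path / "tiny.vcf"
    vcf.write_text(VCF_HEADER + VCF_BODY)
    table = tmp_path / "samples.tsv"
    table.write_text(SAMPLE_TABLE)
    return vcf, table


@pytest.fixture
def mixed_vcf(tmp_path):
    """5 records of which one is triallelic and one an indel."""
    body = (
        "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "1\t200\trs2\tC\tT,G\t.\tPASS\t.\tGT\t0/1\t1/2\t0/0\n"
        "1\t300\trs3\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1\n"
        "1\t400\trs4\tTA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0\n"
        "2\t150\trs5\tT\tC\t.\tPASS\t.\tGT\t1/1\t0/0\t0/0\n"
    )
    vcf = tmp_path / "mixed.vcf"
    vcf.write_text(VCF_HEADER + body)
    table = tmp_path / "samples.tsv"
    table.write_text(SAMPLE_TABLE)
    return vcf, table


def build_gm(codes, positions=None, chroms=None, breeds=None, sexes=None):
    """Construct a GenotypeMatrix from a (n_samples, n_sites) code array."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    if positions is None:
        positions = [100 * (j + 1) for j in range(m)]
    if chroms is None:
        chroms = ["1"] * m
    if breeds is None:
        breeds = ["B1"] * n
    sites = [
        VariantSite(str(chroms[j]), int(positions[j]), f"s{j}", "A", "G")
        for j in range(m)
    ]
    samples = [
        SampleInfo(f"S{i + 1}", breeds[i], sexes[i] if sexes else None)
        for i in range(n)
    ]
    return GenotypeMatrix(sites=sites, samples=samples, calls=codes)


@pytest.fixture
def gm_factory():
    return build_gm


@pytest.fixture(scope="session")
def two_breed_gm():
    """Two strongly diverged simulated breeds (F=0.2, 30+30 samples)."""
    from snppanel.simulate import SimConfig, simulate

    cfg = SimConfig(seed=42, n_breeds=2, samples_per_breed=30, n_sites=2000,
                    chrom_lengths={"1": 40_000_000, "2": 40_000_000},
                    F=0.2, missing_rate=0.01)
    return simulate(cfg)
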