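import numpy as np
import pytest

from droughtmap.io_formats import GenotypeMatrix
from droughtmap.synthetic_data import (
    SimulationConfig,
    simulate_phenotypes,
    simulate_population,
)

VCF_FIXTURE = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##INFO=<ID=QD,Number=1,Type=Float,Description="QD">
##INFO=<ID=FS,Number=1,Type=Float,Description="FS">
##INFO=<ID=MQ,Number=1,Type=Float,Description="MQ">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
chr1\t100\t.\tA\tG\t50\tPASS\tQD=10;FS=1.0;MQ=60\tGT\t0/0\t0/1\t1/1
chr1\t200\t.\tC\tT\t50\tPASS\tQD=10\tGT\t./.\t0/0\t0/1
chr1\t300\t.\tG\tA,T\t50\tPASS\tQD=10\tGT\t0/1\t0/2\t1/1
chr1\t400\t.\tT\tC\t50\tPASS\t.\tGT\t1/1\t1/1\t0/0
chr1\t500\t.\tA\tC\t50\tPASS\tQD=1.5\tGT\t0/0\t0/0\t0/1
"""


@pytest.fixture
def vcf_file(tmp_path):
    """Five records, one multi-allelic; three diploid samples."""
    p = tmp_path / "fixture.vcf"
    p.write_text(VCF_FIXTURE)
    return p


@pytest.fixture(scope="session")
def two_pop_panel():
    """Two clearly differentiated subpopulations, unadmixed ancestry."""
    cfg = SimulationConfig(
        n_samples=150, n_snps=1000, K_true=2, fst=0.2, admixture_alpha=None,
        seed=4, n_qtl=0, recomb_switch=1.0,
    )
    gm, truth = simulate_population(cfg)
    return gm, truth


@pytest.fixture(scope="session")
def pheno_panel():
    """Mid-size panel with latent tolerance and a factor-structured trait table."""
    cfg = SimulationConfig(
        n_samples=300, n_snps=1000, K_true=3, fst=0.1, n_qtl=3,
        qtl_h2=0.3, polygenic_h2=0.3, seed=11,
    )
    gm, truth = simulate_population(cfg)
    panel, truth = simulate_phenotypes(gm, truth, cfg)
    return gm, truth, panel


def toy_matrix(dosages, positions=None, chrom="chr1", sample_prefix="S"):
    """Small GenotypeMatrix from a dense integer array (helper for tests)."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    return GenotypeMatrix(
        sample_ids=[f"{sample_prefix}{i + 1}" for i in range(n)],
        chrom=np.asarray([chrom] * m, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        ref=np.asarray(["A"] * m, dtype=object),
        alt=np.asarray(["G"] * m, dtype=object),
        dosages=d,
    )
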