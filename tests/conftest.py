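import numpy as np
import pytest

from murat.synthetic import SimConfig, simulate_dataset


TINY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./.
1\t250\trs2\tC\tT\t.\tPASS\t.\tGT\t1/1\t1/1\t0/1\t0/0
1\t900\trs3\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1\t0/1
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(TINY_VCF)
    return path


@pytest.fixture
def null_dataset():
    """Seeded null dataset: n=400, 2 correlated phenotypes, 8 rare variants."""
    cfg = SimConfig(n_samples=400, n_variants=8, phenotype_corr=0.542, seed=20240901)
    gm, block = simulate_dataset(cfg)
    keep = [j for j in range(gm.n_variants) if gm.variants[j].maf > 0]
    G = gm.dosages[:, keep]
    mafs = gm.mafs[keep]
    return gm, block, G, mafs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
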