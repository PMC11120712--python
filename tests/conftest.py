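import numpy as np
import pytest

import coresnp as cs

VCF_TEXT = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
##contig=<ID=2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t./.\t0|1\t1|1
1\t300\trs3\tG\tA,T\t.\tPASS\t.\tGT\t0/1\t1/2\t0/0
2\t150\trs4\tT\tC\t.\tPASS\t.\tGT\t1/1\t0/0\t0/1
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(VCF_TEXT)
    return path


@pytest.fixture
def sim_small():
    """Small planted-signal dataset shared by scoring/IFS tests."""
    cfg = cs.SimConfig(
        n_samples=200,
        n_snps=120,
        n_causal=4,
        effect_sizes=(1.0, 1.0, 1.0, 1.0),
        heritability=0.7,
        seed=42,
    )
    g, meta = cs.simulate_genotypes(cfg)
    pheno, truth = cs.simulate_phenotype(g, cfg)
    pheno = cs.discretize_quartiles(pheno)
    return g, meta, pheno, truth


def random_two_class_fixture(rng, n_min=6, n_max=40):
    """Random 2-class feature/label pair with both classes non-empty."""
    n = int(rng.integers(n_min, n_max))
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[: int(rng.integers(2, n - 1))]] = 1
    x = rng.normal(size=n)
    return x, labels
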