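import numpy as np
import pytest

from capripop.genotype_io import GenotypeDataset, SampleRecord, SNPRecord


def make_dataset(genotypes, chroms=None, positions=None, populations=None,
                 alleles=None):
    """Build a small dataset by hand for unit tests."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    chroms = chroms or ["1"] * m
    positions = positions or [1000 * (k + 1) for k in range(m)]
    populations = populations or ["POP"] * n
    alleles = alleles or [("A", "G")] * m
    samples = [SampleRecord(sample_id=f"s{i+1}", population=populations[i])
               for i in range(n)]
    snps = [SNPRecord(snp_id=f"snp{k+1}", chromosome=str(chroms[k]),
                      position_bp=int(positions[k]), allele_a=alleles[k][0],
                      allele_b=alleles[k][1]) for k in range(m)]
    return GenotypeDataset(samples=samples, snps=snps, genotypes=g)


@pytest.fixture
def toy_dataset():
    """3 samples x 4 SNPs, no missingness, dosages chosen by hand."""
    return make_dataset([[0, 1, 2, 0],
                         [1, 1, 1, 0],
                         [2, 1, 0, 1]])


@pytest.fixture
def structured_dataset():
    from capripop.simulate import simulate_structured
    ds, truth = simulate_structured(3, 0.12, 20, 400, seed=11)
    return ds, truth
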