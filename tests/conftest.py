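import numpy as np
import pytest

from cenhap.genotype_io import HaplotypeMatrix, Site


def build_matrix(alleles, positions=None, chrom="chr1", hap_ids=None):
    """HaplotypeMatrix from a plain 0/1 array (rows = haplotypes)."""
    alleles = np.asarray(alleles, dtype=np.int8)
    H, S = alleles.shape
    if positions is None:
        positions = [100 * (j + 1) for j in range(S)]
    if hap_ids is None:
        hap_ids = [f"hap_{i}" for i in range(H)]
    sites = []
    for j in range(S):
        ones = int(alleles[:, j].sum())
        sites.append(Site(chrom, int(positions[j]), "A", "G", min(ones, H - ones)))
    region = (chrom, 0, int(positions[-1]) + 100 if S else 1000)
    return HaplotypeMatrix(list(hap_ids), sites, alleles, region)


@pytest.fixture
def make_matrix():
    return build_matrix


@pytest.fixture
def clean_sim():
    """Small error-free infinite-sites simulation (no recombination)."""
    import cenhap as ch

    params = ch.paper_like_params(seed=11, n_haplotypes=60)
    rng = np.random.default_rng(11)
    gen = ch.simulate_genealogy(params, rng)
    drop = ch.drop_mutations(gen, n_sites=200, rng=rng)
    return gen, drop
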