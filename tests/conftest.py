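import numpy as np
import pandas as pd
import pytest

import haplogp as hg


@pytest.fixture(scope="session")
def small_cfg():
    return hg.SimConfig(
        n_lines=150, n_chrom=2, snps_per_chrom=15, seed=42,
        missing_rate=0.0, founder_haplotypes_per_block=2, h2_target=0.5,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    geno = hg.simulate_genotypes(small_cfg)
    records, truth = hg.simulate_trials(geno, small_cfg)
    return geno, records, truth


@pytest.fixture(scope="session")
def small_adj(small_sim):
    _, records, _ = small_sim
    return hg.adjust_gy_block_effects(records)


def random_snp_matrix(rng, n_lines=60, n_snps=12, missing=0.0, chrom=None):
    """Unstructured random genotypes for oracle comparisons."""
    codes = rng.choice([1.0, -1.0], size=(n_lines, n_snps))
    if missing > 0:
        mask = rng.random(codes.shape) < missing
        codes = np.where(mask, np.nan, codes)
    pos = np.sort(rng.choice(np.arange(1, 10_000_000), size=n_snps, replace=False))
    return hg.SnpMatrix(
        line_ids=[f"L{i}" for i in range(n_lines)],
        snp_ids=[f"S{j}" for j in range(n_snps)],
        chrom=np.array([chrom or "1"] * n_snps, dtype=object),
        pos=pos,
        codes=codes,
    )
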