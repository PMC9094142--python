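import numpy as np
import pandas as pd
import pytest

from bulkmap import simpop


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_genome():
    """1-Mb chromosome, 20 evenly spaced SNPs, 3 cM/Mb."""
    positions = np.arange(50_000, 1_000_001, 50_000)
    return simpop.GenomeModel(
        chrom_name="chrA",
        length_bp=1_000_000,
        cm_per_mb=3.0,
        snp_positions=positions,
    )


@pytest.fixture()
def locus_mid(small_genome):
    return simpop.CausalLocus(position_bp=500_000)


@pytest.fixture()
def toy_pool_table():
    """Deterministic 6-SNP pooled-variant table with varied depths."""
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 6,
            "pos": [100, 200, 300, 400, 500, 600],
            "ref": list("ACGTAC"),
            "alt": list("TGCAGA"),
            "low_ref": [6, 0, 30, 20, 10, 0],
            "low_alt": [6, 10, 30, 20, 30, 0],
            "high_ref": [20, 5, 30, 2, 35, 12],
            "high_alt": [20, 5, 30, 4, 5, 12],
        }
    )
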