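import warnings

import numpy as np
import pandas as pd
import pytest

from methwas import qc, synthio

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_scenario():
    return synthio.SimScenario(name="shared_causal", seed=11, n_ref=300,
                               n_blocks=3, block_size=20, n_gwas=20_000,
                               h2_meth=0.4, k_causal=2)


@pytest.fixture(scope="session")
def small_bundle(small_scenario):
    """Genotypes + methylation + truth + GWAS + expression, QC'd panel."""
    bundle = synthio.simulate_bundle(small_scenario, n_tissues=2)
    geno_qc, _ = qc.filter_variants(bundle["geno"])
    bundle["geno_qc"] = geno_qc
    return bundle


def make_geno(dosages, pos=None, chrom="1", ea=None, oa=None):
    """Hand-built GenotypeMatrix for fixture-style tests."""
    from methwas.types import GenotypeMatrix

    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    pos = pos if pos is not None else np.arange(1, m + 1) * 1000
    ea = ea if ea is not None else ["A"] * m
    oa = oa if oa is not None else ["G"] * m
    variants = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(m)],
        "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa,
    })
    return GenotypeMatrix(dosages=dosages,
                          samples=[f"s{i}" for i in range(n)],
                          variants=variants)
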