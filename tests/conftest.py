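import numpy as np
import pandas as pd
import pytest

from haplofine.synthio import (
    GeneratorConfig,
    HaplotypeMatrix,
    VariantMap,
    generate_haplotype_pool,
    load_variant_map,
    sample_case_control,
)


def make_map(n: int, lead: int = 0, chrom: str = "10", start: int = 100) -> VariantMap:
    """Small ACGT-alleled variant map with evenly spaced positions."""
    rows = {
        "chrom": [chrom] * n,
        "pos": [start + 10 * j for j in range(n)],
        "id": [f"v{j}" for j in range(n)],
        "nonrisk_allele": ["A"] * n,
        "risk_allele": ["G"] * n,
        "annotation": [""] * n,
        "lead": [1 if j == lead else 0 for j in range(n)],
    }
    return VariantMap(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def table1() -> VariantMap:
    return load_variant_map("table1")


@pytest.fixture(scope="session")
def locus_sample(table1):
    """A mid-sized simulated study over the 25-variant map: founders plus
    recombinants, causal variant at the lead, modest covariate effects."""
    cfg = GeneratorConfig(
        n_cases=1500, n_controls=1500, causal_variant="rs3750846", seed=42
    )
    pool = generate_haplotype_pool(table1, cfg)
    hm, pheno = sample_case_control(pool, table1, cfg)
    return hm, pheno, cfg, pool


def hm_from_rows(rows) -> HaplotypeMatrix:
    return HaplotypeMatrix(np.asarray(rows, dtype=np.int8))
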