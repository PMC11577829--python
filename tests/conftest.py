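import numpy as np
import pandas as pd
import pytest

from locus2gene.synthetic import simulate_gwas, simulate_ld_panel


@pytest.fixture(scope="session")
def small_panel():
    """200-variant AR(1)-block panel used across tests."""
    return simulate_ld_panel(200, 20, 0.9, maf_range=(0.1, 0.5), seed=1)


@pytest.fixture(scope="session")
def quantitative_gwas(small_panel):
    """Seeded quantitative GWAS with one planted causal variant (idx 100)."""
    df, truth = simulate_gwas(
        small_panel, 100, 0.5, 10_000, trait_type="quantitative", seed=11
    )
    return df, truth


def make_summary_frame(rows):
    """Helper: build a summary frame from (chrom,pos,ref,alt,eaf,beta,se,p,n)."""
    cols = ["CHROM", "POS", "REF", "ALT", "EAF", "BETA", "SE", "PVAL", "N"]
    df = pd.DataFrame(rows, columns=cols)
    df["EFFECT_ALLELE"] = df["ALT"]
    df["OTHER_ALLELE"] = df["REF"]
    return df


@pytest.fixture
def summary_frame_factory():
    return make_summary_frame
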