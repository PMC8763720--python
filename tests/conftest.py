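import numpy as np
import pytest

from gwaskit import SimConfig, StudyMetadata, gwas_scan, simulate_panel, simulate_phenotype


@pytest.fixture(scope="session")
def small_panel():
    """200 individuals x 150 SNPs with moderate LD."""
    return simulate_panel(SimConfig(n_individuals=200, m_snps=150, ld_rho=0.5, seed=42))


@pytest.fixture(scope="session")
def clean_study(small_panel):
    """A complete canonical scan of a polygenic trait on the small panel."""
    cfg = SimConfig(n_individuals=200, m_snps=150, ld_rho=0.5, h2=0.3, n_causal=20, seed=42)
    y, _ = simulate_phenotype(small_panel, cfg)
    meta = StudyMetadata(
        study_id="clean", trait_name="sim", domain="complex_trait", sample_size=200
    )
    return gwas_scan(small_panel, y, meta)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
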