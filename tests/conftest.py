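import numpy as np
import pandas as pd
import pytest

from largv import (
    GenotypePanel,
    SimConfig,
    eta_adjustments,
    simulate_genotypes,
    standardize,
    windowed_r2,
)


def make_panel(genotypes, chrom="1", spacing=1000):
    """Hand-rolled panel from an explicit dosage matrix."""
    genotypes = np.asarray(genotypes, dtype=float)
    m = genotypes.shape[1]
    meta = pd.DataFrame(
        {
            "snp_id": [f"rs{j}" for j in range(m)],
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * spacing,
            "allele_ref": "A",
            "allele_alt": "C",
        }
    )
    return GenotypePanel(genotypes, meta)


@pytest.fixture(scope="session")
def ld_panel():
    """Moderate AR(1)-LD panel shared by LD/partition/regional tests."""
    cfg = SimConfig(n_individuals=800, n_snps=120, ld_model="ar1", rho=0.7, seed=42)
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def ld_std(ld_panel):
    return standardize(ld_panel)


@pytest.fixture(scope="session")
def ld_windowed(ld_std, ld_panel):
    return windowed_r2(ld_std, ld_panel.snp_meta, window=30)


@pytest.fixture(scope="session")
def ld_eta(ld_windowed, ld_panel):
    return eta_adjustments(ld_windowed, ld_panel.snp_meta["snp_id"].tolist())


@pytest.fixture(scope="session")
def aligned_table(ld_panel, ld_std, ld_eta):
    """Harmonized null-trait summary statistics for the shared panel."""
    from largv import gwas, harmonize

    rng = np.random.default_rng(7)
    y = rng.standard_normal(ld_std.n_individuals)
    stats = gwas(ld_std, y, meta=ld_panel.snp_meta)
    eta_table = ld_panel.snp_meta.copy()
    eta_table["eta"] = ld_eta.eta
    return harmonize(stats, eta_table)
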