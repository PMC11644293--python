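import numpy as np
import pandas as pd
import pytest

from droughtgerm.synthetic import GenotypePanel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_panel(genotypes: np.ndarray, chrom: str = "A01", pos=None) -> GenotypePanel:
    """Wrap a raw (accessions x SNPs) dosage array into a GenotypePanel."""
    n, m = genotypes.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 100
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": ["A"] * m, "alt": ["G"] * m}
    )
    return GenotypePanel(
        accessions=[f"acc{i}" for i in range(n)],
        sites=sites,
        genotypes=np.asarray(genotypes, dtype=float),
    )


@pytest.fixture
def random_panel(rng):
    """60 accessions x 80 polymorphic SNPs with a few missing calls."""
    p = rng.uniform(0.1, 0.5, 80)
    g = rng.binomial(2, p, size=(60, 80)).astype(float)
    g[rng.random(g.shape) < 0.03] = np.nan
    return make_panel(g)


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared by read-only tests: 120 accessions,
    600 SNPs with two causal loci."""
    from droughtgerm.synthetic import GenoSpec, PanelSpec, generate_panel

    spec = PanelSpec(n_accessions=120, seed=7)
    geno = GenoSpec(n_snps=600, causal_snps=((50, 0.8), (400, 0.6)), seed=7)
    table, panel, latent = generate_panel(spec, geno)
    return table, panel, latent
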