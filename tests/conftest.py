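import numpy as np
import pandas as pd
import pytest

from parzev.config import SimulationConfig


@pytest.fixture
def small_config():
    """A scaled-down genome (20 Mb Z) that keeps simulations fast."""
    return SimulationConfig(
        seed=11,
        z_length=20_000_000,
        autosome_lengths={"chr4": 20_000_000, "chr5": 15_000_000},
    )


def make_divergence_table(
    rng,
    n_genes,
    omega=0.15,
    ds_mean=0.05,
    ds_shape=2.0,
    region_class="PAR",
):
    """Independent mini-generator for gene divergence tables.

    Sites are proportional to a lognormal CDS length, each gene carries a
    gamma-distributed lineage rate, and substitution counts are Poisson.
    Kept deliberately separate from parzev.simulate so that tests of the
    estimators do not depend on the package's own generator.
    """
    cds_len = np.maximum(90, rng.lognormal(np.log(1500), 0.6, n_genes)).astype(int)
    s_sites = 0.25 * cds_len
    n_sites = 0.75 * cds_len
    rate = rng.gamma(ds_shape, ds_mean / ds_shape, n_genes)
    s_subs = rng.poisson(rate * s_sites).astype(float)
    n_subs = rng.poisson(omega * rate * n_sites).astype(float)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "chromosome": "chrT",
            "region_class": region_class,
            "n_sites": n_sites,
            "s_sites": s_sites,
            "n_subs": n_subs,
            "s_subs": s_subs,
            "dn": n_subs / n_sites,
            "ds": s_subs / s_sites,
        }
    )
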