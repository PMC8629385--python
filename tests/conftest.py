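import numpy as np
import pandas as pd
import pytest

from devomics import (
    ExprSimConfig,
    ExpressionMatrix,
    GenoSimConfig,
    default_metadata,
    simulate_expression,
    simulate_genotypes,
)
from devomics import popgen


def make_matrix(values, condition="A", biotype=None, timepoints=None):
    """Small ExpressionMatrix from a 2-D array for hand-built fixtures."""
    values = np.asarray(values, dtype=float)
    n, t = values.shape
    if timepoints is None:
        meta = default_metadata().iloc[:t]
    else:
        meta = pd.DataFrame({"day_numeric": np.arange(t, dtype=float),
                             "phase": "Embryonic"},
                            index=pd.Index(timepoints, name="timepoint"))
    genes = pd.Index([f"g{i}" for i in range(n)], name="gene_id")
    df = pd.DataFrame(values, index=genes, columns=list(meta.index))
    bt = pd.Series(biotype if biotype is not None else "pcg", index=genes)
    return ExpressionMatrix(values=df, biotype=bt, condition=condition, meta=meta)


@pytest.fixture(scope="session")
def small_sim():
    """Default-condition simulation at reduced gene count."""
    cfg = ExprSimConfig(n_genes=400, n_mirnas=30, seed=1)
    return cfg, *simulate_expression(cfg)


@pytest.fixture(scope="session")
def geno_panel(tmp_path_factory):
    """Small two-population panel (4k SNPs on a 4 Mb chromosome)."""
    cfg = GenoSimConfig(n_snps=4000, chrom_length=4_000_000, seed=1)
    path = tmp_path_factory.mktemp("geno") / "panel.vcf"
    simulate_genotypes(cfg, path)
    pops = {p: [f"{p}_{i+1}" for i in range(cfg.n_individuals_per_pop)]
            for p in cfg.pop_labels}
    return cfg, popgen.load_and_filter(path, pops)
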