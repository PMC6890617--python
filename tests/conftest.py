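import numpy as np
import pytest

from drumgs import SimConfig, simulate_dataset, vanraden_grm


@pytest.fixture(scope="session")
def small_dataset():
    """A modest polygenic cohort reused across read-only tests."""
    cfg = SimConfig(
        n_individuals=200, n_markers=400, n_qtl=40, h2_target=0.5,
        sex_effect=1.5, maf_range=(0.05, 0.5), seed=12345,
    )
    geno, pheno, truth = simulate_dataset(cfg)
    return cfg, geno, pheno, truth


@pytest.fixture(scope="session")
def small_grm(small_dataset):
    _, geno, _, _ = small_dataset
    return vanraden_grm(geno)
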