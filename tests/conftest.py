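import numpy as np
import pandas as pd
import pytest

from dauerx import synthgen


def small_config(**overrides) -> synthgen.SyntheticStudyConfig:
    defaults = dict(
        n_genes_per_species=400,
        n_orthologs=150,
        class_counts=synthgen.ClassCounts(10, 10, 10, 15, 30),
        n_effect_domains=10,
        domain_members=6,
        n_pioneers=60,
        seed=11,
    )
    defaults.update(overrides)
    return synthgen.SyntheticStudyConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    """A small f=1 study reused by read-only tests."""
    return synthgen.generate_study(small_config(repression_factor=1.0))


@pytest.fixture(scope="session")
def repressed_null_study():
    """f=0.5, no DE at all: the normalization-anchoring scenario."""
    cfg = synthgen.SyntheticStudyConfig(
        seed=5,
        repression_factor=0.5,
        class_counts=synthgen.ClassCounts(0, 0, 0, 0, 0),
        n_effect_domains=0,
        n_pioneers=0,
    )
    return synthgen.generate_study(cfg)


def make_matrix_ges(M: np.ndarray, n_dauer: int, n_exit: int, species="cel"):
    """Wrap a genes x arrays matrix as a GeneExpressionSet (all weights 1)."""
    from dauerx.diffexp import GeneExpressionSet

    n_genes, n_arrays = M.shape
    assert n_arrays == n_dauer + n_exit
    cols = [f"arr{i}" for i in range(n_arrays)]
    conds = ["dauer"] * n_dauer + ["exit"] * n_exit
    genes = [f"g{i:05d}" for i in range(n_genes)]
    return GeneExpressionSet(
        M=pd.DataFrame(M, index=genes, columns=cols),
        weights=pd.DataFrame(np.ones_like(M), index=genes, columns=cols),
        arrays=pd.DataFrame({"array_id": cols, "species": species,
                             "condition": conds}),
    )
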