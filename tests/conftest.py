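import numpy as np
import pandas as pd
import pytest

from consensusgrn.datatypes import CountMatrix, SampleMetadata
from consensusgrn.preprocess import preprocess_pipeline
from consensusgrn.simulate import (
    SimulationConfig,
    sample_grn,
    simulate_compendium,
    tf_list_of,
)


@pytest.fixture(scope="session")
def preset_config():
    """The desk-scale preset: 12 TFs, 60 genes, 40 conditions x 3 replicates."""
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def preset_data(preset_config):
    grn = sample_grn(preset_config)
    cm, meta = simulate_compendium(grn, preset_config)
    return grn, cm, meta


@pytest.fixture(scope="session")
def preset_expression(preset_data):
    grn, cm, meta = preset_data
    replicates, medians, factors = preprocess_pipeline(cm, meta)
    return replicates, medians, factors


@pytest.fixture(scope="session")
def preset_tfs(preset_data, preset_expression):
    grn, _, _ = preset_data
    _, medians, _ = preset_expression
    return tf_list_of(grn).restrict_to(medians.gene_ids)


@pytest.fixture
def tiny_counts():
    counts = pd.DataFrame(
        [[10, 20], [0, 5], [3, 3]],
        index=["gA", "gB", "gC"], columns=["s1", "s2"],
    )
    return CountMatrix(counts)


@pytest.fixture
def tiny_metadata():
    return SampleMetadata(pd.DataFrame({
        "sample_id": ["s1", "s2"],
        "condition_id": ["c1", "c1"],
        "replicate_index": [1, 2],
        "genotype": ["WT", "WT"],
    }))


def two_group_counts(rng, n_genes=2000, n_planted=0, log2fc=2.0,
                     dispersion=0.05, n_per_group=3):
    """NB two-group count matrix with optional planted fold changes in the
    first ``n_planted`` genes (used by the DE calibration tests)."""
    mu0 = rng.lognormal(5.0, 1.0, n_genes)
    fold = np.ones(n_genes)
    fold[:n_planted] = 2.0 ** log2fc
    lib = rng.uniform(0.8, 1.25, 2 * n_per_group)
    mus = np.concatenate(
        [np.tile(mu0[:, None], (1, n_per_group)),
         (mu0 * fold)[:, None] * np.ones((1, n_per_group))], axis=1) * lib
    counts = rng.poisson(rng.gamma(1.0 / dispersion, mus * dispersion))
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(2 * n_per_group)]
    cm = CountMatrix(pd.DataFrame(counts.astype(np.int64), index=genes,
                                  columns=samples))
    meta = SampleMetadata(pd.DataFrame({
        "sample_id": samples,
        "condition_id": [f"c{j}" for j in range(2 * n_per_group)],
        "replicate_index": 1,
        "genotype": ["WT"] * n_per_group + ["mut"] * n_per_group,
    }))
    return cm, meta, genes[:n_planted]
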