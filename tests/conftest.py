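"""Shared fixtures: the default synthetic experiment, generated once per session."""

import pytest

from coopsyn import de_meta, synthetic_data
from coopsyn.synthetic_data import DEGenConfig, DoseResponseConfig


@pytest.fixture(scope="session")
def de_experiment():
    """Default 6-line, 5000-gene DE experiment with planted classes (seed 0)."""
    config = DEGenConfig(seed=0)
    records, truth = synthetic_data.generate_de_tables(config)
    return config, records, truth


@pytest.fixture(scope="session")
def de_records(de_experiment):
    return de_experiment[1]


@pytest.fixture(scope="session")
def de_truth(de_experiment):
    return de_experiment[2]


@pytest.fixture(scope="session")
def meta_table(de_records):
    return de_meta.meta_analyze(de_records)


@pytest.fixture(scope="session")
def gene_labels(meta_table):
    return de_meta.classify_genes(meta_table)


@pytest.fixture(scope="session")
def cooperative_gene_list(de_records):
    return de_meta.cooperative_genes(de_records)


@pytest.fixture(scope="session")
def planted_gene_sets(de_truth):
    return synthetic_data.generate_gene_sets(de_truth, seed=101)


@pytest.fixture(scope="session")
def null_experiment():
    """10,000 genes, all null — calibration fixture for p-value uniformity."""
    config = DEGenConfig(n_genes=10000, class_sizes={"null": 10000}, seed=0)
    records, truth = synthetic_data.generate_de_tables(config)
    return records, truth


@pytest.fixture(scope="session")
def bliss_grid_noise_free():
    """Noise-free checkerboard generated under exact Bliss independence."""
    config = DoseResponseConfig(noise_sd=0.0, synergy_factor=1.0, n_replicates=1, seed=0)
    observed, truth = synthetic_data.generate_dose_response(config)
    return observed, truth
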