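import numpy as np
import pytest

from embryoqtl.datatypes import SimulationTruth
from embryoqtl.simulate import SimulationConfig, make_annotation, simulate_dataset


@pytest.fixture(scope="session")
def tiny_config():
    """Small design for fast structural tests."""
    return SimulationConfig(
        n_f1_per_direction=4,
        n_n2_f1xb6=12,
        n_n2_b6xf1=14,
        n_autosomes=4,
        genes_per_chromosome=25,
        seed=101,
    )


@pytest.fixture(scope="session")
def null_dataset(tiny_config):
    return simulate_dataset(tiny_config)


@pytest.fixture(scope="session")
def effect_config():
    """Full-design simulation (154 N2 + 16 F1) at reduced gene count."""
    return SimulationConfig(n_autosomes=10, genes_per_chromosome=60, seed=202)


@pytest.fixture(scope="session")
def effect_truth(effect_config):
    ann = make_annotation(effect_config)
    genes = ann.index.to_numpy()
    rng = np.random.default_rng(17)
    picks = rng.choice(genes, 48, replace=False)
    cis, mat, imp, dev = picks[:20], picks[20:32], picks[32:40], picks[40:48]
    return SimulationTruth(
        cis_fold={g: 2.0 for g in cis},
        maternal_fold={g: 1.5 for g in mat},
        imprinted={g: ("maternal" if i % 2 else "paternal", 0.02) for i, g in enumerate(imp)},
        somite_slope_expr={g: 0.05 for g in dev[:4]},
        somite_slope_allele={g: 0.1 for g in dev[4:]},
    )


@pytest.fixture(scope="session")
def effect_dataset(effect_config, effect_truth):
    return simulate_dataset(effect_config, effect_truth)
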