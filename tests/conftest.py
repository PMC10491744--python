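import numpy as np
import pandas as pd
import pytest

from connectome_cpm import GeneratorConfig, NodeAtlas, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_atlas():
    """Six nodes: 2 left, 2 right, 1 left cerebellar, 1 midline brainstem."""
    table = pd.DataFrame(
        {
            "node_id": range(6),
            "hemisphere": ["left", "left", "right", "right", "left", "midline"],
            "macroscale_region": [
                "prefrontal", "motor", "prefrontal", "occipital", "cerebellum",
                "brainstem",
            ],
            "label": [f"n{k}" for k in range(6)],
        }
    )
    return NodeAtlas(table)


@pytest.fixture
def small_cohort():
    """40 subjects, 30 nodes, clear planted signal; fast to analyze."""
    config = GeneratorConfig(
        n_subjects=40, n_nodes=30, n_pos_edges=10, n_neg_edges=10,
        effect_r=0.55, seed=11,
    )
    cohort, truth = generate_cohort(config)
    return cohort, truth
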