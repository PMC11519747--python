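import numpy as np
import pandas as pd
import pytest

import ctcpm


@pytest.fixture(scope="session")
def toy_atlas4():
    """Minimal 4-node atlas with two macroscale regions."""
    return ctcpm.AtlasDefinition(
        pd.DataFrame(
            {
                "node_id": [1, 2, 3, 4],
                "region": ["prefrontal", "prefrontal", "cerebellum", "cerebellum"],
                "hemisphere": ["l", "r", "l", "r"],
                "network_name": ["a", "a", "b", "b"],
                "mni_x": [-10.0, 10.0, -20.0, 20.0],
                "mni_y": [40.0, 40.0, -60.0, -60.0],
                "mni_z": [0.0, 0.0, -40.0, -40.0],
            }
        )
    )


@pytest.fixture(scope="session")
def shen_fixture():
    return ctcpm.shen268_synthetic()


@pytest.fixture(scope="session")
def strong_cohort():
    """Desk-scale strong-signal cohort: n=156, P=60, 10 pos + 10 neg edges."""
    cfg = ctcpm.SimulationConfig(
        n_subjects=156,
        n_nodes=60,
        n_signal_edges_pos=10,
        n_signal_edges_neg=10,
        beta_magnitude=0.3,
        seed=11,
    )
    return ctcpm.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def strong_result(strong_cohort):
    cohort, _truth = strong_cohort
    return ctcpm.run_pipeline(cohort, ctcpm.RunConfig(seed=11))
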