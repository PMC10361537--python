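import numpy as np
import pytest

from scihc import SimConfig, generate_ground_truth, render_round
from scihc.synthetic import HEMATOXYLIN


@pytest.fixture(scope="session")
def mini_cfg() -> SimConfig:
    """Small synthetic slide used by most unit tests."""
    return SimConfig(
        width=512,
        height=512,
        n_cells=120,
        markers=("CD138", "BDCA2", "CD141"),
        phenotype_frequencies={"CD138": 0.25, "BDCA2": 0.3, "CD141": 0.2},
        max_shift=15.0,
        field_amplitude=8.0,
        field_smoothness=150.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def mini_gt(mini_cfg):
    return generate_ground_truth(mini_cfg)


@pytest.fixture(scope="session")
def mini_ref(mini_gt):
    return render_round(mini_gt, HEMATOXYLIN)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
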