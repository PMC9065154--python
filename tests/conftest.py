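import numpy as np
import pytest

import clawmorph as cm


@pytest.fixture(scope="session")
def claw_data():
    """Two-group synthetic claw dataset with levers and ground truth."""
    dataset, levers, truth = cm.generate_claw_dataset()
    return dataset, levers, truth


@pytest.fixture(scope="session")
def gpa_result(claw_data):
    dataset, _, _ = claw_data
    return cm.gpa(dataset, sliders=cm.claw_sliders())


@pytest.fixture(scope="session")
def shape_space(gpa_result):
    space = cm.shape_pca(gpa_result)
    return cm.orient_axes(space, tip_index=0, proximal_index=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
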