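import numpy as np
import pytest

from membind.toysim import (
    BilayerModel,
    ProteinBody,
    SimParams,
    SystemState,
    build_bilayer,
    make_c2_like_body,
)

PIP2_FRACTIONS = {"PC": 0.80, "PS": 0.15, "PIP2": 0.05}


@pytest.fixture
def body():
    return make_c2_like_body()


@pytest.fixture
def tetra_body():
    """Minimal non-degenerate neutral 4-bead body."""
    return ProteinBody(
        bead_positions=np.array(
            [[0.3, 0.0, 0.0], [0.0, 0.3, 0.0], [0.0, 0.0, 0.3], [-0.3, -0.3, -0.3]]
        ),
        bead_charges=np.zeros(4),
        bead_labels=["core"] * 4,
    )


@pytest.fixture
def mf_bilayer():
    return build_bilayer(80, PIP2_FRACTIONS, seed=1, mode="mean-field")


@pytest.fixture
def explicit_bilayer():
    return build_bilayer(80, PIP2_FRACTIONS, box_xy=(7.0, 7.0), seed=1)


@pytest.fixture
def params():
    return SimParams(seed=0)


def make_state(body, bilayer, com=(3.5, 3.5, 3.0), quat=(0.0, 0.0, 0.0, 1.0)):
    return SystemState(
        body=body,
        bilayer=bilayer,
        body_com=np.array(com, dtype=float),
        body_orientation=np.array(quat, dtype=float),
    )


@pytest.fixture
def mf_state(body, mf_bilayer):
    return make_state(body, mf_bilayer)
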