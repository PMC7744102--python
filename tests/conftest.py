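import numpy as np
import pandas as pd
import pytest

from glomotopy import synthetic
from glomotopy.geometry import NODE_COLUMNS, Skeleton


@pytest.fixture(scope="session")
def jittered_grid():
    """A generic 66-point planar set with no duplicate inter-point distances."""
    return synthetic.make_lobula_grid(6, 11, 2.0, seed=42)


@pytest.fixture(scope="session")
def default_connectome():
    """One synthetic connectome at the default (fully retinotopic) conditions."""
    return synthetic.generate(synthetic.ConnectomeConfig(seed=7))


def straight_skeleton(n_nodes=11, step=400.0, axis=(1.0, 0.0, 0.0), label="axon",
                      neuron_id="straight"):
    axis = np.asarray(axis, float)
    rows = [(k + 1, k if k else -1, *(axis * step * k), -1.0, label)
            for k in range(n_nodes)]
    return Skeleton(neuron_id, pd.DataFrame(rows, columns=NODE_COLUMNS))
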