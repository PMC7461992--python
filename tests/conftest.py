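import numpy as np
import pytest

from cnsot import get_parameters


@pytest.fixture(scope="session")
def immersed():
    return get_parameters("immersed_rest")


@pytest.fixture(scope="session")
def dry():
    return get_parameters("dry_rest")


@pytest.fixture(scope="session")
def active():
    return get_parameters("active_4_4")


def surv_y(dataset):
    """Pack a dataset's outcome as a structured (event, time) array."""
    y = np.empty(len(dataset), dtype=[("event", bool), ("time", float)])
    y["event"] = dataset.event
    y["time"] = dataset.time
    return y
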