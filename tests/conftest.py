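import numpy as np
import pytest

from qmreff import TissueParams


@pytest.fixture
def wm() -> TissueParams:
    """White matter at 3 T, the reference tissue point."""
    return TissueParams(t1=781.0, t2=65.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
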