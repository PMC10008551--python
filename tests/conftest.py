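import warnings

import numpy as np
import pytest

# arviz emits a refactor FutureWarning on import; irrelevant to the suite
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_source_problem():
    """Noise-free identifiable two-source mixing toy with known solution."""
    from isomix import mixing as mx

    s1 = mx.FoodSource("A", {"protein": {"d13C_coll": (-26.0, 0.01)}}, {"protein": (1.0, 0.0)})
    s2 = mx.FoodSource("B", {"protein": {"d13C_coll": (-12.0, 0.01)}}, {"protein": (1.0, 0.0)})
    true_alpha = 0.7
    target = true_alpha * -26.0 + (1 - true_alpha) * -12.0
    problem = mx.build_problem(
        [s1, s2],
        [mx.ProxyTarget("d13C_coll", target, 0.1)],
        {},
        {"d13C_coll": {"protein": 1.0}},
    )
    return problem, true_alpha
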