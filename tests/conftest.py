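import pytest

from divnorm import DNParams, MLEParams

# Published single-cursor fit parameter sets (experiment 1 learning and
# feedback responses; experiment 2 learning) used as ground truth throughout.


@pytest.fixture
def dn_learning() -> DNParams:
    return DNParams(w=5.3271e-4, k=7.7806e-7, s=22.0, M=3601)


@pytest.fixture
def dn_feedback() -> DNParams:
    return DNParams(w=4.0541e-4, k=9.2642e-5, s=22.0, M=3601)


@pytest.fixture
def dn_exp2() -> DNParams:
    return DNParams(w=2.0002e-4, k=2.1434e-6, s=22.0, M=3601)


@pytest.fixture
def mle_learning() -> MLEParams:
    return MLEParams(c=2.963e5, ratio_sv=122.2, ratio_kv=8.055)
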