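import numpy as np
import pytest

from leakynet import (
    CoarseLMN,
    SISaParams,
    build_sisa,
    default_nn_params,
    default_sisa_params,
    get_gain,
)


def make_single_block(N, a, b, *, weight=0.0, h=0.0, gain_on="zero",
                      gain_off="zero", N0=None):
    """One-block coarse model; leak-only by default."""
    return CoarseLMN(
        sizes=np.array([N]),
        block_weights=np.array([[weight]]),
        block_input=np.array([h]),
        leak_on=np.array([a]),
        leak_off=np.array([b]),
        gain_on=(get_gain(gain_on),),
        gain_off=(get_gain(gain_off),),
        normalizer=float(N0 if N0 is not None else N),
    )


def make_two_block(sizes, a, b, W, h=(0.0, 0.0), gain_on="zero",
                   gain_off="zero"):
    return CoarseLMN(
        sizes=np.asarray(sizes),
        block_weights=np.asarray(W, dtype=float),
        block_input=np.asarray(h, dtype=float),
        leak_on=np.asarray(a, dtype=float),
        leak_off=np.asarray(b, dtype=float),
        gain_on=(get_gain(gain_on),) * 2,
        gain_off=(get_gain(gain_off),) * 2,
        normalizer=float(np.sum(sizes)),
    )


@pytest.fixture
def two_state():
    """Two-state chain: single node, a=1, b=3."""
    return make_single_block(1, 1.0, 3.0)


@pytest.fixture
def sisa_model():
    return build_sisa(default_sisa_params())


@pytest.fixture
def sisa_params():
    return default_sisa_params()


@pytest.fixture
def nn_params():
    return default_nn_params()


@pytest.fixture
def nn_strong_params():
    """Strong-coupling NN regime with a detectable critical size."""
    return default_nn_params(w_excitatory=1.5, w_inhibitory=0.8,
                             activation_leak=1e-4, external_input=1e-4)


def sisa_small(N, a=0.01, beta=0.2, g=0.05):
    """Small SISa instance for hand-checkable propensities."""
    return build_sisa(SISaParams(spontaneous_infection=a, transmission=beta,
                                 recovery=g, N0=float(N), omega=1.0))
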