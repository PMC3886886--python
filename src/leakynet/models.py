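"""SISa epidemic and excitatory/inhibitory neural-network model builders.

The SISa model is a one-population susceptible-infected-susceptible
model with a spontaneous (environmental) infection route: activation
rate ``a + beta_t * z`` per susceptible (``beta_t`` the full-population
transmission coupling), recovery at constant rate ``g``.  The neural
model has two equally sized homogeneous populations of excitatory and
inhibitory neurons; every neuron receives input
``u = h + w_E * z_E - w_I * z_I`` and activates at rate
``leak + tanh(u)_+``, deactivating at constant rate ``alpha``.

Default numeric parameters ship as YAML data files under
``leakynet/data/`` (they are calibration data, not code).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .gains import get_gain
from .model_core import CoarseLMN, NodeLMN, Partition

__all__ = [
    "SISaParams",
    "NNParams",
    "build_sisa",
    "build_nn",
    "default_sisa_params",
    "default_nn_params",
    "fixture_generator",
]


@dataclass(frozen=True)
class SISaParams:
    """SISa rates in 1/day plus the size parameterization."""

    spontaneous_infection: float   # a
    transmission: float            # beta_t, full-population coupling
    recovery: float                # g
    N0: float = 200.0
    omega: float = 1.0

    def __post_init__(self):
        for name in ("spontaneous_infection", "transmission", "recovery"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.N0 <= 0 or self.omega <= 0:
            raise ValueError("N0 and omega must be positive")

    @property
    def is_leaky(self) -> bool:
        return self.spontaneous_infection > 0 and self.recovery > 0


@dataclass(frozen=True)
class NNParams:
    """Neural-network rates in 1/ms plus the size parameterization."""

    w_excitatory: float
    w_inhibitory: float
    external_input: float
    deactivation: float            # alpha
    activation_leak: float
    ei_ratio: tuple[int, int] = (1, 1)
    response: str = "tanh_plus"
    N0: float = 200.0
    omega: float = 1.0

    def __post_init__(self):
        if self.deactivation < 0 or self.activation_leak < 0:
            raise ValueError("rates must be nonnegative")
        if self.N0 <= 0 or self.omega <= 0:
            raise ValueError("N0 and omega must be positive")
        e, i = self.ei_ratio
        if e <= 0 or i <= 0:
            raise ValueError("E:I ratio parts must be positive")

    @property
    def balance(self) -> float:
        """Excitation-minus-inhibition diagnostic; ~0 means balanced."""
        return self.w_excitatory - self.w_inhibitory


def build_sisa(params: SISaParams) -> CoarseLMN:
    """One-block coarse LMN with identity activation gain.

    With ``a = 0`` the origin is absorbing (the classical SIS model:
    once infections die out they never reappear); ``a > 0`` restores
    leakiness and hence irreducibility.
    """
    N = max(1, int(np.rint(params.omega * params.N0)))
    return CoarseLMN(
        sizes=np.array([N]),
        block_weights=np.array([[params.transmission]]),
        block_input=np.array([0.0]),
        leak_on=np.array([params.spontaneous_infection]),
        leak_off=np.array([params.recovery]),
        gain_on=(get_gain("identity"),),
        gain_off=(get_gain("zero"),),
        normalizer=params.N0,
        time_unit="day",
        block_names=("infected",),
    )


def build_nn(params: NNParams) -> CoarseLMN:
    """Two-block (excitatory, inhibitory) coarse LMN.

    Both blocks see the same net input ``h + w_E z_E - w_I z_I``; the
    response function (default ``tanh_plus``) plus a small activation
    leak drives activation, deactivation is a constant rate.
    """
    e, i = params.ei_ratio
    total = params.omega * params.N0
    sizes = np.maximum(1, np.rint(
        total * np.array([e, i]) / (e + i)).astype(int))
    wE, wI = params.w_excitatory, params.w_inhibitory
    W = np.array([[wE, -wI], [wE, -wI]])
    resp = get_gain(params.response)
    return CoarseLMN(
        sizes=sizes,
        block_weights=W,
        block_input=np.array([params.external_input] * 2),
        leak_on=np.array([params.activation_leak] * 2),
        leak_off=np.array([params.deactivation] * 2),
        gain_on=(resp, resp),
        gain_off=(get_gain("zero"), get_gain("zero")),
        normalizer=params.N0,
        time_unit="ms",
        block_names=("excitatory", "inhibitory"),
    )


def _load_defaults(name: str) -> dict:
    with resources.files("leakynet.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def default_sisa_params(**overrides) -> SISaParams:
    """SISa defaults from the shipped calibration file."""
    cfg = _load_defaults("sisa_defaults.yaml")
    cfg.update(overrides)
    return SISaParams(
        spontaneous_infection=float(cfg["spontaneous_infection"]),
        transmission=float(cfg["transmission"]),
        recovery=float(cfg["recovery"]),
        N0=float(cfg["N0"]),
        omega=float(cfg.get("omega", 1.0)),
    )


def default_nn_params(**overrides) -> NNParams:
    """Neural-network defaults from the shipped calibration file."""
    cfg = _load_defaults("nn_defaults.yaml")
    cfg.update(overrides)
    return NNParams(
        w_excitatory=float(cfg["w_excitatory"]),
        w_inhibitory=float(cfg["w_inhibitory"]),
        external_input=float(cfg["external_input"]),
        deactivation=float(cfg["deactivation"]),
        activation_leak=float(cfg["activation_leak"]),
        ei_ratio=tuple(cfg.get("ei_ratio", (1, 1))),
        response=str(cfg.get("response", "tanh_plus")),
        N0=float(cfg["N0"]),
        omega=float(cfg.get("omega", 1.0)),
    )


def fixture_generator(seed: int = 0, *, n_models: int = 10,
                      max_block_size: int = 8) -> list[dict]:
    """Seeded suite of small homogeneous-block models for property tests.

    Each entry holds a :class:`NodeLMN` with exactly block-constant
    parameters, the matching :class:`Partition`, and the coarse-grained
    model.  All leaks are strictly positive, so every generated chain is
    irreducible.
    """
    rng = np.random.default_rng(seed)
    gains = ["zero", "tanh_plus"]
    suite = []
    for _ in range(n_models):
        M = int(rng.integers(1, 3))
        sizes = rng.integers(1, max_block_size + 1, size=M)
        N = int(sizes.sum())
        a_blk = rng.uniform(0.1, 1.0, M)
        b_blk = rng.uniform(0.1, 1.0, M)
        h_blk = rng.uniform(-0.2, 0.5, M)
        w_blk = rng.uniform(-0.5, 0.5, (M, M))
        blocks, lo = [], 0
        for k in range(M):
            blocks.append(tuple(range(lo, lo + int(sizes[k]))))
            lo += int(sizes[k])
        partition = Partition(blocks)
        W = np.zeros((N, N))
        a = np.empty(N)
        b = np.empty(N)
        h = np.empty(N)
        for k, blk in enumerate(blocks):
            for i in blk:
                a[i], b[i], h[i] = a_blk[k], b_blk[k], h_blk[k]
                for l, blk_l in enumerate(blocks):
                    for j in blk_l:
                        if i != j:
                            # per-node weights ~ 1/N_l so the coarse
                            # self-exclusion approximation is exact
                            W[i, j] = w_blk[k, l] / sizes[l]
        gain = get_gain(str(rng.choice(gains)))
        node = NodeLMN(weights=W, external_input=h, leak_on=a, leak_off=b,
                       gain_on=gain, gain_off=get_gain("zero"))
        from .model_core import coarse_grain

        coarse = coarse_grain(node, partition, N0=float(N))
        suite.append({"node": node, "partition": partition, "coarse": coarse})
    return suite
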