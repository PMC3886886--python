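"""Node-level and coarse-grained leaky Markovian network models.

A leaky Markovian network (LMN) is a continuous-time Markov model of
binary nodes.  Node ``i`` activates at rate ``(1 - x_i) * (a_i + phi(u_i))``
and deactivates at rate ``x_i * (b_i + psi(u_i))``, where
``u_i = h_i + sum_j w_ij x_j`` is the net input.  The constant leaks
``a_i, b_i`` make the chain irreducible whenever both are positive.

Coarse graining partitions the nodes into homogeneous blocks and tracks
only the per-block active counts, yielding a lattice-valued birth-death
network whose propensities are

    beta_k(n) = (N_k - n_k) * (a_k + phi_k(u_k(z))),
    delta_k(n) = n_k * (b_k + psi_k(u_k(z))),

with ``u_k(z) = h_k + sum_l Wbar_kl z_l`` and ``z_l = n_l / N_l``.  The
aggregated weight ``Wbar_kl = N_l * w(k, l)`` expresses coupling through
fractions, so it is invariant under rescaling the network size
``Omega = N / N0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .gains import GainFunction, get_gain

__all__ = [
    "NodeLMN",
    "Partition",
    "CoarseLMN",
    "CountState",
    "net_input",
    "node_propensities",
    "coarse_grain",
    "coarse_propensities",
    "resize",
    "read_model_config",
    "write_model_config",
]


class HomogeneityError(ValueError):
    """A partition block violates the block-homogeneity precondition."""


def _as_gain(g) -> GainFunction:
    if isinstance(g, GainFunction):
        return g
    return get_gain(str(g))


@dataclass(frozen=True)
class NodeLMN:
    """Node-resolved LMN; used as a small-N validation oracle.

    Parameters
    ----------
    weights : (N, N) array
        ``weights[i, j]`` is the influence of node ``j`` on node ``i``.
        The diagonal must be exactly zero (no self-regulation).
    external_input : (N,) array
    leak_on, leak_off : (N,) nonnegative arrays, units 1/time.
    gain_on, gain_off : gain-function names or :class:`GainFunction`.
    """

    weights: np.ndarray
    external_input: np.ndarray
    leak_on: np.ndarray
    leak_off: np.ndarray
    gain_on: GainFunction
    gain_off: GainFunction
    time_unit: str = "time"

    def __post_init__(self):
        W = np.array(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be a square matrix")
        if np.any(np.diag(W) != 0.0):
            raise ValueError("diagonal of the weight matrix must be exactly zero")
        n = W.shape[0]
        h = np.broadcast_to(np.asarray(self.external_input, float), (n,)).copy()
        a = np.broadcast_to(np.asarray(self.leak_on, float), (n,)).copy()
        b = np.broadcast_to(np.asarray(self.leak_off, float), (n,)).copy()
        if np.any(a < 0) or np.any(b < 0):
            raise ValueError("leak rates must be nonnegative")
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "external_input", h)
        object.__setattr__(self, "leak_on", a)
        object.__setattr__(self, "leak_off", b)
        object.__setattr__(self, "gain_on", _as_gain(self.gain_on))
        object.__setattr__(self, "gain_off", _as_gain(self.gain_off))

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class Partition:
    """Disjoint index blocks covering ``{0, ..., N-1}``."""

    blocks: tuple[tuple[int, ...], ...]

    def __init__(self, blocks: Sequence[Sequence[int]]):
        norm = tuple(tuple(int(i) for i in blk) for blk in blocks)
        seen: set[int] = set()
        for blk in norm:
            if len(blk) == 0:
                raise ValueError("empty partition block")
            if seen & set(blk):
                raise ValueError("partition blocks are not disjoint")
            seen |= set(blk)
        if seen != set(range(len(seen))) or not seen:
            raise ValueError("partition blocks must cover 0..N-1 exactly")
        object.__setattr__(self, "blocks", norm)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def block_sizes(self) -> np.ndarray:
        return np.array([len(b) for b in self.blocks], dtype=int)


@dataclass(frozen=True)
class CoarseLMN:
    """Block-homogeneous coarse-grained LMN.

    ``block_weights[k, l]`` is the aggregated influence of block ``l`` at
    full activity (``z_l = 1``) on a single node of block ``k``.
    """

    sizes: np.ndarray
    block_weights: np.ndarray
    block_input: np.ndarray
    leak_on: np.ndarray
    leak_off: np.ndarray
    gain_on: tuple[GainFunction, ...]
    gain_off: tuple[GainFunction, ...]
    normalizer: float
    time_unit: str = "time"
    block_names: tuple[str, ...] = ()

    def __post_init__(self):
        sizes = np.asarray(self.sizes, dtype=int)
        if sizes.ndim != 1 or np.any(sizes < 1):
            raise ValueError("sizes must be positive integers")
        M = sizes.shape[0]
        W = np.asarray(self.block_weights, dtype=float).reshape(M, M)
        h = np.broadcast_to(np.asarray(self.block_input, float), (M,)).copy()
        a = np.broadcast_to(np.asarray(self.leak_on, float), (M,)).copy()
        b = np.broadcast_to(np.asarray(self.leak_off, float), (M,)).copy()
        if np.any(a < 0) or np.any(b < 0):
            raise ValueError("leak rates must be nonnegative")
        if float(self.normalizer) <= 0:
            raise ValueError("normalizer N0 must be positive")
        gon = self.gain_on if isinstance(self.gain_on, (tuple, list)) else (self.gain_on,) * M
        gof = self.gain_off if isinstance(self.gain_off, (tuple, list)) else (self.gain_off,) * M
        if len(gon) != M or len(gof) != M:
            raise ValueError("need one gain function per block")
        names = tuple(self.block_names) or tuple(f"block{k}" for k in range(M))
        if len(names) != M:
            raise ValueError("need one name per block")
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "block_weights", W)
        object.__setattr__(self, "block_input", h)
        object.__setattr__(self, "leak_on", a)
        object.__setattr__(self, "leak_off", b)
        object.__setattr__(self, "gain_on", tuple(_as_gain(g) for g in gon))
        object.__setattr__(self, "gain_off", tuple(_as_gain(g) for g in gof))
        object.__setattr__(self, "normalizer", float(self.normalizer))
        object.__setattr__(self, "block_names", names)

    @property
    def n_blocks(self) -> int:
        return self.sizes.shape[0]

    @property
    def n_nodes(self) -> int:
        return int(self.sizes.sum())

    @property
    def fractions(self) -> np.ndarray:
        return self.sizes / self.sizes.sum()

    @property
    def omega(self) -> float:
        """Network size Omega = N / N0."""
        return self.n_nodes / self.normalizer

    @property
    def is_leaky(self) -> bool:
        return bool(np.all(self.leak_on > 0) and np.all(self.leak_off > 0))

    def net_input(self, z: np.ndarray) -> np.ndarray:
        """Per-block net input at fractional activity ``z`` (vectorized
        over a trailing batch of states given as rows)."""
        z = np.asarray(z, dtype=float)
        return self.block_input + z @ self.block_weights.T

    def model_hash(self) -> str:
        import hashlib

        payload = json.dumps(_model_to_dict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class CountState:
    """Integer active counts on the block lattice."""

    counts: np.ndarray

    def __init__(self, counts):
        c = np.atleast_1d(np.asarray(counts, dtype=int))
        object.__setattr__(self, "counts", c)

    def validate(self, model: CoarseLMN) -> "CountState":
        if self.counts.shape != model.sizes.shape:
            raise ValueError("count vector has wrong dimension")
        if np.any(self.counts < 0) or np.any(self.counts > model.sizes):
            raise ValueError(
                f"counts {self.counts.tolist()} outside lattice bounds "
                f"{model.sizes.tolist()}"
            )
        return self

    def fractions(self, model: CoarseLMN) -> np.ndarray:
        return self.counts / model.sizes


# ---------------------------------------------------------------------------
# node-level operations


def _check_binary(x, n):
    x = np.asarray(x)
    if x.shape != (n,) or not np.isin(x, (0, 1)).all():
        raise ValueError("state vector must be binary of length N")
    return x.astype(float)


def net_input(model: NodeLMN, x, i: int) -> float:
    """Net input ``u_i = h_i + sum_j w_ij x_j`` to node ``i``."""
    x = _check_binary(x, model.n_nodes)
    return float(model.external_input[i] + model.weights[i] @ x)


def node_propensities(model: NodeLMN, x, i: int) -> tuple[float, float]:
    """Activation and deactivation rates of node ``i`` in state ``x``."""
    xv = _check_binary(x, model.n_nodes)
    u = net_input(model, x, i)
    rate_on = (1.0 - xv[i]) * (model.leak_on[i] + float(model.gain_on(u)))
    rate_off = xv[i] * (model.leak_off[i] + float(model.gain_off(u)))
    if rate_on < 0 or rate_off < 0:
        raise ValueError("negative propensity; gain functions must be nonnegative")
    return rate_on, rate_off


# ---------------------------------------------------------------------------
# coarse graining


def coarse_grain(model: NodeLMN, partition: Partition, N0: float,
                 *, rtol: float = 1e-12) -> CoarseLMN:
    """Aggregate a block-homogeneous :class:`NodeLMN` into a :class:`CoarseLMN`.

    Requires per-block constant ``a, b, h`` and weights depending only on
    the block pair.  The aggregated weight is ``Wbar_kl = N_l * w(k, l)``;
    the O(1/N_l) self-exclusion correction is dropped (exact when
    per-node weights scale like 1/N).
    """
    if sum(partition.block_sizes) != model.n_nodes:
        raise ValueError("partition does not match model size")
    M = partition.n_blocks
    a = np.empty(M)
    b = np.empty(M)
    h = np.empty(M)
    Wbar = np.empty((M, M))

    def _homog(vals, block_idx, what):
        vals = np.asarray(vals, dtype=float)
        ref = vals.flat[0]
        tol = rtol * max(1.0, abs(ref))
        if np.any(np.abs(vals - ref) > tol):
            raise HomogeneityError(
                f"parameter {what!r} is not constant within block {block_idx}"
            )
        return float(ref)

    for k, blk in enumerate(partition.blocks):
        idx = list(blk)
        a[k] = _homog(model.leak_on[idx], k, "leak_on")
        b[k] = _homog(model.leak_off[idx], k, "leak_off")
        h[k] = _homog(model.external_input[idx], k, "external_input")
    for k, blk_k in enumerate(partition.blocks):
        for l, blk_l in enumerate(partition.blocks):
            sub = model.weights[np.ix_(list(blk_k), list(blk_l))]
            if k == l:
                vals = sub[~np.eye(len(blk_k), dtype=bool)]
                if vals.size == 0:  # singleton block: no internal coupling
                    w = 0.0
                else:
                    w = _homog(vals, k, f"weights[{k},{l}]")
            else:
                w = _homog(sub, k, f"weights[{k},{l}]")
            Wbar[k, l] = len(blk_l) * w

    return CoarseLMN(
        sizes=partition.block_sizes,
        block_weights=Wbar,
        block_input=h,
        leak_on=a,
        leak_off=b,
        gain_on=(model.gain_on,) * M,
        gain_off=(model.gain_off,) * M,
        normalizer=float(N0),
        time_unit=model.time_unit,
    )


def coarse_propensities(model: CoarseLMN, state) -> tuple[np.ndarray, np.ndarray]:
    """Birth and death propensity vectors at a lattice state.

    Accepts a :class:`CountState` or a raw count vector; returns
    ``(beta, delta)`` with ``beta_k = (N_k - n_k)(a_k + phi_k(u_k))`` and
    ``delta_k = n_k (b_k + psi_k(u_k))``.
    """
    if not isinstance(state, CountState):
        state = CountState(state)
    state.validate(model)
    n = state.counts
    z = n / model.sizes
    u = model.net_input(z)
    phi = np.array([float(g(u[k])) for k, g in enumerate(model.gain_on)])
    psi = np.array([float(g(u[k])) for k, g in enumerate(model.gain_off)])
    beta = (model.sizes - n) * (model.leak_on + phi)
    delta = n * (model.leak_off + psi)
    if np.any(beta < 0) or np.any(delta < 0):
        raise ValueError("negative propensity; check gain nonnegativity")
    return beta, delta


def resize(model: CoarseLMN, omega: float) -> CoarseLMN:
    """Return a copy of the model rescaled to network size ``omega``.

    Block sizes become ``max(1, round(omega * N0 * nu_k))`` with
    round-half-even; all rate parameters, weights and inputs are
    unchanged (coupling acts through fractions).
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    nu = model.fractions
    target = omega * model.normalizer * nu
    sizes = np.maximum(1, np.rint(target).astype(int))
    if sizes.sum() < model.n_blocks:
        raise ValueError("omega too small: fewer than one node per block")
    return replace(model, sizes=sizes)


# ---------------------------------------------------------------------------
# configuration I/O


def _model_to_dict(model: CoarseLMN) -> dict:
    total = model.n_nodes
    return {
        "blocks": [
            {
                "name": model.block_names[k],
                "fraction": float(model.sizes[k] / total),
                "leak_on": float(model.leak_on[k]),
                "leak_off": float(model.leak_off[k]),
                "gain_on": model.gain_on[k].name,
                "gain_off": model.gain_off[k].name,
                "input": float(model.block_input[k]),
            }
            for k in range(model.n_blocks)
        ],
        "weights": [[float(w) for w in row] for row in model.block_weights],
        "N0": float(model.normalizer),
        "omega": float(model.omega),
        "time_unit": model.time_unit,
    }


def _model_from_dict(cfg: dict) -> CoarseLMN:
    blocks = cfg["blocks"]
    N0 = float(cfg["N0"])
    omega = float(cfg["omega"])
    fr = np.array([float(b["fraction"]) for b in blocks])
    if not np.isclose(fr.sum(), 1.0, atol=1e-9):
        raise ValueError("block fractions must sum to 1")
    sizes = np.maximum(1, np.rint(omega * N0 * fr).astype(int))
    return CoarseLMN(
        sizes=sizes,
        block_weights=np.asarray(cfg["weights"], dtype=float),
        block_input=np.array([float(b["input"]) for b in blocks]),
        leak_on=np.array([float(b["leak_on"]) for b in blocks]),
        leak_off=np.array([float(b["leak_off"]) for b in blocks]),
        gain_on=tuple(get_gain(b["gain_on"]) for b in blocks),
        gain_off=tuple(get_gain(b["gain_off"]) for b in blocks),
        normalizer=N0,
        time_unit=str(cfg.get("time_unit", "time")),
        block_names=tuple(str(b["name"]) for b in blocks),
    )


def read_model_config(path) -> CoarseLMN:
    """Load a :class:`CoarseLMN` from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    return _model_from_dict(cfg)


def write_model_config(model: CoarseLMN, path) -> None:
    """Write the model config; round-trips losslessly with the reader."""
    path = Path(path)
    cfg = _model_to_dict(model)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
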