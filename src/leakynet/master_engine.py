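"""Exact probabilistic computations on the coarse lattice chain.

The coarse-grained LMN is a continuous-time Markov chain on the lattice
``{0..N_1} x ... x {0..N_M}`` with single-coordinate birth/death moves.
This module builds the (sparse) generator, solves the master equation
(transient and stationary), provides the closed-form birth-death
stationary law used as an oracle for one-dimensional models, and
computes first-passage times, state exit times, and edge affinities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp

from .model_core import CoarseLMN, CountState

__all__ = [
    "LatticeStateSpace",
    "LatticeDistribution",
    "build_generator",
    "solve_transient",
    "solve_stationary",
    "bd_stationary_closedform",
    "mean_first_passage",
    "state_exit_time",
    "max_abs_affinity",
    "lattice_propensities",
]

DEFAULT_STATE_CAP = 500_000


class StateSpaceCapError(ValueError):
    """The lattice exceeds the configured state cap; resize the model."""


class ReducibleChainError(ValueError):
    """Stationary analysis requires an irreducible (leaky) chain."""


@dataclass(frozen=True)
class LatticeStateSpace:
    """Mixed-radix enumeration of the count lattice, ``n_1`` fastest."""

    sizes: np.ndarray

    def __init__(self, sizes):
        object.__setattr__(self, "sizes", np.atleast_1d(np.asarray(sizes, int)))
        if np.any(self.sizes < 1):
            raise ValueError("all block sizes must be >= 1")

    @classmethod
    def of(cls, model: CoarseLMN) -> "LatticeStateSpace":
        return cls(model.sizes)

    @property
    def n_blocks(self) -> int:
        return self.sizes.shape[0]

    @property
    def cardinality(self) -> int:
        return int(np.prod(self.sizes + 1))

    @property
    def strides(self) -> np.ndarray:
        radices = self.sizes + 1
        return np.concatenate(([1], np.cumprod(radices[:-1])))

    def index_of(self, counts) -> int:
        c = np.asarray(counts, dtype=int)
        if np.any(c < 0) or np.any(c > self.sizes):
            raise ValueError("counts outside lattice")
        return int(c @ self.strides)

    def state_of(self, index: int) -> np.ndarray:
        if not 0 <= index < self.cardinality:
            raise ValueError("index outside lattice")
        out = np.empty(self.n_blocks, dtype=int)
        for k, radix in enumerate(self.sizes + 1):
            out[k] = index % radix
            index //= radix
        return out

    def all_states(self) -> np.ndarray:
        """(cardinality, M) array of count vectors in enumeration order."""
        grids = np.meshgrid(*[np.arange(N + 1) for N in self.sizes],
                            indexing="ij")
        # n_1 fastest: reverse the meshgrid stacking order
        cols = [g.reshape(-1, order="F") for g in grids]
        return np.stack(cols, axis=1)


@dataclass
class LatticeDistribution:
    """Probability vector over a :class:`LatticeStateSpace`."""

    space: LatticeStateSpace
    p: np.ndarray
    time: float | str = "stationary"
    omega: float | None = None

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.space.cardinality,):
            raise ValueError("probability vector has wrong length")
        if np.any(self.p < -1e-12):
            raise ValueError("negative probabilities")
        s = self.p.sum()
        if abs(s - 1.0) > 1e-10:
            raise ValueError(f"probabilities sum to {s}, not 1")

    @classmethod
    def point_mass(cls, space: LatticeStateSpace, counts,
                   time=0.0, omega=None) -> "LatticeDistribution":
        p = np.zeros(space.cardinality)
        p[space.index_of(counts)] = 1.0
        return cls(space, p, time=time, omega=omega)

    def prob(self, counts) -> float:
        return float(self.p[self.space.index_of(counts)])

    def marginal(self, k: int) -> np.ndarray:
        """Marginal law of ``n_k``."""
        states = self.space.all_states()
        N = int(self.space.sizes[k])
        return np.bincount(states[:, k], weights=self.p, minlength=N + 1)

    def total_variation(self, other: "LatticeDistribution") -> float:
        return 0.5 * float(np.abs(self.p - other.p).sum())

    def to_tsv(self, path, sidecar: dict | None = None) -> None:
        """Write states + probabilities as TSV with a JSON sidecar."""
        path = Path(path)
        states = self.space.all_states()
        df = pd.DataFrame(
            states, columns=[f"n_{k + 1}" for k in range(self.space.n_blocks)]
        )
        df["probability"] = self.p
        df.to_csv(path, sep="\t", index=False)
        meta = {"time": self.time, "omega": self.omega,
                "sizes": self.space.sizes.tolist()}
        if sidecar:
            meta.update(sidecar)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2))

    @classmethod
    def from_tsv(cls, path) -> "LatticeDistribution":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        ncols = [c for c in df.columns if c.startswith("n_")]
        sizes = df[ncols].max(axis=0).to_numpy()
        space = LatticeStateSpace(sizes)
        p = np.zeros(space.cardinality)
        for _, row in df.iterrows():
            p[space.index_of(row[ncols].to_numpy(dtype=int))] = row["probability"]
        meta_path = path.with_suffix(path.suffix + ".json")
        time, omega = "stationary", None
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            time, omega = meta.get("time", time), meta.get("omega", omega)
        return cls(space, p / p.sum(), time=time, omega=omega)


# ---------------------------------------------------------------------------
# generator


def lattice_propensities(model: CoarseLMN,
                         space: LatticeStateSpace | None = None):
    """Vectorized birth/death propensities over the whole lattice.

    Returns ``(states, beta, delta)`` where ``beta``/``delta`` are
    ``(cardinality, M)`` arrays.
    """
    if space is None:
        space = LatticeStateSpace.of(model)
    states = space.all_states()
    z = states / model.sizes
    u = model.net_input(z)
    phi = np.column_stack([g.fn(u[:, k]) for k, g in enumerate(model.gain_on)])
    psi = np.column_stack([g.fn(u[:, k]) for k, g in enumerate(model.gain_off)])
    beta = (model.sizes - states) * (model.leak_on + phi)
    delta = states * (model.leak_off + psi)
    if np.any(beta < 0) or np.any(delta < 0):
        raise ValueError("negative propensity encountered on the lattice")
    return states, beta, delta


def build_generator(model: CoarseLMN, *, cap: int = DEFAULT_STATE_CAP,
                    check_irreducible: bool = False) -> sp.csr_matrix:
    """Sparse generator Q (rows = from-state) of the lattice chain.

    Off-diagonal entries hold the birth/death propensities of the
    single-step moves ``n -> n +/- e_k``; the diagonal is minus the row
    sum, so every row sums to zero.
    """
    space = LatticeStateSpace.of(model)
    card = space.cardinality
    if card > cap:
        raise StateSpaceCapError(
            f"lattice has {card} states (> cap {cap}); "
            "resize the model to a smaller network size"
        )
    states, beta, delta = lattice_propensities(model, space)
    strides = space.strides
    idx = np.arange(card)

    rows, cols, vals = [], [], []
    for k in range(space.n_blocks):
        up = states[:, k] < model.sizes[k]
        rows.append(idx[up])
        cols.append(idx[up] + strides[k])
        vals.append(beta[up, k])
        dn = states[:, k] > 0
        rows.append(idx[dn])
        cols.append(idx[dn] - strides[k])
        vals.append(delta[dn, k])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    Q = sp.coo_matrix((vals, (rows, cols)), shape=(card, card)).tocsr()
    Q = Q - sp.diags(np.asarray(Q.sum(axis=1)).ravel())
    if check_irreducible and not _is_irreducible(Q):
        raise ReducibleChainError(
            "generator is reducible; leaky models (all leak rates > 0) "
            "guarantee irreducibility"
        )
    return Q.tocsr()


def _is_irreducible(Q: sp.spmatrix) -> bool:
    n_comp, _ = sp.csgraph.connected_components(
        (Q - sp.diags(Q.diagonal())) != 0, directed=True, connection="strong")
    return n_comp == 1


# ---------------------------------------------------------------------------
# master-equation solves


def solve_transient(Q: sp.spmatrix, p0: LatticeDistribution,
                    times: Sequence[float], *,
                    rtol: float = 1e-8, atol: float = 1e-12,
                    ) -> list[LatticeDistribution]:
    """Integrate ``dp/dt = p Q`` from ``p0`` to the requested times.

    Uses a stiff BDF integrator on the adjoint system; mass is conserved
    to 1e-8 and tiny negative excursions (>-1e-12) are clipped and
    renormalized.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be strictly increasing and >= 0")
    QT = Q.T.tocsr()

    def rhs(_t, p):
        return QT @ p

    t0 = 0.0
    out: list[LatticeDistribution] = []
    eval_times = times
    include_t0 = times[0] == 0.0
    if include_t0:
        out.append(LatticeDistribution(p0.space, p0.p.copy(), time=0.0,
                                       omega=p0.omega))
        eval_times = times[1:]
    if eval_times.size:
        sol = solve_ivp(rhs, (t0, float(eval_times[-1])), p0.p,
                        t_eval=eval_times, method="BDF",
                        jac=QT, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"transient integration failed: {sol.message}")
        for j, t in enumerate(eval_times):
            p = sol.y[:, j]
            if p.min() < -1e-9:
                raise RuntimeError(
                    f"transient solve produced probability {p.min()} at t={t}")
            p = np.clip(p, 0.0, None)
            s = p.sum()
            if abs(s - 1.0) > 1e-6:
                raise RuntimeError(f"mass drifted to {s} at t={t}")
            out.append(LatticeDistribution(p0.space, p / s, time=float(t),
                                           omega=p0.omega))
    return out


def solve_stationary(Q: sp.spmatrix,
                     space: LatticeStateSpace | None = None,
                     omega: float | None = None) -> LatticeDistribution:
    """Stationary distribution pi with ``pi Q = 0`` and ``sum(pi) = 1``.

    Solves the sparse normalized null-space system (one balance equation
    replaced by the normalization constraint).
    """
    n = Q.shape[0]
    if not _is_irreducible(Q):
        raise ReducibleChainError(
            "chain is reducible; stationary analysis requires leaky models "
            "(all leak rates > 0)")
    A = sp.lil_matrix(Q.T.tocsr())
    A[-1, :] = 1.0
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    pi = spla.spsolve(A.tocsc(), rhs)
    if not np.all(np.isfinite(pi)):
        raise ReducibleChainError(
            "stationary solve failed; the chain may be reducible "
            "(requires leak rates > 0)")
    resid = np.abs(Q.T @ pi).max()
    scale = max(1.0, np.abs(Q.data).max()) if Q.nnz else 1.0
    if resid > 1e-8 * scale:
        raise ReducibleChainError(
            f"stationary residual {resid:.2e} too large; chain likely reducible")
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    if space is None:
        sizes = _infer_sizes(n)
        space = LatticeStateSpace(sizes) if sizes is not None else None
    if space is None:
        raise ValueError("pass the LatticeStateSpace explicitly")
    return LatticeDistribution(space, pi, time="stationary", omega=omega)


def _infer_sizes(n):
    # 1-D convenience: an n-state chain is a single block of size n-1
    return np.array([n - 1])


def stationary_of(model: CoarseLMN, *, cap: int = DEFAULT_STATE_CAP
                  ) -> LatticeDistribution:
    """Convenience: generator + stationary solve with proper tagging."""
    Q = build_generator(model, cap=cap)
    return solve_stationary(Q, LatticeStateSpace.of(model), omega=model.omega)


def bd_stationary_closedform(birth, death,
                             space: LatticeStateSpace | None = None
                             ) -> LatticeDistribution:
    """Closed-form stationary law of a 1-D birth-death chain.

    ``birth[m]`` is the rate m -> m+1 (m = 0..N-1), ``death[m-1]`` the
    rate m -> m-1 (m = 1..N).  ``pi(n)`` is proportional to the product
    of ``birth[m-1]/death[m-1]`` over m = 1..n; computed in log space.
    This is the independent oracle for every one-dimensional solve.
    """
    lam = np.asarray(birth, dtype=float)
    mu = np.asarray(death, dtype=float)
    if lam.shape != mu.shape or lam.ndim != 1:
        raise ValueError("birth and death vectors must have equal length")
    if np.any(lam <= 0) or np.any(mu <= 0):
        raise ValueError("closed form requires strictly positive rates")
    logw = np.concatenate(([0.0], np.cumsum(np.log(lam) - np.log(mu))))
    logw -= logw.max()
    pi = np.exp(logw)
    pi /= pi.sum()
    if space is None:
        space = LatticeStateSpace([lam.shape[0]])
    return LatticeDistribution(space, pi, time="stationary")


# ---------------------------------------------------------------------------
# passage times and affinity


def mean_first_passage(Q: sp.spmatrix, space: LatticeStateSpace,
                       start, target: Iterable) -> float:
    """Mean first-passage time from ``start`` into the ``target`` set.

    Solves the linear system ``sum_m Q(n, m) tau(m) = -1`` on non-target
    states with ``tau = 0`` on the target.
    """
    start_idx = space.index_of(
        start.counts if isinstance(start, CountState) else start)
    tgt = {
        space.index_of(t.counts if isinstance(t, CountState) else t)
        for t in target
    }
    if not tgt:
        raise ValueError("target set is empty")
    if start_idx in tgt:
        return 0.0
    n = Q.shape[0]
    keep = np.array(sorted(set(range(n)) - tgt))
    sub = Q.tocsr()[keep][:, keep]
    rhs = -np.ones(keep.shape[0])
    try:
        tau = spla.spsolve(sub.tocsc(), rhs)
    except RuntimeError as e:  # pragma: no cover
        raise ValueError(f"singular first-passage system: {e}") from None
    if not np.all(np.isfinite(tau)) or np.any(tau < -1e-9):
        raise ValueError("first-passage system is singular "
                         "(target unreachable from some state)")
    pos = np.searchsorted(keep, start_idx)
    return float(tau[pos])


def state_exit_time(model: CoarseLMN, state) -> float:
    """Expected holding time 1 / (total propensity) at a lattice state.

    Returns ``inf`` for absorbing states.  For the one-block SISa model
    at the origin this is exactly ``1 / (N a)``.
    """
    beta, delta = _propensities_at(model, state)
    total = float(beta.sum() + delta.sum())
    if total == 0.0:
        return float("inf")
    return 1.0 / total


def _propensities_at(model, state):
    from .model_core import coarse_propensities

    return coarse_propensities(model, state)


def max_abs_affinity(Q: sp.spmatrix, p: LatticeDistribution) -> float:
    """Maximum absolute edge affinity of distribution ``p`` on chain Q.

    For every ordered transition pair (n, n') with Q(n,n') > 0, the
    affinity is ``ln[p(n) Q(n,n')] - ln[p(n') Q(n',n)]``; the maximum
    absolute value is zero iff ``p`` satisfies detailed balance on Q.
    """
    Qc = Q.tocoo()
    mask = (Qc.row != Qc.col) & (Qc.data > 0)
    rows, cols, fwd = Qc.row[mask], Qc.col[mask], Qc.data[mask]
    Qr = Q.tocsr()
    rev = np.asarray(Qr[cols, rows]).ravel()
    if np.any(rev <= 0):
        raise ValueError("transition with zero reverse rate; affinity undefined")
    pn = p.p[rows]
    pm = p.p[cols]
    if np.any(pn <= 0) or np.any(pm <= 0):
        raise ValueError("affinity requires strictly positive probabilities "
                         "on states with transitions")
    aff = np.log(pn * fwd) - np.log(pm * rev)
    return float(np.abs(aff).max()) if aff.size else 0.0
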