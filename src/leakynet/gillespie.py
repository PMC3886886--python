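"""Exact stochastic simulation (direct-method SSA) of coarse LMN models.

Event logs record ``(time, block, direction)`` with direction +1 for an
activation and -1 for a deactivation.  Runs are reproducible bit-for-bit
from ``(model, seed, t_end)`` via a counter-based PCG64 generator, and
logs can be streamed to disk in chunks for very long records.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .master_engine import LatticeDistribution, LatticeStateSpace
from .model_core import CoarseLMN, CountState

__all__ = [
    "EventTrajectory",
    "simulate",
    "trajectory_to_series",
    "empirical_stationary",
    "write_event_log",
    "read_event_log",
]


@dataclass
class EventTrajectory:
    """Ordered (time, block, direction) event log of one SSA run."""

    model_hash: str
    initial: np.ndarray
    times: np.ndarray
    blocks: np.ndarray
    directions: np.ndarray
    t_end: float
    seed: int
    time_unit: str = "time"
    absorbed: bool = False

    @property
    def n_events(self) -> int:
        return self.times.shape[0]

    def activation_times(self) -> np.ndarray:
        """Times of +1 events (firings / infections)."""
        return self.times[self.directions == 1]

    def final_counts(self) -> np.ndarray:
        counts = self.initial.copy()
        for k in range(len(counts)):
            sel = self.blocks == k
            counts[k] += int(self.directions[sel].sum())
        return counts


def _scalar_gain(g):
    """Fast scalar versions of the registered gains for the SSA loop."""
    if g.name == "zero":
        return lambda u: 0.0
    if g.name == "identity":
        return lambda u: u
    if g.name == "tanh_plus":
        return lambda u: math.tanh(u) if u > 0.0 else 0.0
    fn = g.fn
    return lambda u: float(fn(u))


def simulate(model: CoarseLMN, t_end: float, seed: int,
             initial=None, *, sink: Callable | None = None,
             chunk: int = 1_000_000) -> EventTrajectory:
    """Direct-method SSA run of the coarse lattice chain.

    Waiting times are exponential with the total propensity; the channel
    is drawn proportionally to the individual propensities.  If ``sink``
    is given it is called with ``(times, blocks, directions)`` numpy
    chunks as they fill (events are then not retained in memory).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    sizes = model.sizes.astype(np.int64)
    M = sizes.shape[0]
    if initial is None:
        counts = np.zeros(M, dtype=np.int64)
    else:
        if isinstance(initial, CountState):
            initial = initial.counts
        counts = np.asarray(initial, dtype=np.int64).copy()
        CountState(counts).validate(model)
    init = counts.copy()

    rng = np.random.default_rng(np.random.PCG64(seed))
    a = model.leak_on
    b = model.leak_off
    h = model.block_input
    W = model.block_weights
    gains_on = [_scalar_gain(g) for g in model.gain_on]
    gains_off = [_scalar_gain(g) for g in model.gain_off]

    t = 0.0
    times_buf: list[np.ndarray] = []
    blocks_buf: list[np.ndarray] = []
    dirs_buf: list[np.ndarray] = []
    ct = np.empty(chunk)
    cb = np.empty(chunk, dtype=np.int16)
    cd = np.empty(chunk, dtype=np.int8)
    fill = 0
    absorbed = False

    def flush():
        nonlocal fill
        if fill == 0:
            return
        chunk_t = ct[:fill].copy()
        chunk_b = cb[:fill].copy()
        chunk_d = cd[:fill].copy()
        if sink is not None:
            sink(chunk_t, chunk_b, chunk_d)
        else:
            times_buf.append(chunk_t)
            blocks_buf.append(chunk_b)
            dirs_buf.append(chunk_d)
        fill = 0

    # plain-scalar inner loop: rng.choice / array ops are too slow per event
    sizes_l = [int(s) for s in sizes]
    a_l = [float(v) for v in a]
    b_l = [float(v) for v in b]
    h_l = [float(v) for v in h]
    W_l = [[float(w) for w in row] for row in W]
    counts_l = [int(c) for c in counts]
    rates = [0.0] * (2 * M)
    while True:
        total = 0.0
        for k in range(M):
            u = h_l[k]
            for l in range(M):
                u += W_l[k][l] * counts_l[l] / sizes_l[l]
            rk_on = (sizes_l[k] - counts_l[k]) * (a_l[k] + float(gains_on[k](u)))
            rk_off = counts_l[k] * (b_l[k] + float(gains_off[k](u)))
            rates[k] = rk_on
            rates[M + k] = rk_off
            total += rk_on + rk_off
        if total <= 0.0:
            absorbed = True
            break
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            break
        r = rng.random() * total
        acc = 0.0
        ch = 2 * M - 1
        for j in range(2 * M):
            acc += rates[j]
            if r < acc:
                ch = j
                break
        if ch < M:
            counts_l[ch] += 1
            k, d = ch, 1
        else:
            counts_l[ch - M] -= 1
            k, d = ch - M, -1
        ct[fill] = t
        cb[fill] = k
        cd[fill] = d
        fill += 1
        if fill == chunk:
            flush()
    flush()

    if sink is not None:
        times = np.empty(0)
        blocks = np.empty(0, dtype=np.int16)
        dirs = np.empty(0, dtype=np.int8)
    else:
        times = np.concatenate(times_buf) if times_buf else np.empty(0)
        blocks = (np.concatenate(blocks_buf) if blocks_buf
                  else np.empty(0, dtype=np.int16))
        dirs = (np.concatenate(dirs_buf) if dirs_buf
                else np.empty(0, dtype=np.int8))
    return EventTrajectory(
        model_hash=model.model_hash(),
        initial=init,
        times=times,
        blocks=blocks,
        directions=dirs,
        t_end=float(t_end),
        seed=int(seed),
        time_unit=model.time_unit,
        absorbed=absorbed,
    )


def trajectory_to_series(traj: EventTrajectory, query_times=None):
    """Piecewise-constant fraction series from an event log.

    Without ``query_times`` returns the native right-continuous step
    series ``(times, fractions, total)`` sampled at 0 and at every event
    time; with ``query_times`` the series is sampled there instead.
    Fractions are per-block ``n_k / N_k``; ``total`` is the overall
    active fraction ``sum_k n_k / sum_k N_k``.
    """
    # reconstruct per-block sizes from the trajectory bounds is not
    # possible; carry counts only (caller has the model for sizes)
    M = traj.initial.shape[0]
    counts = np.zeros((traj.n_events + 1, M), dtype=np.int64)
    counts[0] = traj.initial
    if traj.n_events:
        deltas = np.zeros((traj.n_events, M), dtype=np.int64)
        deltas[np.arange(traj.n_events), traj.blocks] = traj.directions
        counts[1:] = traj.initial + np.cumsum(deltas, axis=0)
    knots = np.concatenate(([0.0], traj.times))
    if np.any(counts < 0):
        raise ValueError("event log leaves the lattice (negative count)")
    if query_times is None:
        return knots, counts
    q = np.asarray(query_times, dtype=float)
    if np.any(q < 0):
        raise ValueError("query before time 0")
    pos = np.searchsorted(knots, q, side="right") - 1
    return q, counts[pos]


def empirical_stationary(traj: EventTrajectory, model: CoarseLMN,
                         burn_in: float = 0.0) -> LatticeDistribution:
    """Time-weighted occupancy of the lattice after ``burn_in``."""
    if traj.t_end - burn_in <= 0:
        raise ValueError("burn_in must leave a positive observation window")
    space = LatticeStateSpace.of(model)
    knots, counts = trajectory_to_series(traj)
    # segment j occupies [knots[j], knots[j+1]); last runs to t_end
    ends = np.concatenate((knots[1:], [traj.t_end]))
    starts = knots
    durations = np.clip(ends, burn_in, None) - np.clip(starts, burn_in, None)
    durations = np.clip(durations, 0.0, None)
    weights = np.zeros(space.cardinality)
    idx = counts @ space.strides
    np.add.at(weights, idx, durations)
    total = weights.sum()
    if total <= 0:
        raise ValueError("no observation time after burn-in")
    return LatticeDistribution(space, weights / total, time="empirical",
                               omega=model.omega)


# ---------------------------------------------------------------------------
# event-log I/O


def write_event_log(traj: EventTrajectory, path) -> None:
    """TSV event log (time, block, direction) + JSON header sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time\tblock\tdirection\n")
        for t, k, d in zip(traj.times, traj.blocks, traj.directions):
            fh.write(f"{float(t)!r}\t{int(k)}\t{int(d)}\n")
    header = {
        "model_hash": traj.model_hash,
        "seed": traj.seed,
        "t_end": traj.t_end,
        "time_unit": traj.time_unit,
        "initial": traj.initial.tolist(),
        "absorbed": traj.absorbed,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(header, indent=2))


def read_event_log(path) -> EventTrajectory:
    path = Path(path)
    data = np.genfromtxt(path, delimiter="\t", skip_header=1,
                         dtype=None, encoding=None)
    if data.size == 0:
        times = np.empty(0)
        blocks = np.empty(0, dtype=np.int16)
        dirs = np.empty(0, dtype=np.int8)
    else:
        data = np.atleast_1d(data)
        times = np.array([row[0] for row in data], dtype=float)
        blocks = np.array([row[1] for row in data], dtype=np.int16)
        dirs = np.array([row[2] for row in data], dtype=np.int8)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("event times must be strictly increasing")
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = (json.loads(meta_path.read_text()) if meta_path.exists() else {})
    nblocks = int(blocks.max()) + 1 if blocks.size else 1
    initial = np.asarray(meta.get("initial", [0] * nblocks), dtype=np.int64)
    return EventTrajectory(
        model_hash=meta.get("model_hash", ""),
        initial=initial,
        times=times,
        blocks=blocks,
        directions=dirs,
        t_end=float(meta.get("t_end", times[-1] if times.size else 0.0)),
        seed=int(meta.get("seed", -1)),
        time_unit=meta.get("time_unit", "time"),
        absorbed=bool(meta.get("absorbed", False)),
    )
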