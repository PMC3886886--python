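"""Avalanche detection, power-law diagnostics, and shape collapse.

Two detectors are provided:

* threshold detector — an avalanche is a maximal half-open interval on
  which the total active fraction is >= theta (ties at the threshold
  belong to the avalanche); its size counts the activation events inside;
* bin detector — time is partitioned into equal bins and an avalanche is
  a maximal run of consecutive nonempty bins delimited by empty bins;
  the per-bin event counts form the avalanche shape.

Size distributions are log-binned and fit by ordinary least squares in
log-log coordinates (the adjusted R^2 of that line is the scale-free
diagnostic).  Mean size vs duration yields the scaling exponent gamma,
and rescaling mean shapes by ``T^(1-gamma)`` with time mapped to [0, 1]
gives the shape collapse; the collapse error is the across-duration
variance of the rescaled shapes averaged over the common grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Avalanche",
    "AvalancheCatalog",
    "BinnedAvalancheSet",
    "PowerLawFit",
    "CollapseResult",
    "detect_threshold_avalanches",
    "fit_size_distribution",
    "rsq_vs_omega",
    "bin_avalanches",
    "size_duration_scaling",
    "shape_collapse",
    "synth_selfsimilar_avalanches",
]


@dataclass(frozen=True)
class Avalanche:
    start: float
    end: float
    activation_count: int
    fractional_size: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class AvalancheCatalog:
    """Threshold-detected avalanches over an observation span."""

    threshold: float
    avalanches: list[Avalanche]
    span: float
    time_unit: str = "time"

    @property
    def count(self) -> int:
        return len(self.avalanches)

    @property
    def rate(self) -> float:
        """Avalanches per time unit."""
        return self.count / self.span if self.span > 0 else 0.0

    @property
    def fractional_sizes(self) -> np.ndarray:
        return np.array([a.fractional_size for a in self.avalanches])

    @property
    def durations(self) -> np.ndarray:
        return np.array([a.duration for a in self.avalanches])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "start": [a.start for a in self.avalanches],
                "end": [a.end for a in self.avalanches],
                "duration": [a.duration for a in self.avalanches],
                "size": [a.activation_count for a in self.avalanches],
                "fractional_size": [a.fractional_size for a in self.avalanches],
            }
        )
        df.to_csv(path, sep="\t", index=False)


@dataclass
class BinnedAvalancheSet:
    """Bin-detected avalanches: durations in bins, sizes in events."""

    delta: float
    durations: np.ndarray          # integer bin counts per avalanche
    sizes: np.ndarray              # total events per avalanche
    shapes: list[np.ndarray]       # per-bin event counts
    truncated: np.ndarray          # touches a record boundary
    n_bins: int

    @property
    def count(self) -> int:
        return self.durations.shape[0]

    def durations_time(self) -> np.ndarray:
        return self.durations * self.delta

    def filtered(self, include_truncated: bool = False) -> "BinnedAvalancheSet":
        if include_truncated:
            return self
        keep = ~self.truncated
        return BinnedAvalancheSet(
            delta=self.delta,
            durations=self.durations[keep],
            sizes=self.sizes[keep],
            shapes=[s for s, k in zip(self.shapes, keep) if k],
            truncated=self.truncated[keep],
            n_bins=self.n_bins,
        )


@dataclass
class PowerLawFit:
    slope: float
    intercept: float
    adj_r_squared: float
    fit_range: tuple[float, float]
    bin_edges: np.ndarray
    n_points: int

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "slope": self.slope,
            "intercept": self.intercept,
            "adj_r_squared": self.adj_r_squared,
            "fit_range": list(self.fit_range),
            "n_points": self.n_points,
        }, indent=2))


@dataclass
class CollapseResult:
    gamma: float
    grid: np.ndarray               # common rescaled-time grid in [0, 1]
    rescaled_shapes: dict[int, np.ndarray]
    collapse_error: float

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "gamma": self.gamma,
            "grid": self.grid.tolist(),
            "rescaled_shapes": {str(k): v.tolist()
                                for k, v in self.rescaled_shapes.items()},
            "collapse_error": self.collapse_error,
        }, indent=2))


# ---------------------------------------------------------------------------
# threshold detector


def detect_threshold_avalanches(traj, model, theta: float
                                ) -> AvalancheCatalog:
    """Threshold avalanches of an event trajectory.

    An avalanche is a maximal half-open interval [start, end) on which
    the total active fraction is >= theta; its size counts the +1 events
    with time in the interval, and its fractional size divides by the
    total node count.
    """
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must lie in (0, 1]")
    N = int(model.sizes.sum())
    total0 = int(np.asarray(traj.initial).sum())
    totals = total0 + np.concatenate(
        ([0], np.cumsum(traj.directions.astype(np.int64))))
    knots = np.concatenate(([0.0], traj.times))
    frac = totals / N
    active = frac >= theta

    avalanches: list[Avalanche] = []
    i = 0
    n = active.shape[0]
    while i < n:
        if not active[i]:
            i += 1
            continue
        j = i
        while j < n and active[j]:
            j += 1
        start = knots[i]
        end = knots[j] if j < n else traj.t_end
        sel = (traj.times >= start) & (traj.times < end) & (traj.directions == 1)
        count = int(sel.sum())
        if count > 0:
            avalanches.append(Avalanche(start=float(start), end=float(end),
                                        activation_count=count,
                                        fractional_size=count / N))
        i = j
    return AvalancheCatalog(threshold=theta, avalanches=avalanches,
                            span=float(traj.t_end),
                            time_unit=getattr(traj, "time_unit", "time"))


# ---------------------------------------------------------------------------
# power-law fit of the size distribution


def fit_size_distribution(catalog: AvalancheCatalog,
                          s_range: tuple[float, float] | None = None,
                          *, bins_per_decade: int = 50,
                          min_avalanches: int = 10) -> PowerLawFit:
    """OLS power-law fit of the log-binned fractional-size density.

    Sizes are histogrammed into logarithmic bins (empty bins dropped,
    not zero-filled); the regression of log-density on log-size runs
    over the nonempty bins inside ``s_range`` (default [theta, 1)).
    """
    sizes = catalog.fractional_sizes
    if s_range is None:
        s_range = (catalog.threshold, 1.0)
    lo, hi = s_range
    in_range = sizes[(sizes >= lo) & (sizes < hi)]
    if in_range.size < min_avalanches:
        raise ValueError(
            f"only {in_range.size} avalanches in range; need {min_avalanches}")
    n_decades = np.log10(hi / lo)
    n_bins = max(2, int(np.ceil(bins_per_decade * n_decades)))
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    hist, _ = np.histogram(in_range, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    nonempty = hist > 0
    if nonempty.sum() < 3:
        raise ValueError("fewer than 3 nonempty log-bins; cannot fit")
    dens = hist[nonempty] / (widths[nonempty] * in_range.size)
    x = np.log10(centers[nonempty])
    y = np.log10(dens)
    slope, intercept, r2 = _ols(x, y)
    m = x.size
    adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
    return PowerLawFit(slope=float(slope), intercept=float(intercept),
                       adj_r_squared=float(adj), fit_range=(lo, hi),
                       bin_edges=edges, n_points=int(m))


def _ols(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    syy = ((y - ym) ** 2).sum()
    r2 = 1.0 - (resid ** 2).sum() / syy if syy > 0 else 1.0
    return slope, intercept, r2


def rsq_vs_omega(model, omega_grid: Sequence[float], *, t_end: float,
                 theta: float, seed: int = 0, burn_in: float = 0.0,
                 smooth_degree: int = 4) -> pd.DataFrame:
    """Adjusted R^2 of the size-distribution fit per network size.

    Runs a seeded SSA at each Omega, detects threshold avalanches, fits
    the size distribution, and (for grids with > degree points) adds a
    least-squares polynomial smoother column.
    """
    from .gillespie import simulate
    from .model_core import resize

    rows = []
    for i, om in enumerate(np.asarray(omega_grid, float)):
        m = resize(model, om)
        traj = simulate(m, t_end, seed + i)
        try:
            cat = detect_threshold_avalanches(traj, m, theta)
            fit = fit_size_distribution(cat)
            rows.append({"omega": m.omega, "adj_r_squared": fit.adj_r_squared,
                         "n_avalanches": cat.count})
        except ValueError:
            rows.append({"omega": m.omega, "adj_r_squared": np.nan,
                         "n_avalanches": 0})
    df = pd.DataFrame(rows)
    ok = df["adj_r_squared"].notna()
    if ok.sum() > smooth_degree:
        coeffs = np.polyfit(df.loc[ok, "omega"], df.loc[ok, "adj_r_squared"],
                            smooth_degree)
        df["smoothed"] = np.polyval(coeffs, df["omega"])
    return df


# ---------------------------------------------------------------------------
# bin detector


def bin_avalanches(event_times, delta: float, *,
                   t_start: float = 0.0, t_end: float | None = None
                   ) -> BinnedAvalancheSet:
    """Bin activation events and extract maximal nonempty-bin runs."""
    if delta <= 0:
        raise ValueError("bin width delta must be positive")
    times = np.sort(np.asarray(event_times, dtype=float))
    if t_end is None:
        t_end = times[-1] + delta if times.size else t_start + delta
    n_bins = int(np.ceil((t_end - t_start) / delta))
    if times.size == 0:
        return BinnedAvalancheSet(delta=delta,
                                  durations=np.empty(0, int),
                                  sizes=np.empty(0, int), shapes=[],
                                  truncated=np.empty(0, bool), n_bins=n_bins)
    bin_idx = np.floor((times - t_start) / delta).astype(np.int64)
    bin_idx = np.clip(bin_idx, 0, n_bins - 1)
    occupied, counts = np.unique(bin_idx, return_counts=True)

    durations, sizes, shapes, truncated = [], [], [], []
    run_start = 0
    breaks = np.nonzero(np.diff(occupied) > 1)[0]
    bounds = np.concatenate(([0], breaks + 1, [occupied.size]))
    for s, e in zip(bounds[:-1], bounds[1:]):
        bins = occupied[s:e]
        shape = counts[s:e]
        durations.append(bins.size)
        sizes.append(int(shape.sum()))
        shapes.append(shape.astype(np.int64))
        truncated.append(bool(bins[0] == 0 or bins[-1] == n_bins - 1))
    return BinnedAvalancheSet(
        delta=float(delta),
        durations=np.array(durations, dtype=np.int64),
        sizes=np.array(sizes, dtype=np.int64),
        shapes=shapes,
        truncated=np.array(truncated, dtype=bool),
        n_bins=n_bins,
    )


def size_duration_scaling(avset: BinnedAvalancheSet, *,
                          min_count: int = 10,
                          include_truncated: bool = False):
    """Exponent gamma from OLS of log mean size on log duration.

    Avalanches are grouped by duration (in bins); groups with fewer than
    ``min_count`` members are dropped.  Returns ``(gamma, diagnostics)``
    where diagnostics holds the group table and fit statistics.
    """
    avset = avset.filtered(include_truncated)
    if avset.count == 0:
        raise ValueError("no avalanches to fit")
    durations = avset.durations
    uniq, inverse, counts = np.unique(durations, return_inverse=True,
                                      return_counts=True)
    mean_sizes = np.bincount(inverse, weights=avset.sizes) / counts
    keep = counts >= min_count
    if keep.sum() < 3:
        raise ValueError(
            f"need >= 3 duration groups with >= {min_count} avalanches; "
            f"have {int(keep.sum())}")
    T = uniq[keep] * avset.delta
    S = mean_sizes[keep]
    slope, intercept, r2 = _ols(np.log10(T), np.log10(S))
    diagnostics = {
        "durations": T,
        "mean_sizes": S,
        "group_counts": counts[keep],
        "intercept": float(intercept),
        "r_squared": float(r2),
    }
    return float(slope), diagnostics


def shape_collapse(avset: BinnedAvalancheSet, gamma: float, *,
                   n_grid: int = 101, min_count: int = 2,
                   durations: Sequence[int] | None = None,
                   include_truncated: bool = False) -> CollapseResult:
    """Collapse mean avalanche shapes onto a single scaling function.

    The mean shape of each duration group is scaled by ``T^(1-gamma)``
    and its time axis mapped onto [0, 1]; shapes are pinned to zero at
    both rescaled endpoints (no activity immediately before or after an
    avalanche) and linearly interpolated onto a common grid.  The
    collapse error is the across-duration variance averaged over the
    grid, normalized by the squared mean rescaled height.
    """
    avset = avset.filtered(include_truncated)
    uniq, inverse, counts = np.unique(avset.durations, return_inverse=True,
                                      return_counts=True)
    if durations is not None:
        wanted = set(int(d) for d in durations)
        sel_durs = [d for d in uniq if int(d) in wanted]
    else:
        sel_durs = [d for d, c in zip(uniq, counts) if c >= min_count and d >= 2]
    if len(sel_durs) < 2:
        raise ValueError("need mean shapes for at least 2 distinct durations")

    grid = np.linspace(0.0, 1.0, n_grid)
    rescaled: dict[int, np.ndarray] = {}
    for d in sel_durs:
        members = [s for s, di in zip(avset.shapes, avset.durations) if di == d]
        if not members:
            raise ValueError(f"no shapes of duration {d}")
        mean_shape = np.mean(np.stack(members), axis=0)
        T = d * avset.delta
        scaled = mean_shape * T ** (1.0 - gamma)
        # pin to zero at both rescaled endpoints; interior bins at centers
        xs = np.concatenate(([0.0], (np.arange(d) + 0.5) / d, [1.0]))
        ys = np.concatenate(([0.0], scaled, [0.0]))
        rescaled[int(d)] = np.interp(grid, xs, ys)

    stack = np.stack(list(rescaled.values()))
    var = stack.var(axis=0).mean()
    scale = np.mean(stack) ** 2
    err = float(var / scale) if scale > 0 else float(var)
    return CollapseResult(gamma=float(gamma), grid=grid,
                          rescaled_shapes=rescaled, collapse_error=err)


# ---------------------------------------------------------------------------
# self-similar fixture generator


def synth_selfsimilar_avalanches(gamma: float,
                                 scaling_fn: Callable[[np.ndarray], np.ndarray],
                                 durations: Sequence[int],
                                 counts: Sequence[int] | int,
                                 noise: str = "none",
                                 seed: int = 0,
                                 delta: float = 1.0,
                                 amplitude: float = 50.0,
                                 normalize_sizes: bool = False
                                 ) -> BinnedAvalancheSet:
    """Generate avalanches with exact (or Poisson-noisy) self-similar shapes.

    Each avalanche of duration ``T = d * delta`` has per-bin expected
    counts ``amplitude * T^(gamma-1) * F((t + 1/2)/d)``, so the
    bin-detector pipeline must recover ``gamma`` and collapse with zero
    error when noise is off.  With ``normalize_sizes`` each shape is
    scaled so the total size is exactly ``amplitude * T^gamma`` (makes
    the size-duration exponent exact regardless of how the discrete bin
    sum of the scaling function tracks its integral).
    """
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    durations = [int(d) for d in durations]
    if any(d < 2 for d in durations):
        raise ValueError("durations must span at least 2 bins")
    if isinstance(counts, int):
        counts = [counts] * len(durations)
    if noise not in ("none", "poisson"):
        raise ValueError("noise must be 'none' or 'poisson'")
    rng = np.random.default_rng(seed)

    all_durations, all_sizes, all_shapes, trunc = [], [], [], []
    for d, c in zip(durations, counts):
        T = d * delta
        u = (np.arange(d) + 0.5) / d
        expected = amplitude * T ** (gamma - 1.0) * np.asarray(scaling_fn(u),
                                                              dtype=float)
        if np.any(expected < 0):
            raise ValueError("scaling function must be nonnegative")
        if normalize_sizes:
            expected *= amplitude * T ** gamma / expected.sum()
        for _ in range(c):
            if noise == "poisson":
                shape = rng.poisson(expected)
            else:
                shape = expected.copy()
            all_durations.append(d)
            all_sizes.append(shape.sum())
            all_shapes.append(shape)
            trunc.append(False)
    return BinnedAvalancheSet(
        delta=float(delta),
        durations=np.array(all_durations, dtype=np.int64),
        sizes=np.array(all_sizes),
        shapes=all_shapes,
        truncated=np.array(trunc, dtype=bool),
        n_bins=int(max(durations)),
    )
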