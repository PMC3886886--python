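"""Potential-energy landscapes and network-size thermodynamics.

The potential of a strictly positive distribution ``p`` is
``V(n) = ln[p(n*) / p(n)]`` with ``n*`` the most probable state, so the
ground state(s) sit at ``V = 0`` and ``exp(-V)/Z`` reproduces ``p``.
From ``p`` we compute (all in nats, Boltzmann constant 1):

* internal potential energy  ``U = E[V] = S - I*``
* entropy                    ``S = -sum p ln p``
* self-information of the most likely state  ``I* = -ln p(n*)``
* free potential energy      ``F = U - S = -I*``

Sweeping the network size Omega yields pressure-like Omega-derivatives
(``Pi = -dU/dOmega``, ``P = dI*/dOmega = -dF/dOmega``) and the bulk
modulus ``B = Omega * |dP/dOmega|``, whose pulse marks the critical
network size at which the stationary ground state reallocates between
the macroscopic well and the inactive origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .macro_lna import find_fixed_point, macro_system
from .master_engine import LatticeDistribution, LatticeStateSpace, stationary_of
from .model_core import CoarseLMN, resize

__all__ = [
    "PotentialLandscape",
    "ThermoPoint",
    "ThermoProfile",
    "potential_from_distribution",
    "thermo_point",
    "sweep_omega",
    "detect_critical_size",
    "critical_vs_parameter",
]


@dataclass
class PotentialLandscape:
    """Potential values over a lattice, zero at the ground state(s)."""

    space: LatticeStateSpace
    V: np.ndarray
    ground_states: list[np.ndarray]
    omega: float | None = None
    source: float | str = "stationary"

    def value(self, counts) -> float:
        return float(self.V[self.space.index_of(counts)])

    def to_distribution(self) -> LatticeDistribution:
        """Boltzmann reconstruction exp(-V)/Z of the source distribution."""
        w = np.exp(-self.V)
        return LatticeDistribution(self.space, w / w.sum(),
                                   time=self.source, omega=self.omega)


@dataclass
class ThermoPoint:
    """Thermodynamic summary of one distribution at network size Omega."""

    omega: float
    U: float
    S: float
    F: float
    Istar: float
    Pi: float = np.nan
    P: float = np.nan
    B: float = np.nan


@dataclass
class ThermoProfile:
    """Ordered thermodynamic points over an Omega grid."""

    points: list[ThermoPoint]
    ground_states: list[tuple[int, ...]]
    V_origin: np.ndarray
    V_macro: np.ndarray
    macro_fixed_point: np.ndarray
    critical_size: float | None = None
    critical_size_bulk: float | None = None
    detectors_agree: bool | None = None

    @property
    def omegas(self) -> np.ndarray:
        return np.array([pt.omega for pt in self.points])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "omega": [pt.omega for pt in self.points],
                "U": [pt.U for pt in self.points],
                "S": [pt.S for pt in self.points],
                "F": [pt.F for pt in self.points],
                "Istar": [pt.Istar for pt in self.points],
                "Pi": [pt.Pi for pt in self.points],
                "P": [pt.P for pt in self.points],
                "B": [pt.B for pt in self.points],
                "V_origin": self.V_origin,
                "V_macro": self.V_macro,
            }
        )
        df["ground_state"] = [
            ",".join(map(str, gs)) for gs in self.ground_states
        ]
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def potential_from_distribution(p: LatticeDistribution, *,
                                tie_rtol: float = 1e-9
                                ) -> PotentialLandscape:
    """Potential ``V(n) = ln[p(n*)/p(n)]`` of a strictly positive law.

    States whose probability is within relative ``tie_rtol`` of the
    maximum all count as ground states; the enumeration-order (i.e.
    lexicographically with ``n_1`` fastest) smallest one defines ``n*``.

    States whose probability underflowed the stationary solver's
    precision (exactly zero in double precision) get ``V = +inf``; if
    more than half the lattice is zero the distribution is treated as
    structurally non-leaky and rejected.
    """
    zero = p.p <= 0.0
    if zero.mean() > 0.5:
        raise ValueError(
            "potential undefined: most states have zero probability; "
            "use leaky parameters (all leak rates > 0)"
        )
    pmax = p.p.max()
    ground_idx = np.nonzero(p.p >= pmax * (1.0 - tie_rtol))[0]
    with np.errstate(divide="ignore"):
        V = np.log(pmax) - np.log(p.p)
    V[ground_idx] = 0.0
    grounds = [p.space.state_of(int(i)) for i in ground_idx]
    return PotentialLandscape(p.space, V, grounds, omega=p.omega,
                              source=p.time)


def thermo_point(p: LatticeDistribution, omega: float) -> ThermoPoint:
    """Compute (U, S, F, I*) for one distribution; no pressures yet."""
    mask = p.p > 0
    S = float(-(p.p[mask] * np.log(p.p[mask])).sum())
    Istar = float(-np.log(p.p.max()))
    U = S - Istar
    F = U - S
    # re-verify the defining identity U = E[V] on the supported states
    V_supported = np.log(p.p.max()) - np.log(p.p[mask])
    U_direct = float((p.p[mask] * V_supported).sum())
    if abs(U_direct - U) > 1e-9 * max(1.0, abs(U)):
        raise AssertionError("thermodynamic identity U = S - I* violated")
    return ThermoPoint(omega=omega, U=U, S=S, F=F, Istar=Istar)


def _finite_differences(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Central differences at interior points, one-sided at the ends."""
    return np.gradient(y, x)


def nearest_lattice_state(space: LatticeStateSpace, x: np.ndarray) -> np.ndarray:
    """Lattice state whose fractions are Euclidean-nearest to ``x``
    (componentwise rounding; ties resolved downward = lexicographic)."""
    target = np.asarray(x, float) * space.sizes
    lo = np.floor(target).astype(int)
    # round-half-down so ties go to the lexicographically smaller state
    n = np.where(target - lo > 0.5, lo + 1, lo)
    return np.clip(n, 0, space.sizes)


def sweep_omega(model: CoarseLMN, omega_grid: Sequence[float], *,
                progress: bool = False) -> ThermoProfile:
    """Resize/solve/summarize over an Omega grid and attach pressures.

    For every grid value the model is resized, the stationary law solved
    exactly, and (U, S, F, I*) recorded together with the potential at
    the origin and at the lattice state nearest the macroscopic fixed
    point.  Pressures use central differences on the realized (integer
    node count) Omega values; duplicate realized sizes are collapsed.
    """
    omega_grid = np.asarray(omega_grid, dtype=float)
    if omega_grid.ndim != 1 or omega_grid.size < 5:
        raise ValueError("need a grid of at least 5 network sizes")
    if np.any(np.diff(omega_grid) <= 0):
        raise ValueError("omega grid must be strictly increasing")

    xstar = find_fixed_point(macro_system(model))

    points: list[ThermoPoint] = []
    grounds: list[tuple[int, ...]] = []
    v_origin: list[float] = []
    v_macro: list[float] = []
    seen_sizes: set[tuple[int, ...]] = set()
    for om in omega_grid:
        m = resize(model, om)
        key = tuple(int(s) for s in m.sizes)
        if key in seen_sizes:
            continue
        seen_sizes.add(key)
        try:
            pi = stationary_of(m)
        except Exception as e:
            raise RuntimeError(f"stationary solve failed at omega={om}: {e}")
        pt = thermo_point(pi, m.omega)
        land = potential_from_distribution(pi)
        points.append(pt)
        grounds.append(tuple(int(v) for v in land.ground_states[0]))
        origin = np.zeros(m.n_blocks, dtype=int)
        v_origin.append(land.value(origin))
        v_macro.append(land.value(nearest_lattice_state(land.space, xstar)))
        if progress:  # pragma: no cover
            print(f"omega={m.omega:.4f} U={pt.U:.4f} I*={pt.Istar:.4f}")

    om = np.array([pt.omega for pt in points])
    U = np.array([pt.U for pt in points])
    Istar = np.array([pt.Istar for pt in points])
    Pi = -_finite_differences(om, U)
    P = _finite_differences(om, Istar)
    B = om * np.abs(_finite_differences(om, P))
    for pt, pi_v, p_v, b_v in zip(points, Pi, P, B):
        pt.Pi, pt.P, pt.B = float(pi_v), float(p_v), float(b_v)

    profile = ThermoProfile(
        points=points,
        ground_states=grounds,
        V_origin=np.array(v_origin),
        V_macro=np.array(v_macro),
        macro_fixed_point=xstar,
    )
    _attach_critical(profile)
    return profile


class NoCriticalSizeError(ValueError):
    """No ground-state crossing inside the scanned Omega range."""


def detect_critical_size(profile: ThermoProfile) -> float:
    """Critical network size from the ground-state reallocation.

    Primary detector: the Omega at which ``V(origin) - V(macro-well)``
    changes sign (linear interpolation between bracketing grid points).
    Secondary detector: the argmax of the bulk modulus; both stored on
    the profile with an agreement flag (within one grid step).
    """
    _attach_critical(profile)
    if profile.critical_size is None:
        diff = profile.V_origin - profile.V_macro
        mono = "origin" if np.all(diff <= 0) else "macroscopic well"
        raise NoCriticalSizeError(
            f"no critical size in range: ground state stays at the {mono} "
            f"over omega in [{profile.omegas[0]}, {profile.omegas[-1]}]"
        )
    return profile.critical_size


def _attach_critical(profile: ThermoProfile) -> None:
    om = profile.omegas
    diff = profile.V_origin - profile.V_macro  # > 0 where macro well wins
    crossing = None
    for j in range(len(om) - 1):
        if diff[j] == 0.0:
            crossing = float(om[j])
            break
        if diff[j] * diff[j + 1] < 0:
            frac = diff[j] / (diff[j] - diff[j + 1])
            crossing = float(om[j] + frac * (om[j + 1] - om[j]))
            break
    profile.critical_size = crossing
    B = np.array([pt.B for pt in profile.points])
    if np.all(np.isnan(B)):
        profile.critical_size_bulk = None
    else:
        profile.critical_size_bulk = float(om[int(np.nanargmax(B))])
    if crossing is not None and profile.critical_size_bulk is not None:
        step = np.max(np.diff(om))
        profile.detectors_agree = bool(
            abs(crossing - profile.critical_size_bulk) <= 1.5 * step)


def critical_vs_parameter(model_family: Callable[[float], CoarseLMN],
                          param_grid: Sequence[float],
                          omega_grid: Sequence[float]) -> pd.DataFrame:
    """Critical size as a function of a model parameter.

    ``model_family(value)`` must return a valid model; parameter values
    for which no crossing exists in the Omega range yield NaN.
    """
    rows = []
    for val in param_grid:
        model = model_family(float(val))
        try:
            profile = sweep_omega(model, omega_grid)
            oc = detect_critical_size(profile)
        except NoCriticalSizeError:
            oc = np.nan
        rows.append({"param": float(val), "omega_c": oc})
    return pd.DataFrame(rows)
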