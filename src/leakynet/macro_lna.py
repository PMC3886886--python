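"""Macroscopic rate equations and the linear noise approximation (LNA).

The deterministic limit of the fractional activity process obeys

    dx_k/dt = g_k(x) = (1 - x_k)[a_k + phi_k(u_k(x))] - x_k[b_k + psi_k(u_k(x))]

on the unit hypercube.  The LNA places a Gaussian around the stable
fixed point ``x*`` with covariance ``C`` solving the Lyapunov equation
``A C + C A^T + D = 0``, where ``A`` is the drift Jacobian at ``x*`` and
``D = diag(r_k / N_k)`` with ``r_k`` the total per-node jump rate at
``x*`` (jump sizes are ``1/N_k`` on the fraction lattice).  For
zero-coupling models this reproduces the exact binomial variance
``x*(1 - x*)/N`` — the convention that fixes the diffusion scaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_continuous_lyapunov
from scipy.optimize import root

from .model_core import CoarseLMN

__all__ = [
    "MacroSystem",
    "LNAResult",
    "macro_system",
    "integrate_macro",
    "find_fixed_point",
    "lna",
    "lna_lattice_distribution",
    "lna_landscape",
]


@dataclass(frozen=True)
class MacroSystem:
    """Deterministic drift of the fractional activity process."""

    model: CoarseLMN

    @property
    def dim(self) -> int:
        return self.model.n_blocks

    def drift(self, x: np.ndarray) -> np.ndarray:
        m = self.model
        x = np.asarray(x, dtype=float)
        u = m.net_input(x)
        phi = np.array([float(g(u[k])) for k, g in enumerate(m.gain_on)])
        psi = np.array([float(g(u[k])) for k, g in enumerate(m.gain_off)])
        return (1.0 - x) * (m.leak_on + phi) - x * (m.leak_off + psi)

    def jacobian(self, x: np.ndarray, *, fd_step: float = 1e-6) -> np.ndarray:
        """Analytic Jacobian when gain derivatives are registered,
        otherwise central finite differences."""
        m = self.model
        x = np.asarray(x, dtype=float)
        have_derivs = all(g.deriv is not None for g in m.gain_on) and all(
            g.deriv is not None for g in m.gain_off)
        if have_derivs:
            u = m.net_input(x)
            phi = np.array([float(g(u[k])) for k, g in enumerate(m.gain_on)])
            psi = np.array([float(g(u[k])) for k, g in enumerate(m.gain_off)])
            dphi = np.array([float(g.deriv(u[k])) for k, g in enumerate(m.gain_on)])
            dpsi = np.array([float(g.deriv(u[k])) for k, g in enumerate(m.gain_off)])
            A = ((1.0 - x) * dphi - x * dpsi)[:, None] * m.block_weights
            A[np.diag_indices_from(A)] += -(m.leak_on + phi) - (m.leak_off + psi)
            return A
        M = self.dim
        A = np.empty((M, M))
        for j in range(M):
            e = np.zeros(M)
            e[j] = fd_step
            A[:, j] = (self.drift(x + e) - self.drift(x - e)) / (2 * fd_step)
        return A


def macro_system(model: CoarseLMN) -> MacroSystem:
    return MacroSystem(model)


def integrate_macro(system: MacroSystem, x0, t_grid: Sequence[float]):
    """Integrate the macroscopic ODE; returns (t_grid, (T, M) trajectory)."""
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if np.any(x0 < 0) or np.any(x0 > 1):
        raise ValueError("initial condition must lie in the unit hypercube")
    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(lambda _t, x: system.drift(x), (t_grid[0], t_grid[-1]),
                    x0, t_eval=t_grid, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"macroscopic integration failed: {sol.message}")
    traj = sol.y.T
    if traj.min() < -1e-9 or traj.max() > 1 + 1e-9:
        raise RuntimeError("trajectory left the unit hypercube")
    return t_grid, np.clip(traj, 0.0, 1.0)


def find_fixed_point(system: MacroSystem, *, t_horizon: float | None = None,
                     multistart: int = 0, warn=None) -> np.ndarray:
    """Stable fixed point of the macroscopic flow.

    Integrates from the hypercube center for a long horizon, then
    polishes with a root finder to ``||g(x*)|| <= 1e-12``.  With
    ``multistart > 0``, additional corners are integrated to detect
    multiple attractors (the analysis assumes a unique stable interior
    fixed point).
    """
    m = system.model
    if t_horizon is None:
        scale = float(np.min(m.leak_on + m.leak_off))
        t_horizon = 200.0 / max(scale, 1e-6)
    x0 = np.full(system.dim, 0.5)
    _, traj = integrate_macro(system, x0, [0.0, t_horizon])
    guess = traj[-1]
    sol = root(system.drift, guess, jac=system.jacobian, tol=1e-14)
    xstar = sol.x
    if np.max(np.abs(system.drift(xstar))) > 1e-10:
        raise RuntimeError("fixed-point polishing did not converge")
    xstar = np.clip(xstar, 0.0, 1.0)
    if warn is None:
        warn = lambda msg: None
    if np.any(xstar < 1e-6) or np.any(xstar > 1 - 1e-6):
        warn("fixed point is boundary-adjacent")
    if multistart:
        rng = np.random.default_rng(0)
        for _ in range(multistart):
            y0 = rng.uniform(0, 1, system.dim)
            _, tr = integrate_macro(system, y0, [0.0, t_horizon])
            alt = root(system.drift, tr[-1], jac=system.jacobian, tol=1e-14).x
            if np.linalg.norm(alt - xstar) > 1e-4:
                warn(f"multiple fixed points detected: {alt} vs {xstar}")
    return xstar


@dataclass
class LNAResult:
    """Gaussian stationary approximation around the macroscopic fixed point."""

    fixed_point: np.ndarray
    jacobian: np.ndarray
    diffusion: np.ndarray
    covariance: np.ndarray
    stable: bool
    model: CoarseLMN

    def to_json(self, path) -> None:
        payload = {
            "fixed_point": self.fixed_point.tolist(),
            "jacobian": self.jacobian.tolist(),
            "diffusion": self.diffusion.tolist(),
            "covariance": self.covariance.tolist(),
            "stable": self.stable,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def lna(model: CoarseLMN) -> LNAResult:
    """Linear noise approximation at the stable macroscopic fixed point."""
    system = macro_system(model)
    xstar = find_fixed_point(system)
    A = system.jacobian(xstar)
    eig = np.linalg.eigvals(A)
    stable = bool(np.all(eig.real < 0))
    if not stable:
        raise ValueError("LNA invalid: unstable fixed point "
                         f"(Jacobian eigenvalues {eig})")
    u = model.net_input(xstar)
    phi = np.array([float(g(u[k])) for k, g in enumerate(model.gain_on)])
    psi = np.array([float(g(u[k])) for k, g in enumerate(model.gain_off)])
    r = (1.0 - xstar) * (model.leak_on + phi) + xstar * (model.leak_off + psi)
    D = np.diag(r / model.sizes)
    # A C + C A^T = -D
    C = solve_continuous_lyapunov(A, -D)
    C = 0.5 * (C + C.T)
    return LNAResult(fixed_point=xstar, jacobian=A, diffusion=D,
                     covariance=C, stable=stable, model=model)


def lna_lattice_distribution(result: LNAResult, space):
    """LNA Gaussian discretized and renormalized on the count lattice.

    Also records (as ``.mass_outside``) the Gaussian probability mass
    lying outside the unit hypercube — the pathology that makes the LNA
    unreliable near criticality.
    """
    from scipy.stats import multivariate_normal

    from .master_engine import LatticeDistribution

    C = result.covariance
    if np.linalg.matrix_rank(C) < C.shape[0]:
        raise ValueError("singular LNA covariance")
    states = space.all_states()
    z = states / space.sizes
    mvn = multivariate_normal(mean=result.fixed_point, cov=C)
    dens = mvn.pdf(z)
    dens = np.atleast_1d(dens)
    total = dens.sum()
    if total <= 0:
        raise ValueError("Gaussian density vanishes on the lattice")
    dist = LatticeDistribution(space, dens / total, time="stationary",
                               omega=result.model.omega)
    lo = np.zeros(C.shape[0])
    hi = np.ones(C.shape[0])
    inside = _box_mass(mvn, lo, hi)
    dist.mass_outside = float(max(0.0, 1.0 - inside))
    return dist


def _box_mass(mvn, lo, hi):
    dim = lo.shape[0]
    if dim == 1:
        from scipy.stats import norm

        mu = mvn.mean[0]
        sd = np.sqrt(mvn.cov[0, 0])
        return float(norm.cdf(hi[0], mu, sd) - norm.cdf(lo[0], mu, sd))
    # inclusion-exclusion over the CDF corners
    total = 0.0
    for mask in range(1 << dim):
        corner = np.where([(mask >> k) & 1 for k in range(dim)], hi, lo)
        sign = (-1) ** (dim - bin(mask).count("1"))
        total += sign * float(mvn.cdf(corner))
    return total


def lna_landscape(result: LNAResult, space):
    """Quadratic LNA potential ``(z - x*)^T C^{-1} (z - x*) / 2`` on the
    lattice, shifted so its lattice minimum is zero."""
    from .landscape_thermo import PotentialLandscape

    C = result.covariance
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        raise ValueError("singular LNA covariance") from None
    states = space.all_states()
    z = states / space.sizes
    d = z - result.fixed_point
    V = 0.5 * np.einsum("ij,jk,ik->i", d, Cinv, d)
    V -= V.min()
    ground_idx = np.nonzero(V <= V.min() + 1e-15)[0]
    grounds = [space.state_of(int(i)) for i in ground_idx]
    return PotentialLandscape(space, V, grounds,
                              omega=result.model.omega, source="lna")
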