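"""Registry of named scalar gain functions.

Gain functions map a real net input ``u`` to a nonnegative rate
contribution.  They are referenced by name in model configurations so
that models remain serializable; user code may register additional
functions (optionally with an analytic derivative, used by the
linear-noise machinery when available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = ["GainFunction", "register_gain", "get_gain", "available_gains"]


@dataclass(frozen=True)
class GainFunction:
    """A named nonnegative scalar function with optional derivative.

    Both ``fn`` and ``deriv`` must accept and return numpy arrays
    (vectorized evaluation over lattices relies on this).
    """

    name: str
    fn: Callable[[np.ndarray], np.ndarray]
    deriv: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __call__(self, u):
        return self.fn(np.asarray(u, dtype=float))


_REGISTRY: dict[str, GainFunction] = {}


def register_gain(name, fn, deriv=None, *, overwrite=False):
    """Register a gain function under ``name``.

    Parameters
    ----------
    name : str
        Registry key used in model configs.
    fn : callable
        Vectorized nonnegative function of the net input.
    deriv : callable, optional
        Vectorized derivative; enables analytic Jacobians downstream.
    overwrite : bool
        Allow replacing an existing entry.
    """
    if name in _REGISTRY and not overwrite:
        raise ValueError(f"gain function {name!r} already registered")
    g = GainFunction(name, fn, deriv)
    _REGISTRY[name] = g
    return g


def get_gain(name: str) -> GainFunction:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown gain function {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def available_gains() -> list[str]:
    return sorted(_REGISTRY)


def _tanh_plus(u):
    u = np.asarray(u, dtype=float)
    return np.where(u > 0.0, np.tanh(u), 0.0)


def _tanh_plus_deriv(u):
    u = np.asarray(u, dtype=float)
    return np.where(u > 0.0, 1.0 - np.tanh(u) ** 2, 0.0)


register_gain("zero", lambda u: np.zeros_like(np.asarray(u, dtype=float)),
              lambda u: np.zeros_like(np.asarray(u, dtype=float)))
register_gain("identity", lambda u: np.asarray(u, dtype=float),
              lambda u: np.ones_like(np.asarray(u, dtype=float)))
register_gain("tanh_plus", _tanh_plus, _tanh_plus_deriv)
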