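"""Growth-curve families.

A growth curve is a known nonlinear function ``g(phi, t)`` mapping an
``m``-vector of plant-level parameters and a time point to an expected
measurement.  Curves carry named fixed constants (for instance the logistic
scale ``gamma``) that are known, not estimated.  A small registry lets users
plug in any evaluable curve; the fitting machinery only ever calls
``curve.evaluate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict

import numpy as np

__all__ = [
    "GrowthCurve",
    "logistic_curve",
    "asymptotic_regression_curve",
    "register_curve",
    "get_curve",
    "available_curves",
]


class CurveError(ValueError):
    """Invalid curve constant, domain violation, or registry conflict."""


@dataclass(frozen=True)
class GrowthCurve:
    """A named curve family ``g(phi, t)`` with ``m`` plant-level parameters.

    ``evaluate`` is vectorized: ``phi`` has shape ``(..., m)`` and ``t`` any
    shape broadcastable against ``phi[..., 0]``; the result has the broadcast
    shape.  Scalar and vectorized evaluation agree elementwise.
    """

    name: str
    m: int
    evaluate_fn: Callable[..., np.ndarray]
    constants: Dict[str, float] = field(default_factory=dict)

    def evaluate(self, phi, t):
        phi = np.asarray(phi, dtype=float)
        if phi.shape[-1] != self.m:
            raise CurveError(
                f"curve '{self.name}' expects {self.m} parameters, "
                f"got phi with last axis {phi.shape[-1]}"
            )
        return self.evaluate_fn(phi, np.asarray(t, dtype=float), **self.constants)

    def with_constants(self, **constants) -> "GrowthCurve":
        """Return a copy with updated fixed constants."""
        merged = dict(self.constants)
        unknown = set(constants) - set(merged)
        if unknown:
            raise CurveError(f"unknown constants for '{self.name}': {sorted(unknown)}")
        merged.update(constants)
        return GrowthCurve(self.name, self.m, self.evaluate_fn, merged)


def logistic_curve(phi, gamma: float, t):
    """Logistic growth ``A / (1 + exp(-gamma (t - x)))``.

    ``phi = (A, x)`` with ``A`` the asymptote and ``x`` the time of
    half-maximum; ``gamma > 0`` is the fixed scale.  ``g(phi, x) = A/2``
    exactly for any ``gamma``.
    """
    if gamma <= 0:
        raise CurveError(f"logistic scale gamma must be > 0, got {gamma}")
    phi = np.asarray(phi, dtype=float)
    a = phi[..., 0]
    x = phi[..., 1]
    t = np.asarray(t, dtype=float)
    if t.ndim and a.ndim:
        a = a[..., None]
        x = x[..., None]
    # exp argument clipped to keep the value finite for extreme proposals
    z = np.clip(-gamma * (t - x), -700.0, 700.0)
    return a / (1.0 + np.exp(z))


def _logistic_eval(phi, t, gamma):
    return logistic_curve(phi, gamma, t)


def asymptotic_regression_curve(phi, t):
    """Asymptotic regression ``phi1 (1 - exp(-exp(phi2) t))`` for ``t >= 0``.

    Saturates at ``phi1``; ``exp(phi2)`` is the rate constant of the
    exponential approach to the asymptote.  Monotone nondecreasing in ``t``
    when ``phi1 > 0``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise CurveError("asymptotic regression curve requires t >= 0")
    phi = np.asarray(phi, dtype=float)
    a = phi[..., 0]
    b = phi[..., 1]
    if t.ndim and a.ndim:
        a = a[..., None]
        b = b[..., None]
    rate = np.exp(np.clip(b, -700.0, 700.0))
    return a * (-np.expm1(-np.clip(rate * t, 0.0, 700.0)))


def _asymptotic_eval(phi, t):
    return asymptotic_regression_curve(phi, t)


def _constant_eval(phi, t):
    # degenerate "curve" g(phi, t) = phi1: reduces the model to a linear
    # mixed model; used for analytic cross-checks
    phi = np.asarray(phi, dtype=float)
    a = phi[..., 0]
    t = np.asarray(t, dtype=float)
    if t.ndim and a.ndim:
        a = a[..., None]
    return a * np.ones_like(t)


_REGISTRY: Dict[str, GrowthCurve] = {}


def register_curve(curve: GrowthCurve, probe_phi=None, probe_t: float = 1.0) -> GrowthCurve:
    """Register a curve under its name; returns the registered curve.

    The curve is probed at one point to catch non-evaluable definitions
    early.  Duplicate names are an error.
    """
    if curve.name in _REGISTRY:
        raise CurveError(f"curve '{curve.name}' already registered")
    if curve.m < 1:
        raise CurveError("a growth curve needs at least one parameter")
    phi = np.ones(curve.m) if probe_phi is None else np.asarray(probe_phi, dtype=float)
    value = curve.evaluate(phi, probe_t)
    if not np.all(np.isfinite(value)):
        raise CurveError(f"curve '{curve.name}' evaluates non-finite at probe point")
    _REGISTRY[curve.name] = curve
    return curve


def get_curve(name: str, **constants) -> GrowthCurve:
    """Fetch a registered curve by name, optionally overriding constants."""
    try:
        curve = _REGISTRY[name]
    except KeyError:
        raise CurveError(
            f"unknown curve '{name}'; available: {sorted(_REGISTRY)}"
        ) from None
    return curve.with_constants(**constants) if constants else curve


def available_curves():
    return sorted(_REGISTRY)


register_curve(
    GrowthCurve("logistic", 2, _logistic_eval, {"gamma": 0.3}),
    probe_phi=(50.0, 13.0),
)
register_curve(
    GrowthCurve("asymptotic_regression", 2, _asymptotic_eval),
    probe_phi=(4.41, -6.12),
)
register_curve(GrowthCurve("constant", 1, _constant_eval))
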