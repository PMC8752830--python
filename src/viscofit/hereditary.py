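"""Hereditary (Boltzmann-superposition) integrals for spherical indentation.

For a spherical probe of radius ``R`` on an incompressible half-space the
stiffness-side map from an indentation history ``h(t)`` to force is

    F(t) = [8 sqrt(R) / (3 (1 - nu))] * int_0^t G(t - z) d/dz[h(z)^{3/2}] dz

and the compliance-side map from force to ``h^{3/2}`` uses the creep
compliance ``J`` with the reciprocal prefactor.

Discretization
--------------
Curves start from zero contact (``h(0) = F(0) = 0``), so a second
integration by parts moves the time derivative off the sampled data and
onto the smooth material kernel:

    int_0^t G(t - z) y'(z) dz = G(0) y(t) + int_0^t G'(t - z) y(z) dz

with ``y = h^{3/2}``.  The remaining convolution has an analytic kernel
(a sum of decaying exponentials) and is evaluated with the trapezoidal
rule on the uniform acquisition grid.  Each exponential term admits an
exact first-order recursion, implemented via :func:`scipy.signal.lfilter`,
so the cost is O(n) per arm.  For a zero-arm (purely elastic) model the
scheme reduces *exactly* to the closed-form Hertz expression at every
sample, and the overall quadrature error is O(dt^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .core_models import (
    GeneralizedKelvinVoigt,
    GeneralizedMaxwell,
)
from .exceptions import DomainError, NonUniformGridError

__all__ = [
    "ContactGeometry",
    "lr_prefactor",
    "uniform_dt",
    "exp_convolve_trap",
    "ramp_exp_convolve_trap",
    "predict_force",
    "predict_indentation",
    "action_integral",
]

_GRID_RTOL = 1e-6


@dataclass(frozen=True)
class ContactGeometry:
    """Spherical probe radius ``R`` (m) and sample Poisson ratio ``nu``.

    ``nu = 0.5`` (incompressible limit) is allowed; the contact prefactor
    uses ``(1 - nu)`` and stays finite.
    """

    R: float
    nu: float = 0.5

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise DomainError(f"probe radius must be > 0, got {self.R}")
        if not (0.0 <= self.nu <= 0.5):
            raise DomainError(f"Poisson ratio must be in [0, 0.5], got {self.nu}")


def lr_prefactor(geom: ContactGeometry) -> float:
    """Contact scale ``8 sqrt(R) / (3 (1 - nu))`` of the spherical framework."""
    return 8.0 * np.sqrt(geom.R) / (3.0 * (1.0 - geom.nu))


def uniform_dt(t: np.ndarray) -> float:
    """Return the grid spacing, validating uniformity and a zero origin."""
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise NonUniformGridError("time grid must be a 1-D array with >= 2 samples")
    if abs(t[0]) > _GRID_RTOL * (t[-1] - t[0]):
        raise NonUniformGridError("time grid must start at 0")
    dts = np.diff(t)
    dt = float(dts[0])
    if dt <= 0 or np.any(np.abs(dts - dt) > _GRID_RTOL * dt):
        raise NonUniformGridError(
            "time grid must be strictly increasing and uniformly spaced; "
            "resample the curve before calling"
        )
    return dt


def exp_convolve_trap(tau: float, y: np.ndarray, dt: float) -> np.ndarray:
    """Trapezoidal convolution ``S_i = int_0^{t_i} exp(-(t_i - z)/tau) y(z) dz``.

    Requires ``y[0] == 0``; under that condition the first-order recursion

        S_i = a S_{i-1} + (dt/2) (a y_{i-1} + y_i),   a = exp(-dt/tau)

    reproduces the trapezoidal sum exactly and runs in O(n).
    """
    a = np.exp(-dt / tau)
    return lfilter([dt / 2.0, a * dt / 2.0], [1.0, -a], y)


def ramp_exp_convolve_trap(tau: float, y: np.ndarray, dt: float) -> np.ndarray:
    """Trapezoidal convolution of the kernel ``t * exp(-t/tau)`` with ``y``.

    Used by analytic Jacobians (the tau-derivative of an exponential kernel).
    Requires ``y[0] == 0``; the kernel vanishes at 0 so trapezoid endpoint
    corrections drop out and a second-order recursion suffices.
    """
    a = np.exp(-dt / tau)
    return lfilter([0.0, a * dt * dt], [1.0, -2.0 * a, a * a], y)


def _check_series(t, x, name: str) -> tuple[np.ndarray, np.ndarray, float]:
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    dt = uniform_dt(t)
    if x.shape != t.shape:
        raise DomainError(f"{name} and t must have identical shapes")
    return t, x, dt


def maxwell_convolution(model: GeneralizedMaxwell, t, y32) -> np.ndarray:
    """Evaluate ``int_0^t G(t - z) d[y32]/dz dz`` on the grid (no prefactor).

    ``y32`` is the ``h^{3/2}`` series with ``y32[0] = 0``.
    """
    t, y, dt = _check_series(t, y32, "h^{3/2}")
    out = model.glassy_modulus * y
    for gn, tau in model.arms:
        out = out - (gn / tau) * exp_convolve_trap(tau, y, dt)
    return out


def kelvinvoigt_convolution(model: GeneralizedKelvinVoigt, t, F) -> np.ndarray:
    """Evaluate ``int_0^t J(t - z) dF/dz dz`` on the grid (no prefactor)."""
    t, f, dt = _check_series(t, F, "F")
    out = model.Jg * f
    for jn, tau in model.arms:
        out = out + (jn / tau) * exp_convolve_trap(tau, f, dt)
    return out


def predict_force(model: GeneralizedMaxwell, t, h, geom: ContactGeometry) -> np.ndarray:
    """Force series (N) for an indentation history on a uniform grid.

    ``h`` must be non-negative with ``h[0] = 0`` (contact at the origin).
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise DomainError("indentation must be >= 0")
    if h.size and h[0] != 0.0:
        raise DomainError("indentation must start at 0 (contact at t=0)")
    y = h ** 1.5
    return lr_prefactor(geom) * maxwell_convolution(model, t, y)


def predict_indentation(
    model: GeneralizedKelvinVoigt, t, F, geom: ContactGeometry
) -> np.ndarray:
    """``h^{3/2}`` series (m^{3/2}) for a force history on a uniform grid."""
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise DomainError("force must be >= 0 on the repulsive segment")
    if F.size and F[0] != 0.0:
        raise DomainError("force must start at 0 (contact at t=0)")
    return kelvinvoigt_convolution(model, t, F) / lr_prefactor(geom)


def action_integral(model, curve, geom: ContactGeometry | None = None):
    """Return ``(normalized_observable, model_convolution)`` for a curve.

    These are the two series the SSE fitting cost compares.  For the
    Maxwell family the observable is the normalized force
    ``(3 (1 - nu) / (8 sqrt(R))) F(t)`` and the model side is the relaxation
    convolution of ``h^{3/2}``; for the Kelvin-Voigt family the observable
    is ``h^{3/2}`` and the model side is the creep convolution of ``F``
    scaled by the reciprocal prefactor.
    """
    geom = geom if geom is not None else curve.geom
    pref = lr_prefactor(geom)
    y = np.asarray(curve.h, dtype=float) ** 1.5
    if isinstance(model, GeneralizedMaxwell):
        obs = np.asarray(curve.F, dtype=float) / pref
        pred = maxwell_convolution(model, curve.t, y)
        return obs, pred
    if isinstance(model, GeneralizedKelvinVoigt):
        obs = y
        pred = kelvinvoigt_convolution(model, curve.t, curve.F) / pref
        return obs, pred
    raise TypeError(f"unsupported model type {type(model)!r}")
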