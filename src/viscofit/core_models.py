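"""Generalized Maxwell and generalized Kelvin-Voigt material models.

Both models are discrete spring/dashpot (Prony) series.  The stiffness-side
generalized Maxwell model is described by its relaxation modulus

    G(t) = Ge + sum_n Gn * exp(-t / tau_n)

and the compliance-side generalized Kelvin-Voigt model by its creep
compliance

    J(t) = Jg + sum_n Jn * (1 - exp(-t / tau_n)).

The differential-operator response functions (relaxance / retardance)
contain impulsive terms and are therefore never materialized in the time
domain; every computation in this package goes through ``G(t)``, ``J(t)``
or the closed-form harmonic expressions below.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .exceptions import DomainError, UnsupportedConversionError

__all__ = [
    "GeneralizedMaxwell",
    "GeneralizedKelvinVoigt",
    "relaxation_modulus",
    "creep_compliance",
    "harmonic_moduli",
    "loss_angle",
    "sls_interconvert",
    "model_to_dict",
    "model_from_dict",
    "model_to_json",
    "model_from_json",
]


def _check_arms(arms) -> tuple[tuple[float, float], ...]:
    out = tuple((float(g), float(tau)) for g, tau in arms)
    for g, tau in out:
        if g <= 0:
            raise DomainError(f"arm magnitude must be > 0, got {g}")
        if tau <= 0:
            raise DomainError(f"arm timescale must be > 0, got {tau}")
    taus = [tau for _, tau in out]
    if any(b <= a for a, b in zip(taus, taus[1:])):
        raise DomainError(f"arm timescales must be strictly increasing, got {taus}")
    return out


@dataclass(frozen=True)
class GeneralizedMaxwell:
    """Equilibrium modulus ``Ge`` (Pa) plus ordered ``(Gn, tau_n)`` arms.

    Arm timescales are strictly increasing: arm 1 is the fastest.
    """

    Ge: float
    arms: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "Ge", float(self.Ge))
        if self.Ge <= 0:
            raise DomainError(f"Ge must be > 0, got {self.Ge}")
        object.__setattr__(self, "arms", _check_arms(self.arms))

    @property
    def n_arms(self) -> int:
        return len(self.arms)

    @property
    def moduli(self) -> np.ndarray:
        return np.array([g for g, _ in self.arms], dtype=float)

    @property
    def taus(self) -> np.ndarray:
        return np.array([tau for _, tau in self.arms], dtype=float)

    @property
    def glassy_modulus(self) -> float:
        """Instantaneous modulus G(0) = Ge + sum(Gn)."""
        return self.Ge + float(sum(g for g, _ in self.arms))


@dataclass(frozen=True)
class GeneralizedKelvinVoigt:
    """Glassy compliance ``Jg`` (1/Pa) plus ordered ``(Jn, tau_n)`` arms."""

    Jg: float
    arms: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "Jg", float(self.Jg))
        if self.Jg <= 0:
            raise DomainError(f"Jg must be > 0, got {self.Jg}")
        object.__setattr__(self, "arms", _check_arms(self.arms))

    @property
    def n_arms(self) -> int:
        return len(self.arms)

    @property
    def compliances(self) -> np.ndarray:
        return np.array([j for j, _ in self.arms], dtype=float)

    @property
    def taus(self) -> np.ndarray:
        return np.array([tau for _, tau in self.arms], dtype=float)

    @property
    def equilibrium_compliance(self) -> float:
        """Long-time compliance J(inf) = Jg + sum(Jn)."""
        return self.Jg + float(sum(j for j, _ in self.arms))


Model = Union[GeneralizedMaxwell, GeneralizedKelvinVoigt]


def relaxation_modulus(model: GeneralizedMaxwell, t) -> np.ndarray | float:
    """Relaxation modulus ``G(t) = Ge + sum Gn exp(-t/tau_n)`` in Pa.

    ``t`` may be a scalar or array of non-negative times (s).  The result is
    monotone non-increasing, equals the glassy modulus at ``t = 0`` and tends
    to ``Ge`` as ``t -> inf``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("relaxation_modulus requires t >= 0")
    g = np.full_like(t_arr, model.Ge, dtype=float)
    for gn, tau in model.arms:
        g = g + gn * np.exp(-t_arr / tau)
    return float(g) if np.isscalar(t) or t_arr.ndim == 0 else g


def creep_compliance(model: GeneralizedKelvinVoigt, t) -> np.ndarray | float:
    """Creep compliance ``J(t) = Jg + sum Jn (1 - exp(-t/tau_n))`` in 1/Pa."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("creep_compliance requires t >= 0")
    j = np.full_like(t_arr, model.Jg, dtype=float)
    for jn, tau in model.arms:
        j = j + jn * (1.0 - np.exp(-t_arr / tau))
    return float(j) if np.isscalar(t) or t_arr.ndim == 0 else j


def harmonic_moduli(model: Model, omega) -> tuple[np.ndarray, np.ndarray]:
    """Storage and loss moduli (Pa) at angular frequency ``omega`` (rad/s).

    Maxwell family::

        storage = Ge + sum Gn w^2 tau^2 / (1 + w^2 tau^2)
        loss    = sum Gn w tau / (1 + w^2 tau^2)

    Kelvin-Voigt family: the complex compliance
    ``J' = Jg + sum Jn/(1+w^2 tau^2)``, ``J'' = sum Jn w tau/(1+w^2 tau^2)``
    is inverted to ``storage = J'/(J'^2+J''^2)``, ``loss = J''/(J'^2+J''^2)``.
    """
    w = np.asarray(omega, dtype=float)
    if np.any(w <= 0):
        raise DomainError("harmonic_moduli requires omega > 0")
    scalar = np.isscalar(omega) or w.ndim == 0
    w = np.atleast_1d(w)
    if isinstance(model, GeneralizedMaxwell):
        storage = np.full_like(w, model.Ge)
        loss = np.zeros_like(w)
        for gn, tau in model.arms:
            wt = w * tau
            denom = 1.0 + wt * wt
            storage = storage + gn * wt * wt / denom
            loss = loss + gn * wt / denom
    elif isinstance(model, GeneralizedKelvinVoigt):
        jp = np.full_like(w, model.Jg)
        jpp = np.zeros_like(w)
        for jn, tau in model.arms:
            wt = w * tau
            denom = 1.0 + wt * wt
            jp = jp + jn / denom
            jpp = jpp + jn * wt / denom
        mag2 = jp * jp + jpp * jpp
        storage = jp / mag2
        loss = jpp / mag2
    else:  # pragma: no cover - defensive
        raise TypeError(f"unsupported model type {type(model)!r}")
    if scalar:
        return float(storage[0]), float(loss[0])
    return storage, loss


def loss_angle(storage, loss) -> np.ndarray | float:
    """Loss angle ``atan(loss / storage)`` in degrees, in [0, 90)."""
    s = np.asarray(storage, dtype=float)
    l = np.asarray(loss, dtype=float)
    if np.any(s <= 0):
        raise DomainError("loss_angle requires storage > 0")
    if np.any(l < 0):
        raise DomainError("loss_angle requires loss >= 0")
    ang = np.degrees(np.arctan2(l, s))
    if np.isscalar(storage) and np.isscalar(loss):
        return float(ang)
    return ang


def sls_interconvert(model: Model) -> Model:
    """Convert a single-arm model to its physically equivalent twin.

    A standard linear solid has closed-form dual representations.  For a
    one-arm Maxwell model ``(Ge, G1, tau)``::

        Jg        = 1 / (Ge + G1)
        Jg + J1   = 1 / Ge
        tau_ret   = tau * (Ge + G1) / Ge

    The inverse map (Kelvin-Voigt -> Maxwell) is also supported.  Multi-arm
    interconversion requires Laplace-domain root finding and raises
    :class:`UnsupportedConversionError`.
    """
    if isinstance(model, GeneralizedMaxwell):
        if model.n_arms != 1:
            raise UnsupportedConversionError(
                f"closed-form interconversion requires exactly 1 arm, got {model.n_arms}"
            )
        g1, tau = model.arms[0]
        glassy = model.Ge + g1
        jg = 1.0 / glassy
        j1 = 1.0 / model.Ge - jg
        tau_ret = tau * glassy / model.Ge
        return GeneralizedKelvinVoigt(Jg=jg, arms=((j1, tau_ret),))
    if isinstance(model, GeneralizedKelvinVoigt):
        if model.n_arms != 1:
            raise UnsupportedConversionError(
                f"closed-form interconversion requires exactly 1 arm, got {model.n_arms}"
            )
        j1, tau_ret = model.arms[0]
        ge = 1.0 / (model.Jg + j1)
        glassy = 1.0 / model.Jg
        g1 = glassy - ge
        tau = tau_ret * ge / glassy
        return GeneralizedMaxwell(Ge=ge, arms=((g1, tau),))
    raise TypeError(f"unsupported model type {type(model)!r}")


# --- JSON (de)serialization -------------------------------------------------

def model_to_dict(model: Model) -> dict:
    if isinstance(model, GeneralizedMaxwell):
        return {
            "family": "maxwell",
            "equilibrium_or_glassy": model.Ge,
            "arms": [[g, tau] for g, tau in model.arms],
            "units": "Pa",
        }
    if isinstance(model, GeneralizedKelvinVoigt):
        return {
            "family": "kelvinvoigt",
            "equilibrium_or_glassy": model.Jg,
            "arms": [[j, tau] for j, tau in model.arms],
            "units": "1/Pa",
        }
    raise TypeError(f"unsupported model type {type(model)!r}")


def model_from_dict(doc: dict) -> Model:
    family = doc["family"]
    arms = tuple((float(a), float(b)) for a, b in doc.get("arms", []))
    if family == "maxwell":
        return GeneralizedMaxwell(Ge=float(doc["equilibrium_or_glassy"]), arms=arms)
    if family == "kelvinvoigt":
        return GeneralizedKelvinVoigt(Jg=float(doc["equilibrium_or_glassy"]), arms=arms)
    raise ValueError(f"unknown model family {family!r}")


def model_to_json(model: Model) -> str:
    return json.dumps(model_to_dict(model), sort_keys=True)


def model_from_json(text: str) -> Model:
    return model_from_dict(json.loads(text))
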