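"""Synthetic constant-velocity spherical-indentation force curves.

Generates the repulsive approach segment only: ``h(t) = speed * t`` on a
uniform grid at the instrument sampling rate, force from the generalized
Maxwell hereditary integral, optional additive Gaussian force noise
(seeded).  Every synthetic curve carries its ground-truth model so
recovery tests can close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .core_models import GeneralizedMaxwell
from .exceptions import DomainError
from .hereditary import ContactGeometry, predict_force
from .preprocess_io import MIN_SAMPLES, ForceCurve

__all__ = [
    "RampProtocol",
    "simulate_curve",
    "simulate_population",
    "default_benchmark_model",
    "sample_model",
]


@dataclass(frozen=True)
class RampProtocol:
    """Constant-velocity approach ramp.

    Exactly one trigger criterion (``max_force`` in N or ``max_indentation``
    in m) must be set.  ``noise_sd`` is the SD of additive Gaussian force
    noise in N, applied after the trigger is evaluated.
    """

    speed: float = 2.0e-6
    sampling_rate: float = 50e3
    max_force: Optional[float] = 10e-9
    max_indentation: Optional[float] = None
    noise_sd: float = 0.0
    seed: int = 0
    max_duration: float = 10.0

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise DomainError(f"speed must be > 0, got {self.speed}")
        if self.sampling_rate <= 0:
            raise DomainError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if (self.max_force is None) == (self.max_indentation is None):
            raise DomainError("exactly one of max_force / max_indentation must be set")
        if self.noise_sd < 0:
            raise DomainError(f"noise_sd must be >= 0, got {self.noise_sd}")


def _grid(protocol: RampProtocol, duration: float) -> np.ndarray:
    n = int(np.floor(duration * protocol.sampling_rate)) + 1
    return np.arange(n) / protocol.sampling_rate


def simulate_curve(
    model: GeneralizedMaxwell,
    protocol: RampProtocol,
    geom: ContactGeometry,
) -> ForceCurve:
    """Simulate one noisy approach curve; deterministic for a given seed."""
    if protocol.max_indentation is not None:
        duration = protocol.max_indentation / protocol.speed
        if duration > protocol.max_duration:
            raise DomainError(
                f"indentation trigger needs {duration:.3g} s > max_duration "
                f"{protocol.max_duration} s"
            )
        t = _grid(protocol, duration)
        h = protocol.speed * t
        F = predict_force(model, t, h, geom)
    else:
        # grow the grid until the force trigger fires
        duration = max(0.05, (MIN_SAMPLES + 1) / protocol.sampling_rate)
        while True:
            t = _grid(protocol, min(duration, protocol.max_duration))
            h = protocol.speed * t
            F = predict_force(model, t, h, geom)
            hit = np.flatnonzero(F >= protocol.max_force)
            if hit.size:
                end = hit[0] + 1
                t, h, F = t[:end], h[:end], F[:end]
                break
            if duration >= protocol.max_duration:
                raise DomainError(
                    f"force trigger {protocol.max_force:.3g} N unreachable within "
                    f"max_duration {protocol.max_duration} s"
                )
            duration *= 2.0

    if t.size < MIN_SAMPLES:
        raise DomainError(
            "trigger fired before the minimum curve length; lower the speed or "
            "raise the trigger"
        )

    if protocol.noise_sd > 0:
        rng = np.random.default_rng(protocol.seed)
        F = F + rng.normal(0.0, protocol.noise_sd, size=F.size)
        F[0] = 0.0  # contact origin stays exact

    return ForceCurve(
        t=t, h=h, F=F, geom=geom,
        sampling_rate=protocol.sampling_rate,
        provenance={
            "synthetic": True,
            "seed": protocol.seed,
            "speed_m_per_s": protocol.speed,
            "noise_sd_n": protocol.noise_sd,
        },
        ground_truth=model,
    ).validate()


def default_benchmark_model(n_arms: int = 3) -> GeneralizedMaxwell:
    """Fixed decade-spaced benchmark model used by the method comparison.

    Timescales start at 1e-4 s and step by decades; magnitudes sit inside
    the default 1e2-1e4 Pa ground-truth range.
    """
    mags = [1200.0, 600.0, 300.0, 150.0]
    if n_arms > len(mags):
        raise DomainError(f"benchmark supports up to {len(mags)} arms")
    arms = tuple((mags[i], 1e-4 * 10.0 ** i) for i in range(n_arms))
    return GeneralizedMaxwell(Ge=400.0, arms=arms)


def sample_model(
    rng: np.random.Generator,
    n_arms: int,
    modulus_range: tuple[float, float] = (1e2, 1e4),
    tau_first: float = 1e-4,
    tau_decade_step: float = 10.0,
) -> GeneralizedMaxwell:
    """Draw a random ground-truth model: log-uniform moduli, decade-spaced taus."""
    lo, hi = np.log10(modulus_range[0]), np.log10(modulus_range[1])
    ge = 10.0 ** rng.uniform(lo, hi)
    arms = []
    for i in range(n_arms):
        g = 10.0 ** rng.uniform(lo, hi)
        tau = tau_first * tau_decade_step ** i
        arms.append((g, tau))
    return GeneralizedMaxwell(Ge=ge, arms=tuple(arms))


ModelSource = Union[
    GeneralizedMaxwell,
    Sequence[GeneralizedMaxwell],
    tuple,  # (base_model, lognormal_sigma) jitter spec
    Callable[[np.random.Generator], GeneralizedMaxwell],
]


def _jittered(base: GeneralizedMaxwell, sigma: float, rng) -> GeneralizedMaxwell:
    ge = base.Ge * np.exp(rng.normal(0.0, sigma))
    arms = tuple(
        (g * np.exp(rng.normal(0.0, sigma)), tau * np.exp(rng.normal(0.0, sigma)))
        for g, tau in base.arms
    )
    return GeneralizedMaxwell(Ge=ge, arms=arms)


def simulate_population(
    models: ModelSource,
    n_curves: int,
    protocol: RampProtocol,
    geom: ContactGeometry,
    seed: int = 0,
) -> list[ForceCurve]:
    """Simulate ``n_curves`` curves with per-curve derived seeds.

    ``models`` may be a single model (replicated), a sequence of models
    (cycled), a ``(base_model, lognormal_sigma)`` jitter spec, or a callable
    ``rng -> model``.  Deterministic given ``seed``.
    """
    if n_curves < 1:
        raise DomainError("n_curves must be >= 1")

    def model_for(i: int) -> GeneralizedMaxwell:
        rng = np.random.default_rng([seed % 2**32, 7, i])
        if isinstance(models, GeneralizedMaxwell):
            return models
        if callable(models):
            return models(rng)
        if (
            isinstance(models, tuple)
            and len(models) == 2
            and isinstance(models[0], GeneralizedMaxwell)
            and np.isscalar(models[1])
        ):
            return _jittered(models[0], float(models[1]), rng)
        if isinstance(models, (list, tuple)) and all(
            isinstance(m, GeneralizedMaxwell) for m in models
        ):
            return models[i % len(models)]
        raise DomainError(f"invalid model source spec: {models!r}")

    out = []
    for i in range(n_curves):
        proto_i = replace(protocol, seed=int(np.random.default_rng(
            [seed % 2**32, 11, i]).integers(0, 2**31)))
        curve = simulate_curve(model_for(i), proto_i, geom)
        curve.provenance["population_index"] = i
        out.append(curve)
    return out
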