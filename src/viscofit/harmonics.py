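"""Frequency-domain storage/loss/loss-angle spectra and their aggregation.

A quasi-static ramp excites mechanical action at all frequencies between
the inverse experiment duration and the sampling rate; spectra are
evaluated on a log-spaced grid over exactly that band.  Population
averaging happens in the frequency domain: each fitted model predicts its
own spectrum, and the aggregate is the pointwise simple average with
Student-t confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .core_models import harmonic_moduli, loss_angle
from .exceptions import DomainError

__all__ = ["HarmonicSpectrum", "frequency_grid", "spectrum", "aggregate"]

_QUANTITIES = ("storage", "loss", "angle")


@dataclass
class HarmonicSpectrum:
    """Storage (Pa), loss (Pa) and loss angle (deg) on a frequency grid (Hz).

    ``bands`` maps each quantity name to a ``(ci_low, ci_high)`` array pair;
    it is empty for single-curve spectra.
    """

    f: np.ndarray
    storage: np.ndarray
    loss: np.ndarray
    angle: np.ndarray
    n: int = 1
    bands: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.storage = np.asarray(self.storage, dtype=float)
        self.loss = np.asarray(self.loss, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if np.any(np.diff(self.f) <= 0):
            raise DomainError("frequency grid must be strictly increasing")


def frequency_grid(duration: float, sampling_rate: float,
                   points_per_decade: int = 50) -> np.ndarray:
    """Log-spaced grid from ``1/duration`` to ``sampling_rate``, inclusive.

    The endpoints equal the stated bounds exactly.
    """
    if duration <= 0 or sampling_rate <= 0:
        raise DomainError("duration and sampling_rate must be > 0")
    f_lo = 1.0 / duration
    f_hi = float(sampling_rate)
    if f_hi <= f_lo:
        raise DomainError(
            f"degenerate band: 1/duration = {f_lo:.3g} Hz >= sampling rate {f_hi:.3g} Hz"
        )
    decades = np.log10(f_hi / f_lo)
    n = max(int(np.ceil(decades * points_per_decade)) + 1, 2)
    grid = np.logspace(np.log10(f_lo), np.log10(f_hi), n)
    grid[0], grid[-1] = f_lo, f_hi
    return grid


def spectrum(model, f, *, angular: bool = True) -> HarmonicSpectrum:
    """Single-model spectrum on grid ``f`` (Hz).

    ``angular=True`` evaluates the harmonic moduli at ``omega = 2 pi f``;
    ``False`` uses ``omega = f`` directly (the Hz-like reciprocal-timestep
    convention).  The choice shifts spectra horizontally by ``2 pi``.
    """
    f = np.asarray(f, dtype=float)
    omega = 2.0 * np.pi * f if angular else f
    storage, loss = harmonic_moduli(model, omega)
    return HarmonicSpectrum(
        f=f, storage=storage, loss=loss, angle=loss_angle(storage, loss), n=1
    )


def aggregate(spectra: list[HarmonicSpectrum], level: float = 0.95,
              band_style: str = "mean") -> HarmonicSpectrum:
    """Pointwise average of spectra sharing one grid, with t-distribution bands.

    ``band_style="mean"`` gives the standard CI of the mean,
    ``mean +/- t * sd / sqrt(n)``; ``band_style="observation"`` gives the
    wider observation range ``mean +/- t * sd``.
    """
    if not spectra:
        raise DomainError("aggregate requires at least one spectrum")
    if band_style not in ("mean", "observation"):
        raise DomainError(f"unknown band style {band_style!r}")
    f = spectra[0].f
    for s in spectra[1:]:
        if s.f.shape != f.shape or not np.allclose(s.f, f, rtol=1e-12):
            raise DomainError("all spectra must share one frequency grid")
    n = len(spectra)
    stacks = {
        "storage": np.vstack([s.storage for s in spectra]),
        "loss": np.vstack([s.loss for s in spectra]),
        "angle": np.vstack([s.angle for s in spectra]),
    }
    means = {q: a.mean(axis=0) for q, a in stacks.items()}
    bands = {}
    if n >= 2:
        tq = float(stats.t.ppf(0.5 * (1.0 + level), n - 1))
        for q, a in stacks.items():
            sd = a.std(axis=0, ddof=1)
            half = tq * sd if band_style == "observation" else tq * sd / np.sqrt(n)
            bands[q] = (means[q] - half, means[q] + half)
    return HarmonicSpectrum(
        f=f, storage=means["storage"], loss=means["loss"], angle=means["angle"],
        n=n, bands=bands,
    )


def write_spectrum_csv(spec: HarmonicSpectrum, path) -> None:
    """CSV export: frequency, quantities, and ci columns when bands exist."""
    cols = ["frequency_hz", "storage_pa", "loss_pa", "loss_angle_deg"]
    data = [spec.f, spec.storage, spec.loss, spec.angle]
    for q, unit in zip(_QUANTITIES, ("storage_pa", "loss_pa", "loss_angle_deg")):
        if q in spec.bands:
            lo, hi = spec.bands[q]
            cols += [f"ci_low_{unit}", f"ci_high_{unit}"]
            data += [lo, hi]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# viscofit harmonic spectrum; n={spec.n}\n")
        fh.write(",".join(cols) + "\n")
        for row in zip(*data):
            fh.write(",".join(repr(float(v)) for v in row) + "\n")
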