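"""Pseudo-elastic (Hertzian) baseline fits and population statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DomainError
from .fitting import fit_elastic
from .hereditary import ContactGeometry, lr_prefactor

__all__ = ["HertzResult", "WelchResult", "fit_hertz", "summarize_population", "welch_test"]


@dataclass(frozen=True)
class HertzResult:
    """Rate-independent moduli from the elastic spherical-contact law.

    ``G`` is the shear-form modulus fitted through the ``8 sqrt(R)/(3(1-nu))``
    prefactor; ``E = 2 G (1 + nu)`` is the Young's-type conversion.
    """

    E: float
    G: float
    sse: float
    curve_id: str = ""


def fit_hertz(curve, geom: ContactGeometry | None = None) -> HertzResult:
    """Closed-form Hertz fit: least-squares slope of normalized force on h^{3/2}."""
    geom = geom if geom is not None else curve.geom
    g = fit_elastic(curve, geom)
    y = np.asarray(curve.h, dtype=float) ** 1.5
    obs = np.asarray(curve.F, dtype=float) / lr_prefactor(geom)
    r = obs - g * y
    return HertzResult(
        E=2.0 * g * (1.0 + geom.nu),
        G=g,
        sse=float(r @ r),
        curve_id=str(curve.provenance.get("source", "")),
    )


def _values(results) -> np.ndarray:
    vals = np.array([r.E if isinstance(r, HertzResult) else float(r) for r in results])
    if vals.size == 0:
        raise DomainError("empty population")
    return vals


def summarize_population(results) -> dict:
    """Median/quartiles/whiskers with outliers beyond 1.5x the interquartile range."""
    vals = np.sort(_values(results))
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    outliers = vals[(vals < lo_fence) | (vals > hi_fence)]
    return {
        "n": int(vals.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "whisker_low": float(inliers.min()),
        "whisker_high": float(inliers.max()),
        "outliers": [float(v) for v in outliers],
        "mean": float(vals.mean()),
    }


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    significant: bool  # at alpha = 0.05


def welch_test(group_a, group_b, alpha: float = 0.05) -> WelchResult:
    """Unpaired two-tailed t-test with Welch's correction.

    Statistic ``t = (mean_a - mean_b) / sqrt(va/na + vb/nb)`` with
    Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0,
                               significant=False)
        raise DomainError("degenerate zero-variance groups with distinct means")
    sa, sb = va / a.size, vb / b.size
    t_stat = float((a.mean() - b.mean()) / np.sqrt(sa + sb))
    df = float((sa + sb) ** 2 / (
        sa**2 / (a.size - 1) + sb**2 / (b.size - 1)
    ))
    p = float(2.0 * stats.t.sf(abs(t_stat), df))
    return WelchResult(t=t_stat, df=df, p=p, significant=p < alpha)
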