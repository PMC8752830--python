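"""Force-curve I/O, calibration, contact-point detection and trimming.

File formats (plain text, '#' comment lines, UTF-8, '.' decimal):

* preprocessed curve CSV, header ``time_s,indentation_m,force_n``
* raw curve CSV, header ``time_s,z_m,deflection_m`` (piezo extension ``z``
  and cantilever deflection ``d``; force is ``k * d`` and indentation is
  ``(z - z_contact) - (d - d_baseline)``)

Experiment configuration is a YAML/JSON mapping with keys
``spring_constant_n_per_m, tip_radius_m, poisson_ratio, sampling_rate_hz,
column_map, contact_threshold_sd, baseline_fraction, units``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core_models import GeneralizedMaxwell, model_from_dict, model_to_dict
from .exceptions import DegenerateInputError, DomainError, NoContactError
from .hereditary import ContactGeometry, uniform_dt

__all__ = [
    "ExperimentConfig",
    "ForceCurve",
    "RawRecord",
    "read_curve",
    "write_curve",
    "detect_contact_and_trim",
]

MIN_SAMPLES = 16

# multiplicative factors to SI for the declared unit strings
_UNIT_FACTORS = {
    "s": 1.0, "ms": 1e-3, "us": 1e-6,
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9,
    "n": 1.0, "mn": 1e-3, "un": 1e-6, "nn": 1e-9, "pn": 1e-12,
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Instrument calibration and preprocessing knobs."""

    spring_constant_n_per_m: Optional[float] = None
    tip_radius_m: float = 12.5e-6
    poisson_ratio: float = 0.5
    sampling_rate_hz: float = 50e3
    column_map: dict = field(default_factory=dict)
    contact_threshold_sd: float = 3.0
    baseline_fraction: float = 0.5
    confirm_samples: int = 10
    units: dict = field(default_factory=dict)

    @property
    def geometry(self) -> ContactGeometry:
        return ContactGeometry(R=self.tip_radius_m, nu=self.poisson_ratio)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ValueError(f"config file {path} did not parse to a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


@dataclass
class ForceCurve:
    """One preprocessed repulsive-approach indentation record.

    ``t`` is uniform and starts at 0 (the contact point); ``h`` and ``F``
    are zero there.  All quantities are SI.
    """

    t: np.ndarray
    h: np.ndarray
    F: np.ndarray
    geom: ContactGeometry
    sampling_rate: float
    k: Optional[float] = None
    provenance: dict = field(default_factory=dict)
    ground_truth: Optional[GeneralizedMaxwell] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        self.F = np.asarray(self.F, dtype=float)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def n(self) -> int:
        return int(self.t.size)

    def validate(self) -> "ForceCurve":
        if not (self.t.size == self.h.size == self.F.size):
            raise DomainError("t, h, F must have equal lengths")
        if self.t.size < MIN_SAMPLES:
            raise DomainError(f"curve needs >= {MIN_SAMPLES} samples, got {self.t.size}")
        uniform_dt(self.t)
        scale_h = float(np.max(np.abs(self.h))) or 1.0
        scale_f = float(np.max(np.abs(self.F))) or 1.0
        if abs(self.h[0]) > 1e-9 * scale_h or abs(self.F[0]) > 1e-9 * scale_f:
            raise DomainError("curve must be re-zeroed: h(0) = F(0) = 0")
        # noise may push force slightly negative near contact; indentation
        # must stay physical up to float fuzz
        if np.min(self.h) < -1e-9 * scale_h:
            raise DomainError("indentation must be >= 0 on the repulsive segment")
        if float(np.min(self.F)) < -0.2 * scale_f:
            raise DomainError("force is strongly negative; not a repulsive segment")
        return self

    def decimated(self, max_points: int) -> "ForceCurve":
        """Uniform-stride decimation to at most ``max_points`` samples."""
        stride = int(np.ceil(self.n / max_points))
        if stride <= 1:
            return self
        return replace(
            self,
            t=self.t[::stride].copy(),
            h=self.h[::stride].copy(),
            F=self.F[::stride].copy(),
            sampling_rate=self.sampling_rate / stride,
        )


@dataclass
class RawRecord:
    """Parsed file contents prior to contact detection, in SI units."""

    t: np.ndarray
    kind: str  # "raw" (z/deflection) or "preprocessed" (indentation/force)
    z: Optional[np.ndarray] = None
    d: Optional[np.ndarray] = None
    h: Optional[np.ndarray] = None
    F: Optional[np.ndarray] = None
    config: ExperimentConfig = field(default_factory=ExperimentConfig)
    source: str = ""


_CANONICAL = {
    "time": ("time_s", "time", "t"),
    "z": ("z_m", "z", "height", "piezo"),
    "deflection": ("deflection_m", "deflection", "d"),
    "indentation": ("indentation_m", "indentation", "h"),
    "force": ("force_n", "force", "f"),
}


def _find_column(df: pd.DataFrame, logical: str, config: ExperimentConfig):
    mapped = config.column_map.get(logical)
    if mapped is not None:
        if mapped not in df.columns:
            raise ValueError(f"mapped column {mapped!r} for {logical!r} not in file")
        return mapped
    lower = {c.lower().strip(): c for c in df.columns}
    for alias in _CANONICAL[logical]:
        if alias in lower:
            return lower[alias]
    return None


def _unit_factor(logical: str, config: ExperimentConfig) -> float:
    unit = config.units.get(logical)
    if unit is None:
        return 1.0
    try:
        return _UNIT_FACTORS[unit.lower()]
    except KeyError:
        raise ValueError(f"unknown unit {unit!r} for column {logical!r}") from None


def read_curve(path, config: ExperimentConfig | None = None) -> RawRecord:
    """Parse a delimited text force-curve file into SI-unit arrays.

    Accepts either (time, z, deflection) or (time, indentation, force)
    column sets; returns a :class:`RawRecord` whose ``kind`` records which.
    """
    config = config or ExperimentConfig()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    tcol = _find_column(df, "time", config)
    if tcol is None:
        raise ValueError(f"{path}: no time column found (have {list(df.columns)})")
    t = df[tcol].to_numpy(dtype=float) * _unit_factor("time", config)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column is not strictly increasing")

    hcol = _find_column(df, "indentation", config)
    fcol = _find_column(df, "force", config)
    if hcol is not None and fcol is not None:
        h = df[hcol].to_numpy(dtype=float) * _unit_factor("indentation", config)
        F = df[fcol].to_numpy(dtype=float) * _unit_factor("force", config)
        return RawRecord(t=t, kind="preprocessed", h=h, F=F, config=config,
                         source=str(path))

    zcol = _find_column(df, "z", config)
    dcol = _find_column(df, "deflection", config)
    if zcol is not None and dcol is not None:
        if config.spring_constant_n_per_m is None:
            raise ValueError(
                f"{path}: z/deflection data requires spring_constant_n_per_m in the config"
            )
        z = df[zcol].to_numpy(dtype=float) * _unit_factor("z", config)
        d = df[dcol].to_numpy(dtype=float) * _unit_factor("deflection", config)
        return RawRecord(t=t, kind="raw", z=z, d=d, config=config, source=str(path))

    raise ValueError(
        f"{path}: need either (time, indentation, force) or (time, z, deflection) "
        f"columns; found {list(df.columns)}"
    )


def write_curve(curve: ForceCurve, path, sidecar: bool = False) -> None:
    """Write a preprocessed curve CSV (and optional ground-truth sidecar JSON)."""
    path = Path(path)
    meta = {
        "tip_radius_m": curve.geom.R,
        "poisson_ratio": curve.geom.nu,
        "sampling_rate_hz": curve.sampling_rate,
        "spring_constant_n_per_m": curve.k,
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# viscofit force curve; metadata: {json.dumps(meta, sort_keys=True)}\n")
        fh.write("time_s,indentation_m,force_n\n")
        for ti, hi, fi in zip(curve.t, curve.h, curve.F):
            fh.write(f"{float(ti)!r},{float(hi)!r},{float(fi)!r}\n")
    if sidecar:
        doc = {"provenance": curve.provenance}
        if curve.ground_truth is not None:
            doc["ground_truth"] = model_to_dict(curve.ground_truth)
        with open(path.with_suffix(".json"), "w", encoding="utf-8", newline="\n") as fh:
            json.dump(doc, fh, sort_keys=True, indent=1)
            fh.write("\n")


def load_curve(path, config: ExperimentConfig | None = None) -> ForceCurve:
    """Read + trim in one step; sidecar ground truth is attached if present."""
    rec = read_curve(path, config)
    curve = detect_contact_and_trim(rec, rec.config)
    sidecar = Path(path).with_suffix(".json")
    if sidecar.exists():
        doc = json.loads(sidecar.read_text(encoding="utf-8"))
        curve.provenance.update(doc.get("provenance", {}))
        if "ground_truth" in doc:
            curve.ground_truth = model_from_dict(doc["ground_truth"])
    return curve


def _rezero(t, h, F, config, source, provenance=None) -> ForceCurve:
    t = t - t[0]
    # snap the origin exactly to zero (float re-zeroing)
    t[0] = 0.0
    h = h - h[0]
    F = F - F[0]
    h[0] = 0.0
    F[0] = 0.0
    h_scale = float(np.max(np.abs(h))) or 1.0
    if np.min(h) < -0.01 * h_scale:
        raise DomainError("indentation is substantially negative after re-zeroing")
    h = np.maximum(h, 0.0)
    return ForceCurve(
        t=t, h=h, F=F,
        geom=config.geometry,
        sampling_rate=config.sampling_rate_hz,
        k=config.spring_constant_n_per_m,
        provenance=provenance or {"source": source},
    ).validate()


def detect_contact_and_trim(record: RawRecord, config: ExperimentConfig | None = None) -> ForceCurve:
    """Baseline-correct, locate the contact point, and trim to the repulsive segment.

    The baseline is a linear fit of deflection over the first
    ``baseline_fraction`` of the approach; the contact point is the last
    sample before the corrected force exceeds ``contact_threshold_sd`` times
    the baseline residual SD, confirmed over ``confirm_samples`` subsequent
    samples.  Already-preprocessed records are passed through with float
    re-zeroing only (idempotence).
    """
    config = config or record.config
    if record.kind == "preprocessed":
        return _rezero(record.t.copy(), record.h.copy(), record.F.copy(),
                       config, record.source)

    k = config.spring_constant_n_per_m
    if k is None:
        raise ValueError("spring_constant_n_per_m is required for raw records")
    t, z, d = record.t, record.z, record.d
    n = t.size
    nb = max(int(config.baseline_fraction * n), 2)
    coeff = np.polyfit(t[:nb], d[:nb], 1)
    d_corr = d - np.polyval(coeff, t)
    resid_sd = float(np.std(d_corr[:nb], ddof=1))
    if resid_sd == 0.0:
        resid_sd = 1e-15
    thr = config.contact_threshold_sd * resid_sd

    m = config.confirm_samples
    above = d_corr > thr
    idx = None
    for i in np.flatnonzero(above):
        if i + m <= n and np.all(above[i:i + m]):
            idx = i
            break
        if i + m > n:
            break
    if idx is None:
        raise NoContactError(
            f"no contact detected (threshold {thr:.3e} m over {m} samples)"
        )
    c = max(idx - 1, 0)

    F = k * (d_corr - d_corr[c])
    h = (z - z[c]) - (d_corr - d_corr[c])
    tt = t[c:].copy()
    hh = h[c:].copy()
    FF = F[c:].copy()
    if tt.size < MIN_SAMPLES:
        raise DegenerateInputError("repulsive segment too short after trimming")
    # noise can leave slightly negative indentation right at contact
    hh = np.maximum(hh, 0.0)
    return _rezero(tt, hh, FF, config, record.source,
                   provenance={"source": record.source, "contact_index": int(c)})
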