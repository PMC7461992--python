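"""Multi-segment exposure profiles with air-break recovery.

A treatment table or dive is an ordered sequence of oxygen and air
segments.  Oxygen segments accrue the dose index ``K = t**2 * po2**c``;
air segments let it decay exponentially, ``K -> K * exp(-0.079 * t)``.
When oxygen resumes (or PO2 changes), accumulation restarts from the
*equivalent time* ``sqrt(K / po2**c)`` -- the oxygen time at the new PO2
that would have produced the carried-over index -- so the quadratic
time-course continues from the right dose rather than from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import numpy as np
import pandas as pd
import yaml

from ._exceptions import DomainError
from .parameters import InterpolatedParameters, RiskParameters, get_parameters
from .risk import risk_from_log_index

__all__ = [
    "RECOVERY_RATE",
    "AIR_PO2_THRESHOLD",
    "Segment",
    "ExposureProfile",
    "RiskTrajectory",
    "decay_index",
    "equivalent_time",
    "accumulate",
    "read_profile",
    "write_profile",
    "read_trajectory",
    "write_trajectory",
]

#: Recovery rate constant of the dose index during air breathing (1/min).
RECOVERY_RATE = 0.079

#: Default PO2 threshold (bar) below which an unlabelled segment is
#: classified as an air break.  The toxicity data envelope starts above
#: 2 bar, so 1.0 bar is a conservative, explicit cut.
AIR_PO2_THRESHOLD = 1.0

_PARAMS = Union[RiskParameters, InterpolatedParameters]


@dataclass(frozen=True)
class Segment:
    """One interval of an exposure profile.

    ``kind`` is ``"oxygen"`` (accrues dose at ``po2``), ``"air"`` (pure
    recovery; its po2 is ignored for accrual) or ``None`` (classified by
    PO2 threshold at accumulation time).
    """

    po2: float
    duration: float
    kind: str | None = None

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise DomainError(f"segment duration must be >= 0 min, got {self.duration}")
        if self.po2 < 0:
            raise DomainError(f"segment po2 must be >= 0 bar, got {self.po2}")
        if self.kind not in (None, "oxygen", "air"):
            raise DomainError(f"segment kind must be 'oxygen' or 'air', got {self.kind!r}")

    def resolved_kind(self, air_threshold: float = AIR_PO2_THRESHOLD) -> str:
        if self.kind is not None:
            return self.kind
        return "air" if self.po2 < air_threshold else "oxygen"


@dataclass(frozen=True)
class ExposureProfile:
    """An ordered sequence of segments plus the parameter set to evaluate under."""

    segments: tuple[Segment, ...]
    condition: str | None = None

    def __init__(
        self, segments: Iterable[Segment | dict], condition: str | None = None
    ) -> None:
        segs = tuple(
            s if isinstance(s, Segment) else Segment(**s) for s in segments
        )
        if not segs:
            raise DomainError("exposure profile must contain at least one segment")
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "condition", condition)

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))


@dataclass(frozen=True)
class RiskTrajectory:
    """Dose index and risk recorded along a profile.

    ``time``, ``log_k`` and ``risk`` have one entry per recorded point;
    the default sampling records every segment boundary (segment count + 1
    points, starting at t = 0 with K = 0).
    """

    time: np.ndarray
    log_k: np.ndarray
    risk: np.ndarray

    @property
    def k(self) -> np.ndarray:
        return np.exp(self.log_k)

    @property
    def final_k(self) -> float:
        return float(math.exp(self.log_k[-1])) if np.isfinite(self.log_k[-1]) else 0.0

    @property
    def final_log_k(self) -> float:
        return float(self.log_k[-1])

    @property
    def final_risk(self) -> float:
        return float(self.risk[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.time, "K": self.k, "risk": self.risk}
        )


def decay_index(K: float, trec: float) -> float:
    """Dose index after ``trec`` minutes of air breathing: ``K * exp(-0.079*trec)``."""
    if K < 0:
        raise DomainError(f"K must be >= 0, got {K}")
    if trec < 0:
        raise DomainError(f"trec must be >= 0 min, got {trec}")
    return K * math.exp(-RECOVERY_RATE * trec)


def equivalent_time(K: float, po2: float, c: float) -> float:
    """Oxygen time at ``po2`` that would have produced index ``K``.

    ``sqrt(K / po2**c)``, evaluated in the log domain; 0 when K = 0.
    """
    if K < 0:
        raise DomainError(f"K must be >= 0, got {K}")
    if po2 <= 0:
        raise DomainError(f"po2 must be > 0 bar, got {po2}")
    if K == 0:
        return 0.0
    return math.exp(0.5 * (math.log(K) - c * math.log(po2)))


def _equivalent_time_log(log_k: float, po2: float, c: float) -> float:
    return 0.0 if log_k == -math.inf else math.exp(0.5 * (log_k - c * math.log(po2)))


def _resolve_params(profile: ExposureProfile, params: _PARAMS | str | None) -> _PARAMS:
    if params is None:
        if profile.condition is None:
            raise DomainError(
                "no parameter set: the profile names no condition and none was passed"
            )
        return get_parameters(profile.condition)
    if isinstance(params, str):
        return get_parameters(params)
    return params


def accumulate(
    profile: ExposureProfile,
    params: _PARAMS | str | None = None,
    *,
    air_threshold: float = AIR_PO2_THRESHOLD,
    resolution: float | None = None,
) -> RiskTrajectory:
    """Accumulate the dose index across a profile and report the trajectory.

    Oxygen segments advance ``K`` along the quadratic time-course at their
    PO2, resuming from the equivalent time of the carried-over index; air
    segments decay ``K`` exponentially at 0.079/min and accrue nothing.
    Risk is evaluated at every recorded point.

    Parameters
    ----------
    profile : ExposureProfile
    params : RiskParameters, registry name, or None
        Defaults to the profile's own ``condition``.  Must be
        risk-capable (an interpolated-MET set raises).
    air_threshold : float
        PO2 (bar) below which unlabelled segments count as air breaks.
    resolution : float, optional
        If given, additionally sample every ``resolution`` minutes inside
        segments; by default only segment boundaries are recorded.
    """
    p = _resolve_params(profile, params)
    # fail fast on risk-incapable sets (clear error rather than at transform)
    if not getattr(p, "risk_capable", False):
        from .risk import _require_risk_capable

        _require_risk_capable(p)
    c = p.c

    times = [0.0]
    log_ks = [-math.inf]
    clock = 0.0
    log_k = -math.inf
    for seg in profile.segments:
        kind = seg.resolved_kind(air_threshold)
        steps: list[float] = []
        if resolution is not None and resolution > 0 and seg.duration > 0:
            n_sub = int(math.ceil(seg.duration / resolution))
            steps = [seg.duration * i / n_sub for i in range(1, n_sub)]
        steps.append(seg.duration)
        if kind == "oxygen":
            t_eq = _equivalent_time_log(log_k, seg.po2, c)
            lp = c * math.log(seg.po2)
            for dt in steps:
                t = t_eq + dt
                times.append(clock + dt)
                log_ks.append(2.0 * math.log(t) + lp if t > 0 else -math.inf)
        else:
            for dt in steps:
                times.append(clock + dt)
                log_ks.append(log_k - RECOVERY_RATE * dt)
        clock += seg.duration
        log_k = log_ks[-1]

    time = np.asarray(times)
    log_k_arr = np.asarray(log_ks)
    risk_arr = np.asarray(
        [risk_from_log_index(lk, p) if np.isfinite(lk) else 0.0 for lk in log_k_arr]
    )
    return RiskTrajectory(time=time, log_k=log_k_arr, risk=risk_arr)


# -- profile and trajectory I/O ---------------------------------------------


def read_profile(source: str | Path | TextIO) -> ExposureProfile:
    """Read a profile config (YAML or JSON; JSON is a YAML subset).

    Expected structure::

        condition: dry_rest        # optional registry name
        segments:
          - {po2_bar: 2.8, duration_min: 20, kind: oxygen}
          - {po2_bar: 0.59, duration_min: 5, kind: air}
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        is_path = "\n" not in source and Path(source).is_file()
        text = Path(source).read_text() if is_path else source
    else:
        text = source.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "segments" not in doc:
        raise DomainError("profile config must be a mapping with a 'segments' list")
    segs = []
    for i, raw in enumerate(doc["segments"] or []):
        if not isinstance(raw, dict):
            raise DomainError(f"segment {i} must be a mapping")
        try:
            segs.append(
                Segment(
                    po2=float(raw["po2_bar"]),
                    duration=float(raw["duration_min"]),
                    kind=raw.get("kind"),
                )
            )
        except KeyError as e:
            raise DomainError(f"segment {i} is missing required key {e}") from None
    return ExposureProfile(segments=segs, condition=doc.get("condition"))


def write_profile(profile: ExposureProfile, path: str | Path) -> None:
    """Write a profile config; read_profile round-trips it bit-exactly."""
    doc: dict = {}
    if profile.condition is not None:
        doc["condition"] = profile.condition
    doc["segments"] = [
        {
            "po2_bar": s.po2,
            "duration_min": s.duration,
            **({"kind": s.kind} if s.kind is not None else {}),
        }
        for s in profile.segments
    ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def write_trajectory(traj: RiskTrajectory, path: str | Path) -> None:
    """Write a trajectory as delimited text (time_min, K, risk)."""
    traj.to_frame().to_csv(path, index=False)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    """Read a trajectory written by :func:`write_trajectory`.

    Uses the round-trip float parser so re-reading is bit-exact.
    """
    return pd.read_csv(path, float_precision="round_trip")
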