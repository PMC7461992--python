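"""Fitted parameter sets for the CNS oxygen-toxicity power equation.

A parameter set couples the PO2 exponent ``c`` of the dose index
``K = t**2 * po2**c`` with the lognormal location/scale ``(mu, sigma)``
of half the log-index at symptom onset, and the critical index ``kc``
at which the toxicity probability reaches 50%.  The registry ships the
three published human sets: immersed at rest, dry at rest, and active
diving at 4.4 MET.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from types import MappingProxyType
from typing import Mapping, TextIO

import yaml

from ._exceptions import DomainError, UnsupportedOperationError

__all__ = [
    "RiskParameters",
    "InterpolatedParameters",
    "REGISTRY",
    "get_parameters",
    "interpolate_met",
    "load_registry",
    "dump_registry",
    "bar_from_ata",
    "bar_from_kpa",
    "MET_SLOPE",
    "MET_INTERCEPT",
    "MET_KC",
]

#: Linear MET dependence of the PO2 exponent for submerged humans:
#: c(MET) = MET_INTERCEPT + MET_SLOPE * MET, anchored at c(1) = 10.93.
MET_SLOPE = -1.21
MET_INTERCEPT = 12.14
#: Critical index used with the MET-interpolated exponent (constant in MET).
MET_KC = 6.57e7

_MET_RANGE = (1.0, 4.4)


@dataclass(frozen=True)
class RiskParameters:
    """One fitted parameter set of the power equation.

    Attributes
    ----------
    name : str
        Registry key, e.g. ``"immersed_rest"``.
    condition : str
        One of ``"immersed"``, ``"dry"``, ``"active"``.
    met : float
        Metabolic rate in MET units (1 = rest).
    c : float
        Dimensionless PO2 exponent of the dose index.
    mu : float
        Location of ``0.5*ln(K)`` at symptom onset (log units).
    sigma : float
        Scale of ``0.5*ln(K)`` at symptom onset (log units).
    kc : float
        Critical index (min^2 * bar^c) at which risk reaches 50%.
    """

    name: str
    condition: str
    met: float
    c: float
    mu: float
    sigma: float
    kc: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise DomainError(f"sigma must be > 0, got {self.sigma}")
        if self.c <= 0:
            raise DomainError(f"c must be > 0, got {self.c}")
        if self.kc <= 0:
            raise DomainError(f"kc must be > 0, got {self.kc}")
        if self.met < 1:
            raise DomainError(f"met must be >= 1, got {self.met}")

    @property
    def risk_capable(self) -> bool:
        """Whether the set carries the scale needed for risk probabilities."""
        return True

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "met": self.met,
            "c": self.c,
            "mu": self.mu,
            "sigma": self.sigma,
            "kc": self.kc,
        }


@dataclass(frozen=True)
class InterpolatedParameters:
    """MET-interpolated exponent and critical index, without a scale.

    Sigma is unknown between the 1-MET and 4.4-MET anchor points, so this
    type supports dose-index arithmetic only; any attempt to use it for a
    risk probability raises :class:`UnsupportedOperationError`.
    """

    met: float
    c: float
    kc: float
    extrapolated: bool = False

    @property
    def risk_capable(self) -> bool:
        return False

    @property
    def sigma(self) -> float:  # noqa: D102 - deliberate refusal
        raise UnsupportedOperationError(
            "interpolated-MET parameter sets carry no sigma; risk "
            "probabilities are available only for the fitted 1 and 4.4 MET sets"
        )

    mu = sigma  # both halves of the risk transform are unavailable


def _entry(name, condition, met, c, mu, sigma, kc) -> RiskParameters:
    return RiskParameters(
        name=name, condition=condition, met=met, c=c, mu=mu, sigma=sigma, kc=kc
    )


#: Published parameter sets.  The at-rest entries satisfy kc ~= exp(2*mu)
#: to printed rounding; the active-diving set stores kc = exp(18.02) as
#: printed, which is not exp(2*9.63) -- both values are kept as published.
REGISTRY: Mapping[str, RiskParameters] = MappingProxyType(
    {
        "immersed_rest": _entry(
            "immersed_rest", "immersed", 1.0, 10.93, 8.99, 0.81, 6.42e7
        ),
        "dry_rest": _entry("dry_rest", "dry", 1.0, 12.99, 11.34, 0.65, 7.10e9),
        "active_4_4": _entry(
            "active_4_4", "active", 4.4, 6.8, 9.63, 2.02, math.exp(18.02)
        ),
    }
)

_ALIASES = {
    "immersed": "immersed_rest",
    "dry": "dry_rest",
    "active": "active_4_4",
}


def get_parameters(name: str) -> RiskParameters:
    """Look up a registry entry by name (case-insensitive; short aliases ok).

    Raises
    ------
    KeyError
        If the name matches no entry; the message lists valid names.
    """
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    try:
        return REGISTRY[key]
    except KeyError:
        valid = ", ".join(sorted(REGISTRY))
        raise KeyError(
            f"unknown parameter set {name!r}; registry entries: {valid}"
        ) from None


def interpolate_met(met: float, *, extrapolate: bool = False) -> InterpolatedParameters:
    """Interpolate the PO2 exponent at an intermediate metabolic rate.

    The exponent falls linearly with workload, ``c = 12.14 - 1.21*MET``,
    anchored at the fitted submerged endpoints (10.93 at rest, ~6.8 at
    4.4 MET); the critical index stays at ``6.57e7`` across MET.  The
    result carries no sigma: risk probabilities cannot be computed from it.

    Parameters
    ----------
    met : float
        Metabolic rate in MET units, normally within [1, 4.4].
    extrapolate : bool
        Allow MET outside [1, 4.4]; a warning is attached to the result.
    """
    lo, hi = _MET_RANGE
    outside = not (lo <= met <= hi)
    if outside and not extrapolate:
        raise DomainError(
            f"met={met} outside the supported range [{lo}, {hi}]; "
            "pass extrapolate=True to override"
        )
    if outside:
        warnings.warn(
            f"met={met} is outside the anchored range [{lo}, {hi}]; "
            "the linear relation is extrapolated",
            UserWarning,
            stacklevel=2,
        )
    c = MET_INTERCEPT + MET_SLOPE * met
    if c <= 0:
        raise DomainError(f"met={met} yields non-positive exponent c={c}")
    return InterpolatedParameters(met=met, c=c, kc=MET_KC, extrapolated=outside)


# -- unit converters (explicit; never auto-applied) -------------------------

_BAR_PER_ATA = 1.01325


def bar_from_ata(ata: float) -> float:
    """Convert a pressure in atmospheres absolute to bar."""
    return ata * _BAR_PER_ATA


def bar_from_kpa(kpa: float) -> float:
    """Convert a pressure in kilopascal to bar."""
    return kpa / 100.0


# -- registry serialisation --------------------------------------------------


def dump_registry(
    entries: Mapping[str, RiskParameters] | None = None,
    stream: TextIO | None = None,
) -> str | None:
    """Serialise parameter sets to a YAML document, one block per name."""
    entries = REGISTRY if entries is None else entries
    doc = {name: p.to_dict() for name, p in entries.items()}
    return yaml.safe_dump(doc, stream, sort_keys=True)


def load_registry(source: str | Path | TextIO) -> dict[str, RiskParameters]:
    """Read parameter sets from a YAML document produced by dump_registry.

    Accepts a path, a YAML string, or an open text stream.  Validation is
    performed by the RiskParameters constructor.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        p = Path(source)
        text = p.read_text() if ("\n" not in source and p.is_file()) else source
    else:
        text = source.read()
    doc = yaml.safe_load(io.StringIO(text))
    if not isinstance(doc, dict):
        raise DomainError("registry document must be a mapping of named blocks")
    out: dict[str, RiskParameters] = {}
    for name, block in doc.items():
        if not isinstance(block, dict):
            raise DomainError(f"registry block {name!r} must be a mapping")
        out[str(name)] = RiskParameters(name=str(name), **block)
    return out


def with_name(params: RiskParameters, name: str) -> RiskParameters:
    """Return a copy of a parameter set under a new registry name."""
    return replace(params, name=name)
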