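"""Closed-form dose-index and risk computations.

The dose of hyperbaric oxygen accumulated over a continuous exposure is
summarised by the index ``K = t**2 * po2**c`` (t in minutes, PO2 in bar).
Symptom onset is modelled as ``0.5*ln(K) ~ Normal(mu, sigma)``, so the
probability of CNS oxygen toxicity by index K is
``Phi((0.5*ln(K) - mu) / sigma)``.

All index arithmetic is carried in the log domain: with exponents up to
c ~ 13 and PO2 up to ~4 bar, the index spans tens of orders of magnitude
and naive powers overflow or lose precision.
"""

from __future__ import annotations

import math
from typing import Union

import numpy as np
from scipy.stats import norm

from ._exceptions import DomainError, UnsupportedOperationError
from .parameters import InterpolatedParameters, RiskParameters

__all__ = ["cns_ot_index", "log_cns_ot_index", "risk", "z_score", "time_for_risk"]

ArrayLike = Union[float, np.ndarray]

_PARAMS = Union[RiskParameters, InterpolatedParameters]


def _require_risk_capable(params: _PARAMS) -> RiskParameters:
    if not getattr(params, "risk_capable", False):
        raise UnsupportedOperationError(
            "risk computation requires a fitted parameter set with sigma; "
            f"got {type(params).__name__} (MET-interpolated sets support "
            "dose-index arithmetic only)"
        )
    return params


def log_cns_ot_index(t: ArrayLike, po2: ArrayLike, c: float) -> ArrayLike:
    """Natural log of the dose index, ``2*ln(t) + c*ln(po2)``.

    Returns ``-inf`` where ``t == 0``.  Inputs are validated as in
    :func:`cns_ot_index`.
    """
    t = np.asarray(t, dtype=float)
    po2 = np.asarray(po2, dtype=float)
    if np.any(t < 0):
        raise DomainError(f"t must be >= 0 minutes, got {t[t < 0].min()}")
    if np.any(po2 <= 0):
        raise DomainError(f"po2 must be > 0 bar, got {po2[po2 <= 0].min()}")
    with np.errstate(divide="ignore"):
        out = 2.0 * np.log(t) + c * np.log(po2)
    return out if out.ndim else float(out)


def cns_ot_index(t: ArrayLike, po2: ArrayLike, c: float) -> ArrayLike:
    """Dose index ``K = t**2 * po2**c`` for a continuous oxygen exposure.

    Parameters
    ----------
    t : float or array
        Exposure time in minutes, >= 0.
    po2 : float or array
        Oxygen partial pressure in bar, > 0.
    c : float
        PO2 exponent.

    Returns
    -------
    float or array
        The index in min^2 * bar^c; 0 where t == 0.
    """
    logk = log_cns_ot_index(t, po2, c)
    out = np.exp(logk)
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def z_score(K: ArrayLike, params: _PARAMS) -> ArrayLike:
    """Standard-normal deviate of the risk transform, ``(0.5*ln K - mu)/sigma``."""
    p = _require_risk_capable(params)
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise DomainError(f"K must be > 0, got {K[K <= 0].min()}")
    out = (0.5 * np.log(K) - p.mu) / p.sigma
    return out if out.ndim else float(out)


def risk(K: ArrayLike, params: _PARAMS) -> ArrayLike:
    """Probability of CNS oxygen toxicity at dose index K.

    ``Phi((0.5*ln K - mu)/sigma)``; K = 0 maps to probability 0 (the
    continuous limit), so zero-length exposures evaluate cleanly.
    """
    p = _require_risk_capable(params)
    K = np.asarray(K, dtype=float)
    if np.any(K < 0):
        raise DomainError(f"K must be >= 0, got {K[K < 0].min()}")
    with np.errstate(divide="ignore"):
        z = np.where(K > 0, (0.5 * np.log(np.where(K > 0, K, 1.0)) - p.mu) / p.sigma, -np.inf)
    out = norm.cdf(z)
    return out if out.ndim else float(out)


def risk_from_log_index(log_k: ArrayLike, params: _PARAMS) -> ArrayLike:
    """Risk from ln(K); ``-inf`` (K = 0) maps to 0."""
    p = _require_risk_capable(params)
    log_k = np.asarray(log_k, dtype=float)
    out = norm.cdf((0.5 * log_k - p.mu) / p.sigma)
    return out if out.ndim else float(out)


def time_for_risk(p: float, po2: float, params: _PARAMS) -> float:
    """Oxygen time (minutes) at a constant PO2 reaching a target risk.

    Inverts the risk transform in closed form:
    ``t = exp(mu + sigma * Phi^-1(p) - (c/2) * ln(po2))``.
    """
    pars = _require_risk_capable(params)
    if not 0.0 < p < 1.0:
        raise DomainError(f"p must lie strictly in (0, 1), got {p}")
    if po2 <= 0:
        raise DomainError(f"po2 must be > 0 bar, got {po2}")
    return math.exp(
        pars.mu + pars.sigma * norm.ppf(p) - 0.5 * pars.c * math.log(po2)
    )
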