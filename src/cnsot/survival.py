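"""Censored maximum-likelihood fitting of the power-equation parameters.

The power equation is exactly a lognormal accelerated-failure-time model:
if symptom onset at PO2 = p occurs at time T, then

    ln(T) ~ Normal(mu - (c/2) * ln(p), sigma)

which is the same statement as ``0.5 * ln(K) ~ Normal(mu, sigma)`` with
``K = T**2 * p**c``.  Events contribute the lognormal density at their
onset time; exposures that ended symptom-free contribute the survival
probability at their end time (right censoring).  The fit maximises this
likelihood over ``(c, mu, ln sigma)`` by quasi-Newton iteration with an
analytic gradient and a deterministic multi-start; standard errors come
from the inverse observed information at the optimum.

The estimator follows the scikit-learn protocol (``fit(X, y)`` with a
structured event/time ``y`` as in scikit-survival), and module-level
functions wrap it for the dataset-in, report-out workflow.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator

from ._exceptions import ConvergenceError, DomainError, IdentifiabilityError
from .parameters import RiskParameters

__all__ = [
    "ExposureRecord",
    "ExposureDataset",
    "FitResult",
    "TestResult",
    "PowerEquationAFT",
    "neg_log_likelihood",
    "fit_mle",
    "wald_test",
    "lr_test",
    "read_records",
    "write_records",
]

_LN_2PI = math.log(2.0 * math.pi)

RECORD_COLUMNS = ["po2_bar", "time_min", "event"]
OPTIONAL_COLUMNS = ["condition", "source", "excluded"]


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class ExposureRecord:
    """One observed exposure: PO2 (bar), time (min) and outcome.

    ``time`` is the symptom-onset time when ``event`` is true, otherwise
    the end of the exposure (right-censoring time).
    """

    po2: float
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise DomainError(f"time must be > 0 min, got {self.time}")
        if self.po2 <= 0:
            raise DomainError(f"po2 must be > 0 bar, got {self.po2}")


@dataclass(frozen=True)
class ExposureDataset:
    """A collection of exposure records under one condition label."""

    po2: np.ndarray
    time: np.ndarray
    event: np.ndarray
    condition: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        po2 = np.atleast_1d(np.asarray(self.po2, dtype=float))
        time = np.atleast_1d(np.asarray(self.time, dtype=float))
        event = np.atleast_1d(np.asarray(self.event, dtype=bool))
        if not (po2.shape == time.shape == event.shape):
            raise DomainError("po2, time and event must have equal length")
        if po2.size == 0:
            raise DomainError("dataset must be non-empty")
        if np.any(time <= 0):
            raise DomainError("time must be > 0 min for every record")
        if np.any(po2 <= 0):
            raise DomainError("po2 must be > 0 bar for every record")
        object.__setattr__(self, "po2", po2)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)

    def __len__(self) -> int:
        return int(self.po2.size)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @classmethod
    def from_records(
        cls,
        records: Iterable[ExposureRecord],
        condition: str | None = None,
        source: str | None = None,
    ) -> "ExposureDataset":
        recs = list(records)
        return cls(
            po2=np.array([r.po2 for r in recs]),
            time=np.array([r.time for r in recs]),
            event=np.array([r.event for r in recs]),
            condition=condition,
            source=source,
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        condition: str | None = None,
        include_excluded: bool = False,
    ) -> "ExposureDataset":
        """Build a dataset from a records table.

        Rows flagged ``excluded`` are dropped unless ``include_excluded``;
        ``condition`` filters on the table's condition column.
        """
        df = frame
        if condition is not None and "condition" in df.columns:
            df = df[df["condition"].astype(str).str.lower() == condition.lower()]
        if not include_excluded and "excluded" in df.columns:
            df = df[~df["excluded"].fillna(False).astype(bool)]
        if df.empty:
            raise DomainError(
                f"no records remain for condition={condition!r} after filtering"
            )
        return cls(
            po2=df["po2_bar"].to_numpy(float),
            time=df["time_min"].to_numpy(float),
            event=df["event"].to_numpy().astype(bool),
            condition=condition,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "po2_bar": self.po2,
                "time_min": self.time,
                "event": self.event.astype(int),
            }
        )
        if self.condition is not None:
            df["condition"] = self.condition
        if self.source is not None:
            df["source"] = self.source
        return df

    def concat(self, other: "ExposureDataset") -> "ExposureDataset":
        return ExposureDataset(
            po2=np.concatenate([self.po2, other.po2]),
            time=np.concatenate([self.time, other.time]),
            event=np.concatenate([self.event, other.event]),
            condition=None,
        )


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood estimates with uncertainty.

    ``se``, ``lower95`` and ``upper95`` are keyed by term (``c``, ``mu``,
    ``sigma``, ``kc``); the kc interval is lognormal via the delta method
    on ``2*mu``, the others are normal-approximation intervals.
    """

    c: float
    mu: float
    sigma: float
    kc: float
    se: dict[str, float]
    lower95: dict[str, float]
    upper95: dict[str, float]
    log_likelihood: float
    cov: np.ndarray  # 3x3 covariance of (c, mu, sigma)
    converged: bool
    n_iter: int
    n_obs: int
    n_events: int
    condition: str | None = None

    @property
    def params(self) -> RiskParameters:
        """The fit as a risk-capable parameter set."""
        return RiskParameters(
            name=self.condition or "fitted",
            condition=self.condition or "fitted",
            met=1.0,
            c=self.c,
            mu=self.mu,
            sigma=self.sigma,
            kc=math.exp(2.0 * self.mu),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for term, est in [
            ("kc", self.kc),
            ("c", self.c),
            ("mu", self.mu),
            ("sigma", self.sigma),
        ]:
            rows.append(
                {
                    "term": term,
                    "estimate": est,
                    "se": self.se.get(term, float("nan")),
                    "lower95": self.lower95[term],
                    "upper95": self.upper95[term],
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, indent: int = 2) -> str:
        doc = {
            "condition": self.condition,
            "n_obs": self.n_obs,
            "n_events": self.n_events,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "terms": self.to_frame().to_dict(orient="records"),
        }
        return json.dumps(doc, indent=indent)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a Wald or likelihood-ratio comparison."""

    method: str  # "wald" | "likelihood_ratio"
    statistic: float
    df: int
    p_value: float

    def __str__(self) -> str:
        return (
            f"{self.method}: statistic={self.statistic:.4g}, "
            f"df={self.df}, p={self.p_value:.4g}"
        )


# ---------------------------------------------------------------------------
# likelihood


def _nll_terms(theta, log_t, half_log_p2, event):
    """Vectorised negative log-likelihood.

    ``theta`` has shape (3, ...) = (c, mu, log_sigma) so the same code
    serves the optimiser and elementwise numerical differentiation; the
    data axis is appended last for broadcasting.
    """
    theta = np.asarray(theta, dtype=float)
    c, mu, log_sigma = theta[0], theta[1], theta[2]
    extra = np.ndim(c)  # broadcast data against any parameter batch dims
    if extra:
        lt = log_t.reshape((-1,) + (1,) * extra)
        hp = half_log_p2.reshape((-1,) + (1,) * extra)
        ev = event.reshape((-1,) + (1,) * extra)
    else:
        lt, hp, ev = log_t, half_log_p2, event
    sigma = np.exp(log_sigma)
    z = (lt - (mu - c * hp)) / sigma
    event_term = log_sigma + lt + 0.5 * z * z + 0.5 * _LN_2PI
    censor_term = -norm.logsf(z)
    return np.sum(np.where(ev, event_term, censor_term), axis=0)


def _nll_grad(theta, log_t, half_log_p2, event):
    """Analytic gradient of the negative log-likelihood in (c, mu, log_sigma)."""
    c, mu, log_sigma = theta
    sigma = math.exp(log_sigma)
    z = (log_t - (mu - c * half_log_p2)) / sigma
    # events: d/dz of (0.5 z^2) = z ; censored: hazard of the normal at z
    with np.errstate(over="ignore"):
        dz = np.where(event, z, np.exp(norm.logpdf(z) - norm.logsf(z)))
    g_c = np.sum(dz * half_log_p2 / sigma)
    g_mu = np.sum(-dz / sigma)
    g_ls = np.sum(np.where(event, 1.0, 0.0) - dz * z)
    return np.array([g_c, g_mu, g_ls])


def neg_log_likelihood(
    c: float, mu: float, sigma: float, dataset: ExposureDataset
) -> float:
    """Negative log-likelihood of the censored lognormal AFT model.

    With location ``mu - (c/2) * ln(po2)``: events contribute the negative
    log lognormal density of their onset time, censored records the
    negative log survival at their end time.
    """
    if sigma <= 0:
        raise DomainError(f"sigma must be > 0, got {sigma}")
    log_t = np.log(dataset.time)
    half_log_p2 = 0.5 * np.log(dataset.po2)
    return float(
        _nll_terms(
            np.array([c, mu, math.log(sigma)]), log_t, half_log_p2, dataset.event
        )
    )


# ---------------------------------------------------------------------------
# estimator


class PowerEquationAFT(BaseEstimator):
    """Lognormal AFT fit of the CNS-OT power equation, scikit-learn style.

    ``fit(X, y)`` takes ``X`` as the PO2 column (n,) or (n, 1), in bar,
    and ``y`` as a structured array with ``event`` (bool) and ``time``
    (min) fields, as produced by ``sksurv.util.Surv`` — or a DataFrame
    with those columns.

    Parameters
    ----------
    n_starts : int
        Deterministic multi-start count over an exponent grid (guards
        against local minima).
    tol : float
        Relative-objective convergence tolerance passed to L-BFGS-B.
    max_iter : int
        Iteration cap per start.

    Attributes
    ----------
    c_, mu_, sigma_ : float
        Maximum-likelihood estimates.
    kc_ : float
        Critical index ``exp(2 * mu_)``.
    se_ : dict
        Standard errors for ``c``, ``mu``, ``sigma``.
    cov_ : ndarray
        3x3 covariance of ``(c, mu, sigma)`` from the observed information.
    log_likelihood_ : float
        Maximised log-likelihood.
    converged_ : bool
    n_iter_ : int
    """

    _C_GRID = (4.0, 8.0, 11.0, 14.0, 18.0)

    def __init__(self, n_starts: int = 5, tol: float = 1e-8, max_iter: int = 500):
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter

    # -- data marshalling ---------------------------------------------------

    @staticmethod
    def _unpack_y(y):
        if isinstance(y, pd.DataFrame):
            return y["event"].to_numpy(bool), y["time"].to_numpy(float)
        y = np.asarray(y)
        if y.dtype.names:
            names = {n.lower(): n for n in y.dtype.names}
            ev = y[names.get("event", y.dtype.names[0])].astype(bool)
            tm = y[names.get("time", y.dtype.names[-1])].astype(float)
            return ev, tm
        raise DomainError(
            "y must be a structured (event, time) array or a DataFrame "
            "with 'event' and 'time' columns"
        )

    def _validate(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise DomainError("X must be a single PO2 column")
            X = X[:, 0]
        event, time = self._unpack_y(y)
        ds = ExposureDataset(po2=X, time=time, event=event)
        return ds

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y) -> "PowerEquationAFT":
        ds = self._validate(X, y)
        if ds.n_events < 1:
            raise IdentifiabilityError(
                "at least one event is required; all records are censored"
            )
        if np.unique(ds.po2).size < 2:
            raise IdentifiabilityError(
                "the exponent c is unidentifiable from a single PO2 level; "
                "at least two distinct levels are required"
            )

        log_t = np.log(ds.time)
        half_log_p2 = 0.5 * np.log(ds.po2)
        args = (log_t, half_log_p2, ds.event)

        starts = self._starting_points(log_t, half_log_p2, ds.event)
        bounds = [(1e-3, 60.0), (-30.0, 60.0), (-12.0, 4.0)]
        best = None
        total_iter = 0
        for x0 in starts:
            res = optimize.minimize(
                _nll_terms,
                x0,
                args=args,
                jac=_nll_grad,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-8},
            )
            total_iter += int(res.nit)
            if best is None or res.fun < best.fun:
                best = res
        assert best is not None

        # projected gradient: components pointing out of an active bound
        # do not count against convergence
        grad = _nll_grad(best.x, *args)
        for j, (lo, hi) in enumerate(bounds):
            if (best.x[j] <= lo + 1e-12 and grad[j] > 0) or (
                best.x[j] >= hi - 1e-12 and grad[j] < 0
            ):
                grad[j] = 0.0
        H_opt = self._hessian(best.x, args)
        scale = max(1.0, abs(float(best.fun)))
        # Newton decrement g'H^-1 g is curvature-aware: near-singular or
        # very steep likelihoods are judged by the implied objective gap,
        # not by the raw gradient norm
        try:
            decrement = 0.5 * float(grad @ np.linalg.solve(H_opt, grad))
        except np.linalg.LinAlgError:
            decrement = math.inf
        self.converged_ = bool(best.success) and bool(
            np.linalg.norm(grad) <= 1e-4 * scale or 0 <= decrement <= 1e-6 * scale
        )
        self.n_iter_ = total_iter
        c, mu, log_sigma = best.x
        self.c_ = float(c)
        self.mu_ = float(mu)
        self.sigma_ = float(math.exp(log_sigma))
        self.kc_ = float(math.exp(2.0 * mu))
        self.log_likelihood_ = float(-best.fun)
        self.cov_ = self._covariance(H_opt)
        self.se_ = {
            "c": float(math.sqrt(max(self.cov_[0, 0], 0.0))),
            "mu": float(math.sqrt(max(self.cov_[1, 1], 0.0))),
            "sigma": float(math.sqrt(max(self.cov_[2, 2], 0.0))),
        }
        self.n_features_in_ = 1
        self.n_obs_ = len(ds)
        self.n_events_ = ds.n_events
        return self

    def _starting_points(self, log_t, half_log_p2, event):
        """Deterministic inits: exponent grid, moment-matched (mu, sigma)."""
        ev = event.astype(bool)
        grid = self._C_GRID[: max(1, int(self.n_starts))]
        starts = []
        for c0 in grid:
            half_log_k = log_t[ev] + c0 * half_log_p2[ev]
            mu0 = float(np.mean(half_log_k))
            s0 = float(np.std(half_log_k))
            starts.append(np.array([c0, mu0, math.log(max(s0, 0.05))]))
        return starts

    @staticmethod
    def _hessian(x, args) -> np.ndarray:
        """Observed information in (c, mu, ln sigma) coordinates, by
        central differences of the analytic gradient."""
        H = np.empty((3, 3))
        for j in range(3):
            h = 1e-5 * max(1.0, abs(x[j]))
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            H[:, j] = (_nll_grad(xp, *args) - _nll_grad(xm, *args)) / (2.0 * h)
        return 0.5 * (H + H.T)

    def _covariance(self, H_opt: np.ndarray) -> np.ndarray:
        """Inverse observed information mapped to (c, mu, sigma) by the
        delta method (Jacobian diag(1, 1, sigma))."""
        try:
            cov_opt = np.linalg.inv(H_opt)
        except np.linalg.LinAlgError:
            return np.full((3, 3), np.nan)
        J = np.diag([1.0, 1.0, self.sigma_])
        return J @ cov_opt @ J.T

    # -- prediction ---------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "c_"):
            raise ConvergenceError("estimator is not fitted; call fit first")

    def predict(self, X) -> np.ndarray:
        """Median symptom-onset time (min) at each PO2."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        po2 = X[:, 0] if X.ndim == 2 else X
        return np.exp(self.mu_ - 0.5 * self.c_ * np.log(po2))

    def predict_risk(self, X, time: float) -> np.ndarray:
        """Probability of CNS-OT by ``time`` minutes at each PO2."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        po2 = X[:, 0] if X.ndim == 2 else X
        z = (np.log(time) - (self.mu_ - 0.5 * self.c_ * np.log(po2))) / self.sigma_
        return norm.cdf(z)

    def score(self, X, y) -> float:
        """Mean log-likelihood per record (higher is better)."""
        self._check_fitted()
        ds = self._validate(X, y)
        return -neg_log_likelihood(self.c_, self.mu_, self.sigma_, ds) / len(ds)

    def result(self, condition: str | None = None) -> FitResult:
        """Package the fitted state as a FitResult report."""
        self._check_fitted()
        z95 = norm.ppf(0.975)
        se_kc_log = 2.0 * self.se_["mu"]  # delta method on ln kc = 2 mu
        lower = {
            "c": self.c_ - z95 * self.se_["c"],
            "mu": self.mu_ - z95 * self.se_["mu"],
            "sigma": self.sigma_ - z95 * self.se_["sigma"],
            "kc": self.kc_ * math.exp(-z95 * se_kc_log),
        }
        upper = {
            "c": self.c_ + z95 * self.se_["c"],
            "mu": self.mu_ + z95 * self.se_["mu"],
            "sigma": self.sigma_ + z95 * self.se_["sigma"],
            "kc": self.kc_ * math.exp(z95 * se_kc_log),
        }
        return FitResult(
            c=self.c_,
            mu=self.mu_,
            sigma=self.sigma_,
            kc=self.kc_,
            se={**self.se_, "kc": float("nan")},
            lower95=lower,
            upper95=upper,
            log_likelihood=self.log_likelihood_,
            cov=self.cov_,
            converged=self.converged_,
            n_iter=self.n_iter_,
            n_obs=self.n_obs_,
            n_events=self.n_events_,
            condition=condition,
        )


# ---------------------------------------------------------------------------
# functional wrappers


def fit_mle(
    dataset: ExposureDataset, init: Sequence[float] | None = None
) -> FitResult:
    """Fit (c, mu, sigma) to a dataset by censored maximum likelihood.

    ``init`` optionally replaces the default multi-start with a single
    (c, mu, sigma) starting point.  Non-convergence is flagged on the
    result, not silently ignored.
    """
    est = PowerEquationAFT()
    if init is not None:
        c0, mu0, s0 = init
        if s0 <= 0:
            raise DomainError(f"initial sigma must be > 0, got {s0}")
        est._C_GRID = (float(c0),)
        est.n_starts = 1
        # monkeyed grid start still moment-matches mu unless given: use exact init
        est._starting_points = lambda *a: [  # type: ignore[method-assign]
            np.array([c0, mu0, math.log(s0)])
        ]
    y = np.empty(len(dataset), dtype=[("event", bool), ("time", float)])
    y["event"] = dataset.event
    y["time"] = dataset.time
    est.fit(dataset.po2, y)
    return est.result(condition=dataset.condition)


def wald_test(fit_immersed: FitResult, fit_dry: FitResult) -> TestResult:
    """Joint Wald test of equality of (c, mu, sigma) between two fits.

    The statistic is ``d' (V1 + V2)^-1 d`` on the parameter-difference
    vector, chi-square with 3 degrees of freedom under equality.
    """
    for f in (fit_immersed, fit_dry):
        if not f.converged:
            raise ConvergenceError(
                "wald_test requires converged fits; refit or inspect the data"
            )
    d = np.array(
        [
            fit_immersed.c - fit_dry.c,
            fit_immersed.mu - fit_dry.mu,
            fit_immersed.sigma - fit_dry.sigma,
        ]
    )
    V = fit_immersed.cov + fit_dry.cov
    stat = float(d @ np.linalg.solve(V, d))
    p = float(chi2.sf(stat, df=3))
    return TestResult(method="wald", statistic=stat, df=3, p_value=p)


def lr_test(
    dataset_immersed: ExposureDataset, dataset_dry: ExposureDataset
) -> TestResult:
    """Likelihood-ratio test of one shared (c, mu, sigma) vs separate sets.

    ``2 * (ll_immersed + ll_dry - ll_pooled)``, chi-square with 3 df.
    """
    fit_i = fit_mle(dataset_immersed)
    fit_d = fit_mle(dataset_dry)
    fit_pooled = fit_mle(dataset_immersed.concat(dataset_dry))
    stat = 2.0 * (
        fit_i.log_likelihood + fit_d.log_likelihood - fit_pooled.log_likelihood
    )
    stat = max(stat, 0.0)  # nested models: negative only by numerical error
    p = float(chi2.sf(stat, df=3))
    return TestResult(method="likelihood_ratio", statistic=stat, df=3, p_value=p)


# ---------------------------------------------------------------------------
# records I/O


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a delimited records file.

    Required columns: ``po2_bar``, ``time_min``, ``event`` (0/1); optional:
    ``condition``, ``source``, ``excluded``.
    """
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"records file {path} is missing columns: {missing}")
    return df


def write_records(data: ExposureDataset | pd.DataFrame, path: str | Path) -> None:
    """Write records as delimited text with a header."""
    df = data.to_frame() if isinstance(data, ExposureDataset) else data
    df.to_csv(path, index=False)
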