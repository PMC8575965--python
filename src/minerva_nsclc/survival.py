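"""Survival statistics engine: Cox proportional-hazards regression with
Efron/Breslow tie handling, Wald summaries on the log-hazard scale,
Kaplan-Meier product-limit estimation with Greenwood variance, and the
two-group log-rank test.

The Cox model used throughout is

    h_i(t) = h0(t) * exp(beta' x_i)

with the partial likelihood maximised by Newton iteration; the baseline
hazard h0 is never estimated (no downstream output needs it).  Wald z-scores,
hazard ratios and confidence intervals are all computed on the log-hazard
scale: z = beta / se(beta), HR = exp(beta), CI = exp(beta -+ z_crit * se).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, DegenerateDataError

__all__ = [
    "SurvivalObservation",
    "CoxFit",
    "WaldSummary",
    "KMCurve",
    "KMSummary",
    "fit_cox",
    "cox_score_test",
    "wald_summary",
    "km_estimate",
    "km_summary",
    "km_to_frame",
    "logrank_test",
]

_MAX_ABS_COEF = 30.0  # |beta| beyond this on a binary/standardised scale
                      # signals a monotone partial likelihood


@dataclass
class SurvivalObservation:
    """One (time, event) observation with named covariates."""

    time: float
    event: bool
    covariates: dict

    def __post_init__(self):
        if not (self.time > 0 and math.isfinite(self.time)):
            raise DegenerateDataError(f"time must be finite and > 0, got {self.time}")


@dataclass
class CoxFit:
    names: list
    coefficients: np.ndarray
    covariance: np.ndarray
    log_partial_likelihood: float
    n: int
    n_events: int
    converged: bool
    ties_method: str
    n_iter: int = 0

    def coef(self, term: str) -> float:
        return float(self.coefficients[self._idx(term)])

    def se(self, term: str) -> float:
        i = self._idx(term)
        return float(np.sqrt(self.covariance[i, i]))

    def _idx(self, term: str) -> int:
        try:
            return self.names.index(term)
        except ValueError:
            raise KeyError(f"term {term!r} not in fit ({self.names})") from None


@dataclass
class WaldSummary:
    term: str
    hr: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    level: float = 0.95


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at every distinct observed time."""

    times: np.ndarray
    surv: np.ndarray
    greenwood_var: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.surv[idx])

    def variance_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.greenwood_var[idx])


@dataclass
class KMSummary:
    horizons: list  # (horizon, estimate, ci_low, ci_high)
    median: float | None  # None = not reached


# ---------------------------------------------------------------------------
# data marshalling
# ---------------------------------------------------------------------------


def _as_arrays(data, covariates):
    if isinstance(data, pd.DataFrame):
        frame = data
    else:  # sequence of SurvivalObservation
        frame = pd.DataFrame(
            [{"time": o.time, "event": o.event, **o.covariates} for o in data]
        )
    if covariates is None:
        covariates = [c for c in frame.columns if c not in ("time", "event")]
    covariates = list(covariates)
    time = np.asarray(frame["time"], dtype=float)
    event = np.asarray(frame["event"], dtype=bool)
    X = np.asarray(frame[covariates], dtype=float)
    return time, event, X, covariates


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------


class _PartialLikelihood:
    """Efron/Breslow log partial likelihood with analytic gradient and
    observed information, vectorised over untied event times."""

    def __init__(self, time, event, X, ties):
        order = np.argsort(-time, kind="stable")  # descending: risk set = prefix
        self.t = time[order]
        self.e = event[order]
        self.X = X[order]
        self.ties = ties
        # group rows by tied time value; "end" = last prefix index of a group
        uniq, inv = np.unique(-self.t, return_inverse=True)
        n_groups = len(uniq)
        self.group_end = np.zeros(n_groups, dtype=int)
        np.maximum.at(self.group_end, inv, np.arange(len(self.t)))
        deaths_per_group = np.bincount(inv[self.e], minlength=n_groups)
        self.inv = inv
        # singleton-death groups handled vectorised; tied-death groups looped
        ev_idx = np.flatnonzero(self.e)
        self.single_ev = ev_idx[deaths_per_group[inv[ev_idx]] == 1]
        self.single_end = self.group_end[inv[self.single_ev]]
        self.tied_groups = [
            (self.group_end[g], ev_idx[inv[ev_idx] == g])
            for g in np.flatnonzero(deaths_per_group > 1)
        ]

    def __call__(self, beta):
        """Return (loglik, gradient, observed information)."""
        X, e = self.X, self.e
        p = X.shape[1]
        eta = X @ beta
        eta = np.clip(eta, -700, 700)
        w = np.exp(eta)
        cs0 = np.cumsum(w)
        cs1 = np.cumsum(w[:, None] * X, axis=0)
        cs2 = np.cumsum(w[:, None, None] * (X[:, :, None] * X[:, None, :]), axis=0)

        ll = float(eta[e].sum())
        grad = X[e].sum(axis=0).astype(float)
        info = np.zeros((p, p))

        # untied event times (vectorised)
        se_ = self.single_end
        if len(se_):
            s0 = cs0[se_]
            m = cs1[se_] / s0[:, None]
            ll -= float(np.log(s0).sum())
            grad -= m.sum(axis=0)
            info += np.einsum("kij,k->ij", cs2[se_], 1.0 / s0)
            info -= np.einsum("ki,kj->ij", m, m)

        # tied event times
        for end, death_idx in self.tied_groups:
            d = len(death_idx)
            S0, S1, S2 = cs0[end], cs1[end], cs2[end]
            if self.ties == "breslow":
                ll -= d * math.log(S0)
                mu = S1 / S0
                grad -= d * mu
                info += d * (S2 / S0 - np.outer(mu, mu))
            else:  # efron
                wd = w[death_idx]
                s0d = wd.sum()
                s1d = (wd[:, None] * X[death_idx]).sum(axis=0)
                s2d = (
                    wd[:, None, None]
                    * (X[death_idx][:, :, None] * X[death_idx][:, None, :])
                ).sum(axis=0)
                for l in range(d):
                    f = l / d
                    den = S0 - f * s0d
                    mu = (S1 - f * s1d) / den
                    ll -= math.log(den)
                    grad -= mu
                    info += (S2 - f * s2d) / den - np.outer(mu, mu)
        return ll, grad, info


def fit_cox(
    data,
    covariates: Sequence[str] | None = None,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton iteration.

    Parameters
    ----------
    data : pandas.DataFrame with columns ``time``, ``event`` and covariates,
        or a sequence of :class:`SurvivalObservation`.
    covariates : ordered covariate names entering the linear predictor
        (default: every non-time/event column).
    ties : ``"efron"`` (default) or ``"breslow"`` partial likelihood.

    Raises
    ------
    DegenerateDataError
        zero events, or a covariate constant across all observations.
    ConvergenceError
        monotone likelihood / perfect separation (names the covariate).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    time, event, X, names = _as_arrays(data, covariates)
    n, p = X.shape
    if n == 0:
        raise DegenerateDataError("no observations")
    if not np.all(np.isfinite(time)) or (time <= 0).any():
        raise DegenerateDataError("all times must be finite and > 0")
    n_events = int(event.sum())
    if n_events == 0:
        raise DegenerateDataError("no events in data; Cox model is undefined")
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise DegenerateDataError(
                f"covariate {name!r} is constant (value {X[0, j]!r}); "
                "its effect is not identifiable"
            )

    pl = _PartialLikelihood(time, event, X, ties)
    beta = np.zeros(p)
    ll, grad, info = pl(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise ConvergenceError(
                "singular information matrix; covariates may be collinear"
            ) from None
        # step-halving line search; tolerance relative to |ll| absorbs
        # floating-point noise near the optimum
        alpha = 1.0
        for _ in range(40):
            cand = beta + alpha * step
            ll_new, grad_new, info_new = pl(cand)
            if ll_new >= ll - 1e-9 * (abs(ll) + 1.0):
                break
            alpha /= 2
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        worst = int(np.argmax(np.abs(beta)))
        if abs(beta[worst]) > _MAX_ABS_COEF:
            raise ConvergenceError(
                f"monotone partial likelihood: coefficient for {names[worst]!r} "
                "diverges (perfect separation or no events in a covariate level)",
                covariate=names[worst],
            )
    else:
        converged = np.linalg.norm(grad) < tol
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise ConvergenceError("information matrix singular at optimum") from None
    # a huge coefficient with an exploding standard error is a monotone
    # likelihood that flattened out before the divergence guard tripped
    for j in range(p):
        if abs(beta[j]) > 10 and math.sqrt(max(cov[j, j], 0.0)) > 1e3:
            raise ConvergenceError(
                f"monotone partial likelihood: coefficient for {names[j]!r} "
                "is unbounded (perfect separation)",
                covariate=names[j],
            )
    return CoxFit(
        names=names,
        coefficients=beta,
        covariance=cov,
        log_partial_likelihood=ll,
        n=n,
        n_events=n_events,
        converged=converged,
        ties_method=ties,
        n_iter=it,
    )


def cox_score_test(data, covariates=None, ties: str = "breslow") -> tuple:
    """Rao score test of beta = 0: U(0)' I(0)^-1 U(0) ~ chi2(p).

    With a single binary group indicator, Breslow ties and tie-free data this
    equals the two-group log-rank chi-square.
    """
    time, event, X, _ = _as_arrays(data, covariates)
    if event.sum() == 0:
        raise DegenerateDataError("no events")
    pl = _PartialLikelihood(time, event, np.asarray(X, float), ties)
    _, grad, info = pl(np.zeros(X.shape[1]))
    chi2 = float(grad @ np.linalg.solve(info, grad))
    return chi2, float(stats.chi2.sf(chi2, X.shape[1]))


def wald_summary(fit: CoxFit, term: str, level: float = 0.95) -> WaldSummary:
    """Hazard ratio, CI, z and two-sided p for one fitted term.

    All quantities live on the log-hazard scale: z = beta/se(beta),
    HR = exp(beta), CI = exp(beta -+ z_crit*se), p = 2*(1 - Phi(|z|)).
    """
    beta = fit.coef(term)
    se = fit.se(term)
    zcrit = float(stats.norm.ppf(0.5 + level / 2))
    z = beta / se if se > 0 else math.copysign(math.inf, beta) if beta else 0.0

    def safe_exp(x):  # flat likelihoods can produce huge standard errors
        return math.inf if x > 709 else math.exp(x)

    return WaldSummary(
        term=term,
        hr=safe_exp(beta),
        ci_low=safe_exp(beta - zcrit * se),
        ci_high=safe_exp(beta + zcrit * se),
        z=z,
        p=float(2 * stats.norm.sf(abs(z))),
        level=level,
    )


def z_from_printed_ci(hr: float, ci_low: float, ci_high: float, level: float = 0.95):
    """Reconstruct the Wald z from a printed HR and CI (log-scale formula):
    se = (ln ci_high - ln ci_low) / (2 * z_crit), z = ln(hr)/se."""
    zcrit = float(stats.norm.ppf(0.5 + level / 2))
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * zcrit)
    return math.log(hr) / se


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def km_estimate(time, event=None) -> KMCurve:
    """Product-limit estimator.

    At tied times events precede censorings (censored subjects at t remain in
    the risk set for events at t).  Greenwood variance accumulates
    S(t)^2 * sum d/(n(n-d)) over event times <= t.
    """
    if event is None:  # sequence of SurvivalObservation
        obs = list(time)
        time = np.array([o.time for o in obs], dtype=float)
        event = np.array([o.event for o in obs], dtype=bool)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise DegenerateDataError("empty input to km_estimate")

    uniq = np.unique(time)
    n_risk = np.array([(time >= t).sum() for t in uniq], dtype=int)
    n_event = np.array([(event & (time == t)).sum() for t in uniq], dtype=int)
    frac = 1.0 - n_event / n_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(
            n_event > 0, n_event / (n_risk * (n_risk - n_event)).astype(float), 0.0
        )
        inc = np.where(np.isfinite(inc), inc, 0.0)  # S hits 0: variance term capped
    gw = surv**2 * np.cumsum(inc)
    return KMCurve(times=uniq, surv=surv, greenwood_var=gw, n_risk=n_risk, n_event=n_event)


def _loglog_ci(s: float, var: float, level: float) -> tuple:
    if s >= 1.0:
        return 1.0, 1.0
    if s <= 0.0:
        return 0.0, 0.0
    zcrit = float(stats.norm.ppf(0.5 + level / 2))
    se_theta = math.sqrt(var) / abs(s * math.log(s))
    lo = s ** math.exp(zcrit * se_theta)
    hi = s ** math.exp(-zcrit * se_theta)
    return lo, hi


def km_summary(curve: KMCurve, horizons: Sequence[float] = (24.0,), level: float = 0.95) -> KMSummary:
    """Survival estimates with log-log CIs at fixed horizons plus the median.

    The median is the earliest time at which S drops to 0.5 or below;
    ``median=None`` means not reached.
    """
    rows = []
    for h in horizons:
        if h < 0:
            raise ValueError(f"horizon must be >= 0, got {h}")
        s = curve.survival_at(h)
        lo, hi = _loglog_ci(s, curve.variance_at(h), level)
        rows.append((float(h), s, lo, hi))
    below = np.flatnonzero(curve.surv <= 0.5)
    median = float(curve.times[below[0]]) if below.size else None
    return KMSummary(horizons=rows, median=median)


def km_to_frame(curve: KMCurve, level: float = 0.95) -> pd.DataFrame:
    """Plot-ready tab-separable table: time, n_risk, n_event, surv, CI."""
    lo, hi = zip(
        *(
            _loglog_ci(s, v, level)
            for s, v in zip(curve.surv, curve.greenwood_var)
        )
    )
    return pd.DataFrame(
        {
            "time": curve.times,
            "n_risk": curve.n_risk,
            "n_event": curve.n_event,
            "surv": curve.surv,
            "ci_low": lo,
            "ci_high": hi,
        }
    )


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


def logrank_test(time_a, event_a, time_b=None, event_b=None) -> tuple:
    """Two-group log-rank test (1 df).  Returns (chi2, p).

    Accepts either four arrays or two sequences of SurvivalObservation.
    """
    if time_b is None:  # two observation lists
        obs_a, obs_b = list(time_a), list(event_a)
        time_a = np.array([o.time for o in obs_a], float)
        event_a = np.array([o.event for o in obs_a], bool)
        time_b = np.array([o.time for o in obs_b], float)
        event_b = np.array([o.event for o in obs_b], bool)
    time_a, event_a = np.asarray(time_a, float), np.asarray(event_a, bool)
    time_b, event_b = np.asarray(time_b, float), np.asarray(event_b, bool)
    if time_a.size == 0 or time_b.size == 0:
        raise DegenerateDataError("log-rank requires both groups non-empty")
    if event_a.sum() + event_b.sum() == 0:
        raise DegenerateDataError("log-rank requires at least one event")

    times = np.unique(np.concatenate([time_a[event_a], time_b[event_b]]))
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        n1 = int((time_a >= t).sum())
        n2 = int((time_b >= t).sum())
        d1 = int((event_a & (time_a == t)).sum())
        d2 = int((event_b & (time_b == t)).sum())
        n, d = n1 + n2, d1 + d2
        if n1 == 0 or n2 == 0 or n <= 1:
            continue
        e1 = d * n1 / n
        v = d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
        o_minus_e += d1 - e1
        var += v
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))
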