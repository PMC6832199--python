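"""Right-censored survival machinery: Kaplan-Meier, log-rank, univariate Cox.

Conventions: deaths precede censoring at tied times (subjects censored at an
event time are still counted at risk there); the Cox partial likelihood uses
the Breslow tie correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigError, DegenerateInputError, InputError


def _validate_times(times: np.ndarray, events: np.ndarray) -> None:
    if times.size != events.size:
        raise InputError("times and events must be aligned")
    if np.any(times <= 0):
        raise InputError("all times must be > 0")


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate over the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    greenwood_var: np.ndarray
    n_subjects: int

    def to_table(self) -> list[dict]:
        return [
            {
                "time": float(t),
                "at_risk": int(n),
                "events": int(d),
                "survival": float(s),
                "greenwood_var": float(v),
            }
            for t, n, d, s, v in zip(
                self.event_times,
                self.at_risk,
                self.events,
                self.survival,
                self.greenwood_var,
            )
        ]

    def step_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """(time, survival) step-function vertices starting at (0, 1)."""
        t = np.concatenate([[0.0], self.event_times])
        s = np.concatenate([[1.0], self.survival])
        return t, s


def km_fit(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored subjects at an event time remain in the risk set of that time.
    Greenwood variance is set to 0 where the estimate reaches 0.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    _validate_times(t, e)

    event_times = np.unique(t[e])
    at_risk = np.array([(t >= tau).sum() for tau in event_times], dtype=int)
    deaths = np.array([((t == tau) & e).sum() for tau in event_times], dtype=int)

    surv = np.cumprod(1.0 - deaths / at_risk) if event_times.size else np.array([])
    # Greenwood: S^2 * sum d / (n (n - d)); last factor guarded at S = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        increments = np.where(
            at_risk > deaths, deaths / (at_risk * (at_risk - deaths)), 0.0
        )
    gvar = surv**2 * np.cumsum(increments) if event_times.size else np.array([])
    return KMCurve(
        event_times=event_times,
        survival=surv,
        at_risk=at_risk,
        events=deaths,
        greenwood_var=gvar,
        n_subjects=int(t.size),
    )


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    observed: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "p_value": self.p_value,
            "observed": {str(k): v for k, v in self.observed.items()},
            "expected": {str(k): v for k, v in self.expected.items()},
        }


def logrank_test(
    times: Sequence[float],
    events: Sequence[bool],
    group_labels: Sequence[Hashable],
) -> LogRankResult:
    """k-group log-rank test with hypergeometric variance, df = k - 1."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    _validate_times(t, e)
    g = np.asarray(group_labels)
    if g.size != t.size:
        raise InputError("group labels must align with times")
    labels = np.unique(g)
    k = labels.size
    if k < 2:
        raise InputError("logrank_test: need at least 2 non-empty groups")

    taus = np.unique(t[e])
    # per event time: total at risk / deaths, and per group
    n_tot = np.array([(t >= tau).sum() for tau in taus], dtype=float)
    d_tot = np.array([((t == tau) & e).sum() for tau in taus], dtype=float)
    n_g = np.array(
        [[((t >= tau) & (g == lab)).sum() for tau in taus] for lab in labels],
        dtype=float,
    )
    d_g = np.array(
        [[((t == tau) & e & (g == lab)).sum() for tau in taus] for lab in labels],
        dtype=float,
    )

    observed = d_g.sum(axis=1)
    expected = (d_tot * n_g / n_tot).sum(axis=1)

    # covariance of (O - E) for the first k-1 groups
    with np.errstate(divide="ignore", invalid="ignore"):
        mult = np.where(
            n_tot > 1, d_tot * (n_tot - d_tot) / (n_tot - 1), 0.0
        )
    p_g = n_g / n_tot  # (k, T)
    cov = np.zeros((k - 1, k - 1))
    for a in range(k - 1):
        for b in range(k - 1):
            delta = 1.0 if a == b else 0.0
            cov[a, b] = np.sum(mult * p_g[a] * (delta - p_g[b]))

    diff = (observed - expected)[: k - 1]
    if not np.any(np.abs(diff) > 0) or not np.any(cov):
        chi2 = 0.0
    else:
        chi2 = float(diff @ np.linalg.pinv(cov) @ diff)
        chi2 = max(0.0, chi2)
    df = k - 1
    p = float(sps.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return LogRankResult(
        chi_square=chi2,
        df=df,
        p_value=p,
        observed={lab.item() if hasattr(lab, "item") else lab: float(o)
                  for lab, o in zip(labels, observed)},
        expected={lab.item() if hasattr(lab, "item") else lab: float(x)
                  for lab, x in zip(labels, expected)},
    )


# ---------------------------------------------------------------------------
# univariate Cox proportional hazards (Breslow ties)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxFit:
    beta: float
    se: float
    hazard_ratio: float
    p_value: float
    n_iter: int
    converged: bool


def breslow_loglik(
    times: Sequence[float],
    events: Sequence[bool],
    covariate: Sequence[float],
    beta: float,
) -> float:
    """Breslow partial log-likelihood at a given beta (used by tests too)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    x = np.asarray(covariate, dtype=float)
    ll = 0.0
    for tau in np.unique(t[e]):
        dead = (t == tau) & e
        risk = t >= tau
        ll += float(x[dead].sum() * beta)
        ll -= float(dead.sum()) * math.log(float(np.exp(beta * x[risk]).sum()))
    return ll


def cox_univariate(
    times: Sequence[float],
    events: Sequence[bool],
    covariate: Sequence[float],
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Newton-Raphson maximization of the Breslow partial likelihood.

    Starts at beta = 0; converged when the absolute score drops below
    ``tol``.  Monotone likelihood (separation) is reported via
    ``converged=False`` rather than silently returning a huge beta.
    """
    if ties != "breslow":
        raise ConfigError("only the 'breslow' tie correction is implemented")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    x = np.asarray(covariate, dtype=float)
    _validate_times(t, e)
    if x.size != t.size:
        raise InputError("covariate must align with times")
    if not e.any():
        raise DegenerateInputError("cox_univariate: no events observed")
    if np.unique(x[e]).size < 2 or np.unique(x).size < 2:
        raise DegenerateInputError(
            "cox_univariate: need >= 2 distinct covariate values among events"
        )

    x_sd = float(np.std(x))
    taus = np.unique(t[e])
    dead_masks = [(t == tau) & e for tau in taus]
    risk_masks = [t >= tau for tau in taus]
    s_obs = np.array([x[m].sum() for m in dead_masks])
    d_cnt = np.array([m.sum() for m in dead_masks], dtype=float)

    beta = 0.0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        score = 0.0
        info = 0.0
        for s, d, rm in zip(s_obs, d_cnt, risk_masks):
            w = np.exp(beta * x[rm])
            sw = w.sum()
            m1 = (w * x[rm]).sum() / sw
            m2 = (w * x[rm] ** 2).sum() / sw
            score += s - d * m1
            info += d * (m2 - m1 * m1)
        if abs(score) < tol:
            converged = True
            break
        if info <= 0:
            break
        step = score / info
        # dampen huge steps (in per-SD units) to keep Newton stable
        cap = 2.0 / max(x_sd, 1e-12)
        beta += max(-cap, min(cap, step))
        if abs(beta) * x_sd > 15:  # monotone likelihood / separation
            break

    if abs(beta) * x_sd > 15:
        converged = False
    se = 1.0 / math.sqrt(info) if info > 0 else math.inf
    z = beta / se if se > 0 and math.isfinite(se) else 0.0
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return CoxFit(
        beta=float(beta),
        se=float(se),
        hazard_ratio=float(math.exp(beta)),
        p_value=p,
        n_iter=n_iter,
        converged=converged,
    )
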