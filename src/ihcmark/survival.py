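"""Survival analysis for biomarker cohorts, written from first principles.

Implements the product-limit (Kaplan-Meier) estimator, the two-group
log-rank test, univariate Cox proportional-hazards regression (Efron or
Breslow tie handling, Newton-Raphson on the partial likelihood), and the
minimum-p-value cutpoint search that dichotomizes a continuous marker at
the threshold whose two survival groups differ most, subject to a
minimum-group-size constraint (splits leaving fewer than 10% of patients
on one side are considered unreliable and excluded).

Conventions
-----------
* Times are strictly positive; ``event=True`` marks an observed death,
  ``False`` right-censoring.
* At tied times, events precede censorings: a patient censored at *t*
  is still at risk for events at *t*.
* The min-p search inflates the type-I error of its reported p-value;
  :func:`minp_permutation_adjust` offers an opt-in permutation correction
  and is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalSample",
    "KMCurve",
    "LogrankResult",
    "CoxFit",
    "CutpointResult",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "cox_score_statistic",
    "optimal_survival_cutpoint",
    "minp_permutation_adjust",
]


@dataclass
class SurvivalSample:
    """One patient's follow-up: time in months, event flag, optional group."""

    time: float
    event: bool
    group: int | None = None


@dataclass
class KMCurve:
    """Product-limit estimate: S(t) steps down only at event times."""

    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival_probs[idx - 1])


@dataclass
class LogrankResult:
    chi_square: float
    p_value: float
    defined: bool = True


@dataclass
class CoxFit:
    """Univariate Cox fit: hazard(t) = h0(t) * exp(beta * x)."""

    beta: float
    hazard_ratio: float
    std_err: float
    wald_p: float
    converged: bool
    n_iter: int = 0
    divergence_direction: int = 0  # sign of drift if the likelihood is monotone


@dataclass
class CutpointResult:
    """Best survival split of a continuous marker.

    ``passes_constraint`` records the 10% minimum-group-size reliability
    rule regardless of the fraction the search itself enforced.
    """

    threshold: float
    n_low: int
    n_high: int
    chi_square: float
    p_value: float
    passes_constraint: bool


def _validate(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape or t.ndim != 1 or t.size == 0:
        raise ValueError("times and events must be equal-length 1-D arrays")
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ValueError("survival times must be finite and strictly positive")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    ``S(t) = prod over event times t_i <= t of (1 - d_i / n_i)`` where
    ``d_i`` counts deaths at ``t_i`` and ``n_i`` the patients at risk
    (time >= t_i, censorings at t_i included).
    """
    t, e = _validate(times, events)
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    uniq = np.unique(ts[es])
    if uniq.size == 0:
        return KMCurve(event_times=np.empty(0), survival_probs=np.empty(0),
                       at_risk=np.empty(0, dtype=int))
    # at risk = number with time >= t_i
    n_at_risk = t.size - np.searchsorted(ts, uniq, side="left")
    deaths = np.array([(ts[es] == u).sum() for u in uniq])
    surv = np.cumprod(1.0 - deaths / n_at_risk)
    return KMCurve(event_times=uniq, survival_probs=surv,
                   at_risk=n_at_risk.astype(int))


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-group log-rank test on one degree of freedom.

    At each distinct pooled event time the observed deaths in group A are
    compared with their hypergeometric expectation given the margins; the
    statistic is ``(O - E)^2 / V`` referred to chi-square(1).
    """
    ta, ea = _validate(times_a, events_a)
    tb, eb = _validate(times_b, events_b)
    if ea.sum() + eb.sum() == 0:
        return LogrankResult(chi_square=np.nan, p_value=np.nan, defined=False)

    uniq = np.unique(np.concatenate([ta[ea], tb[eb]]))
    sa, sb = np.sort(ta), np.sort(tb)
    n1 = ta.size - np.searchsorted(sa, uniq, side="left")
    n2 = tb.size - np.searchsorted(sb, uniq, side="left")
    sae = np.sort(ta[ea])
    sbe = np.sort(tb[eb])
    d1 = np.searchsorted(sae, uniq, side="right") - np.searchsorted(sae, uniq, side="left")
    d2 = np.searchsorted(sbe, uniq, side="right") - np.searchsorted(sbe, uniq, side="left")
    n = n1 + n2
    d = d1 + d2

    o_minus_e = (d1 - d * n1 / n).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    v = v_terms[n > 1].sum()
    if v <= 0:
        return LogrankResult(chi_square=np.nan, p_value=np.nan, defined=False)
    chi2 = o_minus_e ** 2 / v
    return LogrankResult(chi_square=float(chi2),
                         p_value=float(stats.chi2.sf(chi2, df=1)))


def _cox_derivatives(beta, x, event_time_groups, ties):
    """Log partial likelihood and its first two derivatives at beta."""
    loglik = grad = hess = 0.0
    ex = np.exp(beta * x)
    for risk_idx, death_idx in event_time_groups:
        s0 = ex[risk_idx].sum()
        s1 = (ex[risk_idx] * x[risk_idx]).sum()
        s2 = (ex[risk_idx] * x[risk_idx] ** 2).sum()
        xd = x[death_idx]
        d = death_idx.size
        loglik += beta * xd.sum()
        if ties == "efron":
            s0d = ex[death_idx].sum()
            s1d = (ex[death_idx] * xd).sum()
            s2d = (ex[death_idx] * xd ** 2).sum()
        for ell in range(d):
            if ties == "efron":
                frac = ell / d
                phi0 = s0 - frac * s0d
                phi1 = s1 - frac * s1d
                phi2 = s2 - frac * s2d
            else:  # breslow
                phi0, phi1, phi2 = s0, s1, s2
            loglik -= np.log(phi0)
            grad_term = phi1 / phi0
            grad -= grad_term
            hess -= phi2 / phi0 - grad_term ** 2
        grad += xd.sum()
    return loglik, grad, hess


def _event_time_groups(times, events):
    """Indices of (risk set, tied deaths) at each distinct event time."""
    order = np.argsort(times, kind="stable")
    ts = times[order]
    groups = []
    for u in np.unique(times[events]):
        at_risk = order[np.searchsorted(ts, u, side="left"):]
        deaths = at_risk[(times[at_risk] == u) & events[at_risk]]
        groups.append((at_risk, deaths))
    return groups


def cox_univariate(times, events, covariate, ties: str = "efron",
                   max_iter: int = 100, tol: float = 1e-10) -> CoxFit:
    """Univariate Cox proportional-hazards fit by Newton-Raphson.

    Maximizes the partial likelihood in the scalar coefficient ``beta``;
    Efron's approximation handles tied event times by default ("breslow"
    is available). The standard error is the inverse square root of the
    observed information; ``wald_p`` is the two-sided normal Wald p-value.

    A monotone partial likelihood (perfect separation of events by the
    covariate) cannot be maximized: the fit is flagged ``converged=False``
    with the drift direction recorded.
    """
    t, e = _validate(times, events)
    x = np.asarray(covariate, dtype=float)
    if x.shape != t.shape:
        raise ValueError("covariate must match times in length")
    if e.sum() < 2:
        raise ValueError("need at least two events to fit a Cox model")
    if np.ptp(x) == 0:
        raise ValueError("covariate does not vary")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")

    groups = _event_time_groups(t, e)
    beta = 0.0
    for it in range(1, max_iter + 1):
        _, grad, hess = _cox_derivatives(beta, x, groups, ties)
        if hess >= 0:  # flat or degenerate likelihood
            break
        step = -grad / hess
        # dampen wild steps early on
        step = np.clip(step, -5.0, 5.0)
        beta += step
        if abs(beta) > 50:
            return CoxFit(beta=beta, hazard_ratio=np.exp(beta), std_err=np.inf,
                          wald_p=np.nan, converged=False, n_iter=it,
                          divergence_direction=int(np.sign(beta)))
        if abs(step) < tol and abs(grad) < 1e-7:
            _, grad, hess = _cox_derivatives(beta, x, groups, ties)
            se = float(1.0 / np.sqrt(-hess))
            z = beta / se
            return CoxFit(beta=float(beta), hazard_ratio=float(np.exp(beta)),
                          std_err=se, wald_p=float(2 * stats.norm.sf(abs(z))),
                          converged=True, n_iter=it)
    return CoxFit(beta=float(beta), hazard_ratio=float(np.exp(beta)),
                  std_err=np.inf, wald_p=np.nan, converged=False,
                  n_iter=max_iter, divergence_direction=int(np.sign(beta)))


def cox_score_statistic(times, events, covariate, ties: str = "breslow") -> float:
    """Cox score test statistic at beta = 0, ``U(0)^2 / I(0)``.

    With a binary covariate, Breslow tie handling and tie-free data this
    equals the log-rank chi-square analytically.
    """
    t, e = _validate(times, events)
    x = np.asarray(covariate, dtype=float)
    groups = _event_time_groups(t, e)
    _, grad, hess = _cox_derivatives(0.0, x, groups, ties)
    return float(grad ** 2 / -hess)


def optimal_survival_cutpoint(scores, times, events,
                              min_group_frac: float = 0.10
                              ) -> CutpointResult | None:
    """Minimum-p-value dichotomization of a continuous marker.

    Sweeps candidate thresholds (midpoints of consecutive unique scores);
    for each, patients with score above the threshold are compared to
    patients at or below it by the log-rank test. Splits where the smaller
    group holds less than ``min_group_frac`` of the cohort are excluded as
    unreliable. Returns the admissible split with the smallest p-value
    (ties broken toward the lower threshold), or None when no admissible
    split exists.
    """
    s = np.asarray(scores, dtype=float)
    t, e = _validate(times, events)
    if s.shape != t.shape:
        raise ValueError("scores must match times in length")
    uniq = np.unique(s)
    if uniq.size < 2:
        return None
    n = s.size
    best = None
    for thr in (uniq[:-1] + uniq[1:]) / 2.0:
        high = s > thr
        n_high = int(high.sum())
        n_low = n - n_high
        if min(n_low, n_high) < min_group_frac * n:
            continue
        lr = logrank_test(t[~high], e[~high], t[high], e[high])
        if not lr.defined:
            continue
        key = (lr.p_value, thr)
        if best is None or key < best[0]:
            best = (key, CutpointResult(
                threshold=float(thr), n_low=n_low, n_high=n_high,
                chi_square=lr.chi_square, p_value=lr.p_value,
                passes_constraint=min(n_low, n_high) / n >= 0.10))
    return None if best is None else best[1]


def minp_permutation_adjust(scores, times, events, n_perm: int, seed: int,
                            min_group_frac: float = 0.10) -> float:
    """Permutation correction for the multiplicity of the min-p search.

    Re-runs the full cutpoint search on ``n_perm`` random permutations of
    the score-to-patient assignment and returns
    ``(1 + #{permuted min-p <= observed min-p}) / (n_perm + 1)``.
    ``n_perm = 0`` disables the adjustment and passes the raw minimum p
    through, which is the default behavior of the pipeline.
    """
    observed = optimal_survival_cutpoint(scores, times, events, min_group_frac)
    if observed is None:
        raise ValueError("no admissible cutpoint to adjust")
    if n_perm == 0:
        return observed.p_value
    if n_perm < 100:
        raise ValueError("n_perm must be 0 (off) or at least 100")
    rng = np.random.default_rng(seed)
    s = np.asarray(scores, dtype=float)
    count = 0
    for _ in range(n_perm):
        perm = optimal_survival_cutpoint(rng.permutation(s), times, events,
                                         min_group_frac)
        if perm is not None and perm.p_value <= observed.p_value:
            count += 1
    return (1 + count) / (n_perm + 1)
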