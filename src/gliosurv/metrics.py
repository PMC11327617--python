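"""From-scratch survival evaluation statistics.

Implements the full evaluation stack used by the survival model: the
time-dependent concordance index (Antolini formulation), the censoring-
weighted Brier score and its time integral (Graf), the Kaplan–Meier
product-limit estimator, the two-group log-rank test, a Newton–Raphson Cox
proportional-hazards fit with Breslow tie handling, and the Schoenfeld
residual test of the proportionality assumption.

Conventions used throughout: at tied times, deaths precede censorings in the
risk-set bookkeeping (a subject censored at t remains at risk for the deaths
at t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StepFunction",
    "MetricReport",
    "ctd",
    "km_estimator",
    "brier_score",
    "integrated_brier",
    "logrank_test",
    "CoxFit",
    "fit_cox",
    "schoenfeld_ph_test",
    "dichotomize",
    "predicted_median_months",
]


@dataclass
class StepFunction:
    """Right-continuous step function starting at 1.0, e.g. a survival curve."""

    jump_times: np.ndarray
    values: np.ndarray

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_times, t, side="right") - 1
        vals = np.concatenate([[1.0], self.values])
        out = vals[idx + 1]
        return out if out.shape else float(out)

    def left_limit(self, t) -> np.ndarray:
        """Value just before t, G(t−)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_times, t, side="left") - 1
        vals = np.concatenate([[1.0], self.values])
        out = vals[idx + 1]
        return out if out.shape else float(out)


@dataclass
class MetricReport:
    ctd: float
    ibs: float
    brier_times: np.ndarray
    brier_values: np.ndarray
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    schoenfeld_p: dict | None = None


def ctd(cif_matrix, times, events) -> float:
    """Time-dependent concordance index (Antolini).

    ``cif_matrix[i, j]`` is the model's predicted cumulative incidence for
    subject *j* evaluated at subject *i*'s time bin, so risk comparisons are
    made at the earlier subject's own time.  A pair (i, j) is comparable when
    time_i < time_j and subject i has an observed event; it is concordant
    when F̂(bin_i | x_i) > F̂(bin_i | x_j), and ties count 1/2.
    """
    M = np.asarray(cif_matrix, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(times)
    if M.shape != (n, n):
        raise ValueError("cif_matrix must be (n, n): rows index the evaluation "
                         "subject/time, columns the predicted subject")
    ti, tj = np.meshgrid(times, times, indexing="ij")
    comparable = (ti < tj) & (events[:, None] == 1)
    np.fill_diagonal(comparable, False)
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    own = np.diag(M)[:, None]
    conc = (own > M) & comparable
    tied = np.isclose(own - M, 0.0) & comparable
    return float((conc.sum() + 0.5 * tied.sum()) / n_pairs)


def km_estimator(times, events) -> StepFunction:
    """Kaplan–Meier product-limit estimator S(t) = Π_{t_i ≤ t} (1 − d_i/n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty sample")
    uniq = np.unique(times[events == 1])
    n_at_risk = np.array([(times >= t).sum() for t in uniq], dtype=float)
    d = np.array([((times == t) & (events == 1)).sum() for t in uniq], dtype=float)
    surv = np.cumprod(1.0 - d / n_at_risk) if uniq.size else np.array([])
    return StepFunction(jump_times=uniq, values=surv)


def censoring_km(times, events) -> StepFunction:
    """KM estimate Ĝ of the censoring distribution (event indicator flipped)."""
    return km_estimator(times, 1 - np.asarray(events, dtype=int))


def brier_score(surv_at_t, times, events, t: float, censor_km: StepFunction) -> float:
    """Censoring-weighted Brier score at horizon ``t`` (Graf et al.).

    ``surv_at_t[i]`` is subject i's predicted S(t).  Subjects with an event
    by t are weighted by 1/Ĝ(time_i−); subjects still under observation at t
    by 1/Ĝ(t); subjects censored before t contribute 0.
    """
    S = np.asarray(surv_at_t, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    died = (times <= t) & (events == 1)
    alive = times > t
    score = np.zeros_like(S)
    if died.any():
        g = censor_km.left_limit(times[died])
        if np.any(g <= 0):
            raise ZeroDivisionError("censoring survival Ĝ(time−) is 0 at a needed point")
        score[died] = S[died] ** 2 / g
    if alive.any():
        g_t = censor_km(t)
        if g_t <= 0:
            raise ZeroDivisionError("censoring survival Ĝ(t) is 0 at the horizon")
        score[alive] = (1.0 - S[alive]) ** 2 / g_t
    return float(score.mean())


def integrated_brier(brier_values, eval_times) -> float:
    """Trapezoidal time-average of the Brier score over [t_1, t_last]."""
    bs = np.asarray(brier_values, dtype=float)
    ts = np.asarray(eval_times, dtype=float)
    if ts.size < 2 or ts[-1] <= ts[0]:
        raise ValueError("need >= 2 distinct evaluation times")
    return float(np.trapezoid(bs, ts) / (ts[-1] - ts[0]))


def logrank_test(groups, times, events) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p-value, 1 df)."""
    groups = np.asarray(groups, dtype=int)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(set(groups.tolist())) != 2:
        raise ValueError("need exactly two nonempty groups")
    g1 = groups == np.max(groups)
    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ------------------------------------------------------------------ Cox model


@dataclass
class CoxFit:
    coef: np.ndarray
    cov: np.ndarray  # inverse observed information
    n_iter: int
    loglik: float

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _cox_derivatives(beta, X, times, events):
    """Breslow partial log-likelihood, score and information.

    Risk sets are accumulated by descending time; tied event times share a
    single risk set (deaths before censorings at ties).
    """
    n, p = X.shape
    order = np.argsort(-times, kind="stable")
    Xs, ts, es = X[order], times[order], events[order]
    eta = Xs @ beta
    w = np.exp(eta)
    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        t = ts[i]
        j = i
        while j < n and ts[j] == t:  # everyone at this time enters the risk set
            s0 += w[j]
            s1 += w[j] * Xs[j]
            s2 += w[j] * np.outer(Xs[j], Xs[j])
            j += 1
        for k in range(i, j):
            if es[k] == 1:
                xbar = s1 / s0
                loglik += eta[k] - np.log(s0)
                score += Xs[k] - xbar
                info += s2 / s0 - np.outer(xbar, xbar)
        i = j
    return loglik, score, info


def fit_cox(covariates, times, events, max_iter: int = 100, tol: float = 1e-8) -> CoxFit:
    """Newton–Raphson maximization of the Breslow-tie Cox partial likelihood.

    Converges when the max absolute score falls below ``tol``; raises on
    constant covariate columns, absence of events, or non-convergence
    (e.g. separation).
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if X.shape[0] != times.size:
        raise ValueError("covariate rows must match the number of subjects")
    if events.sum() < 1:
        raise ValueError("need at least one event")
    if np.any(np.std(X, axis=0) == 0):
        raise ValueError("constant covariate column")
    beta = np.zeros(X.shape[1])
    loglik = -np.inf
    for it in range(1, max_iter + 1):
        ll, score, info = _cox_derivatives(beta, X, times, events)
        if np.max(np.abs(score)) < tol:
            cov = np.linalg.inv(info)
            return CoxFit(coef=beta, cov=cov, n_iter=it, loglik=ll)
        step = np.linalg.solve(info, score)
        # step-halving if the likelihood worsens (beyond float noise)
        for _ in range(30):
            cand = beta + step
            ll_new, _, _ = _cox_derivatives(cand, X, times, events)
            if not np.isfinite(ll) or ll_new >= ll - 1e-9 * (1.0 + abs(ll)):
                break
            step = step / 2.0
        beta = beta + step
        if np.max(np.abs(beta)) > 50:
            raise RuntimeError("Cox fit diverged (possible separation)")
        loglik = ll
    raise RuntimeError(f"Cox fit did not converge in {max_iter} iterations")


def schoenfeld_residuals(fit: CoxFit, covariates, times, events):
    """Schoenfeld residuals x_k − x̄(t_k) at each event, with the risk-set
    weighted covariance V_k, ordered by event time."""
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    w = np.exp(X @ fit.coef)
    ev_idx = np.where(events == 1)[0]
    order = ev_idx[np.argsort(times[ev_idx], kind="stable")]
    resid = np.empty((order.size, X.shape[1]))
    vbars = np.empty((order.size, X.shape[1], X.shape[1]))
    for r, k in enumerate(order):
        at_risk = times >= times[k]
        ww = w[at_risk]
        Xr = X[at_risk]
        s0 = ww.sum()
        xbar = (ww[:, None] * Xr).sum(axis=0) / s0
        resid[r] = X[k] - xbar
        s2 = (ww[:, None, None] * Xr[:, :, None] * Xr[:, None, :]).sum(axis=0) / s0
        vbars[r] = s2 - np.outer(xbar, xbar)
    return resid, vbars, times[order]


def schoenfeld_ph_test(fit: CoxFit, covariates, times, events) -> dict:
    """Grambsch–Therneau test of proportional hazards per covariate.

    Scaled Schoenfeld residuals are correlated against Kaplan–Meier
    transformed time g(t) = 1 − Ŝ_KM(t); each covariate yields a 1-df
    chi-square statistic.  Returns {index: p-value}.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 3:
        raise ValueError("need at least 3 events for the proportionality test")
    resid, _, ev_times = schoenfeld_residuals(fit, covariates, times, events)
    d = resid.shape[0]
    km = km_estimator(times, events)
    g = 1.0 - np.asarray(km(ev_times), dtype=float)
    g = g - g.mean()
    # scaled residuals s* = d · Cov(β̂) · r (Grambsch–Therneau); the additive
    # β̂ term drops out against the centred time transform
    scaled = d * resid @ fit.cov
    pvals = {}
    denom_g = float((g**2).sum())
    for j in range(resid.shape[1]):
        num = float(g @ scaled[:, j]) ** 2
        den = d * fit.cov[j, j] * denom_g
        chi2 = num / den
        pvals[j] = float(stats.chi2.sf(chi2, df=1))
    return pvals


# ------------------------------------------------------------- risk grouping


def predicted_median_months(monthly_survival) -> np.ndarray:
    """First integer month at which the predicted S drops below 0.5
    (np.inf when the curve never crosses within the horizon)."""
    S = np.atleast_2d(np.asarray(monthly_survival, dtype=float))
    below = S < 0.5
    med = np.full(S.shape[0], np.inf)
    any_below = below.any(axis=1)
    med[any_below] = below[any_below].argmax(axis=1) + 1  # months are 1-based
    return med


def dichotomize(monthly_survival, threshold_months: float = 12.0) -> np.ndarray:
    """Favorable (1) iff predicted median survival strictly exceeds the
    threshold; a median exactly at the threshold is unfavorable (0)."""
    med = predicted_median_months(monthly_survival)
    return (med > threshold_months).astype(int)
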