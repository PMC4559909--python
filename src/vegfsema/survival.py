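"""Kaplan-Meier estimation, log-rank tests, and Cox proportional hazards.

Times are in years (biochemical-recurrence follow-up).  Conventions: at a
tied time, events precede censorings; the Cox partial likelihood uses
Breslow tie handling (Efron available by flag), maximised by Newton-Raphson
with step-halving so the log-likelihood trace is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import ExpressionMatrix
from .plsda import PLSDAClassifier


@dataclass
class SurvivalCurve:
    """Product-limit estimate: S(t) is a right-continuous step function."""

    event_times: np.ndarray   # distinct times with >= 1 event
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray      # S at each event time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_times(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and events must align")
    if (t < 0).any() or not np.isfinite(t).all():
        raise ValueError("times must be finite and >= 0")
    return t, e


def kaplan_meier(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    At each distinct event time, S multiplies by (1 - d/n) where d is the
    number of events and n the number at risk; subjects censored exactly at
    an event time are still at risk for it (events precede censorings).
    """
    t, e = _check_times(times, events)
    ev_times = np.unique(t[e])
    at_risk, n_events, surv = [], [], []
    s = 1.0
    for u in ev_times:
        n = int((t >= u).sum())
        d = int((e & (t == u)).sum())
        s *= 1.0 - d / n
        at_risk.append(n)
        n_events.append(d)
        surv.append(s)
    return SurvivalCurve(event_times=ev_times, at_risk=np.array(at_risk),
                         n_events=np.array(n_events), survival=np.array(surv))


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float
    observed: np.ndarray   # per group
    expected: np.ndarray


def log_rank(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank test (O-E with hypergeometric variance, 1 df)."""
    ta, ea = _check_times(times_a, events_a)
    tb, eb = _check_times(times_b, events_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(len(ta), bool), np.ones(len(tb), bool)])
    o_a = 0.0
    e_a = 0.0
    var = 0.0
    for u in np.unique(t[e]):
        at_risk = t >= u
        n = at_risk.sum()
        n_a = (at_risk & ~grp).sum()
        d = (e & (t == u)).sum()
        d_a = (e & (t == u) & ~grp).sum()
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    total_events = float(e.sum())
    if var == 0.0:
        chi2 = 0.0
        p = 1.0
    else:
        chi2 = (o_a - e_a) ** 2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(chi2=float(chi2), df=1, p=p,
                         observed=np.array([o_a, total_events - o_a]),
                         expected=np.array([e_a, total_events - e_a]))


@dataclass
class CoxFit:
    coef: np.ndarray
    se: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    information: np.ndarray

    @property
    def z(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def p(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.z))


def _cox_derivatives(beta: np.ndarray, t: np.ndarray, e: np.ndarray,
                     X: np.ndarray, efron: bool) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow/Efron partial log-likelihood, score and information."""
    n, p = X.shape
    eta = X @ beta
    order = np.argsort(-t, kind="stable")  # decreasing time
    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    # running risk-set sums, built by walking times downward
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    ts = t[order]
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        block = order[i:j]
        w = np.exp(eta[block])
        s0 += w.sum()
        s1 += (w[:, None] * X[block]).sum(axis=0)
        s2 += (w[:, None, None] * X[block][:, :, None] * X[block][:, None, :]).sum(axis=0)
        dead = block[e[block]]
        d = len(dead)
        if d:
            xd = X[dead]
            ll += eta[dead].sum()
            if efron and d > 1:
                wd = np.exp(eta[dead])
                d0 = wd.sum()
                d1 = (wd[:, None] * xd).sum(axis=0)
                d2 = (wd[:, None, None] * xd[:, :, None] * xd[:, None, :]).sum(axis=0)
                for k in range(d):
                    f = k / d
                    a0 = s0 - f * d0
                    a1 = s1 - f * d1
                    a2 = s2 - f * d2
                    ll -= np.log(a0)
                    score_term = a1 / a0
                    score -= score_term
                    info += a2 / a0 - np.outer(score_term, score_term)
                score += xd.sum(axis=0)
            else:
                ll -= d * np.log(s0)
                mean = s1 / s0
                score += xd.sum(axis=0) - d * mean
                info += d * (s2 / s0 - np.outer(mean, mean))
        i = j
    return ll, score, info


def cox_fit(times, events, covariates, max_iter: int = 50, tol: float = 1e-9,
            efron: bool = False) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson with step-halving."""
    t, e = _check_times(times, events)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p:
        raise ValueError("need more subjects than covariates")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant covariate")
    if not e.any():
        raise ValueError("no events: partial likelihood is flat")
    X = X - X.mean(axis=0)  # centering improves conditioning; coef unchanged

    beta = np.zeros(p)
    ll, score, info = _cox_derivatives(beta, t, e, X, efron)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        new_beta = beta + step
        new_ll, new_score, new_info = _cox_derivatives(new_beta, t, e, X, efron)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll) and halvings < 30:
            step = step / 2
            new_beta = beta + step
            new_ll, new_score, new_info = _cox_derivatives(new_beta, t, e, X, efron)
            halvings += 1
        if not np.isfinite(new_ll) or new_ll < ll:
            break
        delta = new_ll - ll
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        trace.append(ll)
        if delta < tol and np.max(np.abs(score)) < 1e-6 * (1 + np.abs(ll)):
            converged = True
            break
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return CoxFit(coef=beta, se=se, loglik_trace=np.array(trace),
                  converged=converged, n_iter=it, information=info)


def cox_score_test(times, events, covariates, efron: bool = False) -> tuple[float, float]:
    """Score (Rao) test of beta = 0; equals the log-rank chi-square for a
    single binary covariate without ties."""
    t, e = _check_times(times, events)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    X = X - X.mean(axis=0)
    _, score, info = _cox_derivatives(np.zeros(X.shape[1]), t, e, X, efron)
    chi2 = float(score @ np.linalg.solve(info, score))
    return chi2, float(stats.chi2.sf(chi2, df=X.shape[1]))


def compare_survival_by_class(
    m: ExpressionMatrix, model: PLSDAClassifier,
) -> tuple[dict[str, SurvivalCurve], LogRankResult]:
    """Stratify BCR outcomes by the PLS-DA predicted class and test.

    Samples are dichotomised by the classifier's decision threshold
    (predicted aggressive vs indolent), Kaplan-Meier curves estimated per
    class, and a log-rank test run between them.
    """
    md = m.metadata
    annotated = md["bcr_event"].notna()
    if not annotated.any():
        raise ValueError("no BCR annotations")
    sub = m.select_samples(list(md.index[annotated]))
    X = sub.values.to_numpy()
    pred = model.predict(X)
    times = sub.metadata["bcr_time_years"].astype(float).to_numpy()
    events = sub.metadata["bcr_event"].astype(bool).to_numpy()
    agg = pred > 0
    if agg.all() or not agg.any():
        raise ValueError("classifier assigned all samples to one class")
    curves = {
        "aggressive": kaplan_meier(times[agg], events[agg]),
        "indolent": kaplan_meier(times[~agg], events[~agg]),
    }
    lr = log_rank(times[agg], events[agg], times[~agg], events[~agg])
    return curves, lr
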