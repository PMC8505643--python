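"""Survival primitives: Kaplan-Meier, k-group log-rank, Cox proportional hazards.

These are self-contained implementations with the exact degeneracy contract the
downstream threshold scans need (an extreme dichotomisation must become
"non-evaluable", never crash), both Efron and Breslow tie handling in the Cox
fit, and a batch log-rank path that evaluates many dichotomies of one cohort at
once. Results agree with the standard formulations: the log-rank statistic is
the observed-minus-expected quadratic form with hypergeometric variance, and
the Cox fit maximises the partial likelihood by Newton iterations with
step-halving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, InputError

__all__ = [
    "KaplanMeierCurve",
    "LogrankResult",
    "CoxFit",
    "kaplan_meier",
    "logrank_test",
    "logrank_scan",
    "fit_cox",
]


def _validate_survival(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.ndim != 1 or event.shape != time.shape:
        raise InputError("time and event must be aligned 1-D arrays")
    if time.size == 0:
        raise InputError("empty survival input")
    if not np.all(np.isfinite(time)) or np.any(time <= 0):
        raise InputError("survival times must be finite and > 0")
    if not np.isin(event, [0, 1]).all():
        raise InputError("event indicator must be 0 or 1")
    return time, event.astype(int)


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass
class KaplanMeierCurve:
    """Product-limit estimate: right-continuous step function with S(0) = 1."""

    event_times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray      # n_j at risk just before each event time
    events: np.ndarray       # d_j events at each event time
    survival: np.ndarray     # S(t_j) after the step at t_j
    n_total: int

    def survival_at(self, t) -> np.ndarray:
        """S(t) for scalar or array t (right-continuous)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx] if t.ndim else float(s[idx])

    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5, or NaN if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.event_times[below[0]]) if below.size else float("nan")

    def to_dict(self) -> dict:
        return {
            "event_times": self.event_times.tolist(),
            "at_risk": self.at_risk.tolist(),
            "events": self.events.tolist(),
            "survival": self.survival.tolist(),
            "n_total": int(self.n_total),
        }


def kaplan_meier(time, event) -> KaplanMeierCurve:
    """Kaplan-Meier estimator S(t) = prod_{t_j <= t} (1 - d_j / n_j)."""
    time, event = _validate_survival(time, event)
    order = np.argsort(time, kind="stable")
    t_sorted, e_sorted = time[order], event[order]
    uniq, first = np.unique(t_sorted, return_index=True)
    d = np.add.reduceat(e_sorted, first)
    n_at_risk = time.size - first  # sorted ascending: at risk = those with time >= t_j
    keep = d > 0
    et, dj, nj = uniq[keep], d[keep], n_at_risk[keep]
    surv = np.cumprod(1.0 - dj / nj) if et.size else np.empty(0)
    return KaplanMeierCurve(
        event_times=et,
        at_risk=nj.astype(int),
        events=dj.astype(int),
        survival=surv,
        n_total=int(time.size),
    )


# ---------------------------------------------------------------------------
# log-rank

@dataclass
class LogrankResult:
    chi_square: float
    degrees_of_freedom: int
    p_value: float
    groups: list
    observed: np.ndarray   # O_g per group
    expected: np.ndarray   # E_g per group

    def to_dict(self) -> dict:
        return {
            "chi_square": float(self.chi_square),
            "degrees_of_freedom": int(self.degrees_of_freedom),
            "p_value": float(self.p_value),
            "groups": [str(g) for g in self.groups],
            "observed": self.observed.tolist(),
            "expected": self.expected.tolist(),
        }


def logrank_test(time, event, group) -> LogrankResult:
    """k-group log-rank test.

    At each distinct event time j with d_j events and n_j at risk, the expected
    events in group g are E_gj = d_j n_gj / n_j; the covariance of (O - E) uses
    the multivariate hypergeometric form. The statistic is the quadratic form on
    the first k-1 groups, chi-square with k-1 df.

    Raises :class:`DegenerateDataError` if fewer than two non-empty groups or no
    events at all (an explicit refusal, never NaN).
    """
    time, event = _validate_survival(time, event)
    group = np.asarray(group)
    if group.shape != time.shape:
        raise InputError("group labels must align with time/event")
    labels, gidx = np.unique(group, return_inverse=True)
    k = labels.size
    if k < 2:
        raise DegenerateDataError("log-rank needs >= 2 non-empty groups")
    if event.sum() == 0:
        raise DegenerateDataError("log-rank needs >= 1 event")

    order = np.argsort(time, kind="stable")
    t_s, e_s, g_s = time[order], event[order], gidx[order]
    uniq, first = np.unique(t_s, return_index=True)
    # at-risk per group just before each distinct time = suffix counts
    onehot = np.zeros((t_s.size, k))
    onehot[np.arange(t_s.size), g_s] = 1.0
    suffix = np.cumsum(onehot[::-1], axis=0)[::-1]          # (n, k)
    n_g = suffix[first]                                      # (m, k)
    n_tot = n_g.sum(axis=1)
    d_tot = np.add.reduceat(e_s, first)
    d_g = np.vstack([np.add.reduceat(e_s * onehot[:, g], first) for g in range(k)]).T

    at_event = d_tot > 0
    n_g, n_tot, d_tot, d_g = n_g[at_event], n_tot[at_event], d_tot[at_event], d_g[at_event]

    p_g = n_g / n_tot[:, None]
    E = d_tot[:, None] * p_g
    O = d_g
    # covariance: c_j * (diag(p) - p p^T) with c_j = d_j (n_j - d_j) / (n_j - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(n_tot > 1, d_tot * (n_tot - d_tot) / (n_tot - 1), 0.0)
    V = np.einsum("j,jg,jh->gh", c, p_g, -p_g)
    V[np.diag_indices(k)] += np.einsum("j,jg->g", c, p_g)

    diff = (O - E).sum(axis=0)
    O_sum, E_sum = O.sum(axis=0), E.sum(axis=0)
    sub, Vsub = diff[: k - 1], V[: k - 1, : k - 1]
    try:
        chi2 = float(sub @ np.linalg.solve(Vsub, sub))
    except np.linalg.LinAlgError:
        chi2 = float(sub @ np.linalg.pinv(Vsub) @ sub)
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogrankResult(
        chi_square=chi2,
        degrees_of_freedom=df,
        p_value=p,
        groups=list(labels),
        observed=O_sum,
        expected=E_sum,
    )


def logrank_scan(time, event, high: np.ndarray, min_group_size: int = 0,
                 min_group_events: int = 0):
    """Two-group log-rank for many dichotomies of one cohort at once.

    ``high`` is an (m, n) boolean matrix; row i defines the "high" group of
    dichotomy i. Returns a dict of arrays of length m: ``chi_square``, ``p``,
    ``o_high``, ``e_high``, ``variance``, and ``evaluable`` (False where a group
    is smaller than ``min_group_size`` or has fewer than ``min_group_events``
    events; statistics are NaN there). Degenerate rows never raise: a scan over
    extreme percentiles must not crash.
    """
    time, event = _validate_survival(time, event)
    high = np.atleast_2d(np.asarray(high, dtype=bool))
    if high.shape[1] != time.size:
        raise InputError("dichotomy matrix width must equal the cohort size")
    m, n = high.shape

    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    H = high[:, order]
    uniq, first = np.unique(t_s, return_index=True)
    d_tot = np.add.reduceat(e_s, first)
    at_event = d_tot > 0
    n_tot = (n - first)[at_event].astype(float)
    d_tot = d_tot[at_event].astype(float)

    Hf = H.astype(float)
    suffix = np.cumsum(Hf[:, ::-1], axis=1)[:, ::-1]        # (m, n)
    n1 = suffix[:, first][:, at_event]                       # at risk in high
    d1 = np.add.reduceat(Hf * e_s, first, axis=1)[:, at_event]

    p1 = n1 / n_tot
    E1 = (d_tot * p1).sum(axis=1)
    O1 = d1.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(n_tot > 1, d_tot * (n_tot - d_tot) / (n_tot - 1), 0.0)
    V = (c * p1 * (1.0 - p1)).sum(axis=1)

    n_high = high.sum(axis=1)
    ev_high = (high & (event == 1)).sum(axis=1)
    n_events = int(event.sum())
    evaluable = (
        (n_high >= max(min_group_size, 1))
        & ((n - n_high) >= max(min_group_size, 1))
        & (ev_high >= min_group_events)
        & ((n_events - ev_high) >= min_group_events)
        & (V > 0)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(evaluable, (O1 - E1) ** 2 / V, np.nan)
    p = np.where(evaluable, stats.chi2.sf(np.where(evaluable, chi2, 0.0), 1), np.nan)
    return {
        "chi_square": chi2,
        "p": p,
        "o_high": O1,
        "e_high": E1,
        "variance": V,
        "evaluable": evaluable,
        "n_high": n_high,
        "events_high": ev_high,
    }


# ---------------------------------------------------------------------------
# Cox proportional hazards

@dataclass
class CoxFit:
    """Cox partial-likelihood fit summary.

    ``hazard_ratios`` is exactly exp(coefficients); p-values are two-sided Wald.
    ``converged`` is False on non-convergence or monotone likelihood (perfect
    separation), in which case estimates must not be trusted.
    """

    names: list
    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: float
    null_log_likelihood: float
    n: int
    n_events: int
    tie_method: str
    converged: bool
    monotone_likelihood: bool = False
    iterations: int = 0

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coefficients / self.standard_errors

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def confidence_intervals(self, alpha: float = 0.05) -> np.ndarray:
        """(p, 2) array of hazard-ratio CI bounds."""
        zq = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.coefficients - zq * self.standard_errors)
        hi = np.exp(self.coefficients + zq * self.standard_errors)
        return np.column_stack([lo, hi])

    @property
    def lr_statistic(self) -> float:
        """Likelihood-ratio statistic of the full model against the null."""
        return 2.0 * (self.log_likelihood - self.null_log_likelihood)

    def to_dict(self) -> dict:
        ci = self.confidence_intervals()
        return {
            "covariates": [str(n) for n in self.names],
            "coefficients": self.coefficients.tolist(),
            "hazard_ratios": self.hazard_ratios.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "wald_z": self.z.tolist(),
            "p_values": self.p_values.tolist(),
            "hr_ci_low": ci[:, 0].tolist(),
            "hr_ci_high": ci[:, 1].tolist(),
            "log_likelihood": float(self.log_likelihood),
            "lr_statistic": float(self.lr_statistic),
            "n": int(self.n),
            "n_events": int(self.n_events),
            "tie_method": self.tie_method,
            "converged": bool(self.converged),
            "monotone_likelihood": bool(self.monotone_likelihood),
        }


def _cox_ll_grad_hess(beta, X, first, d_tot, event_s, tie_method):
    """Log partial likelihood, gradient and Hessian at beta.

    X is sorted ascending by time; ``first`` indexes distinct times; risk sets
    are suffixes. The Breslow terms are fully vectorised; Efron corrections are
    applied per tied-event group only.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -700, 700)
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    # suffix (reverse cumulative) sums evaluated at the first index of each time
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    at_event = d_tot > 0
    fe = first[at_event]
    d = d_tot[at_event]
    S0, S1, S2 = s0[fe], s1[fe], s2[fe]

    ev = event_s == 1
    ll = float(eta[ev].sum())
    grad = X[ev].sum(axis=0)
    hess = np.zeros((p, p))

    if tie_method == "breslow":
        ll -= float((d * np.log(S0)).sum())
        m1 = S1 / S0[:, None]
        grad -= (d[:, None] * m1).sum(axis=0)
        hess -= np.einsum("j,jab->ab", d, S2 / S0[:, None, None])
        hess += np.einsum("j,ja,jb->ab", d, m1, m1)
    else:  # efron
        # groups with a single event reduce to Breslow; vectorise those
        single = d == 1
        if single.any():
            S0s, S1s, S2s = S0[single], S1[single], S2[single]
            ll -= float(np.log(S0s).sum())
            m1 = S1s / S0s[:, None]
            grad -= m1.sum(axis=0)
            hess -= np.einsum("jab->ab", S2s / S0s[:, None, None])
            hess += np.einsum("ja,jb->ab", m1, m1)
        multi = np.nonzero(~single)[0]
        if multi.size:
            # per-group tied-death sums
            idx_all = np.nonzero(at_event)[0]
            last = np.empty_like(first)
            last[:-1] = first[1:]
            last[-1] = n
            for j in multi:
                gi = idx_all[j]
                lo, hi = first[gi], last[gi]
                dead = np.nonzero(ev[lo:hi])[0] + lo
                dj = dead.size
                s0D = w[dead].sum()
                s1D = wx[dead].sum(axis=0)
                s2D = wxx[dead].sum(axis=0)
                for l in range(dj):
                    f = l / dj
                    den = S0[j] - f * s0D
                    num1 = S1[j] - f * s1D
                    num2 = S2[j] - f * s2D
                    ll -= np.log(den)
                    m1 = num1 / den
                    grad -= m1
                    hess -= num2 / den - np.outer(m1, m1)
    return ll, grad, hess


def fit_cox(
    X,
    time,
    event,
    names: Optional[Sequence[str]] = None,
    tie_method: str = "efron",
    max_iter: int = 100,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton iterations.

    Efron tie correction by default (Breslow available via ``tie_method``);
    step-halving guarantees the partial likelihood never decreases; convergence
    when the max |score| < ``score_tol`` or the relative log-likelihood change
    < ``ll_tol``. Monotone likelihood (perfect separation) is flagged, not
    silently reported as a huge finite estimate.
    """
    time, event = _validate_survival(time, event)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != time.size:
        raise InputError("covariate rows must match the number of samples")
    if not np.all(np.isfinite(X)):
        raise InputError("covariates contain missing or non-finite values")
    if event.sum() == 0:
        raise DegenerateDataError("Cox fit needs >= 1 event")
    if tie_method not in ("efron", "breslow"):
        raise InputError(f"unknown tie method {tie_method!r}")
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = names[int(np.nonzero(sds == 0)[0][0])]
        raise InputError(f"constant covariate {bad!r}")
    center = X.mean(axis=0)
    Xc = X - center
    if np.linalg.matrix_rank(Xc) < p:
        raise InputError("covariate matrix is rank deficient (collinear covariates)")

    order = np.argsort(time, kind="stable")
    Xs, e_s = Xc[order], event[order]
    t_s = time[order]
    _, first = np.unique(t_s, return_index=True)
    d_tot = np.add.reduceat(e_s, first)

    beta = np.zeros(p)
    ll, grad, hess = _cox_ll_grad_hess(beta, Xs, first, d_tot, e_s, tie_method)
    null_ll = ll
    converged = False
    monotone = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < score_tol:
            converged = True
            break
        info = -hess
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving: never let the log partial likelihood decrease
        factor = 1.0
        for _ in range(40):
            cand = beta + factor * step
            ll_new, grad_new, hess_new = _cox_ll_grad_hess(
                cand, Xs, first, d_tot, e_s, tie_method
            )
            if ll_new >= ll - 1e-14:
                break
            factor /= 2.0
        rel_change = abs(ll_new - ll) / max(abs(ll), 1.0)
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(beta)) > 40:
            monotone = True
            break
        if rel_change < ll_tol:
            converged = True
            break
    if np.max(np.abs(grad)) < score_tol:
        converged = True
    if monotone:
        converged = False

    info = -hess
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return CoxFit(
        names=list(names),
        coefficients=beta,
        standard_errors=se,
        log_likelihood=float(ll),
        null_log_likelihood=float(null_ll),
        n=n,
        n_events=int(event.sum()),
        tie_method=tie_method,
        converged=bool(converged),
        monotone_likelihood=monotone,
        iterations=it,
    )
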