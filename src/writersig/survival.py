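"""Survival machinery: product-limit curves, log-rank, Cox PH, prognostic
screening, maximally selected rank-statistic cutpoints, time-dependent AUC
and Harrell's concordance.

Everything is implemented directly on the partial-likelihood / counting-
process definitions so each estimator can be audited against hand-worked
examples; established survival packages are used only as independent
cross-checks in the test suite.

Conventions: censorings at an event time are still at risk for that event
(the usual product-limit convention); Cox ties are handled with the Efron
correction; score ties in the concordance count one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "KMCurve",
    "CoxResult",
    "CutpointResult",
    "km_curve",
    "logrank",
    "logrank_z",
    "cox_fit",
    "prognostic_screen",
    "max_rank_cutpoint",
    "td_auc",
    "c_index",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    median: float | None

    def survival_at(self, t: float, left: bool = False) -> float:
        """Step-function value S(t); ``left`` gives the left limit S(t-)."""
        side = "left" if left else "right"
        i = np.searchsorted(self.event_times, t, side=side)
        return 1.0 if i == 0 else float(self.survival[i - 1])


def _check_surv(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.size == 0:
        raise InputError("empty survival input")
    if np.any(t <= 0):
        raise InputError("survival times must be positive")
    if not np.isin(e, (0, 1)).all():
        raise InputError("event indicators must be 0 or 1")
    return t, e.astype(int)


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    The median is the first event time at which survival drops to 0.5 or
    below, or None if the curve never reaches 0.5.
    """
    t, e = _check_surv(times, events)
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    uniq = np.unique(ts[es == 1])
    if uniq.size == 0:
        return KMCurve(np.array([]), np.array([]), np.array([], int),
                       np.array([], int), None)
    at_risk = ts.size - np.searchsorted(ts, uniq, side="left")
    ev_ts = ts[es == 1]
    n_events = (np.searchsorted(ev_ts, uniq, side="right")
                - np.searchsorted(ev_ts, uniq, side="left"))
    # exact rational product so each value is the correctly rounded
    # estimate; without censoring the product telescopes to (n - D)/n
    from fractions import Fraction
    acc = Fraction(1)
    survival = np.empty(uniq.size)
    for i, (d, r) in enumerate(zip(n_events, at_risk)):
        acc *= Fraction(int(r - d), int(r))
        survival[i] = float(acc)
    below = np.flatnonzero(survival <= 0.5)
    median = float(uniq[below[0]]) if below.size else None
    return KMCurve(uniq, survival, at_risk.astype(int), n_events.astype(int), median)


# ---------------------------------------------------------------------------
# log-rank

def _logrank_oe_var(t, e, group1: np.ndarray) -> tuple[float, float]:
    """Sum of observed-minus-expected events in group 1 and its variance
    under the hypergeometric null, over all distinct event times."""
    order = np.argsort(t, kind="stable")
    ts, es, gs = t[order], e[order], group1[order]
    uniq = np.unique(ts[es == 1])
    idx = np.searchsorted(ts, uniq, side="left")
    n_tot = ts.size - idx
    # group-1 members at risk (suffix counts)
    suffix_g = np.concatenate([np.cumsum(gs[::-1])[::-1], [0]])
    n1 = suffix_g[idx]
    ev_ts, ev_g = ts[es == 1], gs[es == 1]
    lo = np.searchsorted(ev_ts, uniq, side="left")
    hi = np.searchsorted(ev_ts, uniq, side="right")
    d = hi - lo
    cum_ev_g = np.concatenate([[0], np.cumsum(ev_g)])
    d1 = cum_ev_g[hi] - cum_ev_g[lo]
    frac = n1 / n_tot
    oe = float(np.sum(d1 - d * frac))
    ok = n_tot > 1
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = d * frac * (1 - frac) * (n_tot - d) / (n_tot - 1)
    var = float(np.sum(terms[ok]))
    return oe, var


def logrank_z(times, events, group) -> float:
    """Standardized two-group log-rank statistic (O-E)/sqrt(V)."""
    t, e = _check_surv(times, events)
    g = np.asarray(group)
    levels = np.unique(g)
    if len(levels) != 2:
        raise InputError(f"log-rank needs exactly two groups, got {len(levels)}")
    if e.sum() == 0:
        raise InputError("log-rank undefined without any events")
    oe, var = _logrank_oe_var(t, e, g == levels[0])
    if var <= 0:
        return 0.0
    return oe / np.sqrt(var)


def logrank(times, events, group) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its p-value."""
    z = logrank_z(times, events, group)
    chi2 = z * z
    return float(chi2), float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)

@dataclass
class CoxResult:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    hazard_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_value: np.ndarray
    log_likelihood: float
    n_events: int
    n_iter: int
    converged: bool
    separation: bool = False

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef, "se": self.se, "hazard_ratio": self.hazard_ratio,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p_value": self.p_value,
        }, index=self.names)


def _cox_loglik_grad_hess(beta, X, event_blocks):
    """Efron partial log-likelihood with gradient and Hessian.

    event_blocks: list of (risk_index_start, death_row_indices) over rows of
    X sorted by descending time; the risk set of a block is rows
    [0:risk_index_start).
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # stabilize; partial likelihood is shift-invariant
    theta = np.exp(eta)
    wX = theta[:, None] * X
    cum0 = np.concatenate([[0.0], np.cumsum(theta)])
    cum1 = np.vstack([np.zeros(p), np.cumsum(wX, axis=0)])
    # second-moment cumulative sums
    outer = wX[:, :, None] * X[:, None, :]
    cum2 = np.concatenate([np.zeros((1, p, p)), np.cumsum(outer, axis=0)])

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for stop, deaths in event_blocks:
        d = len(deaths)
        s0 = cum0[stop]
        s1 = cum1[stop]
        s2 = cum2[stop]
        td = theta[deaths]
        s0d = td.sum()
        s1d = wX[deaths].sum(axis=0)
        s2d = outer[deaths].sum(axis=0)
        ll += eta[deaths].sum()
        for l in range(d):
            f = l / d
            a0 = s0 - f * s0d
            a1 = s1 - f * s1d
            a2 = s2 - f * s2d
            ll -= np.log(a0)
            grad_term = a1 / a0
            grad -= grad_term
            hess -= a2 / a0 - np.outer(grad_term, grad_term)
        grad += X[deaths].sum(axis=0)
    return ll, grad, hess


def cox_fit(times, events, covariates, names: list[str] | None = None,
            max_iter: int = 100, tol: float = 1e-9) -> CoxResult:
    """Cox proportional-hazards fit by Newton-Raphson with Efron ties.

    ``covariates`` is samples x p (a vector is treated as one covariate).
    Wald 95% confidence intervals and p-values are reported per covariate.
    Non-convergence and monotone-likelihood (separation) are flagged, not
    raised.
    """
    t, e = _check_surv(times, events)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != t.size:
        raise InputError("covariate rows must match number of samples")
    if not np.isfinite(X).all():
        raise InputError("covariates must be finite")
    if e.sum() == 0:
        raise InputError("Cox model requires at least one event")
    const = np.flatnonzero(X.std(axis=0) == 0)
    if const.size:
        raise InputError(f"constant covariate column(s): {const.tolist()}")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]

    # sort by descending time so risk sets are prefixes
    order = np.argsort(-t, kind="stable")
    ts, es, Xs = t[order], e[order], X[order]
    center = Xs.mean(axis=0)
    Xc = Xs - center

    event_blocks = []
    ev_idx = np.flatnonzero(es == 1)
    for ut in np.unique(ts[ev_idx]):
        deaths = ev_idx[ts[ev_idx] == ut]
        stop = int(np.searchsorted(-ts, -ut, side="right"))
        event_blocks.append((stop, deaths))

    beta = np.zeros(X.shape[1])
    ll, grad, hess = _cox_loglik_grad_hess(beta, Xc, event_blocks)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        new_beta = beta - step
        new_ll, new_grad, new_hess = _cox_loglik_grad_hess(new_beta, Xc, event_blocks)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 20:
            step /= 2.0
            new_beta = beta - step
            new_ll, new_grad, new_hess = _cox_loglik_grad_hess(new_beta, Xc, event_blocks)
            halvings += 1
        delta = np.abs(new_beta - beta).max()
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if delta < tol or np.abs(grad).max() < tol:
            converged = True
            break

    separation = bool(np.abs(beta).max() > 15)
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(beta.size, np.nan)
        converged = False
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    zq = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):
        hr = np.exp(beta)
        ci_low, ci_high = np.exp(beta - zq * se), np.exp(beta + zq * se)
    return CoxResult(list(names), beta, se, hr,
                     ci_low, ci_high, p,
                     float(ll), int(e.sum()), it, converged, separation)


# ---------------------------------------------------------------------------
# prognostic screening

def prognostic_screen(X, clinical: pd.DataFrame, genes: list[str],
                      alpha: float = 0.001, require_both: bool = True) -> list[str]:
    """Screen genes for prognostic value.

    A gene passes iff the univariate Cox model on its standardized
    continuous expression has Wald p < alpha AND the log-rank test on its
    median-split dichotomization has p < alpha (``require_both=False``
    relaxes to either).  Genes whose median split is degenerate fail the
    log-rank arm.
    """
    from .datasets import ExpressionMatrix

    if isinstance(X, ExpressionMatrix):
        frame = X.to_frame()
    else:
        frame = X
    t = clinical["os_years"].to_numpy(dtype=float)
    e = clinical["os_event"].to_numpy(dtype=int)
    passed = []
    for gene in genes:
        expr = frame.loc[gene].to_numpy(dtype=float)
        sd = expr.std()
        if sd == 0:
            continue
        zexpr = (expr - expr.mean()) / sd
        cox_p = cox_fit(t, e, zexpr, names=[gene]).p_value[0]
        high = expr > np.median(expr)
        if 0 < high.sum() < high.size:
            _, lr_p = logrank(t, e, high)
        else:
            lr_p = 1.0
        hits = (cox_p < alpha, lr_p < alpha)
        if (all(hits) if require_both else any(hits)):
            passed.append(gene)
    return passed


# ---------------------------------------------------------------------------
# maximally selected rank statistic

@dataclass
class CutpointResult:
    cutpoint: float
    max_statistic: float
    minprop: float
    group_sizes: tuple[int, int]
    p_value: float | None = None


def _scan_cutpoints(score, t, e, minprop):
    """|standardized log-rank| at every feasible split (low <= cut < high)."""
    uniq = np.unique(score)
    n = score.size
    min_n = minprop * n
    cuts, zs = [], []
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cut = (lo + hi) / 2.0
        high = score > cut
        n_high = int(high.sum())
        if n_high < min_n or (n - n_high) < min_n:
            continue
        try:
            z = logrank_z(t, e, high)
        except InputError:
            continue
        cuts.append(cut)
        zs.append(abs(z))
    return np.array(cuts), np.array(zs)


def max_rank_cutpoint(score, times, events, minprop: float = 0.1,
                      n_permutations: int = 0,
                      seed: int = 0) -> CutpointResult:
    """Cutpoint maximizing the standardized log-rank statistic.

    Candidate cutpoints are midpoints between consecutive distinct score
    values for which both resulting groups hold at least ``minprop`` of the
    samples; ties in the statistic break toward the lower cutpoint.  An
    optional permutation p-value (scores permuted against survival,
    ``n_permutations`` replicates) accounts for the cutpoint optimization.
    """
    s = np.asarray(score, dtype=float)
    t, e = _check_surv(times, events)
    if np.unique(s).size < 2:
        raise InputError("all scores identical; no cutpoint exists")
    cuts, zs = _scan_cutpoints(s, t, e, minprop)
    if cuts.size == 0:
        raise InputError("no feasible cutpoint under minprop constraint")
    best = int(np.argmax(zs))  # argmax takes the first (lowest) on ties
    cut = float(cuts[best])
    stat = float(zs[best])
    n_high = int((s > cut).sum())
    p_value = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            sp = rng.permutation(s)
            _, zp = _scan_cutpoints(sp, t, e, minprop)
            if zp.size and zp.max() >= stat:
                exceed += 1
        p_value = (exceed + 1) / (n_permutations + 1)
    return CutpointResult(cut, stat, minprop, (s.size - n_high, n_high), p_value)


# ---------------------------------------------------------------------------
# time-dependent AUC and concordance

def _censoring_km(t, e) -> KMCurve:
    return km_curve(t, 1 - e)


def td_auc(score, times, events, horizon: float) -> float:
    """Cumulative-case / dynamic-control AUC at ``horizon`` with IPCW.

    Cases are samples with an observed event at or before the horizon,
    controls are samples still under observation beyond it; both are
    weighted by the inverse of the censoring-distribution product-limit
    estimate.
    """
    s = np.asarray(score, dtype=float)
    t, e = _check_surv(times, events)
    cases = (t <= horizon) & (e == 1)
    controls = t > horizon
    if cases.sum() == 0 or controls.sum() == 0:
        raise InputError("AUC undefined: need >= 1 case and >= 1 control at horizon")
    G = _censoring_km(t, e)
    w_case = np.array([1.0 / max(G.survival_at(ti, left=True), 1e-12)
                       for ti in t[cases]])
    w_ctrl = np.full(int(controls.sum()),
                     1.0 / max(G.survival_at(horizon), 1e-12))
    sc = s[cases][:, None]
    st = s[controls][None, :]
    ind = (sc > st) + 0.5 * (sc == st)
    wmat = w_case[:, None] * w_ctrl[None, :]
    return float((ind * wmat).sum() / wmat.sum())


def c_index(score, times, events) -> float:
    """Harrell's concordance index.

    Comparable pairs are those where the shorter time is an observed
    event and the times differ; the pair is concordant when that sample
    has the higher score, and score ties count one half.
    """
    s = np.asarray(score, dtype=float)
    t, e = _check_surv(times, events)
    dt = t[:, None] - t[None, :]
    comparable = (dt < 0) & (e[:, None] == 1)
    if not comparable.any():
        raise InputError("no usable pairs for the concordance index")
    ds = s[:, None] - s[None, :]
    conc = (ds > 0) + 0.5 * (ds == 0)
    return float(conc[comparable].sum() / comparable.sum())
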