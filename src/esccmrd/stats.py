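"""Clinical statistics for perioperative MRD cohorts.

Implements the inferential toolkit the MRD analysis needs, from first
principles:

* 2x2 diagnostics (sensitivity / specificity / PPV / NPV) with a fixed
  table orientation — rows are ctDNA status (positive first), columns are
  recurrence (recurrent first);
* Fisher's exact test with the probability-mass two-sided rule and the
  conditional-MLE odds ratio of the noncentral hypergeometric likelihood
  (the estimator associated with the exact test; the sample cross-product
  ratio can be badly inflated in sparse tables);
* Kaplan-Meier product-limit curves and the two-group log-rank test;
* Cox proportional hazards with Breslow tie handling, Newton-Raphson
  maximization, separation (monotone likelihood) detection, and
  profile-likelihood intervals for separated covariates;
* Wilcoxon rank-sum / Mann-Whitney U with midranks, exact enumeration for
  small samples and a tie-corrected normal approximation otherwise.

The independent implementations in scipy and lifelines are used as
cross-check oracles in the test suite, never as the computation here.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

Status = Literal["positive", "negative", "not_evaluable"]


@dataclass(frozen=True)
class ClinicalRecord:
    """Outcome and covariate row for one patient."""

    patient_id: str
    recurrence: bool
    dfs_months: float
    dfs_event: bool
    os_months: float
    os_event: bool
    age: float
    sex: str
    stage: Literal["I", "II", "III"]
    adjuvant: bool
    preop_status: Status = "not_evaluable"
    postop_status: Status = "not_evaluable"

    def __post_init__(self) -> None:
        if self.dfs_months < 0 or self.os_months < 0:
            raise ValueError("survival times must be >= 0")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a=pos&rec, b=pos&no-rec, c=neg&rec, d=neg&no-rec."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Proportions in [0,1]; None where the denominator is zero."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None


@dataclass(frozen=True)
class FisherResult:
    p_two_sided: float
    or_cmle: float | None  # None when a margin is zero; may be 0.0 or inf at boundary
    or_ci: tuple[float, float] | None
    conf_level: float = 0.95


@dataclass(frozen=True)
class KMLogRankResult:
    curves: dict[object, pd.DataFrame]  # group -> (time, n_risk, n_events, n_censored, survival)
    chi2: float | None
    p_value: float | None
    hazard_ratio_oe: float | None  # (O1/E1)/(O2/E2), first group over second
    groups: tuple = ()


@dataclass(frozen=True)
class CoxResult:
    names: list[str]
    coef: np.ndarray
    hr: np.ndarray
    se: np.ndarray
    p_wald: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    log_likelihood: float
    n_events: int
    converged: bool
    separated: np.ndarray  # bool per covariate: monotone likelihood detected
    score_chi2_null: float  # global score test at beta = 0
    ci_method: list[str] = field(default_factory=list)  # "wald" or "profile"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.names, "coef": self.coef, "hr": self.hr,
                "se": self.se, "p": self.p_wald,
                "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
                "separated": self.separated, "ci_method": self.ci_method,
            }
        )


@dataclass(frozen=True)
class RankSumResult:
    w: float  # Mann-Whitney U of the first sample (midranks)
    p_two_sided: float
    method: Literal["exact", "normal"]


# ---------------------------------------------------------------------------
# 2x2 construction and diagnostics
# ---------------------------------------------------------------------------

def build_contingency(
    records: pd.DataFrame | Sequence[ClinicalRecord],
    timepoint: Literal["preop", "postop"],
) -> ContingencyTable:
    """Cross-tabulate ctDNA status at `timepoint` against clinical recurrence.

    not_evaluable patients are excluded listwise (count logged).
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([vars(r) for r in records])
    if records.empty:
        raise ValueError("empty record list")
    col = f"{timepoint}_status"
    if col not in records.columns:
        raise ValueError(f"records lack column {col}")
    usable = records[records[col].isin(["positive", "negative"])]
    n_excl = len(records) - len(usable)
    if n_excl:
        logger.info("build_contingency: excluded %d not_evaluable patients", n_excl)
    if usable.empty:
        raise ValueError("all patients not_evaluable — no 2x2 table")
    pos = usable[col] == "positive"
    rec = usable["recurrence"].astype(bool)
    return ContingencyTable(
        a=int((pos & rec).sum()), b=int((pos & ~rec).sum()),
        c=int((~pos & rec).sum()), d=int((~pos & ~rec).sum()),
    )


def diagnostic_metrics(t: ContingencyTable) -> DiagnosticMetrics:
    """Sensitivity a/(a+c), specificity d/(b+d), PPV a/(a+b), NPV d/(c+d)."""
    if t.total <= 0:
        raise ValueError("empty table")

    def frac(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return DiagnosticMetrics(
        sensitivity=frac(t.a, t.a + t.c),
        specificity=frac(t.d, t.b + t.d),
        ppv=frac(t.a, t.a + t.b),
        npv=frac(t.d, t.c + t.d),
    )


# ---------------------------------------------------------------------------
# Fisher's exact test + conditional-MLE odds ratio
# ---------------------------------------------------------------------------

def _nchg_log_weights(r1: int, r2: int, c1: int, log_psi: float) -> tuple[np.ndarray, np.ndarray]:
    """Support and log-weights of Fisher's noncentral hypergeometric distribution."""
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    lw = (
        special.gammaln(r1 + 1) - special.gammaln(k + 1) - special.gammaln(r1 - k + 1)
        + special.gammaln(r2 + 1) - special.gammaln(c1 - k + 1)
        - special.gammaln(r2 - (c1 - k) + 1)
        + k * log_psi
    )
    return k, lw


def _nchg_mean(r1: int, r2: int, c1: int, log_psi: float) -> float:
    k, lw = _nchg_log_weights(r1, r2, c1, log_psi)
    w = np.exp(lw - lw.max())
    return float((k * w).sum() / w.sum())


def _nchg_tail(r1: int, r2: int, c1: int, a: int, log_psi: float, upper: bool) -> float:
    k, lw = _nchg_log_weights(r1, r2, c1, log_psi)
    w = np.exp(lw - lw.max())
    w /= w.sum()
    return float(w[k >= a].sum()) if upper else float(w[k <= a].sum())


_LOG_PSI_MAX = 60.0  # psi beyond e^60 is numerically indistinguishable from a boundary


def conditional_mle_or(t: ContingencyTable) -> float:
    """Conditional MLE of the odds ratio given both margins.

    Solves E[a | margins, psi] = a for psi, the score equation of the
    noncentral hypergeometric likelihood; E is strictly increasing in
    log(psi), so a bracketed root search converges to high precision.
    Boundary tables return 0.0 (a at the support minimum) or +inf (maximum).
    """
    r1, r2, c1 = t.a + t.b, t.c + t.d, t.a + t.c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    if t.a == lo:
        return 0.0
    if t.a == hi:
        return math.inf

    def f(log_psi: float) -> float:
        return _nchg_mean(r1, r2, c1, log_psi) - t.a

    root = optimize.brentq(f, -_LOG_PSI_MAX, _LOG_PSI_MAX, xtol=1e-12, rtol=1e-14)
    return float(math.exp(root))


def _conditional_ci(t: ContingencyTable, conf_level: float) -> tuple[float, float]:
    """Exact (Cornfield) conditional CI: equal tail probabilities alpha/2."""
    r1, r2, c1 = t.a + t.b, t.c + t.d, t.a + t.c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    alpha = 1.0 - conf_level

    if t.a == lo:
        lower = 0.0
    else:
        # smallest psi with P(X >= a | psi) = alpha/2
        def f_lo(log_psi: float) -> float:
            return _nchg_tail(r1, r2, c1, t.a, log_psi, upper=True) - alpha / 2

        lower = math.exp(
            optimize.brentq(f_lo, -_LOG_PSI_MAX, _LOG_PSI_MAX, xtol=1e-10)
        )
    if t.a == hi:
        upper = math.inf
    else:
        def f_hi(log_psi: float) -> float:
            return _nchg_tail(r1, r2, c1, t.a, log_psi, upper=False) - alpha / 2

        upper = math.exp(
            optimize.brentq(f_hi, -_LOG_PSI_MAX, _LOG_PSI_MAX, xtol=1e-10)
        )
    return (float(lower), float(upper))


def fisher_exact(
    t: ContingencyTable, conf_level: float = 0.95, compute_or: bool = True
) -> FisherResult:
    """Two-sided Fisher's exact test with conditional-MLE odds ratio.

    The two-sided p is the probability-mass rule: the sum of hypergeometric
    probabilities of all tables with the observed margins that are at most
    as probable as the observed one (relative tie slack 1e-7).  A zero
    margin makes the table degenerate: p = 1 and the odds ratio undefined.
    ``compute_or=False`` skips the odds-ratio root searches when only the
    p-value is needed.
    """
    r1, r2, c1 = t.a + t.b, t.c + t.d, t.a + t.c
    c2 = t.b + t.d
    if min(r1, r2, c1, c2) == 0:
        return FisherResult(p_two_sided=1.0, or_cmle=None, or_ci=None,
                            conf_level=conf_level)

    k, lw = _nchg_log_weights(r1, r2, c1, 0.0)  # psi = 1: central hypergeometric
    logp = lw - special.logsumexp(lw)
    obs = logp[k == t.a][0]
    p = float(np.exp(logp[logp <= obs + math.log(1 + 1e-7)]).sum())
    p = min(1.0, p)
    if not compute_or:
        return FisherResult(p_two_sided=p, or_cmle=None, or_ci=None,
                            conf_level=conf_level)
    return FisherResult(
        p_two_sided=p,
        or_cmle=conditional_mle_or(t),
        or_ci=_conditional_ci(t, conf_level),
        conf_level=conf_level,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier + log-rank
# ---------------------------------------------------------------------------

def _km_one_group(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit estimator; censoring at a death time is handled after deaths."""
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    grid = np.unique(times)
    n = len(times)
    rows = []
    s = 1.0
    for ti in grid:
        at_risk = int((times >= ti).sum())
        d = int(events[times == ti].sum())
        c = int((times == ti).sum()) - d
        if d > 0:
            s *= 1.0 - d / at_risk
        rows.append(
            {"time": float(ti), "n_risk": at_risk, "n_events": d,
             "n_censored": c, "survival": s}
        )
    df = pd.DataFrame(rows, columns=["time", "n_risk", "n_events", "n_censored", "survival"])
    assert n == 0 or df["n_risk"].iloc[0] == n
    return df


def km_logrank(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence | None = None,
) -> KMLogRankResult:
    """Kaplan-Meier curves per group; two-group log-rank test (1 df).

    With a single group (or `groups=None`) only curves are returned.
    The O/E hazard-ratio summary (O1/E1)/(O2/E2) is the classic log-rank
    companion statistic, not a model-based estimate.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) != len(events):
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("negative survival times")
    if groups is None:
        groups = np.zeros(len(times), dtype=int)
    groups = np.asarray(groups)
    if len(groups) != len(times):
        raise ValueError("groups must match times in length")

    labels = tuple(pd.unique(groups))
    curves = {
        g: _km_one_group(times[groups == g], events[groups == g]) for g in labels
    }
    if len(labels) == 1:
        return KMLogRankResult(curves=curves, chi2=None, p_value=None,
                               hazard_ratio_oe=None, groups=labels)
    if len(labels) != 2:
        raise ValueError("log-rank test implemented for exactly two groups")

    g1 = groups == labels[0]
    event_times = np.unique(times[events])
    o1 = e1 = o2 = e2 = v = 0.0
    for ti in event_times:
        n_at = (times >= ti).sum()
        n1_at = (times[g1] >= ti).sum()
        d = (events & (times == ti)).sum()
        d1 = (events & (times == ti) & g1).sum()
        o1 += d1
        o2 += d - d1
        exp1 = d * n1_at / n_at
        e1 += exp1
        e2 += d - exp1
        if n_at > 1:
            v += d * (n1_at / n_at) * (1 - n1_at / n_at) * (n_at - d) / (n_at - 1)
    if v == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (o1 - e1) ** 2 / v
        p = float(stats.chi2.sf(chi2, df=1))
    hr = None
    if e1 > 0 and e2 > 0 and o2 > 0:
        hr = (o1 / e1) / (o2 / e2)
    return KMLogRankResult(curves=curves, chi2=float(chi2), p_value=p,
                           hazard_ratio_oe=hr, groups=labels)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties, Newton-Raphson)
# ---------------------------------------------------------------------------

_BETA_CAP = 15.0  # |coef| beyond this (HR > 3e6) is treated as monotone likelihood


def _breslow_ll_grad_hess(
    beta: np.ndarray, times: np.ndarray, events: np.ndarray, x: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow log partial likelihood, gradient and Hessian.

    Rows must be sorted by descending time so that risk sets are cumulative
    prefixes.  Tied event times share the full risk-set denominator.
    """
    n, p = x.shape
    eta = x @ beta
    eta_shift = eta - eta.max()  # guard overflow; cancels in all ratios
    w = np.exp(eta_shift)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * x, axis=0)
    s2 = np.cumsum(w[:, None, None] * (x[:, :, None] * x[:, None, :]), axis=0)

    # last index of each tied-time block (risk set = prefix through the block)
    block_end = np.empty(n, dtype=np.int64)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and times[j + 1] == times[i]:
            j += 1
        block_end[i : j + 1] = j
        i = j + 1

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    ev_idx = np.flatnonzero(events)
    for i in ev_idx:
        e = block_end[i]
        ll += eta_shift[i] - math.log(s0[e])
        mu = s1[e] / s0[e]
        grad += x[i] - mu
        hess -= s2[e] / s0[e] - np.outer(mu, mu)
    return float(ll), grad, hess


def _newton_cox(
    times: np.ndarray, events: np.ndarray, x: np.ndarray,
    beta0: np.ndarray | None = None, fixed: dict[int, float] | None = None,
    max_iter: int = 100, tol: float = 1e-8,
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray, bool]:
    """Newton-Raphson with step halving; optionally hold some coefficients fixed.

    Returns (beta, ll, grad, hess, converged) with grad/hess over the free
    coordinates embedded in full dimension.
    """
    n, p = x.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    fixed = fixed or {}
    free = np.array([j for j in range(p) if j not in fixed], dtype=np.int64)
    for j, val in fixed.items():
        beta[j] = val

    ll, grad, hess = _breslow_ll_grad_hess(beta, times, events, x)
    converged = False
    for _ in range(max_iter):
        g = grad[free]
        if np.max(np.abs(g), initial=0.0) < tol:
            converged = True
            break
        h = hess[np.ix_(free, free)]
        try:
            step = np.linalg.solve(h, -g)
        except np.linalg.LinAlgError:
            step = -g  # singular Hessian: fall back to gradient direction
        # step halving on the log partial likelihood
        new_ll = -np.inf
        for _half in range(40):
            trial = beta.copy()
            trial[free] = np.clip(beta[free] + step, -_BETA_CAP, _BETA_CAP)
            new_ll, new_grad, new_hess = _breslow_ll_grad_hess(trial, times, events, x)
            if new_ll >= ll - 1e-12:
                break
            step *= 0.5
        if new_ll < ll - 1e-12:
            break  # cannot improve
        beta, ll, grad, hess = trial, new_ll, new_grad, new_hess
    else:
        converged = np.max(np.abs(grad[free]), initial=0.0) < tol
    return beta, ll, grad, hess, converged


def _profile_ci_bound(
    j: int, beta_hat: np.ndarray, ll_max: float,
    times: np.ndarray, events: np.ndarray, x: np.ndarray,
    direction: int, conf_level: float,
) -> float:
    """Profile-likelihood CI bound for coefficient j in the given direction."""
    crit = stats.chi2.ppf(conf_level, df=1)

    def deviance(b: float) -> float:
        fixed = {j: b}
        beta0 = beta_hat.copy()
        beta0[j] = b
        _, ll, _, _, _ = _newton_cox(times, events, x, beta0=beta0, fixed=fixed)
        return 2.0 * (ll_max - ll) - crit

    b0 = beta_hat[j]
    step = 0.5
    b = b0
    for _ in range(80):
        b = b + direction * step
        if abs(b) > _BETA_CAP:
            return direction * math.inf
        if deviance(b) > 0:
            return float(optimize.brentq(deviance, min(b0, b), max(b0, b), xtol=1e-6))
        step *= 1.5
    return direction * math.inf


def cox_ph(
    times: Sequence[float],
    events: Sequence[bool],
    x: np.ndarray,
    names: Sequence[str] | None = None,
    conf_level: float = 0.95,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxResult:
    """Fit a Cox proportional-hazards model (Breslow partial likelihood).

    Monotone likelihood (separation — plausible in small cohorts where all
    events fall in one MRD group) is detected when a coefficient runs to the
    internal cap with the score still pushing outward; such covariates are
    reported with an infinite hazard ratio, a warning, and a
    profile-likelihood interval instead of a meaningless Wald interval.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if len(times) != n or len(events) != n:
        raise ValueError("times, events and covariates must have equal length")
    if events.sum() == 0:
        raise ValueError("no events — Cox model undefined")
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]

    # center covariates for conditioning; shifts do not change the partial likelihood
    x_mean = x.mean(axis=0)
    xc = x - x_mean

    order = np.argsort(-times, kind="stable")
    ts, es, xs = times[order], events[order], xc[order]

    # global score test at beta = 0 (equals the log-rank statistic for a
    # single binary covariate with no tied event times)
    _, g0, h0 = _breslow_ll_grad_hess(np.zeros(p), ts, es, xs)
    try:
        score_chi2 = float(g0 @ np.linalg.solve(-h0, g0))
    except np.linalg.LinAlgError:
        score_chi2 = float("nan")

    beta, ll, grad, hess, converged = _newton_cox(
        ts, es, xs, max_iter=max_iter, tol=tol
    )
    separated = (np.abs(beta) >= _BETA_CAP - 1e-6) & (np.sign(grad) == np.sign(beta))
    if not converged and not separated.any():
        raise RuntimeError(
            f"Cox Newton-Raphson did not converge in {max_iter} iterations "
            f"(max |score| = {np.max(np.abs(grad)):.3g})"
        )
    if separated.any():
        logger.warning(
            "monotone partial likelihood (separation) for covariates %s — "
            "reporting profile-likelihood intervals",
            [names[j] for j in np.flatnonzero(separated)],
        )

    cov = np.full((p, p), np.nan)
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        pass
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    z = stats.norm.ppf(0.5 + conf_level / 2)
    with np.errstate(over="ignore"):  # inf upper bound is a legitimate answer
        ci_lo = np.exp(beta - z * se)
        ci_hi = np.exp(beta + z * se)
    p_wald = 2 * stats.norm.sf(np.abs(beta) / np.where(se > 0, se, np.nan))
    hr = np.exp(beta)
    ci_method = ["wald"] * p

    for j in np.flatnonzero(separated):
        hr[j] = math.inf if beta[j] > 0 else 0.0
        lo_b = _profile_ci_bound(j, beta, ll, ts, es, xs, -1, conf_level)
        hi_b = _profile_ci_bound(j, beta, ll, ts, es, xs, +1, conf_level)
        ci_lo[j] = math.exp(lo_b) if math.isfinite(lo_b) else 0.0
        ci_hi[j] = math.exp(hi_b) if math.isfinite(hi_b) else math.inf
        # likelihood-ratio p against beta_j = 0 replaces the meaningless Wald p
        beta0 = beta.copy()
        beta0[j] = 0.0
        _, ll0, _, _, _ = _newton_cox(ts, es, xs, beta0=beta0, fixed={j: 0.0})
        p_wald[j] = float(stats.chi2.sf(2 * (ll - ll0), df=1))
        se[j] = math.nan
        ci_method[j] = "profile"

    return CoxResult(
        names=names, coef=beta, hr=hr, se=se, p_wald=p_wald,
        ci_lower=ci_lo, ci_upper=ci_hi, log_likelihood=ll,
        n_events=int(events.sum()), converged=bool(converged or separated.any()),
        separated=separated, score_chi2_null=score_chi2, ci_method=ci_method,
    )


_STAGE_CODE = {"I": 1, "II": 2, "III": 3}


def cox_fit(
    records: pd.DataFrame | Sequence[ClinicalRecord],
    covariates: Sequence[str],
    time_col: str = "dfs_months",
    event_col: str = "dfs_event",
    **kwargs,
) -> CoxResult:
    """Cox fit from a clinical table with standard encodings.

    Stage is encoded ordinally (I=1, II=2, III=3); booleans and
    positive/negative statuses as 0/1.  not_evaluable patients are dropped
    listwise when a status covariate is requested (count logged).
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([vars(r) for r in records])
    df = records.copy()
    for col in covariates:
        if col.endswith("_status"):
            keep = df[col].isin(["positive", "negative"])
            if (~keep).any():
                logger.info("cox_fit: dropping %d not_evaluable patients", int((~keep).sum()))
                df = df[keep]
    cols = []
    for col in covariates:
        s = df[col]
        if col == "stage":
            cols.append(s.map(_STAGE_CODE).astype(float))
        elif col.endswith("_status"):
            cols.append((s == "positive").astype(float))
        elif s.dtype == bool or s.dtype == object:
            cols.append(s.astype(bool).astype(float) if s.dtype == bool else
                        pd.factorize(s)[0].astype(float))
        else:
            cols.append(s.astype(float))
    x = np.column_stack([c.to_numpy() for c in cols])
    return cox_ph(
        df[time_col].to_numpy(float), df[event_col].to_numpy(bool), x,
        names=list(covariates), **kwargs,
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum / Mann-Whitney U
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 12  # enumerate all C(n1+n2, n1) assignments up to this pooled size


def rank_sum(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Mann-Whitney U of `x` (midranks) with a two-sided p-value.

    Exact by enumeration of all label assignments when n1+n2 <= 12
    (two-sided rule: total probability of U at least as far from its mean
    as observed); otherwise a normal approximation with tie-corrected
    variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    if n1 + n2 <= _EXACT_MAX_N:
        n = n1 + n2
        dist = []
        for idx in itertools.combinations(range(n), n1):
            ri = ranks[list(idx)].sum()
            dist.append(ri - n1 * (n1 + 1) / 2.0)
        dist = np.asarray(dist)
        p = float((np.abs(dist - mu) >= abs(u - mu) - 1e-12).mean())
        return RankSumResult(w=float(u), p_two_sided=min(1.0, p), method="exact")

    # tie-corrected normal approximation with continuity correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    n = n1 + n2
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return RankSumResult(w=float(u), p_two_sided=1.0, method="normal")
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    p = float(min(1.0, 2 * stats.norm.sf(max(z, 0.0))))
    return RankSumResult(w=float(u), p_two_sided=p, method="normal")
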