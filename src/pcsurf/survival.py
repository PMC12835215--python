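"""Survival stratification: Kaplan-Meier, log-rank and univariate Cox.

Patients are split into high/low expression groups (median split by
default), survival is summarised with the product-limit estimator and
Greenwood variance, groups are compared with the log-rank test, and the
continuous association is quantified by a univariate Cox proportional-
hazards fit maximising the Breslow partial likelihood by Newton-Raphson.
At tied timestamps events precede censorings (the standard convention):
cells censored at t remain at risk for the events at t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm

__all__ = [
    "KMCurve",
    "CoxFit",
    "dichotomize",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "gene_survival_analysis",
]


@dataclass
class KMCurve:
    """Product-limit estimate over the distinct event times."""

    times: np.ndarray        # distinct event times, ascending
    at_risk: np.ndarray      # risk-set size just before each event time
    events: np.ndarray       # events at each time
    survival: np.ndarray     # S(t) just after each event time
    variance: np.ndarray     # Greenwood variance of S(t)

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFit:
    """Univariate Cox fit: log-hazard ratio with Wald inference."""

    beta: float
    hr: float
    se: float
    ci95: tuple[float, float]
    wald_p: float
    iterations: int


def _extract(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    if np.any(time <= 0):
        raise ValueError("times must be positive")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event must be 0/1")
    return time, event


def dichotomize(values, method: str = "median", q: float | None = None) -> np.ndarray:
    """High/low group labels: 'high' iff value > cut, 'low' otherwise.

    ``method``: 'median', 'mean' or 'quantile' (with ``q``).  All values
    identical -> no split exists -> error.
    """
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("degenerate split")
    if method == "median":
        cut = float(np.median(x))
    elif method == "mean":
        cut = float(np.mean(x))
    elif method == "quantile":
        if q is None or not 0.0 < q < 1.0:
            raise ValueError("quantile method needs 0 < q < 1")
        cut = float(np.quantile(x, q))
    else:
        raise ValueError(f"unknown method {method!r}")
    labels = np.where(x > cut, "high", "low")
    if len(np.unique(labels)) < 2:
        raise ValueError("degenerate split")
    return labels


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimator with Greenwood variance.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times t_i,
    with n_i the number at risk just before t_i (censorings at t_i still
    at risk).  With no events the curve is identically 1.
    """
    if len(records) == 0:
        raise ValueError("need at least one record")
    time, event = _extract(records)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    n = time.size

    event_times = np.unique(time[event == 1])
    at_risk = np.empty(event_times.size, dtype=int)
    d = np.empty(event_times.size, dtype=int)
    for i, t in enumerate(event_times):
        at_risk[i] = int(np.sum(time >= t))
        d[i] = int(np.sum((time == t) & (event == 1)))
    frac = 1.0 - d / at_risk
    surv = np.cumprod(frac)
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i<=t} d_i / (n_i (n_i - d_i)).
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf)
        var = surv**2 * np.cumsum(terms)
    var[surv == 0.0] = 0.0  # variance degenerates once the curve hits zero
    return KMCurve(times=event_times, at_risk=at_risk, events=d,
                   survival=surv, variance=var)


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test.

    chi2 = (sum_t (O_A - E_A))^2 / sum_t V_t with, at each distinct event
    time, E_A = d * n_A / n and the hypergeometric variance
    V = d (n_A/n) (1 - n_A/n) (n - d) / (n - 1).  Zero total variance ->
    chi2 = 0, p = 1.  p from chi-square with 1 df.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    ta, ea = _extract(group_a)
    tb, eb = _extract(group_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("need at least one event overall")

    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n_a = int(np.sum(ta >= t))
        n_b = int(np.sum(tb >= t))
        n = n_a + n_b
        d = int(np.sum((ta == t) & (ea == 1))) + int(np.sum((tb == t) & (eb == 1)))
        if n < 2 or d == 0:
            continue
        d_a = int(np.sum((ta == t) & (ea == 1)))
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        var += d * (n_a / n) * (1.0 - n_a / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(_chi2.sf(chi2, 1))


def _breslow_quantities(beta: float, time, event, x):
    """Log partial likelihood, score and information under Breslow ties."""
    order = np.argsort(-time, kind="stable")  # descending time
    t_s, e_s, x_s = time[order], event[order], x[order]
    eta = beta * x_s
    w = np.exp(eta)
    # Cumulative risk-set sums while walking down in time.
    a0 = np.cumsum(w)
    a1 = np.cumsum(w * x_s)
    a2 = np.cumsum(w * x_s**2)
    loglik = score = info = 0.0
    i = 0
    n = t_s.size
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        # risk set at this time = subjects with time >= t, i.e. first j entries
        ev = e_s[i:j] == 1
        d = int(ev.sum())
        if d > 0:
            s0, s1, s2 = a0[j - 1], a1[j - 1], a2[j - 1]
            sx = float(x_s[i:j][ev].sum())
            loglik += beta * sx - d * np.log(s0)
            mean = s1 / s0
            score += sx - d * mean
            info += d * (s2 / s0 - mean**2)
        i = j
    return loglik, score, info


def cox_univariate(
    records: pd.DataFrame, covariate=None, tol: float = 1e-8, max_iter: int = 50
) -> CoxFit:
    """Univariate Cox PH fit by Newton-Raphson on the Breslow likelihood.

    ``covariate`` defaults to a column named 'x' in ``records``.
    Convergence when |delta beta| < tol; divergence (monotone likelihood /
    complete separation) raises.  se = information^(-1/2); 95% CI on the
    hazard-ratio scale; two-sided Wald p.
    """
    time, event = _extract(records)
    if covariate is None:
        covariate = records["x"]
    x = np.asarray(covariate, dtype=float)
    if x.size != time.size:
        raise ValueError("covariate length mismatch")
    if int(event.sum()) < 2:
        raise ValueError("need >= 2 events")
    if np.unique(x).size < 2:
        raise ValueError("constant covariate")

    beta = 0.0
    for it in range(1, max_iter + 1):
        _, score, info = _breslow_quantities(beta, time, event, x)
        if info <= 1e-12 or not np.isfinite(score):
            raise ValueError("divergent hazard estimate")
        delta = score / info
        beta += delta
        if abs(beta) > 50:
            raise ValueError("divergent hazard estimate")
        if abs(delta) < tol:
            break
    else:
        raise ValueError("divergent hazard estimate")

    _, _, info = _breslow_quantities(beta, time, event, x)
    se = float(1.0 / np.sqrt(info))
    lo, hi = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
    wald_p = float(2.0 * _norm.sf(abs(beta) / se))
    return CoxFit(beta=float(beta), hr=float(np.exp(beta)), se=se,
                  ci95=(float(lo), float(hi)), wald_p=wald_p, iterations=it)


def gene_survival_analysis(
    cohort: pd.DataFrame, gene: str, split: str = "median", q: float | None = None
) -> dict:
    """Full per-gene workflow: split, KM per group, log-rank, Cox.

    Cox uses the continuous expression value; the split drives the KM
    curves and log-rank test.  Returns a result dict (cut method, group
    sizes, HR with CI, Wald and log-rank p, per-group KM curves).
    """
    if gene not in cohort.columns:
        raise KeyError(f"gene {gene!r} absent from cohort table")
    labels = dichotomize(cohort[gene].to_numpy(), method=split, q=q)
    high = cohort[labels == "high"]
    low = cohort[labels == "low"]
    chi2, p_lr = logrank_test(high, low)
    fit = cox_univariate(cohort, covariate=cohort[gene])
    return {
        "gene": gene,
        "split": split,
        "n_high": int(len(high)),
        "n_low": int(len(low)),
        "cox": fit,
        "logrank_chi2": chi2,
        "logrank_p": p_lr,
        "km_high": km_estimate(high),
        "km_low": km_estimate(low),
    }
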