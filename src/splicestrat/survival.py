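"""Survival analysis: Kaplan-Meier, log-rank, Cox proportional hazards.

All three estimators are implemented from the definitions rather than
wrapped from another package, since they sit at the core of the analysis:

* Kaplan-Meier product-limit estimator
  ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)`` with the standard convention
  that censorings tied with events remain in the risk set for those events.
* Log-rank test with the hypergeometric mean/variance at each distinct
  event time; the k-group statistic uses the full covariance matrix of the
  observed-minus-expected vector (first k-1 groups) and is chi-square with
  k-1 degrees of freedom.
* Cox proportional-hazards regression maximizing the partial likelihood by
  Newton-Raphson with the Efron tie correction (Breslow available by
  flag).  Wald confidence intervals are ``beta +/- 1.96 * SE``.

With a single binary covariate and no tied event times, the Cox score test
at ``beta = 0`` equals the two-group log-rank chi-square exactly; the test
suite uses this classical identity as a cross-module oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import ConvergenceError, DataError, DesignError, UsageError

__all__ = [
    "KMCurve",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "forest_table",
    "significance_stars",
    "make_design",
    "collapse_stage",
    "km_plot",
    "forest_plot",
]


# ---------------------------------------------------------------- Kaplan-Meier


@dataclass
class KMCurve:
    """Right-continuous product-limit survival curve."""

    times: np.ndarray  # distinct event times, sorted
    surv: np.ndarray  # S(t) at each event time
    at_risk: np.ndarray  # n_i just before each event time
    n_events: np.ndarray  # d_i at each event time
    censor_times: np.ndarray  # times of censored observations

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, S = 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.surv[idx])


def _check_time_event(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if time.size == 0:
        raise UsageError("at least one survival record is required")
    if time.shape != event.shape:
        raise UsageError("time and event must have equal length")
    if not np.all(np.isfinite(time)):
        raise DataError("non-finite survival time")
    if time.min() < 0:
        raise DataError("negative survival time")
    if not np.isin(event, (0, 1)).all():
        raise DataError("event indicator must be 0 (censored) or 1 (event)")
    return time, event


def km_estimate(time: Sequence[float], event: Sequence[int]) -> KMCurve:
    """Kaplan-Meier estimate for one group of right-censored records."""
    time, event = _check_time_event(time, event)
    n = time.size
    order = np.argsort(time, kind="stable")
    t_sorted, e_sorted = time[order], event[order]
    event_times = np.unique(t_sorted[e_sorted == 1])
    surv = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    d_at = np.empty(event_times.size, dtype=int)
    s = 1.0
    for i, t in enumerate(event_times):
        n_i = int(np.sum(t_sorted >= t))  # censored at t still at risk
        d_i = int(np.sum((t_sorted == t) & (e_sorted == 1)))
        s *= 1.0 - d_i / n_i
        surv[i], at_risk[i], d_at[i] = s, n_i, d_i
    return KMCurve(
        times=event_times,
        surv=surv,
        at_risk=at_risk,
        n_events=d_at,
        censor_times=np.sort(time[event == 0]),
    )


# -------------------------------------------------------------------- log-rank


def logrank_test(
    time: Sequence[float], event: Sequence[int], group: Sequence
) -> "LogrankResult":
    """k-group log-rank test of equality of survival distributions.

    At each distinct event time the observed events per group are compared
    with their conditional hypergeometric expectation given the risk sets;
    the chi-square statistic is ``v' V^- v`` over the first k-1 groups with
    k-1 degrees of freedom.  All-censored data yields chi-square 0 and
    p = 1 with a warning.
    """
    time, event = _check_time_event(time, event)
    group = np.asarray(group)
    if group.shape != time.shape:
        raise UsageError("group labels must match record count")
    levels = np.unique(group)
    k = levels.size
    if k < 2:
        raise UsageError(f"log-rank requires >= 2 groups, got {k}")
    gidx = np.searchsorted(levels, group)

    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    event_times = np.unique(time[event == 1])
    for t in event_times:
        at_risk = time >= t
        n = int(at_risk.sum())
        if n < 1:
            continue
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        dying = (time == t) & (event == 1)
        d = int(dying.sum())
        d_g = np.bincount(gidx[dying], minlength=k).astype(float)
        observed += d_g
        expected += d * n_g / n
        if n > 1:
            frac = n_g / n
            # hypergeometric covariance of the event-count vector at t
            c = d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
            cov += c
    v = (observed - expected)[:-1]
    V = cov[:-1, :-1]
    if event_times.size == 0 or not np.any(np.abs(V) > 0):
        warnings.warn(
            "no usable events for the log-rank test; returning p = 1",
            UserWarning,
            stacklevel=2,
        )
        chi2 = 0.0
    else:
        chi2 = float(v @ np.linalg.pinv(V) @ v)
    df = k - 1
    p = float(_sps.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return LogrankResult(
        statistic=chi2,
        p_value=p,
        df=df,
        observed=observed,
        expected=expected,
        groups=list(levels),
    )


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    df: int
    observed: np.ndarray
    expected: np.ndarray
    groups: list


# ------------------------------------------------------------------------- Cox


@dataclass
class CoxResult:
    """Fitted Cox model: per-covariate estimates plus fit diagnostics."""

    summary: pd.DataFrame  # covariate, coef, se, hr, ci_low, ci_high, p
    ties: str
    n: int
    n_events: int
    converged: bool
    n_iter: int
    log_likelihood: float
    score_norm: float  # max |score| at the solution

    @property
    def coefs(self) -> pd.Series:
        return self.summary.set_index("covariate")["coef"]


def _cox_derivatives(
    beta: np.ndarray,
    x_sorted: np.ndarray,
    block_starts: np.ndarray,
    block_event_rows: list[np.ndarray],
    ties: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Partial log-likelihood, score, and information at ``beta``.

    ``x_sorted`` is ordered by ascending time; ``block_starts[i]`` is the
    first row of the i-th distinct event-time block (the risk set is all
    rows from there on), and ``block_event_rows[i]`` are the rows failing
    at that time.
    """
    n, p = x_sorted.shape
    eta = x_sorted @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * x_sorted
    wxx = np.einsum("i,ij,ik->ijk", w, x_sorted, x_sorted)
    # suffix sums over the ascending-time order = risk-set sums
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    for start, rows in zip(block_starts, block_event_rows):
        d = rows.size
        r0, r1, r2 = s0[start], s1[start], s2[start]
        d0 = w[rows].sum()
        d1 = wx[rows].sum(axis=0)
        d2 = wxx[rows].sum(axis=0)
        ll += float(eta[rows].sum())
        score += x_sorted[rows].sum(axis=0)
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            phi0 = r0 - frac * d0
            phi1 = r1 - frac * d1
            phi2 = r2 - frac * d2
            ll -= math.log(phi0)
            score -= phi1 / phi0
            info += phi2 / phi0 - np.outer(phi1, phi1) / phi0**2
    return ll, score, info


def _prepare_design(covariates) -> tuple[np.ndarray, list[str]]:
    if isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite value in the covariate design matrix")
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise DesignError(f"covariate {name!r} is constant")
    return X, names


def cox_fit(
    time: Sequence[float],
    event: Sequence[int],
    covariates,
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-9,
    beta_bound: float = 20.0,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    ``covariates`` is a numeric design matrix (DataFrame columns become
    covariate names); categorical variables must already be one-hot
    encoded (see :func:`make_design`).  A coefficient escaping
    ``|beta| > beta_bound`` signals a monotone partial likelihood
    (complete separation) and raises :class:`ConvergenceError` naming the
    covariate.
    """
    time, event = _check_time_event(time, event)
    if ties not in ("efron", "breslow"):
        raise UsageError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    if event.sum() < 1:
        raise UsageError("Cox regression requires at least one event")
    X, names = _prepare_design(covariates)
    if X.shape[0] != time.size:
        raise UsageError("covariate rows must match record count")
    center = X.mean(axis=0)
    Xc = X - center  # centering leaves beta unchanged, improves conditioning

    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    x_sorted = Xc[order]
    event_times = np.unique(t_sorted[e_sorted == 1])
    block_starts = np.searchsorted(t_sorted, event_times, side="left")
    block_event_rows = [
        np.flatnonzero((t_sorted == t) & (e_sorted == 1)) for t in event_times
    ]

    p = X.shape[1]
    beta = np.zeros(p)
    ll, score, info = _cox_derivatives(beta, x_sorted, block_starts, block_event_rows, ties)
    converged = bool(np.max(np.abs(score)) < tol)
    it = 0
    while it < max_iter and not converged:
        it += 1
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # step-halving guards against overshooting; the slack is relative to
        # |ll| so float noise at the optimum does not trigger spurious halving
        slack = 1e-9 * (abs(ll) + 1.0)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, score_new, info_new = _cox_derivatives(
                cand, x_sorted, block_starts, block_event_rows, ties
            )
            if np.isfinite(ll_new) and ll_new >= ll - slack:
                break
            scale /= 2.0
        beta, ll, score, info = cand, ll_new, score_new, info_new
        if np.max(np.abs(beta)) > beta_bound:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise ConvergenceError(
                f"coefficient for {worst!r} diverged (|beta| > {beta_bound}); "
                "monotone partial likelihood / complete separation"
            )
        converged = bool(np.max(np.abs(score)) < tol)

    se = np.sqrt(np.diag(np.linalg.inv(info)))
    z = beta / se
    pvals = 2.0 * _sps.norm.sf(np.abs(z))
    summary = pd.DataFrame(
        {
            "covariate": names,
            "coef": beta,
            "se": se,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - 1.96 * se),
            "ci_high": np.exp(beta + 1.96 * se),
            "p": pvals,
        }
    )
    return CoxResult(
        summary=summary,
        ties=ties,
        n=int(time.size),
        n_events=int(event.sum()),
        converged=converged,
        n_iter=it,
        log_likelihood=ll,
        score_norm=float(np.max(np.abs(score))),
    )


def cox_score_test(
    time: Sequence[float], event: Sequence[int], covariates, ties: str = "efron"
) -> tuple[float, float]:
    """Cox score (Rao) test at ``beta = 0``: (chi-square, p).

    With one binary covariate and no tied event times this equals the
    two-group log-rank chi-square.
    """
    time, event = _check_time_event(time, event)
    X, _ = _prepare_design(covariates)
    Xc = X - X.mean(axis=0)
    order = np.argsort(time, kind="stable")
    t_sorted, e_sorted, x_sorted = time[order], event[order], Xc[order]
    event_times = np.unique(t_sorted[e_sorted == 1])
    block_starts = np.searchsorted(t_sorted, event_times, side="left")
    block_event_rows = [
        np.flatnonzero((t_sorted == t) & (e_sorted == 1)) for t in event_times
    ]
    _, score, info = _cox_derivatives(
        np.zeros(X.shape[1]), x_sorted, block_starts, block_event_rows, ties
    )
    chi2 = float(score @ np.linalg.solve(info, score))
    return chi2, float(_sps.chi2.sf(chi2, X.shape[1]))


# ------------------------------------------------------------- design helpers

_STAGE_PATTERN = ("IV", "III", "II", "I")


def collapse_stage(stage: pd.Series) -> pd.Series:
    """Collapse AJCC stage strings to ``early`` (I/II) vs ``advanced`` (III/IV).

    Unparseable or missing stages become NA.
    """
    def one(s: object) -> object:
        if s is None or (isinstance(s, float) and math.isnan(s)):
            return pd.NA
        text = str(s).upper().replace("STAGE", "").strip()
        for roman in _STAGE_PATTERN:
            if text.startswith(roman):
                return "advanced" if roman in ("III", "IV") else "early"
        return pd.NA

    return stage.map(one)


def make_design(
    df: pd.DataFrame,
    continuous: Sequence[str] = (),
    categorical: Mapping[str, str | None] | Sequence[str] = (),
) -> pd.DataFrame:
    """Build a numeric Cox design matrix from a clinical table.

    ``categorical`` maps column -> reference level (None = first
    alphabetical level).  Each non-reference level becomes an indicator
    column ``col[level]``.  Rows with any missing value among the used
    columns are dropped (complete-case) -- the caller sees the row count
    change.
    """
    if not isinstance(categorical, Mapping):
        categorical = {c: None for c in categorical}
    used = list(continuous) + list(categorical)
    sub = df[used].dropna()
    out = pd.DataFrame(index=sub.index)
    for col in continuous:
        out[col] = pd.to_numeric(sub[col])
    for col, ref in categorical.items():
        levels = sorted(sub[col].astype(str).unique())
        if ref is None:
            ref = levels[0]
        elif str(ref) not in levels:
            raise DesignError(f"reference level {ref!r} absent from column {col!r}")
        for level in levels:
            if str(level) == str(ref):
                continue
            out[f"{col}[{level}]"] = (sub[col].astype(str) == str(level)).astype(float)
    return out


# ------------------------------------------------------------- forest output


def significance_stars(p: float) -> str:
    """Four-tier star notation: p < 0.05 *, < 0.01 **, < 0.001 ***, < 0.0001 ****."""
    for threshold, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < threshold:
            return stars
    return ""


def forest_table(
    result: CoxResult,
    reference_rows: Sequence[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Tidy hazard-ratio table for forest display.

    One row per covariate level: HR, 95% CI, Wald p, and significance
    stars.  ``reference_rows`` lists (covariate, level) pairs shown with
    HR 1 and an empty CI.  Non-converged fits are refused.
    """
    if not result.converged:
        raise UsageError(
            "refusing to tabulate a non-converged Cox fit "
            f"(max |score| = {result.score_norm:.3g} after {result.n_iter} iterations)"
        )
    rows = []
    for cov, level in reference_rows:
        rows.append(
            {
                "covariate": f"{cov}[{level}]",
                "hr": 1.0,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p": np.nan,
                "stars": "",
                "reference": True,
            }
        )
    for rec in result.summary.itertuples(index=False):
        rows.append(
            {
                "covariate": rec.covariate,
                "hr": rec.hr,
                "ci_low": rec.ci_low,
                "ci_high": rec.ci_high,
                "p": rec.p,
                "stars": significance_stars(rec.p),
                "reference": False,
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- plotting


def km_plot(curves: Mapping[str, KMCurve], path, title: str = "") -> None:
    """Step-function Kaplan-Meier plot, one curve per labeled group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.surv])
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def forest_plot(table: pd.DataFrame, path, title: str = "") -> None:
    """Horizontal forest plot of hazard ratios with 95% CI bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.4 * len(table) + 1.5))
    y = np.arange(len(table))[::-1]
    ax.axvline(1.0, color="grey", lw=0.8)
    for yi, rec in zip(y, table.itertuples(index=False)):
        if not (isinstance(rec.ci_low, float) and math.isnan(rec.ci_low)):
            ax.plot([rec.ci_low, rec.ci_high], [yi, yi], color="black", lw=1)
        ax.plot(rec.hr, yi, "s", color="black", ms=5)
    ax.set_yticks(y)
    ax.set_yticklabels(table["covariate"])
    ax.set_xscale("log")
    ax.set_xlabel("hazard ratio (95% CI)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
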