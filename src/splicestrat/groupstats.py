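"""Group-comparison statistics implemented from first principles.

The comparisons the pipeline needs are authored here rather than delegated:

* Wilcoxon rank-sum (Mann-Whitney) for tumor vs normal expression, with an
  exact small-sample mode that enumerates the full null distribution of the
  rank sum, and a tie-corrected, continuity-corrected normal approximation
  otherwise.
* One-way ANOVA (normal vs AA-tumor vs EA-tumor; protein by isoform group).
* Tukey-Kramer honestly-significant-difference pairwise post-hoc tests.
* The 2^-ddCt relative-expression fold change for qRT-PCR.

SciPy contributes only distribution functions (normal, F, studentized
range) and midranks; the test statistics, exact enumeration, and tie
corrections are computed here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import DataError, UsageError
from .stratify import GroupLabel

__all__ = [
    "TestResult",
    "DdCtResult",
    "wilcoxon_rank_sum",
    "oneway_anova",
    "pairwise_posthoc",
    "ddct_fold_change",
    "protein_by_group",
    "adjust_bh",
]


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, two-sided p, group sizes, method."""

    name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    method: str  # exact | normal_approximation | F | tukey_hsd

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise DataError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class DdCtResult:
    delta_delta_ct: float
    fold_change: float


def _rank_sum_null_counts(n_total: int, n1: int) -> np.ndarray:
    """Number of n1-subsets of ranks {1..n_total} attaining each rank sum.

    Dynamic programming over the subset-sum polynomial; index s of the
    returned array is the count of subsets summing to s.
    """
    max_sum = n_total * (n_total + 1) // 2
    # counts[k, s] = number of k-subsets with sum s
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for rank in range(1, n_total + 1):
        for k in range(min(n1, rank), 0, -1):
            counts[k, rank:] += counts[k - 1, : max_sum + 1 - rank]
    return counts[n1]


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    exact_limit: int = 12,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test of ``x`` vs ``y``.

    The reported statistic is W, the sum of the midranks of ``x`` in the
    pooled sample.  ``mode="exact"`` enumerates the exact null distribution
    of W (requires no ties and combined n <= ``exact_limit``);
    ``mode="approx"`` uses the normal approximation with tie-corrected
    variance and a 0.5 continuity correction; ``mode="auto"`` picks exact
    when eligible.  Exact mode requested on tied data falls back to the
    approximation with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise UsageError("both groups must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("non-finite value in rank-sum input")
    if mode not in ("exact", "approx", "auto"):
        raise UsageError(f"unknown mode {mode!r}")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = _sps.rankdata(pooled)  # midranks
    w = float(ranks[:n1].sum())
    has_ties = np.unique(pooled).size < n

    use_exact = mode == "exact" or (mode == "auto" and n <= exact_limit and not has_ties)
    if use_exact and has_ties:
        warnings.warn(
            "exact Wilcoxon requested with tied data; falling back to the "
            "normal approximation",
            UserWarning,
            stacklevel=2,
        )
        use_exact = False
    if use_exact and n > exact_limit:
        raise UsageError(
            f"exact mode limited to combined n <= {exact_limit}, got {n}"
        )

    mu = n1 * (n + 1) / 2.0
    if use_exact:
        null = _rank_sum_null_counts(n, n1)
        total = null.sum()
        sums = np.arange(null.size)
        # two-sided: mass at least as far from the mean as observed
        p = float(null[np.abs(sums - mu) >= abs(w - mu) - 1e-9].sum() / total)
        return TestResult("wilcoxon_rank_sum", w, min(p, 1.0), (n1, n2), "exact")

    # tie-corrected variance of the rank sum
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(
            "wilcoxon_rank_sum", 0.0, 1.0, (n1, n2), "normal_approximation"
        )
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = float(2.0 * _sps.norm.sf(z))
    return TestResult(
        "wilcoxon_rank_sum", w, min(p, 1.0), (n1, n2), "normal_approximation"
    )


def oneway_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within.

    Degrees of freedom (k-1, N-k).  Zero within-group variance with equal
    means gives F = 0, p = 1; with unequal means the separation is perfect
    and p = 0 is returned explicitly.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise UsageError("ANOVA requires >= 2 groups")
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise UsageError(f"ANOVA group {i} has {g.size} values; >= 2 required")
        if not np.all(np.isfinite(g)):
            raise DataError(f"non-finite value in ANOVA group {i}")
    k = len(arrs)
    ns = np.array([g.size for g in arrs])
    big_n = int(ns.sum())
    grand = float(np.concatenate(arrs).mean())
    means = np.array([g.mean() for g in arrs])
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in arrs))
    df_b, df_w = k - 1, big_n - k
    if df_w < 1:
        raise UsageError("total error degrees of freedom must be >= 1")
    if ss_within == 0.0:
        if ss_between == 0.0:
            return TestResult("oneway_anova", 0.0, 1.0, tuple(ns), "F")
        return TestResult("oneway_anova", float("inf"), 0.0, tuple(ns), "F")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(_sps.f.sf(f, df_b, df_w))
    return TestResult("oneway_anova", f, p, tuple(ns), "F")


def pairwise_posthoc(
    groups: Sequence[Sequence[float]],
    method: str = "tukey",
    names: Sequence[str] | None = None,
) -> list[TestResult]:
    """All pairwise comparisons with Tukey-Kramer adjusted p-values.

    For groups i, j the studentized-range statistic is
    ``q = |m_i - m_j| / sqrt(MS_within/2 * (1/n_i + 1/n_j))`` and the
    adjusted p is the upper tail of the studentized range distribution with
    k groups and N-k error df.  For k = 2 this reduces exactly to the
    unadjusted pooled two-sample t-test.
    """
    if method != "tukey":
        raise UsageError(f"unsupported post-hoc method {method!r}")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    overall = oneway_anova(arrs)  # validates preconditions
    k = len(arrs)
    ns = overall.n_per_group
    df_w = int(sum(ns)) - k
    ms_within = float(sum(((g - g.mean()) ** 2).sum() for g in arrs)) / df_w
    if names is None:
        names = [f"group{i}" for i in range(k)]
    out: list[TestResult] = []
    for i, j in combinations(range(k), 2):
        diff = abs(float(arrs[i].mean() - arrs[j].mean()))
        se = math.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0.0:
            q, p = (0.0, 1.0) if diff == 0.0 else (float("inf"), 0.0)
        else:
            q = diff / se
            p = float(np.clip(_sps.studentized_range.sf(q, k, df_w), 0.0, 1.0))
        out.append(
            TestResult(f"{names[i]}-{names[j]}", q, p, (ns[i], ns[j]), "tukey_hsd")
        )
    return out


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> DdCtResult:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference)_case - (Ct_target - Ct_reference)_control;
    fold change = 2**(-ddCt).
    """
    vals = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if not all(math.isfinite(v) for v in vals):
        raise DataError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return DdCtResult(ddct, 2.0 ** (-ddct))


def protein_by_group(
    protein_table: pd.DataFrame,
    labels: Iterable[GroupLabel],
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Compare each protein between low and high isoform-expression groups.

    ``protein_table`` has sample barcodes as rows and proteins as columns
    (RPPA-style).  Missing values are dropped per protein; a protein with
    fewer than ``min_per_group`` populated values in either group is
    skipped with a warning.  Returns a tidy frame
    (protein, n_low, n_high, statistic, p_value).
    """
    lab = pd.Series({gl.barcode: gl.label for gl in labels})
    common = protein_table.index.intersection(lab.index)
    rows = []
    for protein in protein_table.columns:
        vals = protein_table.loc[common, protein]
        low = vals[(lab.loc[common] == "low") & vals.notna()].to_numpy(float)
        high = vals[(lab.loc[common] == "high") & vals.notna()].to_numpy(float)
        if low.size < min_per_group or high.size < min_per_group:
            warnings.warn(
                f"protein {protein!r} skipped: group sizes "
                f"(low={low.size}, high={high.size}) below {min_per_group}",
                UserWarning,
                stacklevel=2,
            )
            continue
        res = oneway_anova([low, high])
        rows.append(
            {
                "protein": protein,
                "n_low": low.size,
                "n_high": high.size,
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows, columns=["protein", "n_low", "n_high", "statistic", "p_value"])


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adj[idx] = running
    return adj
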