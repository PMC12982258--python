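"""Rank-based statistical battery, implemented from first principles.

The tests here are the inferential core of the cohort analysis: Mann-Whitney
U (exact by enumeration at small n, tie-corrected normal approximation with
continuity correction otherwise), Kruskal-Wallis with tie correction, Dunn's
pairwise post hoc z on pooled mean ranks, Quade's nonparametric ANCOVA
(one-way ANOVA on the residuals of response ranks regressed on covariate
ranks), two-tailed Spearman correlation with the t approximation, Pearson's
chi-squared for contingency tables, Welch's t, and Bonferroni /
Benjamini-Hochberg p-value adjustment.

scipy supplies only midranks (``rankdata``) and reference distributions
(normal, chi-squared, t, F); every statistic and every p-value rule is
computed here.

Conventions
-----------
* Reported Mann-Whitney U is ``min(U1, U2)``; ``U1 + U2 = n1 * n2`` always.
* All rank transforms use midranks for ties.
* Two-tailed p-values throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import f as f_dist
from scipy.stats import norm as norm_dist
from scipy.stats import rankdata
from scipy.stats import t as t_dist

__all__ = [
    "TestResult",
    "CorrelationResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "dunn_posthoc",
    "quade_ancova",
    "spearman",
    "chi_squared",
    "welch_t",
    "adjust_pvalues",
]


@dataclass
class TestResult:
    """A hypothesis-test outcome: statistic, p-values, bookkeeping."""

    method: str
    statistic: float
    p_raw: float
    group_sizes: list[int]
    p_adjusted: Optional[float] = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isnan(self.p_raw) and not (0.0 <= self.p_raw <= 1.0):
            raise ValueError(f"p_raw out of [0, 1]: {self.p_raw}")


@dataclass
class CorrelationResult:
    """A Spearman correlation outcome for one variable pair."""

    pair: tuple[str, str]
    rho: float
    p_raw: float
    n: int
    p_adjusted: Optional[float] = None
    notes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Mann-Whitney U


@lru_cache(maxsize=256)
def _mw_exact_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Null distribution of U1: counts[u] = #rank arrangements with U1 = u.

    Classic recurrence N(u; n1, n2) = N(u - n2; n1 - 1, n2) + N(u; n1, n2 - 1)
    with N(0; i, 0) = N(0; 0, j) = 1.
    """
    # table[(i, j)] is the count vector over u = 0..i*j
    prev: dict[int, list[int]] = {j: [1] for j in range(n2 + 1)}  # i = 0
    for i in range(1, n1 + 1):
        cur: dict[int, list[int]] = {0: [1]}
        for j in range(1, n2 + 1):
            out = [0] * (i * j + 1)
            smaller = prev[j]  # (i-1, j)
            left = cur[j - 1]  # (i, j-1)
            for u in range(i * j + 1):
                c = 0
                if 0 <= u - j < len(smaller):
                    c += smaller[u - j]
                if u < len(left):
                    c += left[u]
                out[u] = c
            cur[j] = out
        prev = cur
    return tuple(prev[n2])


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
) -> TestResult:
    """Two-sample Mann-Whitney U test, two-tailed.

    ``mode``: "exact" (enumeration; tie-free data only), "normal_approx"
    (tie-corrected, with continuity correction), or "auto" (exact when
    n1*n2 <= 400 and there are no ties, else the approximation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u_min = min(u1, u2)
    ties = _has_ties(pooled)

    if mode not in ("exact", "normal_approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and n1 * n2 <= 400 and not ties)
    notes: dict = {"U1": u1, "U2": u2, "ties": ties}

    if use_exact:
        if ties:
            raise ValueError("exact Mann-Whitney p is defined here for tie-free data")
        counts = _mw_exact_counts(n1, n2)
        total = sum(counts)
        # distribution is symmetric about n1*n2/2
        cdf_lo = sum(counts[: int(u_min) + 1]) / total
        p = min(1.0, 2.0 * cdf_lo)
        notes["method_detail"] = "exact enumeration"
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            # all pooled values identical
            p = 1.0
            notes["method_detail"] = "degenerate (zero variance)"
        else:
            mu = n1 * n2 / 2.0
            z = (u_min - mu + 0.5) / np.sqrt(var)  # continuity correction
            p = min(1.0, 2.0 * float(norm_dist.cdf(z)))
            notes["method_detail"] = "normal approximation, tie-corrected, cc"
            notes["z"] = z
    return TestResult(
        method="mann_whitney_u",
        statistic=float(u_min),
        p_raw=float(p),
        group_sizes=[n1, n2],
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn


def _pooled_ranks(groups: Sequence[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray]]:
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    out, start = [], 0
    for g in groups:
        out.append(ranks[start : start + g.size])
        start += g.size
    return pooled, out


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-squared (k-1) reference."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group must be non-empty")
    n = sum(a.size for a in arrs)
    if n < 3:
        raise ValueError("need total N >= 3")
    pooled, rank_groups = _pooled_ranks(arrs)
    h = 12.0 / (n * (n + 1)) * sum(rg.sum() ** 2 / rg.size for rg in rank_groups) - 3 * (
        n + 1
    )
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    notes: dict = {"tie_correction": correction}
    if correction <= 0:
        # all values identical: no information, H defined as 0
        h, p = 0.0, 1.0
    else:
        h = h / correction
        h = max(h, 0.0)
        p = float(chi2_dist.sf(h, len(arrs) - 1))
    return TestResult(
        method="kruskal_wallis",
        statistic=float(h),
        p_raw=p,
        group_sizes=[a.size for a in arrs],
        notes=notes,
    )


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    fwe: str = "bonferroni",
    labels: Optional[Sequence[str]] = None,
) -> list[TestResult]:
    """Dunn's pairwise z tests on pooled mean ranks after Kruskal-Wallis.

    For each pair (i, j): z = (Rbar_i - Rbar_j) / sqrt(S2 * (1/n_i + 1/n_j))
    with S2 = N(N+1)/12 - tie_term / (12 (N-1)); two-tailed normal p; the
    family-wise correction (Bonferroni across the pairs tested) is stored in
    ``p_adjusted``.  Each result also carries the mean-rank difference.
    """
    if fwe not in ("bonferroni", "none"):
        raise ValueError(f"unknown fwe {fwe!r}")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    pooled, rank_groups = _pooled_ranks(arrs)
    n = pooled.size
    s2 = n * (n + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n - 1))
    means = [rg.mean() for rg in rank_groups]
    results: list[TestResult] = []
    pairs = list(itertools.combinations(range(len(arrs)), 2))
    for i, j in pairs:
        diff = means[i] - means[j]
        se = np.sqrt(s2 * (1.0 / arrs[i].size + 1.0 / arrs[j].size))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = diff / se
            p = min(1.0, 2.0 * float(norm_dist.sf(abs(z))))
        results.append(
            TestResult(
                method="dunn",
                statistic=float(z),
                p_raw=p,
                group_sizes=[arrs[i].size, arrs[j].size],
                notes={
                    "pair": (labels[i], labels[j]),
                    "mean_rank_diff": float(diff),
                },
            )
        )
    if fwe == "bonferroni":
        adj = adjust_pvalues([r.p_raw for r in results], "bonferroni")
        for r, a in zip(results, adj):
            r.p_adjusted = a
    return results


# ---------------------------------------------------------------------------
# Quade's nonparametric ANCOVA


def quade_ancova(
    response: Sequence[float],
    groups: Sequence,
    covariates: Optional[Sequence[Sequence[float]]] = None,
) -> TestResult:
    """Quade's rank ANCOVA: group F test on rank-regression residuals.

    The response and each covariate are midranked across all N observations;
    response ranks are regressed (least squares, with intercept) on the
    covariate ranks; the residuals enter a one-way ANOVA across groups with
    df (k-1, N-k).  With no covariates this is exactly one-way ANOVA on
    ranks.  Constant covariates carry no rank information and are dropped
    with a note; collinear covariate ranks are a hard error.
    """
    y = np.asarray(response, dtype=float)
    g = np.asarray(groups)
    if y.size != g.size:
        raise ValueError("response and groups must have equal length")
    n = y.size
    levels, g_idx = np.unique(g, return_inverse=True)
    k = levels.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    cov_list = [np.asarray(c, dtype=float) for c in (covariates or [])]
    for c in cov_list:
        if c.size != n:
            raise ValueError("covariate length mismatch")
    if n < k + len(cov_list) + 2:
        raise ValueError("too few observations for the requested model")

    y_rank = rankdata(y)
    notes: dict = {"n_covariates": len(cov_list)}
    kept = []
    dropped = 0
    for c in cov_list:
        if np.unique(c).size < 2:
            dropped += 1
            continue
        kept.append(rankdata(c))
    if dropped:
        notes["constant_covariates_dropped"] = dropped
    if kept:
        x = np.column_stack([np.ones(n)] + kept)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("covariate rank matrix is singular")
        beta, *_ = np.linalg.lstsq(x, y_rank, rcond=None)
        resid = y_rank - x @ beta
    else:
        resid = y_rank - y_rank.mean()

    grand = resid.mean()
    ssb = 0.0
    ssw = 0.0
    sizes = []
    for lev in range(k):
        e = resid[g_idx == lev]
        sizes.append(e.size)
        ssb += e.size * (e.mean() - grand) ** 2
        ssw += float(((e - e.mean()) ** 2).sum())
    df1, df2 = k - 1, n - k
    # saturated regression (covariate carries the response ranks exactly):
    # residual variation is numerical noise, the group effect is nil
    sst_ranks = float(((y_rank - y_rank.mean()) ** 2).sum())
    if ssb + ssw <= 1e-12 * max(sst_ranks, 1.0):
        ssb, ssw = 0.0, 0.0
    if ssw <= 0:
        if ssb <= 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ssb / df1) / (ssw / df2)
        p = float(f_dist.sf(f_stat, df1, df2))
    notes["df"] = (df1, df2)
    return TestResult(
        method="quade_ancova",
        statistic=float(f_stat),
        p_raw=p,
        group_sizes=sizes,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Spearman correlation


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    pair: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Two-tailed Spearman rank correlation with the t approximation.

    rho is the Pearson correlation of midranks; p comes from
    t = rho sqrt((n-2)/(1-rho^2)) on n-2 df.  |rho| = 1 gives p = 0;
    constant input gives an undefined rho, flagged in notes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must be paired")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return CorrelationResult(
            pair=pair,
            rho=float("nan"),
            p_raw=float("nan"),
            n=n,
            notes={"undefined": "constant input"},
        )
    rx, ry = rankdata(x), rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t_stat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = min(1.0, 2.0 * float(t_dist.sf(abs(t_stat), n - 2)))
    return CorrelationResult(pair=pair, rho=rho, p_raw=p, n=n)


# ---------------------------------------------------------------------------
# Chi-squared, Welch


def chi_squared(table: Sequence[Sequence[float]], yates: bool = False) -> TestResult:
    """Pearson chi-squared test of independence on an r x c count table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("table must hold nonnegative integer counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal: expected counts undefined")
    total = obs.sum()
    expected = np.outer(row, col) / total
    dev = np.abs(obs - expected)
    if yates:
        if obs.shape != (2, 2):
            raise ValueError("Yates correction applies to 2x2 tables only")
        dev = np.maximum(dev - 0.5, 0.0)
    x2 = float((dev**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return TestResult(
        method="chi_squared",
        statistic=x2,
        p_raw=float(chi2_dist.sf(x2, df)),
        group_sizes=[int(r) for r in row],
        notes={"df": df, "yates": yates},
    )


def welch_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Welch's unequal-variance t test with Satterthwaite df, two-tailed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per group")
    n1, n2 = x.size, y.size
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        # both samples constant
        if x.mean() == y.mean():
            t_stat, p, df = 0.0, 1.0, float(n1 + n2 - 2)
        else:
            t_stat, p, df = float("inf"), 0.0, float(n1 + n2 - 2)
    else:
        t_stat = (x.mean() - y.mean()) / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
        p = min(1.0, 2.0 * float(t_dist.sf(abs(t_stat), df)))
    return TestResult(
        method="welch_t",
        statistic=float(t_stat),
        p_raw=float(p),
        group_sizes=[n1, n2],
        notes={"df": float(df)},
    )


# ---------------------------------------------------------------------------
# Multiplicity adjustment


def adjust_pvalues(p: Sequence[float], method: str = "bh_fdr") -> list[float]:
    """Adjust a family of p-values (Bonferroni or Benjamini-Hochberg step-up)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    if method == "bonferroni":
        return list(np.minimum(1.0, m * arr))
    if method == "bh_fdr":
        order = np.argsort(arr, kind="stable")
        ranked = arr[order]
        scaled = ranked * m / np.arange(1, m + 1)
        # step-up: enforce monotone non-decreasing adjusted values
        adj = np.minimum.accumulate(scaled[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        out = np.empty(m)
        out[order] = adj
        return list(out)
    raise ValueError(f"unknown method {method!r}")
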