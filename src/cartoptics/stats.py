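"""Group comparisons of fitted scattering parameters.

Four stratified comparisons are run over the per-sample power-law
parameters (alpha, b, c):

1. between cartilage zones, pooled over anatomical locations;
2. between zones within each location;
3. between locations, pooled over zones;
4. between locations within each zone.

Each comparison first selects a branch: parametric if every group passes
a Kolmogorov–Smirnov normality check (against a normal with estimated
moments) and Levene's test finds homogeneous variances; otherwise
nonparametric.  The parametric branch runs one-way ANOVA with Tukey HSD
post-hoc pairs; the nonparametric branch runs Kruskal–Wallis with Dunn's
post-hoc pairs (Bonferroni-adjusted by default).  Pairwise adjusted
p-values are assembled into a symmetric matrix with a unit diagonal.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupTestResult",
    "select_branch",
    "dunn_posthoc",
    "run_group_test",
    "run_all_tests",
]

Branch = Literal["parametric", "nonparametric"]


@dataclass
class GroupTestResult:
    """Omnibus and pairwise results of one stratified comparison."""

    test_id: int
    parameter: str
    branch: Branch
    omnibus_p: float
    posthoc: pd.DataFrame  # symmetric matrix of adjusted p-values, unit diagonal
    group_labels: list[str]
    stratum: str | None = None
    skipped: bool = False
    reason: str | None = None

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        pairs = []
        for a, b in itertools.combinations(self.group_labels, 2):
            if self.posthoc.loc[a, b] < alpha:
                pairs.append((a, b))
        return pairs


def select_branch(
    groups: Sequence[np.ndarray],
    alpha_level: float = 0.05,
) -> tuple[Branch, dict]:
    """Choose parametric vs nonparametric testing for a set of groups.

    Parametric requires every group to pass KS normality (normal with the
    group's estimated mean and sd) and Levene's test to accept equal
    variances, all at ``alpha_level``.  Groups with fewer than 3 values
    are excluded with a warning; degenerate (zero-variance) groups force
    the nonparametric branch.  Returns the branch and a diagnostics dict
    with the individual p-values.
    """
    usable = []
    for i, grp in enumerate(groups):
        arr = np.asarray(grp, dtype=float)
        if arr.size < 3:
            warnings.warn(f"group {i} has n={arr.size} < 3; excluded", stacklevel=2)
            continue
        usable.append(arr)
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with n >= 3")

    diag: dict = {"normality_p": [], "levene_p": None}
    degenerate = False
    normal_ok = True
    for arr in usable:
        sd = arr.std(ddof=1)
        if sd == 0:
            degenerate = True
            diag["normality_p"].append(np.nan)
            continue
        p = sps.kstest(arr, "norm", args=(arr.mean(), sd)).pvalue
        diag["normality_p"].append(float(p))
        if p < alpha_level:
            normal_ok = False
    if degenerate:
        warnings.warn("zero-variance group; falling back to nonparametric", stacklevel=2)
        return "nonparametric", diag
    lev_p = float(sps.levene(*usable).pvalue)
    diag["levene_p"] = lev_p
    branch: Branch = (
        "parametric" if (normal_ok and lev_p >= alpha_level) else "nonparametric"
    )
    return branch, diag


def dunn_posthoc(
    groups: Sequence[np.ndarray],
    labels: Sequence[str],
    adjust: Literal["bonferroni", "holm"] = "bonferroni",
) -> pd.DataFrame:
    """Dunn's rank-sum pairwise comparisons after Kruskal–Wallis.

    Pooled-rank z statistics with tie correction:

        z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))

    where T = sum(t^3 - t) / (12 (N - 1)) over tie groups.  Two-sided
    p-values are multiplicity-adjusted; adjusted values are never smaller
    than the unadjusted ones.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrs)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for arr in arrs:
        mean_ranks.append(ranks[start : start + arr.size].mean())
        start += arr.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    k = len(arrs)
    raw = {}
    for i, j in itertools.combinations(range(k), 2):
        denom = np.sqrt(var_base * (1.0 / arrs[i].size + 1.0 / arrs[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / denom if denom > 0 else 0.0
        raw[(i, j)] = 2.0 * sps.norm.sf(abs(z))

    m = len(raw)
    mat = pd.DataFrame(np.eye(k), index=labels, columns=labels)
    np.fill_diagonal(mat.values, 1.0)
    if adjust == "bonferroni":
        adj = {pair: min(1.0, p * m) for pair, p in raw.items()}
    elif adjust == "holm":
        order = sorted(raw, key=raw.get)
        adj = {}
        running = 0.0
        for rank, pair in enumerate(order):
            val = min(1.0, raw[pair] * (m - rank))
            running = max(running, val)
            adj[pair] = running
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    for (i, j), p in adj.items():
        mat.iloc[i, j] = p
        mat.iloc[j, i] = p
    return mat


def run_group_test(
    groups: Sequence[np.ndarray],
    labels: Sequence[str],
    branch: Branch,
    test_id: int = 0,
    parameter: str = "",
    stratum: str | None = None,
    dunn_adjust: Literal["bonferroni", "holm"] = "bonferroni",
) -> GroupTestResult:
    """Omnibus + post-hoc comparison on the selected branch.

    Parametric: one-way ANOVA with Tukey HSD pairs.  Nonparametric:
    Kruskal–Wallis with Dunn pairs.  Identical-in-all-groups data yields
    an omnibus p of 1 and no significant pairs.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    labels = list(labels)
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    k = len(arrs)
    mat = pd.DataFrame(np.eye(k), index=labels, columns=labels)
    np.fill_diagonal(mat.values, 1.0)

    all_equal = all(np.array_equal(a, arrs[0]) for a in arrs[1:]) and all(
        np.all(a == a[0]) for a in arrs
    )
    if all_equal:
        mat.values[:] = 1.0
        return GroupTestResult(
            test_id=test_id,
            parameter=parameter,
            branch=branch,
            omnibus_p=1.0,
            posthoc=mat,
            group_labels=labels,
            stratum=stratum,
        )

    if branch == "parametric":
        omnibus_p = float(sps.f_oneway(*arrs).pvalue)
        tk = sps.tukey_hsd(*arrs)
        for i, j in itertools.combinations(range(k), 2):
            p = float(tk.pvalue[i, j])
            mat.iloc[i, j] = p
            mat.iloc[j, i] = p
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            omnibus_p = float(sps.kruskal(*arrs).pvalue)
        mat = dunn_posthoc(arrs, labels, adjust=dunn_adjust)
    if np.isnan(omnibus_p):
        omnibus_p = 1.0
    return GroupTestResult(
        test_id=test_id,
        parameter=parameter,
        branch=branch,
        omnibus_p=omnibus_p,
        posthoc=mat,
        group_labels=labels,
        stratum=stratum,
    )


def _grouped_test(
    df: pd.DataFrame,
    parameter: str,
    group_col: str,
    test_id: int,
    stratum: str | None,
    alpha_level: float,
    min_n: int,
) -> GroupTestResult | None:
    groups = []
    labels = []
    for label, sub in df.groupby(group_col, sort=True):
        vals = sub[parameter].dropna().to_numpy()
        if vals.size >= min_n:
            groups.append(vals)
            labels.append(str(label))
    if len(groups) < 2:
        return GroupTestResult(
            test_id=test_id,
            parameter=parameter,
            branch="nonparametric",
            omnibus_p=np.nan,
            posthoc=pd.DataFrame(),
            group_labels=labels,
            stratum=stratum,
            skipped=True,
            reason=f"fewer than 2 groups with n >= {min_n}",
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        branch, _ = select_branch(groups, alpha_level=alpha_level)
    return run_group_test(
        groups, labels, branch, test_id=test_id, parameter=parameter, stratum=stratum
    )


def run_all_tests(
    fit_table: pd.DataFrame,
    parameters: Sequence[str] = ("alpha", "b", "c"),
    alpha_level: float = 0.05,
    min_n: int = 3,
) -> list[GroupTestResult]:
    """The four stratified comparisons for each parameter.

    ``fit_table`` needs columns ``zone``, ``location`` and one column per
    entry of ``parameters``.  Strata with fewer than two usable groups
    are emitted as skipped results with a reason, not dropped silently.
    """
    required = {"zone", "location", *parameters}
    missing = required - set(fit_table.columns)
    if missing:
        raise ValueError(f"fit_table missing columns: {sorted(missing)}")
    results: list[GroupTestResult] = []
    for param in parameters:
        # Test 1: zones pooled over locations
        results.append(
            _grouped_test(fit_table, param, "zone", 1, None, alpha_level, min_n)
        )
        # Test 2: zones within each location
        for loc, sub in fit_table.groupby("location", sort=True):
            results.append(
                _grouped_test(sub, param, "zone", 2, str(loc), alpha_level, min_n)
            )
        # Test 3: locations pooled over zones
        results.append(
            _grouped_test(fit_table, param, "location", 3, None, alpha_level, min_n)
        )
        # Test 4: locations per zone
        for zone, sub in fit_table.groupby("zone", sort=True):
            results.append(
                _grouped_test(sub, param, "location", 4, str(zone), alpha_level, min_n)
            )
    return [r for r in results if r is not None]
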