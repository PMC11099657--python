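"""Meiotic-progression timing variables and group-comparison statistics.

Variables (hours from imaging start t0 = 0):

* ``tGVBD`` — germinal vesicle breakdown (meiotic resumption);
* ``tPB1`` — completed extrusion of the first polar body;
* ``dMI``  — duration of meiosis I, exactly ``tPB1 - tGVBD``.

Oocytes lacking tPB1 are GV or GVBD-only; they are excluded from
tPB1/dMI summaries but retained for maturation-rate reporting.

Group comparisons follow a fixed gate: Shapiro-Wilk normality per group
at alpha 0.05; all groups normal with more than two groups -> one-way
ANOVA with Tukey's HSD; exactly two normal groups -> Student's t-test;
any non-normal group -> Kruskal-Wallis with Dunn's rank-based pairwise
comparisons (Bonferroni-adjusted).  Outliers are screened with an
iterated two-sided Grubbs test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparisonResult",
    "derive_variables",
    "grubbs_critical_value",
    "grubbs_exclude",
    "dunn_test",
    "compare_groups",
    "maturation_rates",
]

NORMALITY_ALPHA = 0.05


def derive_variables(df: pd.DataFrame) -> pd.DataFrame:
    """Finalize dMI and maturation status on an event-time table.

    Expects columns ``sample_id``, ``tGVBD_h``, ``tPB1_h`` (missing
    events as NaN/None) and optionally ``t0`` (default 0) and
    ``exclusion_flag``.  Returns a copy with ``dMI_h`` computed exactly
    as tPB1 - tGVBD, ``status`` set to GV / GVBD-only / MII, and records
    with tPB1 <= tGVBD flagged ``invalid-annotation`` (their dMI is
    withheld).
    """
    out = df.copy()
    if "t0" not in out:
        out["t0"] = 0.0
    if "exclusion_flag" not in out:
        out["exclusion_flag"] = None
    tgvbd = pd.to_numeric(out["tGVBD_h"], errors="coerce")
    tpb1 = pd.to_numeric(out["tPB1_h"], errors="coerce")

    status = np.where(
        tpb1.notna(), "MII", np.where(tgvbd.notna(), "GVBD-only", "GV")
    )
    dmi = tpb1 - tgvbd
    invalid = tpb1.notna() & tgvbd.notna() & (tpb1 <= tgvbd)
    dmi[invalid] = np.nan
    out["status"] = status
    out["dMI_h"] = dmi
    out.loc[invalid, "exclusion_flag"] = "invalid-annotation"
    return out


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value for sample size ``n``.

    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) quantile of Student's t with n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_exclude(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[list[float], list[float]]:
    """Iterated two-sided Grubbs outlier screen.

    Repeatedly removes the single most extreme point while its
    G = max|x - mean| / SD exceeds the critical value at ``alpha``.
    Groups smaller than three (or with zero spread) are returned
    unchanged — the test is undefined there.
    """
    retained = [float(v) for v in values]
    excluded: list[float] = []
    while len(retained) >= 3:
        arr = np.asarray(retained)
        sd = arr.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(arr - arr.mean())
        idx = int(np.argmax(dev))
        g = dev[idx] / sd
        if g > grubbs_critical_value(len(retained), alpha):
            excluded.append(retained.pop(idx))
        else:
            break
    return retained, excluded


def dunn_test(
    groups: Mapping[str, Sequence[float]], adjust: str = "bonferroni"
) -> dict[tuple[str, str], float]:
    """Dunn's rank-based pairwise comparisons after Kruskal-Wallis.

    Pools all observations, ranks with midranks, and compares mean
    ranks with the tie-corrected normal approximation; two-sided
    p-values are Bonferroni-adjusted over the number of pairs.
    """
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(data)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction sum(t^3 - t) over tied groups
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    offsets = np.cumsum([0] + [len(d) for d in data])
    mean_ranks = {
        g: ranks[offsets[i]: offsets[i + 1]].mean() for i, g in enumerate(names)
    }
    sizes = {g: len(groups[g]) for g in names}
    m = len(names) * (len(names) - 1) // 2
    out: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(names, 2):
        se = math.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1)))
            * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * m)
        out[(a, b)] = float(p)
    return out


@dataclass
class GroupComparisonResult:
    """Outcome of one variable's between-group comparison."""

    variable: str
    groups: dict[str, dict[str, float]]  # name -> {n, mean, sem}
    normality: dict[str, float | None]  # name -> Shapiro-Wilk p (None if n<3)
    test_used: str
    p_value: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    dropped_groups: tuple[str, ...] = ()


def _summaries(groups: Mapping[str, np.ndarray]) -> dict[str, dict[str, float]]:
    out = {}
    for name, vals in groups.items():
        n = len(vals)
        sd = float(np.std(vals, ddof=1)) if n > 1 else float("nan")
        out[name] = {
            "n": n,
            "mean": float(np.mean(vals)),
            "sem": sd / math.sqrt(n) if n > 1 else float("nan"),
        }
    return out


def compare_groups(
    df: pd.DataFrame,
    variable: str,
    grouping: str = "group",
    alpha: float = NORMALITY_ALPHA,
) -> GroupComparisonResult:
    """Compare a timing variable across groups with the fixed test gate.

    ``df`` must carry the grouping column and the variable column;
    records with a missing value are dropped, as are groups left with
    fewer than two observations (with a note in the result).  Groups too
    small for the Shapiro-Wilk test (n < 3) are treated as normal, so
    the parametric branch is not blocked by tiny groups.
    """
    clean = df[[grouping, variable]].dropna()
    groups: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for name, sub in clean.groupby(grouping, sort=False):
        vals = sub[variable].to_numpy(dtype=float)
        if len(vals) < 2:
            dropped.append(str(name))
        else:
            groups[str(name)] = vals
    if len(groups) < 2:
        raise ValueError("need at least two groups with >= 2 observations")

    normality: dict[str, float | None] = {}
    all_normal = True
    for name, vals in groups.items():
        if len(vals) < 3 or np.ptp(vals) == 0:
            normality[name] = None
            continue
        p = float(stats.shapiro(vals).pvalue)
        normality[name] = p
        if p < alpha:
            all_normal = False

    names = list(groups)
    data = [groups[g] for g in names]
    pairwise: dict[tuple[str, str], float] = {}
    if all_normal and len(groups) == 2:
        test_used = "t-test"
        res = stats.ttest_ind(data[0], data[1])
        p_value = float(res.pvalue)
        pairwise[(names[0], names[1])] = p_value
    elif all_normal:
        test_used = "one-way ANOVA + Tukey"
        p_value = float(stats.f_oneway(*data).pvalue)
        tk = stats.tukey_hsd(*data)
        for i, j in itertools.combinations(range(len(names)), 2):
            pairwise[(names[i], names[j])] = float(tk.pvalue[i, j])
    else:
        test_used = "Kruskal-Wallis + Dunn"
        p_value = float(stats.kruskal(*data).pvalue)
        pairwise = dunn_test(groups)

    return GroupComparisonResult(
        variable=variable,
        groups=_summaries(groups),
        normality=normality,
        test_used=test_used,
        p_value=p_value,
        pairwise=pairwise,
        dropped_groups=tuple(dropped),
    )


STAGES = ("GV", "GVBD-only", "MII")


def maturation_rates(
    df: pd.DataFrame, grouping: str = "group"
) -> dict[str, object]:
    """Per-group proportions at each meiotic stage, with a categorical test.

    Builds the group x stage contingency table from the ``status``
    column; empty groups are excluded with a note.  A 2x2 table with any
    expected cell below five is tested with Fisher's exact test,
    anything else with the chi-square test (flagged when expected cells
    are small).
    """
    counts = (
        df.groupby([grouping, "status"], observed=False)
        .size()
        .unstack(fill_value=0)
    )
    for stage in STAGES:
        if stage not in counts.columns:
            counts[stage] = 0
    counts = counts[list(STAGES)]
    empty = [str(g) for g in counts.index[counts.sum(axis=1) == 0]]
    counts = counts[counts.sum(axis=1) > 0]
    proportions = counts.div(counts.sum(axis=1), axis=0)

    # drop all-zero stage columns before testing: chi-square is undefined there
    table = counts.loc[:, counts.sum(axis=0) > 0].to_numpy()
    note = None
    if table.shape[0] < 2 or table.shape[1] < 2:
        test_used, p_value = "none", float("nan")
        note = "degenerate table (fewer than 2 groups or 2 observed stages)"
    else:
        expected = stats.contingency.expected_freq(table)
        small = bool((expected < 5).any())
        if table.shape == (2, 2) and small:
            test_used = "fisher"
            p_value = float(stats.fisher_exact(table).pvalue)
        else:
            test_used = "chi-square"
            p_value = float(stats.chi2_contingency(table).pvalue)
            if small:
                note = "chi-square with expected cells < 5"
    return {
        "counts": counts,
        "proportions": proportions,
        "test_used": test_used,
        "p_value": p_value,
        "excluded_groups": empty,
        "note": note,
    }
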