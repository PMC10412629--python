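"""Enrichment and group-comparison statistics.

TF-binding-site enrichment over lineage-specific H3K9me3 region sets
(two-sided Fisher's exact test on fertilized-specific vs SCNT-specific
overlap counts, BH-adjusted across factors), Kruskal-Wallis with Dunn's
post hoc comparisons, Wilcoxon rank-sum and Student's t group tests, and
replicate Pearson-correlation QC of window signals.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust
from .intervals import IntervalSet, overlap_marked, WindowSignalTable

__all__ = [
    "bh_adjust",
    "fisher_exact_2x2",
    "tf_enrichment",
    "group_tests",
    "kruskal_dunn",
    "replicate_qc",
]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on [[a, b], [c, d]].

    The two-sided p sums hypergeometric probabilities no larger than the
    observed table's (probability-mass rule).  An all-zero margin gives
    p = 1 and an undefined (NaN) odds ratio.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    table = np.array([[a, b], [c, d]], dtype=int)
    res = stats.fisher_exact(table, alternative="two-sided")
    odds = res.statistic
    if b * c == 0 and a * d == 0:
        odds = float("nan")
    elif b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    return float(odds), float(res.pvalue)


def tf_enrichment(
    tf_sites: Mapping[str, IntervalSet],
    fert_specific: IntervalSet,
    scnt_specific: IntervalSet,
) -> pd.DataFrame:
    """Per-factor enrichment of binding sites in fertilized- vs
    SCNT-specific H3K9me3 regions.

    For each factor, k = number of regions of each specific set overlapped
    (reciprocal-50%) by the factor's sites and N = total regions in the
    set; the test is Fisher's exact on [[k_fert, N_fert-k_fert],
    [k_scnt, N_scnt-k_scnt]].  The reported fold change is
    log2(((k_fert+1)/N_fert) / ((k_scnt+1)/N_scnt)) — the +1 smoothing
    enters only the fold change, never the test.  q-values are BH across
    factors.
    """
    if not len(fert_specific) or not len(scnt_specific):
        raise ValueError("region sets must be non-empty")
    n_f, n_s = len(fert_specific), len(scnt_specific)
    rows = []
    for factor, sites in tf_sites.items():
        if len(sites):
            k_f = sum(overlap_marked(r, sites) for r in fert_specific)
            k_s = sum(overlap_marked(r, sites) for r in scnt_specific)
        else:
            k_f = k_s = 0
        if k_f == 0 and k_s == 0:
            fc, p = 0.0, 1.0
        else:
            fc = float(np.log2(((k_f + 1) / n_f) / ((k_s + 1) / n_s)))
            _odds, p = fisher_exact_2x2(k_f, n_f - k_f, k_s, n_s - k_s)
        rows.append(
            {
                "factor": factor,
                "k_fert": k_f,
                "n_fert": n_f,
                "k_scnt": k_s,
                "n_scnt": n_s,
                "log2_fold_change": fc,
                "p": p,
            }
        )
    df = pd.DataFrame(rows).set_index("factor")
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["neg_log10_q"] = -np.log10(np.maximum(df["q"], 1e-300))
    return df


def _rank_sum_exact_threshold() -> int:
    return 25


def group_tests(
    groups: Sequence[np.ndarray],
    test: str,
) -> dict:
    """Two-or-more group comparison.

    ``wilcoxon_2side`` / ``wilcoxon_1side``: Wilcoxon rank-sum, exact
    below n = 25 per group, else normal approximation with continuity
    correction.  ``t_2side``: Welch two-sample t.  ``kw_dunn``:
    Kruskal-Wallis with tie correction followed by Dunn's pairwise
    z-tests, BH-adjusted.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if test in ("wilcoxon_1side", "wilcoxon_2side"):
        if len(groups) != 2:
            raise ValueError("rank-sum test is two-group")
        x, y = groups
        method = (
            "exact"
            if max(len(x), len(y)) <= _rank_sum_exact_threshold()
            and not _has_ties(np.concatenate([x, y]))
            else "asymptotic"
        )
        alternative = "two-sided" if test == "wilcoxon_2side" else "greater"
        res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
        return {"statistic": float(res.statistic), "p": float(res.pvalue)}
    if test == "t_2side":
        if len(groups) != 2:
            raise ValueError("t test is two-group")
        if min(len(g) for g in groups) < 2:
            raise ValueError("t test needs >= 2 values per group")
        res = stats.ttest_ind(groups[0], groups[1], equal_var=False)
        p = float(res.pvalue)
        return {"statistic": float(res.statistic), "p": 1.0 if np.isnan(p) else p}
    if test == "kw_dunn":
        return kruskal_dunn(groups)
    raise ValueError(f"unknown test {test!r}")


def _has_ties(v: np.ndarray) -> bool:
    return len(np.unique(v)) < len(v)


def kruskal_dunn(groups: Sequence[np.ndarray]) -> dict:
    """Kruskal-Wallis H (tie-corrected) plus Dunn's pairwise comparisons.

    Dunn's z for groups i, j uses mean ranks over the pooled sample with
    the tie-corrected variance; pairwise p-values are two-sided and
    BH-adjusted.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return {"H": 0.0, "p": 1.0, "pairwise": pd.DataFrame(
            [], columns=["i", "j", "z", "p", "q"])}
    H, p = stats.kruskal(*groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    bounds = np.cumsum([0] + [len(g) for g in groups])
    mean_ranks = [
        ranks[bounds[i]: bounds[i + 1]].mean() for i in range(len(groups))
    ]
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        ni, nj = len(groups[i]), len(groups[j])
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append({"i": i, "j": j, "z": float(z),
                     "p": float(2.0 * stats.norm.sf(abs(z)))})
    pw = pd.DataFrame(rows)
    pw["q"] = bh_adjust(pw["p"].to_numpy())
    return {"H": float(H), "p": float(p), "pairwise": pw}


def replicate_qc(
    table: WindowSignalTable, threshold: float = 0.90
) -> pd.DataFrame:
    """Pairwise replicate Pearson r per (condition, stage, lineage).

    Pairs with r below ``threshold`` (or undefined from zero variance)
    are flagged.  Computed over the table's windows, which by
    construction are the merged-peak windows.
    """
    keys = sorted(
        {(s.condition, s.stage, s.lineage) for s in table.samples},
        key=lambda t: (t[0], t[1], t[2] or ""),
    )
    rows = []
    for cond, stage, lineage in keys:
        idx = table.sample_index(condition=cond, stage=stage, lineage=lineage)
        if len(idx) < 2:
            continue
        for a, b in combinations(idx, 2):
            x, y = table.signal[:, a], table.signal[:, b]
            if x.std() == 0 or y.std() == 0:
                r = float("nan")
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            rows.append(
                {
                    "condition": cond,
                    "stage": stage,
                    "lineage": lineage,
                    "rep_a": table.samples[a].replicate,
                    "rep_b": table.samples[b].replicate,
                    "pearson_r": r,
                    "flagged": (not np.isfinite(r)) or r < threshold,
                }
            )
    return pd.DataFrame(rows)
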