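"""Gene-activation staging during zygotic genome activation.

Implements median-of-ratios count normalization, a negative-binomial Wald
test for stage-wise differential expression, the sequential
maternal / minor-ZGA / major-ZGA / MGA classification cascade, the
restricted / partial / full activation-degree call (fertilized vs SCNT),
and family-level aggregation of repeat-element signal and methylation.

The cascade follows the stage design oocyte -> PN5 -> early 2-cell (E2C)
-> late 2-cell (L2C) -> 4-cell: maternally loaded genes (> 50 normalized
counts in oocytes) are removed first; genes switched on by the PN5/E2C
stage (> 100 normalized counts, > 2-fold over oocyte, q < 0.01) are minor
ZGA; of the remainder, those switched on at L2C are major ZGA and those
switched on at the 4-cell stage are MGA.  All thresholds are strict
inequalities and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "ZgaThresholds",
    "DEGREE_DEFINING_STAGE",
    "size_factors_median_ratio",
    "nb_de_test",
    "classify_zga",
    "classify_degree",
    "condense_repeat_family",
    "signal_expression_correlation",
    "bh_adjust",
]


class ExpressionMatrix:
    """Genes x samples raw counts with gene lengths and sample metadata.

    Normalized counts are counts divided by per-sample median-of-ratios
    size factors; TPM divides by gene length first and rescales each
    column to one million.
    """

    def __init__(
        self,
        genes: Sequence[str],
        lengths: Sequence[int],
        samples: Sequence[tuple[str, str, int]],  # (stage, condition, replicate)
        counts: np.ndarray,
    ):
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (len(genes), len(samples)):
            raise ValueError(
                f"counts shape {counts.shape} != ({len(genes)}, {len(samples)})"
            )
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        lengths = np.asarray(lengths, dtype=float)
        if (lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        self.genes = list(genes)
        self.lengths = lengths
        self.samples = list(samples)
        self.counts = counts
        self._size_factors: np.ndarray | None = None

    @property
    def size_factors(self) -> np.ndarray:
        if self._size_factors is None:
            self._size_factors = size_factors_median_ratio(self.counts)
        return self._size_factors

    @property
    def normalized(self) -> np.ndarray:
        return self.counts / self.size_factors

    @property
    def tpm(self) -> np.ndarray:
        rate = self.counts / self.lengths[:, None]
        return rate / rate.sum(axis=0, keepdims=True) * 1e6

    def sample_index(self, stage: str | None = None, condition: str | None = None) -> list[int]:
        out = []
        for j, (s, c, _r) in enumerate(self.samples):
            if stage is not None and s != stage:
                continue
            if condition is not None and c != condition:
                continue
            out.append(j)
        return out

    def stage_mean(self, stage: str, condition: str | None = None) -> np.ndarray:
        """Replicate-mean normalized counts at a stage."""
        idx = self.sample_index(stage, condition)
        if not idx:
            raise KeyError(f"no samples at stage {stage!r} (condition {condition!r})")
        return self.normalized[:, idx].mean(axis=1)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.counts.astype(int), index=self.genes)
        df.insert(0, "length", self.lengths.astype(int))
        df.columns = ["length"] + [
            f"{s}_{c}_rep{r}" for s, c, r in self.samples
        ]
        df.index.name = "gene"
        df.to_csv(path, sep="\t")


def size_factors_median_ratio(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factor per sample.

    Per gene with all-positive counts, a geometric-mean pseudo-reference
    is formed; each sample's factor is the median over those genes of
    counts / reference.  The raw medians are kept (no rescaling).
    """
    counts = np.asarray(counts, dtype=float)
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "cannot form the geometric-mean reference"
        )
    sub = counts[allpos]
    log_ref = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_ref[:, None]
    return np.exp(np.median(ratios, axis=0))


def _moment_dispersion(groupA: np.ndarray, groupB: np.ndarray, floor: float = 0.01) -> np.ndarray:
    """Per-gene NB dispersion alpha (var = mu + alpha mu^2) by moments,
    pooled over the two groups and floored."""
    alphas = []
    for g in (groupA, groupB):
        mu = g.mean(axis=1)
        var = g.var(axis=1, ddof=1) if g.shape[1] > 1 else np.zeros_like(mu)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mu) / np.maximum(mu, 1e-12) ** 2
        alphas.append(a)
    alpha = np.nanmean(np.column_stack(alphas), axis=1)
    return np.maximum(np.nan_to_num(alpha), floor)


def nb_de_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    size_factors_a: np.ndarray,
    size_factors_b: np.ndarray,
    dispersion_floor: float = 0.01,
) -> pd.DataFrame:
    """Negative-binomial Wald test per gene between two sample groups.

    Normalizes by the given size factors, moment-estimates a pooled NB
    dispersion (floored), and tests the log2 fold change of group means
    (pseudocount 1) with a Wald z statistic; q-values are BH-adjusted
    across genes.  Returns columns log2fc, p, q, mean_a, mean_b.
    """
    norm_a = np.asarray(counts_a, float) / np.asarray(size_factors_a, float)
    norm_b = np.asarray(counts_b, float) / np.asarray(size_factors_b, float)
    mu_a, mu_b = norm_a.mean(axis=1), norm_b.mean(axis=1)
    log2fc = np.log2((mu_b + 1.0) / (mu_a + 1.0))

    alpha = _moment_dispersion(norm_a, norm_b, dispersion_floor)
    n_a, n_b = norm_a.shape[1], norm_b.shape[1]
    # Var of a normalized-count group mean under NB(mu, alpha)
    var_mean_a = (mu_a + alpha * mu_a**2) / n_a
    var_mean_b = (mu_b + alpha * mu_b**2) / n_b
    # delta method on log2(mu + 1)
    ln2sq = np.log(2.0) ** 2
    var_l2_a = var_mean_a / ((mu_a + 1.0) ** 2 * ln2sq)
    var_l2_b = var_mean_b / ((mu_b + 1.0) ** 2 * ln2sq)
    se = np.sqrt(var_l2_a + var_l2_b)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    dead = (mu_a + mu_b) == 0
    p = np.where(dead | ~np.isfinite(p), 1.0, p)
    log2fc = np.where(dead, 0.0, log2fc)
    q = bh_adjust(p)
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "q": q, "mean_a": mu_a, "mean_b": mu_b}
    )


@dataclass(frozen=True)
class ZgaThresholds:
    """Cascade gates; all comparisons are strict."""

    maternal_max: float = 50.0     # oocyte normalized counts above this -> maternal
    activation_min: float = 100.0  # normalized counts required at the activating stage
    fold_min: float = 2.0          # fold-up vs oocyte
    q_max: float = 0.01            # BH-adjusted p vs oocyte
    degree_restricted_fc: float = 4.0  # fertilized/SCNT fold change above -> restricted
    degree_full_fc: float = 2.0        # below -> full


#: the fertilized stage at which each class's fertilized/SCNT fold change is taken
DEGREE_DEFINING_STAGE = {"minor_ZGA": "E2C", "major_ZGA": "L2C", "MGA": "4C"}

ZGA_STAGE_GATES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("minor_ZGA", ("PN5", "E2C")),
    ("major_ZGA", ("L2C",)),
    ("MGA", ("4C",)),
)


def classify_zga(
    expr: ExpressionMatrix,
    thresholds: ZgaThresholds = ZgaThresholds(),
    de_results: Mapping[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Sequential, mutually exclusive ZGA class per gene (fertilized data).

    Stages oocyte, PN5, E2C, L2C and 4C must all be present.  ``de_results``
    may supply precomputed stage-vs-oocyte test tables (keyed by stage);
    otherwise :func:`nb_de_test` is run here.
    """
    required = ("oocyte", "PN5", "E2C", "L2C", "4C")
    for s in required:
        if not expr.sample_index(stage=s):
            raise KeyError(f"stage {s!r} missing from the expression matrix")

    sf = expr.size_factors
    oo_idx = expr.sample_index(stage="oocyte")
    oo_mean = expr.stage_mean("oocyte")

    if de_results is None:
        de_results = {}
        for stage in ("PN5", "E2C", "L2C", "4C"):
            idx = expr.sample_index(stage=stage)
            de_results[stage] = nb_de_test(
                expr.counts[:, oo_idx], expr.counts[:, idx],
                sf[oo_idx], sf[idx],
            )

    n = len(expr.genes)
    zga = np.full(n, "none", dtype=object)
    maternal = oo_mean > thresholds.maternal_max
    zga[maternal] = "maternal"
    unassigned = ~maternal

    for cls, stages in ZGA_STAGE_GATES:
        hit = np.zeros(n, dtype=bool)
        for stage in stages:
            de = de_results[stage]
            stage_mean = expr.stage_mean(stage)
            fold = (stage_mean + 1.0) / (oo_mean + 1.0)
            hit |= (
                (stage_mean > thresholds.activation_min)
                & (fold > thresholds.fold_min)
                & (de["q"].to_numpy() < thresholds.q_max)
            )
        take = unassigned & hit
        zga[take] = cls
        unassigned &= ~take

    return pd.DataFrame({"gene": expr.genes, "zga_class": zga}).set_index("gene")


def classify_degree(
    calls: pd.DataFrame,
    expr_fert: ExpressionMatrix,
    expr_scnt: ExpressionMatrix,
    thresholds: ZgaThresholds = ZgaThresholds(),
) -> pd.DataFrame:
    """Restricted / partial / full activation in SCNT embryos.

    For each classified gene the fertilized/SCNT fold change
    ``(mean_fert + 1)/(mean_scnt + 1)`` is taken at the class's defining
    stage (minor: E2C, major: L2C, MGA: 4C); > 4 -> restricted, < 2 ->
    full, otherwise partial.  Unclassified genes get ``not_applicable``.
    """
    out = calls.copy()
    out["degree"] = "not_applicable"
    out["fold_change_fert_scnt"] = np.nan
    gene_pos_f = {g: i for i, g in enumerate(expr_fert.genes)}
    gene_pos_s = {g: i for i, g in enumerate(expr_scnt.genes)}
    for cls, stage in DEGREE_DEFINING_STAGE.items():
        genes = out.index[out["zga_class"] == cls]
        if not len(genes):
            continue
        mf = expr_fert.stage_mean(stage)
        ms = expr_scnt.stage_mean(stage)
        for g in genes:
            fc = (mf[gene_pos_f[g]] + 1.0) / (ms[gene_pos_s[g]] + 1.0)
            out.loc[g, "fold_change_fert_scnt"] = fc
            if fc > thresholds.degree_restricted_fc:
                out.loc[g, "degree"] = "restricted"
            elif fc < thresholds.degree_full_fc:
                out.loc[g, "degree"] = "full"
            else:
                out.loc[g, "degree"] = "partial"
    return out


def condense_repeat_family(
    values: Sequence[float],
    mode: str,
    lengths: Sequence[int] | None = None,
    library_size: float | None = None,
) -> float:
    """Aggregate per-copy repeat values to one family-level value.

    ``sum_expression``: read counts are summed over copies and converted
    to RPKM over the summed copy length.  ``mean_methylation``: copy
    values are summed and divided by the copy number.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("at least one copy required")
    if mode == "mean_methylation":
        return float(values.sum() / values.size)
    if mode == "sum_expression":
        if lengths is None or library_size is None:
            raise ValueError("sum_expression requires lengths and library_size")
        total_len = int(np.asarray(lengths).sum())
        from .intervals import rpkm

        return rpkm(float(values.sum()), total_len, library_size)
    raise ValueError(f"unknown mode {mode!r}")


def signal_expression_correlation(signal, expression) -> float:
    """Sample Pearson correlation between per-element H3K9me3 signal and
    expression (e.g. LTR families)."""
    x = np.asarray(signal, dtype=float)
    y = np.asarray(expression, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-D vectors required")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
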