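"""Lineage-specific H3K9me3 domain discovery and the Mcrs1-OE rescue metric.

Merged ICM/TE peak domains are scored by PCA of their signal matrix
(domains as observations, samples as variables); domains with extreme
scores on PC1 or PC2 are the lineage-specific candidates, partitioned by
k-means.  The rescue statistic compares, per domain, Euclidean distances
in (ICM, TE) mean-signal space: A (SCNT vs fertilized), B (OE vs
fertilized) and C (OE vs SCNT).  A > B marks a domain as repaired by
Mcrs1 overexpression; among those, log2(B/C) < 1 marks it as rescued.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

__all__ = [
    "PcaSelection",
    "RescueRecord",
    "pca_select_domains",
    "kmeans_domains",
    "rescue_metric",
    "rescue_fractions",
    "hierarchical_dendrogram",
]


@dataclass
class PcaSelection:
    scores: np.ndarray        # (n_domains, n_pcs) PC scores
    loadings: np.ndarray      # (n_samples, n_pcs) unit-norm loadings
    explained: np.ndarray     # variance explained per PC
    selected: np.ndarray      # bool mask over domains


def pca_select_domains(
    matrix: np.ndarray, n_pcs: int = 2, threshold: float = 3.0
) -> PcaSelection:
    """Select domains with |PC score| > ``threshold`` on any leading PC.

    The signal matrix (domains x samples) is column-centered and
    decomposed by SVD; scores are the projections of domains onto the
    principal axes.  Each component's sign is fixed by forcing its
    largest-magnitude loading positive, so results are deterministic.
    A zero-variance matrix yields no selection.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need >= 3 domains and >= 2 samples")
    if not np.isfinite(X).all():
        raise ValueError("signal matrix must be finite")
    Xc = X - X.mean(axis=0, keepdims=True)
    n_pcs = min(n_pcs, min(Xc.shape))
    if not Xc.any():
        z = np.zeros((X.shape[0], n_pcs))
        return PcaSelection(z, np.zeros((X.shape[1], n_pcs)), np.zeros(n_pcs),
                            np.zeros(X.shape[0], dtype=bool))
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt[:n_pcs].T                     # loadings, columns = PCs
    scores = U[:, :n_pcs] * S[:n_pcs]
    # deterministic orientation: largest |loading| of each PC positive
    for k in range(n_pcs):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
            scores[:, k] = -scores[:, k]
    explained = S[:n_pcs] ** 2 / (X.shape[0] - 1)
    selected = (np.abs(scores) > threshold).any(axis=1)
    return PcaSelection(scores, V, explained, selected)


def kmeans_domains(
    signals: np.ndarray, k: int = 7, seed: int = 0, restarts: int = 10
) -> np.ndarray:
    """k-means labels for the selected-domain signal matrix.

    Euclidean distance on the raw log2 signals, k-means++ initialization,
    best of ``restarts`` by within-cluster sum of squares; deterministic
    under a fixed seed.
    """
    X = np.asarray(signals, dtype=float)
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} domains, got {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    return km.fit_predict(X)


@dataclass
class RescueRecord:
    """Per-domain rescue geometry in (ICM, TE) signal space."""

    A: float  # SCNT vs fertilized
    B: float  # OE vs fertilized
    C: float  # OE vs SCNT
    repaired: bool
    rescued: bool


def rescue_metric(
    fert: np.ndarray,
    scnt: np.ndarray,
    oe: np.ndarray,
    ratio_threshold: float = 1.0,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """A/B/C distances and repaired/rescued flags per domain.

    Inputs are (n_domains, 2) arrays of replicate-averaged (ICM, TE)
    signals per condition.  ``repaired`` iff A > B; ``rescued`` iff
    repaired and log2((B+eps)/(C+eps)) < ``ratio_threshold``.  The eps
    guard makes a domain where OE coincides with both endpoints (B=C=0)
    count as rescued.
    """
    fert, scnt, oe = (np.asarray(m, dtype=float) for m in (fert, scnt, oe))
    if not (fert.shape == scnt.shape == oe.shape) or fert.ndim != 2 or fert.shape[1] != 2:
        raise ValueError("fert/scnt/oe must share shape (n_domains, 2)")
    A = np.linalg.norm(scnt - fert, axis=1)
    B = np.linalg.norm(oe - fert, axis=1)
    C = np.linalg.norm(oe - scnt, axis=1)
    repaired = A > B
    rescued = repaired & (np.log2((B + eps) / (C + eps)) < ratio_threshold)
    return pd.DataFrame(
        {"A": A, "B": B, "C": C, "repaired": repaired, "rescued": rescued}
    )


def rescue_fractions(records: pd.DataFrame) -> tuple[float, float]:
    """Cohort (repaired, rescued) fractions over all domains."""
    n = len(records)
    if n == 0:
        raise ValueError("no domains")
    return float(records["repaired"].mean()), float(records["rescued"].mean())


def hierarchical_dendrogram(
    matrix: np.ndarray, labels: list[str]
) -> tuple[np.ndarray, str]:
    """Average-linkage sample tree on 1 - Pearson distance.

    ``matrix`` is domains x samples; columns are clustered.  Returns the
    scipy linkage matrix and a Newick string with branch lengths.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    if len(labels) != X.shape[1]:
        raise ValueError("one label per sample required")
    corr = np.corrcoef(X.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    return Z, _to_newick(Z, labels)


def _to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Newick serialization of a scipy linkage matrix (heights as depths)."""
    n = len(labels)

    def node(i: int) -> tuple[str, float]:
        if i < n:
            return labels[i], 0.0
        a, b, h, _cnt = Z[i - n]
        sa, ha = node(int(a))
        sb, hb = node(int(b))
        return (f"({sa}:{(h - ha) / 2:.6g},{sb}:{(h - hb) / 2:.6g})", h)

    s, _ = node(2 * n - 2)
    return s + ";"
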