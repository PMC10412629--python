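"""Shared fixtures and brute-force oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from k9dyn.intervals import GenomicInterval, IntervalSet


def brute_covered_positions(s: IntervalSet) -> set[tuple[str, int]]:
    """Per-base oracle: the exact set of (chrom, position) covered bases."""
    out: set[tuple[str, int]] = set()
    for iv in s:
        out.update((iv.chrom, p) for p in range(iv.start, iv.end))
    return out


def brute_overlap_marked(a: GenomicInterval, bset: IntervalSet) -> bool:
    """O(n) pairwise scan of the reciprocal-50% predicate."""
    for b in bset:
        if b.chrom != a.chrom:
            continue
        ov = max(0, min(a.end, b.end) - max(a.start, b.start))
        if ov >= 0.5 * len(a) or ov >= 0.5 * len(b):
            return True
    return False


def random_interval_set(
    rng: np.random.Generator, n: int, chroms=("chr1", "chr2"), span: int = 10_000
) -> IntervalSet:
    ivs = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, 500))
        ivs.append(GenomicInterval(str(rng.choice(chroms)), start, start + length))
    return IntervalSet(ivs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230809)


@pytest.fixture
def small_cfg():
    from k9dyn.simulate import SimConfig

    return SimConfig(seed=11, n_windows=400, n_genes=300, n_domains=120)
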