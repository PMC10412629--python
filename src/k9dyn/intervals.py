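"""Genomic-interval algebra and window-level H3K9me3 signal containers.

Coordinates are 0-based half-open (BED convention) throughout.  The two
workhorse primitives are the reciprocal-overlap predicate used to call a
region "marked" by a peak set (either partner covered over >= 50% of its
own length, the ``bedtools intersect -f 0.5 -e -r`` semantics) and the
1-kb window tiling over which log2 ChIP/Input ratios are computed.
"""

from __future__ import annotations

import json
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "SampleInfo",
    "WindowSignalTable",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "tile_windows",
    "rpkm",
    "window_signal",
    "overlap_len",
    "overlap_marked",
    "marked_fraction",
    "base_coverage_fraction",
    "covered_bases",
    "window_coverage_fractions",
    "promoters_from_tss",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open region ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    ``merge()`` returns the minimal sorted, pairwise non-overlapping set
    covering the same bases; touching intervals (end == next start) are
    joined.  Most downstream operations require a merged set.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), *, sorted_flag: bool = False):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.sorted_flag = sorted_flag

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def sort(self) -> "IntervalSet":
        out = IntervalSet(sorted(self.intervals), sorted_flag=True)
        return out

    def merge(self) -> "IntervalSet":
        return merge_intervals(self)

    # -- fast per-chromosome lookup -------------------------------------
    def _index(self) -> dict[str, tuple[list[int], list[int]]]:
        """Per-chromosome (starts, ends) arrays of the merged set, cached."""
        idx = getattr(self, "_idx_cache", None)
        if idx is None:
            merged = merge_intervals(self)
            idx = {}
            for iv in merged:
                idx.setdefault(iv.chrom, ([], []))
                idx[iv.chrom][0].append(iv.start)
                idx[iv.chrom][1].append(iv.end)
            self._idx_cache = idx
        return idx


def read_bed(path: str | Path) -> IntervalSet:
    """Read a BED3/BED6 file into an :class:`IntervalSet` (file order kept).

    ``track``, ``browser`` and ``#`` comment lines are skipped.  Malformed
    lines raise ``ValueError`` naming the offending line number.
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] != "" else None
            try:
                out.append(GenomicInterval(chrom, start, end, name, score, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(out)


def write_bed(s: IntervalSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for iv in s:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                cols += [
                    iv.name if iv.name is not None else ".",
                    f"{iv.score:g}" if iv.score is not None else ".",
                    iv.strand if iv.strand is not None else ".",
                ]
            fh.write("\t".join(cols) + "\n")


def merge_intervals(s: IntervalSet) -> IntervalSet:
    """Minimal sorted non-overlapping set covering the same bases.

    Touching intervals are merged; idempotent.
    """
    if not len(s):
        return IntervalSet([], sorted_flag=True)
    ivs = sorted(s.intervals)
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = ivs[0].chrom, ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        if iv.chrom == cur_chrom and iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return IntervalSet(merged, sorted_flag=True)


def tile_windows(s: IntervalSet, width: int = 1000) -> IntervalSet:
    """Tile each interval left-to-right into consecutive windows of ``width``.

    A final remainder window shorter than ``width`` is kept, so the union
    of windows covers exactly the input bases.
    """
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    out: list[GenomicInterval] = []
    for iv in s:
        pos = iv.start
        while pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, min(pos + width, iv.end)))
            pos += width
    return IntervalSet(out, sorted_flag=s.sorted_flag)


def rpkm(read_count: float, region_len: int, library_size: float) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if region_len <= 0:
        raise ValueError("region_len must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return read_count / (region_len / 1000.0) / (library_size / 1e6)


def window_signal(chip_rpkm, input_rpkm, pseudocount: float = 1.0):
    """log2((chip + p) / (input + p)); vectorized over arrays."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    chip = np.asarray(chip_rpkm, dtype=float)
    inp = np.asarray(input_rpkm, dtype=float)
    out = np.log2((chip + pseudocount) / (inp + pseudocount))
    if out.ndim == 0:
        return float(out)
    return out


def overlap_len(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _chrom_overlaps(a: GenomicInterval, idx) -> list[tuple[int, int]]:
    """(start, end) of merged-set intervals on a.chrom intersecting a."""
    if a.chrom not in idx:
        return []
    starts, ends = idx[a.chrom]
    lo = bisect_right(ends, a.start)
    hi = bisect_left(starts, a.end)
    return [(starts[i], ends[i]) for i in range(lo, hi)]


def overlap_marked(a: GenomicInterval, bset: IntervalSet) -> bool:
    """Reciprocal 50% overlap against a merged set.

    True iff some b in ``bset`` overlaps ``a`` by at least half of a's
    length OR at least half of b's length (``-f 0.5 -e -r``).
    """
    idx = bset._index()
    half_a = 0.5 * len(a)
    for bs, be in _chrom_overlaps(a, idx):
        ov = min(a.end, be) - max(a.start, bs)
        if ov >= half_a or ov >= 0.5 * (be - bs):
            return True
    return False


def marked_fraction(regions: IntervalSet, peaks: IntervalSet) -> float:
    """Fraction of ``regions`` called marked by ``peaks`` (element level)."""
    if not len(regions):
        raise ValueError("marked_fraction is undefined for empty regions")
    if not len(peaks):
        return 0.0
    hits = sum(overlap_marked(r, peaks) for r in regions)
    return hits / len(regions)


def covered_bases(a: GenomicInterval, bset: IntervalSet) -> int:
    """Bases of ``a`` covered by the merged ``bset``."""
    idx = bset._index()
    return sum(
        min(a.end, be) - max(a.start, bs) for bs, be in _chrom_overlaps(a, idx)
    )


def base_coverage_fraction(regions: IntervalSet, peaks: IntervalSet) -> float:
    """Base-level variant: covered bases of ``regions`` / total bases."""
    total = regions.total_bases()
    if total == 0:
        raise ValueError("base_coverage_fraction undefined for empty regions")
    if not len(peaks):
        return 0.0
    merged_regions = merge_intervals(regions)
    cov = sum(covered_bases(r, peaks) for r in merged_regions)
    return cov / merged_regions.total_bases() if merged_regions.total_bases() else 0.0


def window_coverage_fractions(windows: IntervalSet, peaks: IntervalSet) -> np.ndarray:
    """Per-window fraction of bases covered by the merged peak set."""
    if not len(peaks):
        return np.zeros(len(windows))
    return np.array([covered_bases(w, peaks) / len(w) for w in windows])


def promoters_from_tss(
    tss: Sequence[tuple[str, int, str]], flank: int = 1000
) -> IntervalSet:
    """Promoter = [TSS - flank, TSS + flank), clipped at the chromosome start.

    The window is strand-independent (1 kb upstream and downstream).
    """
    out = []
    for chrom, pos, strand in tss:
        if pos < 0:
            raise ValueError(f"TSS position must be >= 0, got {pos}")
        out.append(
            GenomicInterval(chrom, max(0, pos - flank), pos + flank, strand=strand)
        )
    return IntervalSet(out)


# ---------------------------------------------------------------------------
# window signal table


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one signal column."""

    condition: str  # SCNT / fertilized / SCNT+OE
    stage: str      # CC, 6hpa, 14hpa, 2C, ...
    lineage: str | None = None  # ICM / TE where applicable
    replicate: int = 1

    @property
    def label(self) -> str:
        parts = [self.condition, self.stage]
        if self.lineage:
            parts.append(self.lineage)
        parts.append(f"rep{self.replicate}")
        return "_".join(parts)


class WindowSignalTable:
    """1-kb windows x samples matrix of log2((ChIP+1)/(Input+1)) signals.

    Holds the underlying ChIP and Input RPKM matrices so the defining
    identity ``signal = log2((chip+p)/(input+p))`` can be re-derived at
    any pseudocount.
    """

    def __init__(
        self,
        windows: IntervalSet,
        samples: Sequence[SampleInfo],
        chip_rpkm: np.ndarray,
        input_rpkm: np.ndarray,
        pseudocount: float = 1.0,
    ):
        chip_rpkm = np.asarray(chip_rpkm, dtype=float)
        input_rpkm = np.asarray(input_rpkm, dtype=float)
        if chip_rpkm.shape != (len(windows), len(samples)):
            raise ValueError(
                f"chip_rpkm shape {chip_rpkm.shape} != "
                f"({len(windows)}, {len(samples)})"
            )
        if input_rpkm.shape != chip_rpkm.shape:
            raise ValueError("input_rpkm shape mismatch")
        if (chip_rpkm < 0).any() or (input_rpkm < 0).any():
            raise ValueError("RPKM values must be non-negative")
        self.windows = windows
        self.samples = list(samples)
        self.chip_rpkm = chip_rpkm
        self.input_rpkm = input_rpkm
        self.pseudocount = float(pseudocount)
        self.signal = window_signal(chip_rpkm, input_rpkm, pseudocount)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def sample_index(self, **kwargs) -> list[int]:
        """Indices of samples whose metadata match all given fields."""
        out = []
        for j, s in enumerate(self.samples):
            if all(getattr(s, k) == v for k, v in kwargs.items()):
                out.append(j)
        return out

    def mean_signal(self, **kwargs) -> np.ndarray:
        """Replicate-averaged signal for samples matching the metadata."""
        idx = self.sample_index(**kwargs)
        if not idx:
            raise KeyError(f"no samples match {kwargs}")
        return self.signal[:, idx].mean(axis=1)

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write ``chrom start end <sample...>`` TSV plus a JSON sidecar."""
        path = Path(path)
        df = pd.DataFrame(
            {
                "chrom": [w.chrom for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
            }
        )
        for j, s in enumerate(self.samples):
            df[s.label] = np.round(self.signal[:, j], 6)
        df.to_csv(path, sep="\t", index=False)
        if sidecar is None:
            sidecar = path.with_suffix(path.suffix + ".json")
        meta = [
            {
                "label": s.label,
                "condition": s.condition,
                "stage": s.stage,
                "lineage": s.lineage,
                "replicate": s.replicate,
            }
            for s in self.samples
        ]
        Path(sidecar).write_text(
            json.dumps({"pseudocount": self.pseudocount, "samples": meta}, indent=1)
        )
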