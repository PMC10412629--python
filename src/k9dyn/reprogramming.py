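"""Stage-transition classification of H3K9me3 windows.

Classifies each 1-kb window of donor-cell (CC) H3K9me3 across the early
SCNT stages (CC -> 6 hpa -> 14 hpa -> 2C): which marks are established or
removed at each transition, which donor marks are reprogrammed (removed
before minor ZGA) versus unreprogrammed (retained at 14 hpa / 2C), and
the CpG-bias contingency of de novo promoter H3K9me3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    IntervalSet,
    WindowSignalTable,
    marked_fraction,
    overlap_marked,
    window_coverage_fractions,
)

__all__ = [
    "StagePresence",
    "TRANSITION_LABELS",
    "RPG_LABELS",
    "presence_from_peaks",
    "presence_from_signal",
    "classify_transition",
    "classify_reprogramming",
    "stage_overlap_fraction",
    "cpg_bias_table",
]

TRANSITION_LABELS = ("de_novo", "inherited", "erased", "absent")
RPG_LABELS = (
    "rpg_6hpa",
    "rpg_14hpa",
    "unrpg_14hpa",
    "unrpg_2C",
    "re_established",
    "never_marked",
)

#: stages the reprogrammed/unreprogrammed call is defined over, in order
RPG_STAGES = ("CC", "6hpa", "14hpa", "2C")


@dataclass
class StagePresence:
    """Boolean windows x stages peak-presence matrix."""

    windows: IntervalSet
    stages: tuple[str, ...]
    present: np.ndarray  # bool, shape (n_windows, n_stages)

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.windows), len(self.stages)):
            raise ValueError(
                f"present shape {self.present.shape} != "
                f"({len(self.windows)}, {len(self.stages)})"
            )

    def stage_column(self, stage: str) -> np.ndarray:
        try:
            j = self.stages.index(stage)
        except ValueError:
            raise KeyError(f"stage {stage!r} not in {self.stages}") from None
        return self.present[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [w.chrom for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
            }
        )
        for j, s in enumerate(self.stages):
            df[s] = self.present[:, j].astype(int)
        return df


def presence_from_peaks(
    windows: IntervalSet,
    stage_peaks: Mapping[str, IntervalSet],
    min_coverage: float = 0.5,
) -> StagePresence:
    """Call a window present at a stage iff >= ``min_coverage`` of its
    bases are covered by that stage's (merged) peak set."""
    stages = tuple(stage_peaks)
    cols = []
    for s in stages:
        frac = window_coverage_fractions(windows, stage_peaks[s])
        cols.append(frac >= min_coverage)
    return StagePresence(windows, stages, np.column_stack(cols))


def presence_from_signal(
    table: WindowSignalTable,
    stages: Sequence[str],
    condition: str,
    threshold: float,
) -> StagePresence:
    """Call presence from replicate-averaged log2 ChIP/Input signal.

    A window is present at a stage when its mean signal across that
    stage's replicates exceeds ``threshold`` (midway between the expected
    background and enriched signal levels).
    """
    cols = [
        table.mean_signal(condition=condition, stage=s) > threshold
        for s in stages
    ]
    return StagePresence(table.windows, tuple(stages), np.column_stack(cols))


def classify_transition(
    p: StagePresence, from_stage: str, to_stage: str
) -> np.ndarray:
    """Per-window label for one stage transition.

    (absent, present) -> de_novo; (present, present) -> inherited;
    (present, absent) -> erased; (absent, absent) -> absent.
    """
    a = p.stage_column(from_stage)
    b = p.stage_column(to_stage)
    out = np.empty(len(a), dtype=object)
    out[~a & b] = "de_novo"
    out[a & b] = "inherited"
    out[a & ~b] = "erased"
    out[~a & ~b] = "absent"
    return out


def classify_reprogramming(
    p: StagePresence,
    stages: Sequence[str] = RPG_STAGES,
) -> list[frozenset[str]]:
    """Reprogrammed/unreprogrammed call per window over CC, 6 hpa, 14 hpa, 2C.

    Donor (CC-present) windows are walked in stage order: loss by 6 hpa
    -> ``rpg_6hpa``; loss by 14 hpa -> ``rpg_14hpa``; retention at 14 hpa
    -> ``unrpg_14hpa`` (plus ``unrpg_2C`` when still present at 2C).  Any
    window that regains presence after a loss contradicts both
    definitions and is isolated as ``re_established``.  Windows without
    CC H3K9me3 are ``never_marked``.
    """
    if len(stages) != 4:
        raise ValueError("classification is defined over exactly four stages")
    cc, h6, h14, c2 = (p.stage_column(s) for s in stages)
    out: list[frozenset[str]] = []
    for pat in zip(cc, h6, h14, c2):
        out.append(_classify_pattern(pat))
    return out


def _classify_pattern(pat: tuple[bool, bool, bool, bool]) -> frozenset[str]:
    cc, h6, h14, c2 = (bool(x) for x in pat)
    if not cc:
        return frozenset({"never_marked"})
    if not h6:
        # lost straight away; any later regain is a contradiction
        if h14 or c2:
            return frozenset({"re_established"})
        return frozenset({"rpg_6hpa"})
    if not h14:
        if c2:
            return frozenset({"re_established"})
        return frozenset({"rpg_14hpa"})
    labels = {"unrpg_14hpa"}
    if c2:
        labels.add("unrpg_2C")
    return frozenset(labels)


def stage_overlap_fraction(a: IntervalSet, b: IntervalSet) -> float:
    """Fraction of a's elements marked by b (reciprocal-50% overlap)."""
    if not len(a):
        raise ValueError("stage_overlap_fraction undefined for empty set")
    return marked_fraction(a, b)


def cpg_bias_table(
    promoters: IntervalSet,
    transition: np.ndarray,
    cgi: IntervalSet,
) -> pd.DataFrame:
    """Contingency of de novo promoter H3K9me3 against promoter CpG class.

    ``transition`` gives each promoter's CC -> 6 hpa label; a promoter is
    high-CpG when it is marked (reciprocal-50% overlap) by the CpG-island
    set.  Returns one row per CpG class with the count and percentage of
    de novo promoters within the class.
    """
    transition = np.asarray(transition, dtype=object)
    if len(transition) != len(promoters):
        raise ValueError("one transition label per promoter required")
    high = np.array([overlap_marked(pr, cgi) for pr in promoters])
    de_novo = transition == "de_novo"
    rows = []
    for cls, mask in (("high_CpG", high), ("low_CpG", ~high)):
        n = int(mask.sum())
        k = int((de_novo & mask).sum())
        pct = round(100.0 * k / n, 1) if n else 0.0
        rows.append({"cpg_class": cls, "de_novo": k, "total": n, "de_novo_pct": pct})
    return pd.DataFrame(rows).set_index("cpg_class")
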