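"""Synthetic stage-resolved epigenome, expression and rescue data with a
planted ground-truth manifest.

The generator emulates the downstream products of the SCNT H3K9me3 study
design: per-window peak presence across the early SCNT stages (CC, 6 hpa,
14 hpa, 2C) with Gaussian log2-ratio signal noise and replicate
structure; negative-binomial stage-wise expression for fertilized and
SCNT embryos over oocyte, PN5, E2C, L2C and 4C with planted maternal /
minor-ZGA / major-ZGA / MGA classes and restricted / partial / full
activation degrees; blastocyst (ICM, TE) domain signals with planted
repair / rescue outcomes under Mcrs1 overexpression; and TF binding-site
sets with planted enrichment directions.

Class memberships are planted deterministically (the first floor(f * n)
entries of a seed-shuffled index list per class), so planted fractions
are realized as exact counts; only signal values and counts carry noise.
One root seed spawns an independent, explicitly keyed substream per
artifact, so generating one artifact never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .intervals import (
    GenomicInterval,
    IntervalSet,
    SampleInfo,
    WindowSignalTable,
    merge_intervals,
    tile_windows,
)
from .reprogramming import RPG_STAGES

__all__ = ["SimConfig", "TruthManifest", "Simulator"]

# presence pattern over (CC, 6hpa, 14hpa, 2C) realized by each planted class
_CLASS_PATTERNS: dict[str, tuple[int, int, int, int]] = {
    "rpg_6hpa": (1, 0, 0, 0),
    "rpg_14hpa": (1, 1, 0, 0),
    "unrpg_14hpa": (1, 1, 1, 0),
    "unrpg_2C": (1, 1, 1, 1),
    "re_established": (1, 1, 0, 1),
    "never_marked": (0, 0, 0, 0),
}

# substream keys: adding a new artifact appends a key, never renumbers
_STREAMS = ("epigenome", "expression", "rescue", "tf_sites", "kmeans")


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    seed: int = 0
    # genome / windows
    n_chroms: int = 2
    chrom_len: int = 10_000_000
    n_windows: int = 5_000
    window: int = 1_000
    n_replicates: int = 2
    # planted reprogramming-class fractions (exact counts after planting)
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "rpg_6hpa": 0.25,
            "rpg_14hpa": 0.15,
            "unrpg_14hpa": 0.10,
            "unrpg_2C": 0.15,
            "re_established": 0.05,
            "never_marked": 0.30,
        }
    )
    # Gaussian log2-ratio signal model
    signal_mu_present: float = 2.5
    signal_mu_absent: float = 0.0
    # calibrated so replicate Pearson correlations over peak windows land
    # above the 0.90 QC level the real assay exhibits
    signal_sd: float = 0.3
    # expression model
    n_genes: int = 2_000
    n_expr_replicates: int = 3
    nb_dispersion: float = 0.05
    zga_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "maternal": 0.15,
            "minor_ZGA": 0.10,
            "major_ZGA": 0.20,
            "MGA": 0.10,
            "none": 0.45,
        }
    )
    degree_fractions: dict[str, float] = field(
        default_factory=lambda: {"restricted": 0.3, "partial": 0.3, "full": 0.4}
    )
    # fertilized mean normalized counts per class over the five stages
    nb_mean_grid: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            #                 oocyte  PN5   E2C   L2C    4C
            "maternal":       (500.0, 300.0, 150.0, 80.0, 40.0),
            "minor_ZGA":      (5.0, 400.0, 400.0, 200.0, 100.0),
            "major_ZGA":      (5.0, 20.0, 30.0, 500.0, 400.0),
            "MGA":            (5.0, 10.0, 20.0, 60.0, 500.0),
            "none":           (20.0, 20.0, 20.0, 20.0, 20.0),
        }
    )
    # SCNT suppression of the activating stage, per planted degree
    degree_scnt_divisor: dict[str, float] = field(
        default_factory=lambda: {"restricted": 10.0, "partial": 3.0, "full": 1.2}
    )
    # rescue model
    n_domains: int = 600
    rescue_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "rescued": 0.33,
            "repaired_only": 0.40,
            "not_repaired": 0.27,
        }
    )
    lineage_signal_high: float = 4.0
    lineage_signal_low: float = 0.0
    rescue_signal_sd: float = 0.15
    # TF-site model
    n_factors: int = 20
    n_enriched_factors: int = 5
    tf_rate_high: float = 0.5
    tf_rate_low: float = 0.05

    def __post_init__(self) -> None:
        for name, fracs in (
            ("class_fractions", self.class_fractions),
            ("zga_fractions", self.zga_fractions),
            ("degree_fractions", self.degree_fractions),
            ("rescue_fractions", self.rescue_fractions),
        ):
            total = sum(fracs.values())
            if any(f < 0 for f in fracs.values()) or total > 1.0 + 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to <= 1")
        if self.signal_sd < 0 or self.rescue_signal_sd < 0:
            raise ValueError("signal sd must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for one artifact substream."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS.index(stream),))
        )


@dataclass
class TruthManifest:
    """Planted labels, one per simulated unit per category."""

    window_class: np.ndarray | None = None        # rpg/unrpg label per window
    window_transition: np.ndarray | None = None   # CC->6hpa label per window
    gene_class: np.ndarray | None = None          # ZGA class per gene
    gene_degree: np.ndarray | None = None         # restricted/partial/full
    domain_outcome: np.ndarray | None = None      # rescued/repaired_only/not_repaired
    tf_enriched: np.ndarray | None = None         # bool per factor

    def to_dict(self) -> dict:
        out = {}
        for k, v in asdict(self).items():
            if v is not None:
                out[k] = list(np.asarray(v).tolist())
        return out


def _plant(rng: np.random.Generator, n: int, fractions: Mapping[str, float],
           fill: str | None = None) -> np.ndarray:
    """Assign labels to exactly floor(f*n) shuffled indices per class.

    Any remainder (when fractions sum below 1, or from flooring) gets the
    ``fill`` label (default: the last class listed).
    """
    idx = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    pos = 0
    for cls, f in fractions.items():
        k = int(np.floor(f * n))
        labels[idx[pos: pos + k]] = cls
        pos += k
    fill = fill if fill is not None else list(fractions)[-1]
    labels[idx[pos:]] = fill
    return labels


class Simulator:
    """Generates every synthetic artifact from one :class:`SimConfig`."""

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg

    # -- epigenome ------------------------------------------------------

    def genome_windows(self) -> IntervalSet:
        """n_windows 1-kb tiles spread over the synthetic chromosomes."""
        cfg = self.cfg
        per_chrom = int(np.ceil(cfg.n_windows / cfg.n_chroms))
        out = []
        count = 0
        for c in range(cfg.n_chroms):
            chrom = f"chr{c + 1}"
            span = GenomicInterval(chrom, 0, min(per_chrom * cfg.window, cfg.chrom_len))
            for w in tile_windows(IntervalSet([span]), cfg.window):
                if count >= cfg.n_windows:
                    break
                out.append(w)
                count += 1
        return IntervalSet(out, sorted_flag=True)

    def simulate_epigenome(self):
        """Planted presence, per-stage peak sets, noisy signal table, manifest.

        Returns ``(presence, stage_peaks, signal_table, manifest)`` where
        ``presence`` is the exact planted windows x stages boolean matrix
        over CC, 6 hpa, 14 hpa and 2C, ``stage_peaks`` are the merged
        peak sets realizing it, and ``signal_table`` draws each
        (window, stage, replicate) signal from N(mu_present, sd) or
        N(mu_absent, sd) according to the planted presence.
        """
        from .reprogramming import StagePresence

        cfg = self.cfg
        rng = cfg.rng("epigenome")
        windows = self.genome_windows()
        n = len(windows)
        classes = _plant(rng, n, cfg.class_fractions, fill="never_marked")
        present = np.array(
            [_CLASS_PATTERNS[c] for c in classes], dtype=bool
        )
        presence = StagePresence(windows, RPG_STAGES, present)

        stage_peaks = {
            s: merge_intervals(
                IntervalSet([w for w, p in zip(windows, present[:, j]) if p])
            )
            for j, s in enumerate(RPG_STAGES)
        }

        samples = [
            SampleInfo("SCNT", s, None, r + 1)
            for s in RPG_STAGES
            for r in range(cfg.n_replicates)
        ]
        mu = np.where(
            np.repeat(present, cfg.n_replicates, axis=1),
            cfg.signal_mu_present,
            cfg.signal_mu_absent,
        )
        signal = rng.normal(mu, cfg.signal_sd) if cfg.signal_sd > 0 else mu.astype(float)
        # store as chip/input RPKM pairs realizing the signal exactly:
        # input held at 3 RPKM so chip = 2**signal * 4 - 1 stays >= 0
        # for any signal above -2 (background draws essentially never go
        # lower at the default sd)
        input_rpkm = np.full_like(signal, 3.0)
        chip_rpkm = np.maximum(2.0**signal * 4.0 - 1.0, 0.0)
        table = WindowSignalTable(windows, samples, chip_rpkm, input_rpkm)

        transition = np.where(
            present[:, 0] & present[:, 1], "inherited",
            np.where(present[:, 0] & ~present[:, 1], "erased",
                     np.where(~present[:, 0] & present[:, 1], "de_novo", "absent")),
        ).astype(object)
        manifest = TruthManifest(window_class=classes, window_transition=transition)
        return presence, stage_peaks, table, manifest

    @property
    def presence_threshold(self) -> float:
        """Signal cutoff for presence calls: midway between the two modes."""
        return 0.5 * (self.cfg.signal_mu_present + self.cfg.signal_mu_absent)

    # -- expression -----------------------------------------------------

    def _nb_draw(self, rng: np.random.Generator, mean: np.ndarray) -> np.ndarray:
        alpha = self.cfg.nb_dispersion
        mean = np.asarray(mean, dtype=float)
        if alpha == 0:
            return np.round(mean)
        size = 1.0 / alpha
        p = size / (size + np.maximum(mean, 1e-12))
        out = rng.negative_binomial(size, p)
        return np.where(mean == 0, 0, out)

    def simulate_expression(self):
        """Fertilized and SCNT expression matrices plus the gene manifest.

        Fertilized means follow ``nb_mean_grid`` per planted class; SCNT
        means equal the fertilized means except at the planted class's
        defining stage and later, where they are divided according to the
        planted activation degree.  Counts are NB(mean, dispersion) per
        replicate; at dispersion 0 counts equal the rounded means.
        """
        from .expression import ExpressionMatrix, DEGREE_DEFINING_STAGE

        cfg = self.cfg
        rng = cfg.rng("expression")
        stages = ("oocyte", "PN5", "E2C", "L2C", "4C")
        n = cfg.n_genes
        gene_class = _plant(rng, n, cfg.zga_fractions, fill="none")
        activated = np.isin(gene_class, ("minor_ZGA", "major_ZGA", "MGA"))
        gene_degree = np.full(n, "not_applicable", dtype=object)
        gene_degree[activated] = _plant(
            rng, int(activated.sum()), cfg.degree_fractions, fill="full"
        )

        mean_fert = np.array([cfg.nb_mean_grid[c] for c in gene_class])
        mean_scnt = mean_fert.copy()
        stage_pos = {s: i for i, s in enumerate(stages)}
        for g in np.flatnonzero(activated):
            onset = stage_pos[DEGREE_DEFINING_STAGE[gene_class[g]]]
            mean_scnt[g, onset:] /= cfg.degree_scnt_divisor[gene_degree[g]]

        genes = [f"gene{idx:05d}" for idx in range(n)]
        lengths = rng.integers(500, 5000, size=n)
        mats = {}
        for cond, grid in (("fertilized", mean_fert), ("SCNT", mean_scnt)):
            samples = [
                (s, cond, r + 1)
                for s in stages
                for r in range(cfg.n_expr_replicates)
            ]
            cols = [
                self._nb_draw(rng, grid[:, stage_pos[s]])
                for s, _c, _r in samples
            ]
            mats[cond] = ExpressionMatrix(
                genes, lengths, samples, np.column_stack(cols)
            )
        manifest = TruthManifest(gene_class=gene_class, gene_degree=gene_degree)
        return mats["fertilized"], mats["SCNT"], manifest

    # -- blastocyst domains and rescue ---------------------------------

    def simulate_rescue(self):
        """(ICM, TE) domain signals for fertilized, SCNT and Mcrs1-OE
        embryos with planted repair/rescue outcomes.

        Fertilized domains are lineage-specific (half ICM-high, half
        TE-high); SCNT domains sit at the indistinct midpoint.  The OE
        point is placed per planted outcome: at the fertilized point
        (rescued), 20% of the way from SCNT to fertilized (repaired but
        not rescued, log2(B/C) well above 1), or 30% beyond SCNT away
        from fertilized (not repaired).  Gaussian replicate noise of
        ``rescue_signal_sd`` is added per coordinate and averaged over
        ``n_replicates``.
        """
        cfg = self.cfg
        rng = cfg.rng("rescue")
        n = cfg.n_domains
        outcome = _plant(rng, n, cfg.rescue_fractions, fill="not_repaired")
        icm_high = np.arange(n) % 2 == 0
        hi, lo = cfg.lineage_signal_high, cfg.lineage_signal_low
        fert = np.where(icm_high[:, None], [[hi, lo]], [[lo, hi]]).astype(float)
        scnt = np.full((n, 2), (hi + lo) / 2.0)
        step = fert - scnt
        oe = np.where(
            (outcome == "rescued")[:, None], fert,
            np.where((outcome == "repaired_only")[:, None],
                     scnt + 0.20 * step, scnt - 0.30 * step),
        )

        def noisy(center: np.ndarray) -> np.ndarray:
            if cfg.rescue_signal_sd == 0:
                return center.copy()
            reps = rng.normal(
                center[None, :, :],
                cfg.rescue_signal_sd,
                size=(cfg.n_replicates, n, 2),
            )
            return reps.mean(axis=0)

        signals = {"fertilized": noisy(fert), "SCNT": noisy(scnt), "OE": noisy(oe)}
        manifest = TruthManifest(domain_outcome=outcome)
        return signals, manifest

    def domain_intervals(self) -> IntervalSet:
        """Synthetic domain coordinates (5-kb regions on chr1/chr2)."""
        cfg = self.cfg
        out = []
        per_chrom = int(np.ceil(cfg.n_domains / cfg.n_chroms))
        gap = max(cfg.chrom_len // (per_chrom + 1), 10_000)
        i = 0
        for c in range(cfg.n_chroms):
            for j in range(per_chrom):
                if i >= cfg.n_domains:
                    break
                start = j * gap
                out.append(GenomicInterval(f"chr{c + 1}", start, start + 5_000))
                i += 1
        return IntervalSet(out, sorted_flag=True)

    # -- TF sites -------------------------------------------------------

    def simulate_tf_sites(
        self,
        fert_specific: IntervalSet,
        scnt_specific: IntervalSet,
    ):
        """Per-factor binding-site sets with planted enrichment.

        Enriched factors hit fertilized-specific regions at
        ``tf_rate_high`` and SCNT-specific regions at ``tf_rate_low``;
        null factors hit both at ``tf_rate_low``.  A hit drops a 200-bp
        site at the region midpoint (guaranteeing reciprocal-50% overlap
        of the site).
        """
        if not len(fert_specific) or not len(scnt_specific):
            raise ValueError("region sets must be non-empty")
        cfg = self.cfg
        rng = cfg.rng("tf_sites")
        enriched = np.zeros(cfg.n_factors, dtype=bool)
        enriched[: cfg.n_enriched_factors] = True

        def sites_for(regions: IntervalSet, rate: float) -> list[GenomicInterval]:
            hits = rng.random(len(regions)) < rate
            out = []
            for r, h in zip(regions, hits):
                if h:
                    mid = (r.start + r.end) // 2
                    out.append(GenomicInterval(r.chrom, max(0, mid - 100), mid + 100))
            return out

        tf_sites = {}
        for f in range(cfg.n_factors):
            name = f"TF{f:02d}"
            r_f = cfg.tf_rate_high if enriched[f] else cfg.tf_rate_low
            ivs = sites_for(fert_specific, r_f) + sites_for(
                scnt_specific, cfg.tf_rate_low
            )
            tf_sites[name] = merge_intervals(IntervalSet(ivs))
        manifest = TruthManifest(tf_enriched=enriched)
        return tf_sites, manifest
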