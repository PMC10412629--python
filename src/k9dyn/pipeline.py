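"""End-to-end orchestration over the synthetic cohort.

Runs every analysis stage in dependency order — signal simulation,
presence calling, transition and reprogrammed/unreprogrammed
classification, the ZGA cascade and activation degrees, the lineage
rescue metric, TF-site enrichment and replicate QC — and collects
recovery metrics against the planted truth manifest into one report.
"""

from __future__ import annotations

import json
import time
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enrichment import replicate_qc, tf_enrichment
from .expression import classify_degree, classify_zga
from .intervals import IntervalSet, write_bed
from .lineage import (
    hierarchical_dendrogram,
    kmeans_domains,
    pca_select_domains,
    rescue_fractions,
    rescue_metric,
)
from .reprogramming import (
    RPG_STAGES,
    classify_reprogramming,
    classify_transition,
    presence_from_signal,
    stage_overlap_fraction,
)
from .simulate import SimConfig, Simulator

log = logging.getLogger("k9dyn")

__all__ = ["run_pipeline"]


def _recovery(truth: np.ndarray, called) -> float:
    truth = np.asarray(truth, dtype=object)
    called = np.asarray(called, dtype=object)
    return float((truth == called).mean())


def run_pipeline(cfg: SimConfig, out_dir: str | Path | None = None) -> dict:
    """Simulate, analyse and report.  Identical cfg (incl. seed) gives
    identical outputs; returns the report dict (also written as JSON
    when ``out_dir`` is given)."""
    t0 = time.time()
    sim = Simulator(cfg)
    report: dict = {"config": _jsonable(asdict(cfg)), "version": __version__}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- epigenome: presence, transitions, rpg/unrpg -------------------
    t = time.time()
    presence_true, stage_peaks, table, manifest = sim.simulate_epigenome()
    presence_called = presence_from_signal(
        table, RPG_STAGES, "SCNT", sim.presence_threshold
    )
    rpg_called = [
        sorted(labels)[0] if len(labels) == 1 else "|".join(sorted(labels))
        for labels in classify_reprogramming(presence_called)
    ]
    rpg_truth = [
        "unrpg_14hpa|unrpg_2C" if c == "unrpg_2C" else c
        for c in manifest.window_class
    ]
    transition_called = classify_transition(presence_called, "CC", "6hpa")
    report["reprogramming"] = {
        "n_windows": presence_called.present.shape[0],
        "rpg_recovery": _recovery(rpg_truth, rpg_called),
        "transition_recovery": _recovery(
            manifest.window_transition, transition_called
        ),
        "stage_overlap_CC_vs_2C": stage_overlap_fraction(
            stage_peaks["2C"], stage_peaks["CC"]
        )
        if len(stage_peaks["2C"])
        else float("nan"),
    }
    log.info("reprogramming stage: %d windows in %.1fs",
             presence_called.present.shape[0], time.time() - t)
    if out is not None:
        df = presence_called.to_frame()
        df["rpg_label"] = rpg_called
        df["transition_CC_6hpa"] = transition_called
        df.to_csv(out / "windows.tsv", sep="\t", index=False)
        for stage, peaks in stage_peaks.items():
            write_bed(peaks, out / f"peaks_{stage}.bed")
        table.to_tsv(out / "window_signal.tsv")

    # --- replicate QC ---------------------------------------------------
    qc = replicate_qc(table)
    report["qc"] = {
        "n_pairs": int(len(qc)),
        "min_pearson_r": float(qc["pearson_r"].min()) if len(qc) else float("nan"),
        "n_flagged": int(qc["flagged"].sum()) if len(qc) else 0,
    }
    if out is not None and len(qc):
        qc.to_csv(out / "replicate_qc.tsv", sep="\t", index=False)

    # --- expression: ZGA cascade and degrees ----------------------------
    t = time.time()
    expr_fert, expr_scnt, expr_manifest = sim.simulate_expression()
    calls = classify_zga(expr_fert)
    calls = classify_degree(calls, expr_fert, expr_scnt)
    activated = np.isin(expr_manifest.gene_class, ("minor_ZGA", "major_ZGA", "MGA"))
    correct_class = calls["zga_class"].to_numpy() == expr_manifest.gene_class
    report["zga"] = {
        "n_genes": len(calls),
        "counts": calls["zga_class"].value_counts().to_dict(),
        "class_recovery": float(np.mean(correct_class)),
        "activated_class_recovery": float(np.mean(correct_class[activated])),
        "degree_recovery": _recovery(
            expr_manifest.gene_degree[activated],
            calls["degree"].to_numpy()[activated],
        ),
    }
    extreme = activated & np.isin(expr_manifest.gene_degree, ("restricted", "full"))
    report["zga"]["degree_recovery_restricted_full"] = _recovery(
        expr_manifest.gene_degree[extreme], calls["degree"].to_numpy()[extreme]
    )
    log.info("zga stage: %d genes in %.1fs", len(calls), time.time() - t)
    if out is not None:
        calls.to_csv(out / "zga_calls.tsv", sep="\t")

    # --- lineage: PCA + k-means + rescue --------------------------------
    t = time.time()
    signals, rescue_manifest = sim.simulate_rescue()
    domain_matrix = np.column_stack(
        [signals["fertilized"], signals["SCNT"]]
    )  # fert-ICM fert-TE scnt-ICM scnt-TE
    pca = pca_select_domains(domain_matrix)
    kmeans_input = domain_matrix[pca.selected] if pca.selected.any() else domain_matrix
    labels = kmeans_domains(
        kmeans_input, k=min(7, len(kmeans_input)), seed=cfg.seed
    )
    records = rescue_metric(signals["fertilized"], signals["SCNT"], signals["OE"])
    repaired_frac, rescued_frac = rescue_fractions(records)
    truth_rep = np.isin(rescue_manifest.domain_outcome, ("rescued", "repaired_only"))
    truth_res = rescue_manifest.domain_outcome == "rescued"
    sample_labels = ["fert_ICM", "fert_TE", "SCNT_ICM", "SCNT_TE"]
    _, newick = hierarchical_dendrogram(domain_matrix, sample_labels)
    report["lineage"] = {
        "n_domains": int(len(records)),
        "n_selected": int(pca.selected.sum()),
        "n_clusters": int(len(np.unique(labels))),
        "repaired_fraction": repaired_frac,
        "rescued_fraction": rescued_frac,
        "planted_repaired_fraction": float(truth_rep.mean()),
        "planted_rescued_fraction": float(truth_res.mean()),
        "repaired_recovery": _recovery(truth_rep, records["repaired"].to_numpy()),
        "rescued_recovery": _recovery(truth_res, records["rescued"].to_numpy()),
    }
    log.info("lineage stage: %d domains in %.1fs", len(records), time.time() - t)
    if out is not None:
        records.to_csv(out / "rescue.tsv", sep="\t", index=False)
        (out / "dendrogram.nwk").write_text(newick + "\n")

    # --- TF enrichment ---------------------------------------------------
    t = time.time()
    domains = sim.domain_intervals()
    half = len(domains) // 2
    fert_specific = IntervalSet(domains[:half], sorted_flag=True)
    scnt_specific = IntervalSet(domains[half:], sorted_flag=True)
    tf_sites, tf_manifest = sim.simulate_tf_sites(fert_specific, scnt_specific)
    enr = tf_enrichment(tf_sites, fert_specific, scnt_specific)
    enriched_q = enr["q"].to_numpy()[tf_manifest.tf_enriched]
    null_q = enr["q"].to_numpy()[~tf_manifest.tf_enriched]
    report["enrichment"] = {
        "n_factors": int(len(enr)),
        "enriched_max_q": float(enriched_q.max()),
        "enriched_all_significant": bool((enriched_q < 0.01).all()),
        "null_frac_q05": float((null_q < 0.05).mean()),
    }
    log.info("enrichment stage: %d factors in %.1fs", len(enr), time.time() - t)
    if out is not None:
        enr.to_csv(out / "tf_enrichment.tsv", sep="\t")

    report["wall_time_s"] = round(time.time() - t0, 2)
    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        manifest_all = {
            **manifest.to_dict(),
            **expr_manifest.to_dict(),
            **rescue_manifest.to_dict(),
            **tf_manifest.to_dict(),
        }
        (out / "truth_manifest.json").write_text(json.dumps(manifest_all))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
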