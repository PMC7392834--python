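"""End-to-end orchestration: scan -> thresholds -> annotate -> hotspots ->
overlap -> edge orienting, with a JSON run manifest."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .annotate import build_records, records_to_frame, summarize_counts
from .causality import TraitQtl, run_overlap_causality
from .datatypes import CrossData
from .hotspots import find_hotspots
from .linkage import genotype_probs
from .preprocess import remove_outliers
from .scan import (
    call_peaks,
    cis_permutation_thresholds,
    estimate_effects,
    peak_prob_triples,
    permutation_thresholds,
    probeset_windows,
    scan_all,
    ThresholdSet,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the analysis, defaulted to the study design values."""

    output_dir: str = "results"
    step_cm: float = 1.0
    error_prob: float = 1e-4
    map_function: str = "haldane"
    outlier_p: float = 1e-6
    outlier_max_removed: int = 2
    n_perm: int = 1000
    n_probesets: int = 1000
    iterations: int = 10
    suggestive_pct: float = 80.0
    significant_pct: float = 95.0
    cis_half_window_cm: float = 50.0
    lod_drop: float = 1.8
    hotspot_n_perm: int = 1000
    hotspot_min_eqtl: int = 10
    hotspot_percentile: float = 95.0
    hotspot_trans_only: bool = False
    r_cutoff: float = 0.7
    leo_single_threshold: float = 1.0
    leo_oca_threshold: float = 0.3
    overlap_alpha: float = 0.05
    seed: int = 0
    thresholds: ThresholdSet | None = None   # precomputed override


def run_pipeline(cross: CrossData, config: PipelineConfig,
                 trait_qtls: list[TraitQtl] | None = None) -> dict:
    """Run the full analysis; writes tables and a manifest to the output dir.

    Returns a dict with the in-memory results of every stage
    (records, summary, hotspots, overlap tests, leo results, manifest).
    """
    t_start = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"parameters": {k: v for k, v in asdict(config).items()
                                     if k != "thresholds"},
                      "seed": config.seed, "stages": {}}

    def stage(name: str):
        manifest["stages"][name] = {"t": round(time.time() - t_start, 2)}
        log.info("stage %s", name)

    stage("preprocess")
    expression = remove_outliers(cross.expression, config.outlier_p,
                                 config.outlier_max_removed)
    Y = expression.values.to_numpy(float)
    ids = expression.probesets

    stage("genotype_probs")
    grid = genotype_probs(cross.genotypes, cross.gmap, step_cm=config.step_cm,
                          error_prob=config.error_prob, map_function=config.map_function)

    stage("thresholds")
    windows = probeset_windows(cross.annotation, cross.gmap, config.cis_half_window_cm)
    if config.thresholds is not None:
        thresholds = config.thresholds
    else:
        thresholds = permutation_thresholds(
            Y, ids, grid, cross.covariates, n_perm=config.n_perm,
            n_probesets=config.n_probesets, iterations=config.iterations,
            seed=rng, suggestive_pct=config.suggestive_pct,
            significant_pct=config.significant_pct)
        if any(w is not None for w in windows.values()):
            thresholds = cis_permutation_thresholds(
                Y, ids, grid, cross.covariates, windows, thresholds,
                n_perm=config.n_perm, n_probesets=config.n_probesets,
                iterations=config.iterations, seed=rng,
                suggestive_pct=config.suggestive_pct,
                significant_pct=config.significant_pct)
    manifest["thresholds"] = {
        "trans_suggestive": thresholds.trans_suggestive,
        "trans_significant": thresholds.trans_significant,
        "cis_suggestive": thresholds.cis_suggestive,
        "cis_significant": thresholds.cis_significant,
    }

    stage("scan")
    scan = scan_all(Y, ids, grid, cross.covariates)

    stage("peaks")
    peaks = []
    for pid in ids:
        curve = scan.curve(pid)
        for pk in call_peaks(curve, thresholds, windows.get(pid), cross.gmap,
                             drop=config.lod_drop):
            y = expression.values.loc[pid].to_numpy(float)
            eff = estimate_effects(
                y, peak_prob_triples(grid, pk.chrom, pk.peak_cm),
                cross.covariates, pk.lod, sex_model=pk.model == "sex-interactive")
            for k, v in eff.items():
                setattr(pk, k, v)
            peaks.append(pk)
    records = build_records(peaks, cross.annotation, cross.gmap,
                            config.cis_half_window_cm)
    aio.write_eqtl_table(records, outdir / "eqtl.tsv")
    summary = summarize_counts(records)
    manifest["summary"] = summary

    stage("hotspots")
    hotspots = find_hotspots(records, cross.gmap, n_perm=config.hotspot_n_perm,
                             percentile=config.hotspot_percentile,
                             min_eqtl=config.hotspot_min_eqtl, seed=rng,
                             trans_only=config.hotspot_trans_only)
    aio.write_hotspot_table(hotspots, outdir / "hotspots.tsv")
    manifest["n_hotspots"] = len(hotspots)

    tests, leos = [], []
    if trait_qtls:
        stage("overlap_causality")
        tests, leos = run_overlap_causality(
            records, trait_qtls, cross, grid, r_cutoff=config.r_cutoff,
            alpha=config.overlap_alpha,
            leo_single_threshold=config.leo_single_threshold,
            leo_oca_threshold=config.leo_oca_threshold)
        pd.DataFrame([{
            "trait": t.trait, "probeset": t.probeset,
            "qtl_ci": f"{t.qtl_ci[0]}@{t.qtl_ci[1]:g}-{t.qtl_ci[2]:g}",
            "eqtl_ci": f"{t.eqtl_ci[0]}@{t.eqtl_ci[1]:g}-{t.eqtl_ci[2]:g}",
            "raw_p": t.raw_p, "adjusted_p": t.adjusted_p, "t_value": t.t_value,
            "adj_r_squared": t.adj_r_squared, "m_tests": t.n_effective_tests,
        } for t in tests]).to_csv(outdir / "overlap_tests.tsv", sep="\t", index=False)
        aio.write_leo_table(leos, outdir / "leo.tsv")
        manifest["n_overlap_tests"] = len(tests)
        manifest["n_suggestive_overlaps"] = sum(t.raw_p < config.overlap_alpha for t in tests)
        manifest["n_significant_overlaps"] = sum(t.adjusted_p < config.overlap_alpha for t in tests)

    manifest["row_counts"] = {"eqtl": len(records), "hotspots": len(hotspots),
                              "overlap_tests": len(tests), "leo": len(leos)}
    manifest["elapsed_s"] = round(time.time() - t_start, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {"records": records, "records_frame": records_to_frame(records),
            "summary": summary, "thresholds": thresholds, "hotspots": hotspots,
            "overlap_tests": tests, "leo_results": leos, "scan": scan,
            "grid": grid, "manifest": manifest}
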