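"""End-to-end pipeline: simulate (or load), analyze, report.

``run_demo`` executes every stage on a simulated cohort and writes
schema-stable tables plus a machine-readable ``summary.json`` recording
the software version, a config hash, the seed, and the headline numbers
of each stage. Identical (config, seed) runs produce identical
summaries. No stage touches the network.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .contrast import ContrastSpec, group_contrast
from .expression import (
    ExpressionMatrix,
    extreme_variation_sets,
    filter_expressed,
    lps_response,
    max_min_ratio,
    sex_ratio_analysis,
)
from .network import cluster_profiles, cluster_table, correlation_matrix, mcl, \
    threshold_graph, write_edge_list
from .segregation import CrossSpec, expected_f2_genotype_probs, simulate_f2_genotype_freqs
from .simulate import simulate_cohort
from .variants import breed_frequency_contrast, classify_consequences, \
    consequence_tally, filter_panel, genotype_pca, table_summary

log = logging.getLogger("sibxpress")


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_demo(config: PipelineConfig, outdir: str | Path,
             segregation_replicates: int = 50_000) -> dict:
    """Simulate the full design and run every analysis stage on it."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.simulation.seed,
    }
    try:
        t0 = _stage("simulate")
        cohort = simulate_cohort(config.simulation)
        cohort.panel.to_vcf(out / "cohort.vcf")
        cohort.expression.to_tsv(out / "cohort")
        summary["simulate"] = {
            "n_individuals": len(cohort.pedigree),
            "n_f2_families": int(cohort.pedigree.generation(2)["family"].nunique()),
            "n_samples": cohort.expression.values.shape[1],
            "n_genes": cohort.expression.values.shape[0],
            "n_null_genes": int(len(cohort.truth.null_genes)),
            "seconds": round(time.perf_counter() - t0, 2),
        }

        t0 = _stage("variants")
        founders = cohort.founders
        filt = filter_panel(founders, config.filtration)
        cls = classify_consequences(filt.panel)
        tally = consequence_tally(cls)
        contrast_tbl = breed_frequency_contrast(filt.panel)
        pca = genotype_pca(filt.panel, n_components=2)
        table_summary(filt.panel).to_csv(out / "variant_summary.tsv", sep="\t", index=False)
        breed = filt.panel.samples["breed"].to_numpy()
        pc1 = pca["PC1"].to_numpy()
        separated = (pc1[breed == "broiler"].min() > pc1[breed == "layer"].max()
                     or pc1[breed == "layer"].min() > pc1[breed == "broiler"].max())
        summary["variants"] = {
            "n_in": filt.n_in,
            "n_pass": filt.n_out,
            "high_impact": int(tally.get("HIGH_total", 0)),
            "near_fixed_opposite": int(contrast_tbl["near_fixed_opposite"].sum()),
            "pc1_separates_breeds": bool(separated),
            "seconds": round(time.perf_counter() - t0, 2),
        }

        t0 = _stage("segregation")
        het_cross = CrossSpec(("het", "hom_ref"))
        fixed_cross = CrossSpec(("hom_alt", "hom_ref"))
        sim = simulate_f2_genotype_freqs(het_cross, segregation_replicates,
                                         config.simulation.seed)
        summary["segregation"] = {
            "analytic_hom_alt_founder_het": float(
                expected_f2_genotype_probs(het_cross)["hom_alt"]),  # = 1/16
            "analytic_hom_alt_breed_fixed": float(
                expected_f2_genotype_probs(fixed_cross)["hom_alt"]),  # = 1/4
            "simulated_hom_alt_founder_het": sim.frequencies["hom_alt"],
            "within_3se": sim.within(3.0),
            "seconds": round(time.perf_counter() - t0, 2),
        }

        t0 = _stage("expression_stats")
        expr = cohort.expression
        control = expr.stratum("control")
        lps = expr.stratum("LPS")
        expressed = filter_expressed(control, config.stats.min_max_tpm)
        mm = max_min_ratio(control.subset_genes(expressed))
        mm.to_csv(out / "max_min_control.tsv", sep="\t")
        venn = extreme_variation_sets(control, lps, config.stats.extreme_max,
                                      config.stats.extreme_min)
        sex = sex_ratio_analysis(control, "Z", config.stats.min_max_tpm,
                                 config.stats.bootstrap_reps,
                                 seed=config.simulation.seed)
        lpsr = lps_response(expr, config.stats.min_max_tpm, config.stats.lps_fold,
                            config.stats.pseudocount)
        summary["expression_stats"] = {
            "n_expressed_control": int(len(expressed)),
            "venn": venn.counts(),
            "venn_pct": venn.percentages(),
            "z_mf_median_ratio": sex.median_ratio,
            "lps_induced": lpsr.n_induced,
            "lps_repressed": lpsr.n_repressed,
            "seconds": round(time.perf_counter() - t0, 2),
        }

        t0 = _stage("network")
        corr = correlation_matrix(expr.subset_genes(filter_expressed(expr)),
                                  mode="gene", log_transform=True)
        graph = threshold_graph(corr, config.network.r_min)
        clusters = mcl(graph, config.network.inflation, config.network.expansion,
                       config.network.prune_threshold, config.network.max_iter,
                       config.network.tol, config.network.binarize,
                       config.network.min_cluster_size)
        profiles = cluster_profiles(clusters, expr)
        cluster_table(clusters, profiles).to_csv(out / "clusters.tsv", sep="\t",
                                                 index=False)
        write_edge_list(graph, str(out / "edges.tsv"))
        planted = set(cohort.truth.genes.index[
            cohort.truth.genes["module"] == "lps_trans_target"])
        capture = 0.0
        best_k = 0
        for k, members in enumerate(clusters.clusters, start=1):
            frac = len(planted & set(members)) / max(len(planted), 1)
            if frac > capture:
                capture, best_k = frac, k
        summary["network"] = {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "n_clusters": len(clusters.clusters),
            "converged": clusters.converged,
            "trans_module_capture": round(capture, 4),
            "trans_module_cluster_trend": (
                str(profiles.trends.get(best_k, "")) if best_k else ""),
            "seconds": round(time.perf_counter() - t0, 2),
        }

        t0 = _stage("contrast")
        family = sorted(set(expr.samples["family"]))[0]
        spec = ContrastSpec(family, "control", min_mean=config.contrast.min_mean,
                            ratio_hi=config.contrast.ratio_hi,
                            ratio_lo=config.contrast.ratio_lo)
        res = group_contrast(expr, spec)
        (out / "contrast_up.txt").write_text("\n".join(res.up) + "\n")
        (out / "contrast_down.txt").write_text("\n".join(res.down) + "\n")
        summary["contrast"] = {
            "family": family,
            "n_up": len(res.up),
            "n_down": len(res.down),
            "seconds": round(time.perf_counter() - t0, 2),
        }
    finally:
        log.removeHandler(handler)
        handler.close()

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
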