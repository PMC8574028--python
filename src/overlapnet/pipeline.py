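"""End-to-end orchestration of the five pipeline stages.

(A) normalize, average, filter, log fold changes →
(B) similarity + soft threshold with scale-free beta selection →
(C) cutoff, binarize, hierarchical link clustering → overlapping modules →
(D) module eigengenes + per-trait cross-validated LASSO →
(E) DEG flags, Fisher enrichment, gene report.

``run_all`` is deterministic for a fixed config, inputs and seed; the run
summary records the gene-count funnel n0 ≥ n1 ≥ n2 ≥ affiliated ≥ selected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from . import association, enrichment, hlc, network, preprocess
from .config import PipelineConfig
from .data import CountMatrix, GeneReport, LfcMatrix, NormalizedMatrix, PhenoLfcTable, PhenotypeTable
from .io import write_outputs

logger = logging.getLogger("overlapnet")


@dataclass
class PipelineResult:
    config: PipelineConfig
    size_factors: np.ndarray
    d1: NormalizedMatrix
    d2: NormalizedMatrix
    d2_filtered: NormalizedMatrix
    l0: LfcMatrix
    l1: LfcMatrix
    pheno_lfc: PhenoLfcTable
    similarity: network.SimilarityMatrix
    beta_selection: network.BetaSelection
    adjacency: network.WeightedAdjacency
    cutoff_scan: network.CutoffScan
    cutoff: float
    network: network.BinaryNetwork
    link_partition: hlc.LinkPartition
    affiliation: hlc.AffiliationMatrix
    eigengenes: association.EigengeneMatrix
    fits: list[association.LassoFit]
    selection: association.SelectionResult
    deg: dict[str, bool]
    report: GeneReport
    summary: dict


def _summary(result_parts: dict) -> dict:
    """Assemble the run summary with deterministic key order and plain types."""
    return json.loads(json.dumps(result_parts, sort_keys=True))


def run_all(
    counts: CountMatrix,
    phenotypes: PhenotypeTable,
    config: PipelineConfig | None = None,
    known_genes: Iterable[str] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute stages (A)–(E) and optionally persist every artifact."""
    config = config or PipelineConfig()
    params = config.preprocess.filter_params()

    logger.info("[A] normalizing %d genes × %d samples", counts.n_genes, len(counts.samples.sample_ids))
    sf = preprocess.size_factors(counts)
    d1, d2 = preprocess.normalize_and_average(counts, sf)
    d2_filtered = preprocess.filter_expression(d2, params)
    l0 = preprocess.lfc_expression(d2_filtered, pseudocount=config.preprocess.pseudocount)
    l1 = preprocess.filter_lfc(l0, params)
    pheno_lfc = preprocess.lfc_phenotypes(
        phenotypes, pseudocount=config.preprocess.phenotype_pseudocount
    )
    logger.info("[A] gene funnel: %d → %d → %d", counts.n_genes, l0.n_genes, l1.n_genes)

    logger.info("[B] building similarity matrix over %d genes", l1.n_genes)
    sim = network.similarity_matrix(l1)
    if config.network.beta_override is not None:
        beta = int(config.network.beta_override)
        try:
            fit = network.scale_free_r2(network.soft_power(sim, beta), n_bins=config.network.n_bins)
        except ValueError:  # degenerate distribution; keep the override anyway
            fit = network.ScaleFreeFit(
                beta=beta, r_squared=float("nan"), slope=float("nan"),
                bin_centers=np.array([]), bin_frequencies=np.array([]),
            )
        beta_sel = network.BetaSelection(beta=beta, fit=fit, warning=False, scan=[fit])
        logger.info("[B] beta=%d (config override; scale-free R²=%.3f)", beta, fit.r_squared)
    else:
        beta_sel = network.select_beta(
            sim,
            r2_min=config.network.r2_min,
            beta_grid=config.network.beta_grid,
            n_bins=config.network.n_bins,
        )
        if beta_sel.warning:
            logger.warning(
                "[B] no beta reached R² ≥ %.2f; using argmax beta=%d (R²=%.3f)",
                config.network.r2_min, beta_sel.beta, beta_sel.fit.r_squared,
            )
        logger.info("[B] beta=%d (R²=%.3f)", beta_sel.beta, beta_sel.fit.r_squared)
    adjacency = network.soft_power(sim, beta_sel.beta)

    if config.network.cutoff_scale == "similarity":
        scan_target = network.WeightedAdjacency(
            gene_ids=adjacency.gene_ids, beta=1, values=np.asarray(sim.values)
        )
    else:
        scan_target = adjacency
    scan = network.threshold_scan(scan_target, config.network.cutoff_grid)
    cutoff = network.select_cutoff(scan, override=config.network.cutoff_override)
    net = network.binarize(scan_target, cutoff)
    logger.info("[C] cutoff=%.3g → %d nodes, %d edges", cutoff, net.n_nodes, net.n_edges)

    graph = hlc.LinkGraph.from_binary_network(net)
    partition = hlc.cut_at_max_density(graph)
    aff = hlc.affiliation(graph, partition, min_module_size=config.hlc.min_module_size)
    logger.info(
        "[C] link clustering: D=%.4f, %d modules, %d affiliated genes",
        partition.density, aff.n_modules, len(aff.affiliated_genes()),
    )

    logger.info("[D] eigengenes + LASSO over %d modules × %d traits", aff.n_modules, len(pheno_lfc.trait_names))
    eig = association.eigengene_matrix(l1, aff)
    fits = association.fit_all_traits(
        eig,
        pheno_lfc,
        k_folds=min(config.lasso.k_folds, len(pheno_lfc.genotype_ids)),
        seed=config.seed,
        n_lambda=config.lasso.n_lambda,
        lambda_min_ratio=config.lasso.lambda_min_ratio,
        rule=config.lasso.rule,
    )
    selection = association.select_modules(fits, aff)

    deg = enrichment.deg_flags(l1, threshold=config.enrichment.deg_threshold)
    report = enrichment.build_report(selection, aff, deg, l1, known_genes=known_genes)
    logger.info(
        "[E] %d selected genes, %d DEG, Fisher p=%.3g",
        report.summary["n_selected"], report.summary["deg_selected"], report.summary["deg_fisher_p"],
    )

    summary = _summary(
        {
            "seed": config.seed,
            "funnel": {
                "n0_input_genes": counts.n_genes,
                "n1_expression_filtered": l0.n_genes,
                "n2_lfc_filtered": l1.n_genes,
                "network_nodes": net.n_nodes,
                "affiliated_genes": len(aff.affiliated_genes()),
                "selected_genes": report.summary["n_selected"],
            },
            "beta": beta_sel.beta,
            "beta_r_squared": beta_sel.fit.r_squared,
            "beta_warning": beta_sel.warning,
            "cutoff": cutoff,
            "network_edges": net.n_edges,
            "n_modules": aff.n_modules,
            "partition_density": partition.density,
            "lambda_per_trait": {f.trait_name: f.chosen_lambda for f in fits},
            "modules_per_trait": {
                t: mods for t, mods in selection.modules_per_trait.items()
            },
            "enrichment": report.summary,
        }
    )

    result = PipelineResult(
        config=config,
        size_factors=sf,
        d1=d1,
        d2=d2,
        d2_filtered=d2_filtered,
        l0=l0,
        l1=l1,
        pheno_lfc=pheno_lfc,
        similarity=sim,
        beta_selection=beta_sel,
        adjacency=adjacency,
        cutoff_scan=scan,
        cutoff=cutoff,
        network=net,
        link_partition=partition,
        affiliation=aff,
        eigengenes=eig,
        fits=fits,
        selection=selection,
        deg=deg,
        report=report,
        summary=summary,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        manifest = write_outputs(result, out_dir)
        summary_path = out_dir / "run_summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        manifest["run_summary"] = str(summary_path)
        result.summary["manifest"] = manifest
    return result
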