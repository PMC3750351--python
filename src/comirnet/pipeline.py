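"""End-to-end orchestration of the integrative analysis.

Chains the stages in the order the method runs: between-chip normalization,
outlier screening, systematic-effect adjustment, co-expression network
construction for mRNA and miRNA, module-trait association, all-pairs
miRNA-mRNA correlation with FDR control, sequence-based target prediction
for the surviving candidate pairs, the three-criterion regulatory-link
filter, and per-module term enrichment.

Target prediction runs only on pairs that already pass the module and
negative-correlation criteria: prediction evidence is the confirmatory third
criterion, so scanning the full miRNA x transcript grid would change nothing
downstream while dominating runtime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import coexpression as cx
from . import enrichment as enr
from . import module_trait as mt
from . import pair_integration as pi
from . import preprocess as pp
from . import target_prediction as tp
from .io_formats import (AnnotationMap, CovariateTable, ExpressionMatrix,
                         PhenotypeTable, RunConfig, SequenceSet)


@dataclass
class PipelineResult:
    config: RunConfig
    removed_samples: list[str]
    mrna_residuals: ExpressionMatrix
    mirna_residuals: ExpressionMatrix
    adjusted_phenotypes: PhenotypeTable
    mrna_scan: cx.SoftThresholdScan
    mrna_modules: cx.ModuleDecomposition
    mirna_scan: cx.SoftThresholdScan | None
    mirna_modules: cx.ModuleDecomposition | None
    mrna_trait_matrix: mt.ModuleTraitMatrix
    mirna_trait_matrix: mt.ModuleTraitMatrix | None
    trait_modules: mt.TraitAssociatedModules
    pair_table: pi.PairCorrelationTable
    negative_pairs: pi.PairCorrelationTable
    predictions: pd.DataFrame
    edges_probe_level: pd.DataFrame
    edges_family_level: pd.DataFrame
    edges_confirmed: pd.DataFrame
    enrichment_report: pd.DataFrame | None = None


def run_pipeline(mrna: ExpressionMatrix, mirna: ExpressionMatrix,
                 phenotypes: PhenotypeTable, covariates: CovariateTable,
                 mirna_seqs: SequenceSet | None = None,
                 utr_seqs: SequenceSet | None = None,
                 annotation: AnnotationMap | None = None,
                 families: dict[str, str] | None = None,
                 config: RunConfig | None = None,
                 design: pp.DesignSpec | None = None,
                 mirna_network: bool = True) -> PipelineResult:
    """Run every stage on in-memory inputs and return all intermediates."""
    cfg = config or RunConfig()
    design = design or pp.DesignSpec()
    families = families or {}

    if cfg.log2_transform:
        import numpy as np
        mrna = ExpressionMatrix(np.log2(mrna.data + 1.0), layer_tag="raw")
        mirna = ExpressionMatrix(np.log2(mirna.data + 1.0), layer_tag="raw")
    if cfg.quantile_normalize_mirna:
        mirna = pp.quantile_normalize(mirna)

    mrna, removed = pp.remove_outlier_samples(mrna, cfg.outlier_cut_z)
    kept = mrna.sample_ids
    mirna = mirna.subset_samples(kept)
    phenotypes = PhenotypeTable(phenotypes.data.loc[kept])
    covariates = CovariateTable(covariates.data.loc[kept],
                                categorical=covariates.categorical,
                                numeric=covariates.numeric)

    mrna_res = pp.adjust_for_effects(mrna, covariates, design,
                                     mode=cfg.adjust_mode,
                                     random_effect=cfg.random_effect)
    mirna_res = pp.adjust_for_effects(mirna, covariates, design,
                                      mode=cfg.adjust_mode,
                                      random_effect=cfg.random_effect)
    ph_res = pp.adjust_phenotypes(phenotypes, covariates, design,
                                  mode=cfg.adjust_mode,
                                  random_effect=cfg.random_effect)

    mrna_scan, mrna_mod = cx.build_network(
        mrna_res, cfg.min_module_size_mrna, cfg.beta_grid,
        cfg.scale_free_r2_target, cfg.n_connectivity_bins, cfg.signed_mode,
        gap_lower_quantile=cfg.gap_lower_quantile,
        merge_threshold=cfg.merge_threshold, phenotypes=ph_res)
    mirna_scan = mirna_mod = mirna_mtm = None
    if mirna_network:
        mirna_scan, mirna_mod = cx.build_network(
            mirna_res, cfg.min_module_size_mirna, cfg.beta_grid,
            cfg.scale_free_r2_target, cfg.n_connectivity_bins, cfg.signed_mode,
            gap_lower_quantile=cfg.gap_lower_quantile,
            merge_threshold=cfg.merge_threshold, phenotypes=ph_res)

    mrna_mtm = mt.module_trait_correlation(mrna_mod.eigengenes, ph_res)
    if mirna_mod is not None and len(mirna_mod.modules):
        mirna_mtm = mt.module_trait_correlation(mirna_mod.eigengenes, ph_res)
    trait_mods = mt.select_trait_modules(mrna_mtm, cfg.trait_alpha)

    pairs = pi.all_pairs_correlation(mirna_res, mrna_res)
    pairs = pi.attach_qvalues(pairs, cfg.qvalue_method, cfg.lambda_grid)
    neg = pi.filter_negative_pairs(pairs, cfg.pair_fdr)

    predictions = pd.DataFrame(columns=["miRNA", "target", "site_types",
                                        "best_mfe", "seed_hit", "duplex_hit",
                                        "both"])
    if mirna_seqs is not None and utr_seqs is not None and len(neg.records):
        selected = set(trait_mods.modules)
        labels = mrna_mod.labels
        cand = [(r.miRNA, r.mRNA) for r in neg.records.itertuples(index=False)
                if labels.get(r.mRNA, cx.GREY) in selected
                and r.miRNA in mirna_seqs.sequences and r.mRNA in utr_seqs.sequences]
        cand = sorted(set(cand))
        if cand:
            predictions = tp.predict_targets(
                mirna_seqs, utr_seqs, tp.EnergyModel(), cfg.energy_cutoff,
                cfg.max_loop, cfg.hits_per_target, pairs=cand)

    probe_edges, family_edges = pi.integrate(neg, mrna_mod, trait_mods,
                                             predictions, families)
    confirmed = pi.confirmed_subset(probe_edges)

    report = None
    if annotation is not None:
        report = enr.module_enrichment_report(
            mrna_mod, annotation, kappa_threshold=cfg.kappa_threshold)

    return PipelineResult(cfg, removed, mrna_res, mirna_res, ph_res,
                          mrna_scan, mrna_mod, mirna_scan, mirna_mod,
                          mrna_mtm, mirna_mtm, trait_mods, pairs, neg,
                          predictions, probe_edges, family_edges, confirmed,
                          report)
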