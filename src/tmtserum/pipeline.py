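"""End-to-end orchestrator: PSM table -> peptide matrix -> protein matrix ->
moderated differential abundance -> enrichment, with a stage report.

Stage order is fixed: PSM filters, impurity correction, median scaling,
reference ratios, peptide roll-up (assembly); then missingness filter,
iPCA imputation, quantile normalization, batch correction, unique-group
filter and protein roll-up (preprocessing); then the covariate-adjusted
moderated-t models at both levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assembly, diffexp, enrichment, preprocess
from .datamodel import (
    CHANNELS,
    ConfigurationError,
    FeatureMatrix,
    RunConfig,
    reference_channels,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Bundle of every stage output of one pipeline run."""

    peptide_matrix: FeatureMatrix
    protein_matrix: FeatureMatrix
    peptide_results: pd.DataFrame
    protein_results: pd.DataFrame
    peptide_thresholds: diffexp.DEThresholds
    protein_thresholds: diffexp.DEThresholds
    peptide_summary: dict
    protein_summary: dict
    enrichment: pd.DataFrame | None
    report: list = field(default_factory=list)


def _check_coverage(psm: pd.DataFrame, meta: pd.DataFrame) -> None:
    """Every (plex, channel) carrying data must map to a sample or the pool."""
    refs = reference_channels(meta)
    known = {(str(r["plex"]), r["channel"]) for _, r in meta.iterrows()}
    orphans = []
    for plex, block in psm.groupby("plex"):
        if str(plex) not in {str(p) for p in meta["plex"]}:
            orphans.append((str(plex), "<entire plex>"))
            continue
        for ch in CHANNELS:
            if block[ch].notna().any() and (str(plex), ch) not in known:
                orphans.append((str(plex), ch))
    if orphans:
        raise ConfigurationError(
            f"PSM data carries channels absent from the metadata: {orphans}"
        )
    _ = refs  # validated inside reference_channels via metadata


def run_pipeline(config: RunConfig, psm: pd.DataFrame, meta: pd.DataFrame,
                 annotations: dict | None = None,
                 impurity: pd.DataFrame | None = None) -> PipelineResult:
    """Run the full analysis and return every intermediate of interest.

    Deterministic: no stage draws random numbers, so two runs on the same
    inputs are bit-identical.
    """
    _check_coverage(psm, meta)
    report: list[dict] = []

    def record(phase, stage, n_in, n_out, **detail):
        entry = {"phase": phase, "stage": stage, "n_in": int(n_in),
                 "n_out": int(n_out), **detail}
        report.append(entry)
        log.info("%s/%s: %d -> %d %s", phase, stage, n_in, n_out, detail or "")

    # ---------------- assembly (7 stages) ----------------
    n0 = len(psm)
    step = assembly.filter_psms(psm, interference_threshold=100.0)
    record("assembly", "filter_nonredundant_annotated", n0, len(step))

    n0 = len(step)
    step = assembly.filter_psms(step, config.interference_threshold)
    record("assembly", "filter_isolation_interference", n0, len(step),
           threshold=config.interference_threshold)

    n0 = len(step)
    step = assembly.correct_impurities(
        step, impurity if impurity is not None else assembly.identity_impurity())
    record("assembly", "isotope_impurity_correction", n0, len(step))

    n0 = len(step)
    step = assembly.median_scale(step)
    record("assembly", "median_scaling", n0, len(step))

    step = assembly.compute_ratios(step, meta)
    record("assembly", "reference_ratios_log2", n0, len(step))

    pep = assembly.rollup_peptides(step)
    record("assembly", "peptide_rollup", len(step), pep.values.shape[0])
    record("assembly", "peptide_matrix", pep.values.shape[0],
           pep.values.shape[0], n_samples=pep.values.shape[1])

    # ---------------- preprocessing (5 stages) ----------------
    n0 = pep.values.shape[0]
    pep = preprocess.filter_missing(pep, meta, config.missing_fraction_threshold)
    if pep.values.shape[0] == 0:
        raise ValueError("peptide matrix is empty after the missingness filter")
    pep = preprocess.impute_ipca(pep, config.ipca_components,
                                 tol=config.ipca_tol,
                                 max_iter=config.ipca_max_iter)
    record("preprocess", "missingness_filter_and_imputation",
           n0, pep.values.shape[0],
           threshold=config.missing_fraction_threshold)

    pep = preprocess.quantile_normalize(pep)
    record("preprocess", "quantile_normalization",
           pep.values.shape[0], pep.values.shape[0])

    pep = preprocess.remove_batch(pep, meta)
    record("preprocess", "batch_correction",
           pep.values.shape[0], pep.values.shape[0],
           factors=["plex", "centre"])

    n0 = pep.values.shape[0]
    pep = preprocess.filter_unique_groups(pep)
    record("preprocess", "unique_protein_group_filter", n0,
           pep.values.shape[0])
    if pep.values.shape[0] == 0:
        raise ValueError("peptide matrix is empty after the unique-group filter")

    prot = preprocess.rollup_proteins(pep, config.trim_fraction)
    record("preprocess", "protein_rollup", pep.values.shape[0],
           prot.values.shape[0], trim=config.trim_fraction)

    # ---------------- statistics ----------------
    pep_design = diffexp.DesignSpec(covariates=diffexp.PEPTIDE_COVARIATES)
    pep_fit = diffexp.moderate(diffexp.fit_models(pep, meta, pep_design))
    pep_thr = diffexp.compute_fct(pep, config.fct_multiplier,
                                  alpha=config.peptide_alpha)
    pep_res = diffexp.classify(pep_fit, pep_thr)
    record("statistics", "peptide_models", pep.values.shape[0],
           len(pep_res), fct=pep_thr.fct_rounded, alpha=pep_thr.alpha)

    prot_design = diffexp.DesignSpec(covariates=diffexp.PROTEIN_COVARIATES)
    prot_fit = diffexp.moderate(diffexp.fit_models(prot, meta, prot_design))
    prot_thr = diffexp.compute_fct(prot, config.fct_multiplier,
                                   alpha=config.protein_alpha,
                                   fdr=config.protein_fdr)
    prot_res = diffexp.classify(prot_fit, prot_thr)
    record("statistics", "protein_models", prot.values.shape[0],
           len(prot_res), fct=prot_thr.fct_rounded, alpha=prot_thr.alpha,
           fdr=config.protein_fdr)

    # ---------------- enrichment (peptide level) ----------------
    enr = None
    if annotations is not None:
        regulated_pep = pep_res.index[pep_res["class"] == "significant_and_fc"]
        background_pep = pep_res.index.difference(regulated_pep)
        reg_ids = enrichment.map_features_to_identifiers(regulated_pep, pep.groups)
        bg_ids = enrichment.map_features_to_identifiers(background_pep, pep.groups)
        bg_ids -= reg_ids  # an identifier with any regulated peptide counts as regulated
        enr = enrichment.fisher_enrich(
            reg_ids, bg_ids, annotations,
            min_matches=config.enrichment_min_matches,
            adjp_threshold=config.enrichment_adjp,
        )
        record("statistics", "functional_enrichment",
               len(reg_ids) + len(bg_ids), len(enr))

    return PipelineResult(
        peptide_matrix=pep, protein_matrix=prot,
        peptide_results=pep_res, protein_results=prot_res,
        peptide_thresholds=pep_thr, protein_thresholds=prot_thr,
        peptide_summary=diffexp.summarize_classes(pep_res),
        protein_summary=diffexp.summarize_classes(prot_res),
        enrichment=enr, report=report,
    )
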