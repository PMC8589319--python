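"""End-to-end orchestration: searched PSM tables to regulated-site resource.

Stage order: filter -> target-decoy FDR -> localization gate -> aggregate
to sites -> equal-loading normalization -> site-to-protein normalization ->
median centering -> differential statistics (permutation route and
moderated-t route) -> annotation -> abundance ranking -> copy numbers.
Every stage logs its input/output row counts; no record is dropped without
appearing in a report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .annotate import annotate_sites
from .psm import (
    FilterThresholds,
    aggregate_to_sites,
    filter_psms,
    target_decoy_fdr,
)
from .quantnorm import (
    equal_loading_normalize,
    median_center,
    normalize_site_to_protein,
    proteomic_ruler_copies,
    rank_site_abundance,
)
from .simulate import treated_channels
from .stats import PermutationConfig, benjamini_hochberg, moderated_t, permutation_fdr

logger = logging.getLogger("diglyq")


@dataclass
class AnalysisSettings:
    """Statistics and normalization settings for a pipeline run."""

    s0: float = 2.0
    fdr_level: float = 0.01
    n_permutations: int = 250
    seed: int = 0
    psm_fdr_level: float = 0.01
    thresholds: FilterThresholds = field(
        default_factory=lambda: FilterThresholds(digly_mode=True)
    )
    normalize_to_protein: bool = True
    ploidy: int = 2
    genome_size_bp: float = 2.7e9


@dataclass
class ResultBundle:
    site_matrix: pd.DataFrame
    normalized_log_matrix: pd.DataFrame
    permutation_results: pd.DataFrame
    moderated_results: pd.DataFrame
    annotated: Optional[pd.DataFrame]
    ranking: pd.DataFrame
    copy_numbers: Optional[pd.DataFrame]
    filter_report: object
    ambiguous_sites: pd.DataFrame
    manifest: Dict


def _log_stage(name: str, n_in: int, n_out: int) -> None:
    logger.info("stage %-22s in=%d out=%d", name, n_in, n_out)


def _reference_ratios(matrix: pd.DataFrame, ref_cols: Sequence[str]) -> pd.DataFrame:
    """Per-feature ratios to the mean of the reference (untreated) channels."""
    ref = matrix[list(ref_cols)].mean(axis=1)
    return matrix.div(ref.replace(0, np.nan), axis=0)


def run_analysis(
    psm_table: pd.DataFrame,
    protein_table: pd.DataFrame,
    annotation_table: Optional[pd.DataFrame],
    sequences: Mapping[str, str],
    channels: Sequence[str],
    group_labels: Sequence[str],
    settings: AnalysisSettings | None = None,
) -> ResultBundle:
    """Run the full quantitative analysis on in-memory tables.

    ``channels`` are the reporter columns present in both the PSM and
    protein tables; ``group_labels`` give each channel's condition (labels
    containing ``"AO"`` are the depolarized group).  The contrast tested is
    AO vs untreated among non-spare channels.
    """
    settings = settings or AnalysisSettings()
    channels = list(channels)
    group_labels = list(group_labels)

    kept, report = filter_psms(psm_table, settings.thresholds)
    _log_stage("filter_psms", len(psm_table), len(kept))

    confident = target_decoy_fdr(kept, settings.psm_fdr_level, by="peptide")
    _log_stage("target_decoy_fdr", len(kept), len(confident))

    sites, ambiguous = aggregate_to_sites(confident, sequences, channels)
    _log_stage("aggregate_to_sites", len(confident), len(sites))

    site_ids = sites["protein"] + "_K" + sites["site"].astype(str)
    site_matrix = sites.set_index(site_ids)[channels]

    prot_matrix = protein_table.set_index("protein")[channels]
    prot_matrix = equal_loading_normalize(prot_matrix)
    site_norm = equal_loading_normalize(site_matrix)
    _log_stage("equal_loading", len(site_matrix), len(site_norm))

    treated = treated_channels(group_labels)
    spare = [
        c for c, g in zip(channels, group_labels) if "AO" not in g and "UT" not in g
    ]
    used_channels = [c for c in channels if c not in spare]
    used_labels = [
        "AO" if t else "UT"
        for c, (g, t) in zip(channels, zip(group_labels, treated))
        if c not in spare
    ]
    ref_cols = [c for c, l in zip(used_channels, used_labels) if l == "UT"]

    site_ratio = _reference_ratios(site_norm[used_channels], ref_cols)
    prot_ratio = _reference_ratios(prot_matrix[used_channels], ref_cols)
    site_to_protein = dict(zip(site_ids, sites["protein"]))
    if settings.normalize_to_protein:
        site_ratio, norm_flags = normalize_site_to_protein(
            site_ratio, prot_ratio, site_to_protein
        )
    else:
        norm_flags = pd.Series(False, index=site_ratio.index)
    _log_stage("site_to_protein", len(site_ratio), len(site_ratio))

    log_matrix = np.log2(site_ratio.replace(0, np.nan))
    log_matrix = log_matrix.dropna(how="any")
    log_matrix = median_center(log_matrix)
    _log_stage("median_center", len(site_ratio), len(log_matrix))

    perm = permutation_fdr(
        log_matrix,
        used_labels,
        PermutationConfig(
            s0=settings.s0,
            fdr_level=settings.fdr_level,
            n_permutations=settings.n_permutations,
            seed=settings.seed,
        ),
        group_pair=("AO", "UT"),
    )
    mod = moderated_t(log_matrix, used_labels, group_pair=("AO", "UT"))
    mod["q_bh"] = benjamini_hochberg(mod["p"].to_numpy())
    _log_stage("diff_stats", len(log_matrix), int(perm["significant"].sum()))

    gene_of = dict(zip(protein_table["protein"], protein_table["gene"]))
    perm_out = perm.copy()
    perm_out["protein"] = [site_to_protein[i] for i in perm_out.index]
    perm_out["gene"] = perm_out["protein"].map(gene_of).fillna("")
    perm_out["normalized_to_protein"] = norm_flags.reindex(perm_out.index).fillna(False)

    annotated = None
    if annotation_table is not None:
        annotated = annotate_sites(perm_out.reset_index(), annotation_table)
        _log_stage("annotate", len(perm_out), len(annotated))

    ranking = rank_site_abundance(sites, channels)
    _log_stage("rank_sites", len(sites), len(ranking))

    copy_numbers = None
    if {"intensity", "molecular_weight"}.issubset(protein_table.columns):
        histones = [
            p for p in protein_table["protein"] if str(p).upper().startswith("HIST")
        ]
        if histones:
            copy_numbers = proteomic_ruler_copies(
                protein_table.set_index("protein")["intensity"],
                protein_table.set_index("protein")["molecular_weight"],
                histones,
                ploidy=settings.ploidy,
                genome_size_bp=settings.genome_size_bp,
            )
            _log_stage("proteomic_ruler", len(protein_table), len(copy_numbers))

    manifest = {
        "version": __version__,
        "seed": settings.seed,
        "s0": settings.s0,
        "fdr_level": settings.fdr_level,
        "n_permutations": settings.n_permutations,
        "n_psms_in": len(psm_table),
        "n_psms_kept": len(confident),
        "n_sites": len(sites),
        "n_ambiguous_sites": len(ambiguous),
        "n_significant": int(perm["significant"].sum()),
        "channels": channels,
        "group_labels": group_labels,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()

    return ResultBundle(
        site_matrix=site_matrix,
        normalized_log_matrix=log_matrix,
        permutation_results=perm_out,
        moderated_results=mod,
        annotated=annotated,
        ranking=ranking,
        copy_numbers=copy_numbers,
        filter_report=report,
        ambiguous_sites=ambiguous,
        manifest=manifest,
    )


def export_resource_tables(bundle: ResultBundle) -> pd.DataFrame:
    """Peptide-level master table for the searchable resource export.

    One row per quantified site with every field the online resource
    filters on: gene, site, fold change, p/q, significance, mitochondrial
    flag and subcompartment, total-proteome presence, and rank abundance.
    Sections absent from the bundle yield columns marked unavailable
    (empty strings / NaN).
    """
    res = bundle.permutation_results
    master = pd.DataFrame(
        {
            "id": res.index,
            "gene": res["gene"],
            "protein": res["protein"],
            "log2fc": res["log2fc"],
            "p": res["p"],
            "q": res["q"],
            "significant": res["significant"],
            "direction": res["direction"],
            "normalized_to_protein": res["normalized_to_protein"],
        }
    ).set_index("id")
    if bundle.annotated is not None:
        ann = bundle.annotated.set_index("id")
        master["mitochondrial"] = ann["mitochondrial"]
        master["subcompartment"] = ann["subcompartment"]
    else:
        master["mitochondrial"] = ""
        master["subcompartment"] = ""
    rank_ids = bundle.ranking["protein"] + "_K" + bundle.ranking["site"].astype(str)
    rank_map = dict(zip(rank_ids, bundle.ranking["rank_abundance"]))
    master["rank_abundance"] = [rank_map.get(i, np.nan) for i in master.index]
    master["in_total_proteome"] = master["protein"].isin(
        set(bundle.copy_numbers["protein"]) if bundle.copy_numbers is not None else set()
    )
    return master.reset_index()
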