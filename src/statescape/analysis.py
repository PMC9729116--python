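"""End-to-end analysis drivers wiring the stage modules together.

These functions run the canonical order of operations on in-memory objects:
expression QC and transforms, per-sample NMF consensus, the snATAC/RNA
integration and pseudobulk CRE-linking chain, TF-circuit selection, and the
spatial statistics, and (when ground truth is available) score the results
against the planted structure.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import atac as atac_mod
from . import expression as expr_mod
from . import integration, links as links_mod, metaprograms as mp_mod
from . import spatial as spatial_mod
from . import tf_circuits as tf_mod
from .simulate import GroundTruth, SimConfig, gen_atac, gen_expression

logger = logging.getLogger(__name__)


def prepare_expression(expr, housekeeping_set=None):
    """Cell QC, gene QC and the E/Ea/Er transforms."""
    if housekeeping_set is None:
        hk_col = expr.gene_meta.get("housekeeping")
        housekeeping_set = (
            list(expr.genes[hk_col.to_numpy(dtype=bool)]) if hk_col is not None
            else expr_mod.DEFAULT_HOUSEKEEPING
        )
    mat = expr_mod.qc_filter_cells(expr, housekeeping_set=housekeeping_set)
    mat = expr_mod.qc_filter_genes(mat)
    E, Er = expr_mod.transform(mat)
    return mat, E, Er


def run_metaprogram_analysis(
    expr, n_overdispersed: int = 10000, k: int = 6, n_meta: int | None = None,
    seed: int = 0, housekeeping_set=None,
):
    """QC, transform, per-sample NMF and consensus merge.

    Returns a dict with the QC'd matrix, transforms, programs, metaprograms,
    the per-cell metaprogram score table and assigned labels.
    """
    mat, E, Er = prepare_expression(expr, housekeeping_set)
    genes = expr_mod.select_overdispersed_genes(mat, n=n_overdispersed)
    frozen = (mat.cell_meta["protocol"] == "frozen").any()
    programs = mp_mod.run_all_samples_nmf(
        Er, mat.cell_meta["sample_id"], genes, k=k, seed=seed,
        exclude_prefixes=mp_mod.RIBOSOMAL_PREFIXES if frozen else (),
    )
    prog_scores = mp_mod.score_programs(Er, programs)
    metas, detail = mp_mod.cluster_and_merge(programs, prog_scores, n_meta=n_meta)
    meta_scores = expr_mod.score_signatures(
        Er, {m.name: m.top_genes for m in metas}
    )
    labels = expr_mod.assign_state(meta_scores)
    return dict(matrix=mat, E=E, Er=Er, overdispersed=genes, programs=programs,
                program_scores=prog_scores, metaprograms=metas,
                cluster_detail=detail, scores=meta_scores, labels=labels)


def annotate_metaprograms(metaprograms, signatures: dict) -> dict:
    """Match each reference signature to its best-overlapping metaprogram.

    This is the user-annotation step: technical or redundant metaprograms are
    left unmatched.  Returns signature name -> (metaprogram, overlap size).
    """
    out = {}
    for name, genes in signatures.items():
        best = max(metaprograms, key=lambda m: (len(set(m.top_genes) & set(genes)), m.name))
        out[name] = (best, len(set(best.top_genes) & set(genes)))
    return out


def run_link_analysis(
    expr, peak_mat, annotation, qc_table,
    pseudobulk_seed: int = 0,
    n_seeds: int = 200, k_neighbors: int = 99,
    window: int = 250_000, min_abs_r: float = 0.2, alpha: float = 0.05,
    housekeeping_set=None,
):
    """The full CRE-linking chain.

    snATAC QC -> TF-IDF/LSI -> per-sample centering; RNA QC/transform; gene
    activities -> joint CCA -> nucleus-to-cell matching; 200 pseudobulk
    neighborhoods; candidate pairing, correlation, BH and link filtering.
    Returns a dict with the links table and every intermediate object.
    """
    pm = atac_mod.qc_filter_atac(peak_mat, qc_table)
    lsi = atac_mod.tfidf_lsi(pm)
    corrected = integration.center_by_sample(
        lsi.coords, pm.nucleus_meta["sample_id"]
    )
    rna, E, Er = prepare_expression(expr, housekeeping_set)
    activity, act_genes = atac_mod.gene_activity(pm, annotation)
    joint = integration.joint_cca(
        Er.Er, activity, Er.genes, act_genes, Er.cells, pm.nuclei
    )
    match = integration.match_modalities(
        joint,
        rna_samples=rna.cell_meta["sample_id"],
        atac_samples=pm.nucleus_meta["sample_id"],
    )
    pseudobulks = integration.build_pseudobulks(
        corrected, pm, match, rna.tpm, rna.cells,
        n_seeds=n_seeds, k_neighbors=k_neighbors, seed=pseudobulk_seed,
    )
    cpm, tpm = integration.pseudobulk_matrices(pseudobulks)
    pairs = links_mod.candidate_pairs(
        pm.peaks, annotation, rna_genes=rna.genes, window=window
    )
    link_table = links_mod.link_correlation(cpm, tpm, pairs, pm.peaks.index, rna.genes)
    link_table = links_mod.filter_links(link_table, min_abs_r=min_abs_r, alpha=alpha)
    return dict(peak_matrix=pm, lsi=lsi, corrected=corrected, rna=rna, Er=Er,
                activity=activity, activity_genes=act_genes, joint=joint,
                match=match, pseudobulks=pseudobulks, peak_cpm=cpm,
                gene_tpm=tpm, pairs=pairs, links=link_table)


def score_links_against_truth(links: pd.DataFrame, truth: GroundTruth) -> dict:
    """Recall / realized FDP of passing links against the planted pairs."""
    true_set = set(truth.true_links)
    is_true = np.array([
        (p, g) in true_set for p, g in zip(links["peak"], links["gene"])
    ])
    called = links["passes"].to_numpy()
    n_true_cand = int(is_true.sum())
    recall = float((called & is_true).sum() / n_true_cand) if n_true_cand else float("nan")
    n_called = int(called.sum())
    fdp = float((called & ~is_true).sum() / n_called) if n_called else 0.0
    mean_r = float(links.loc[is_true, "pcc"].mean()) if n_true_cand else float("nan")
    return dict(recall=recall, fdp=fdp, n_called=n_called,
                n_true_candidates=n_true_cand, mean_true_pcc=mean_r)


def state_cre_peaks(links: pd.DataFrame, signatures: dict) -> dict:
    """Passing-link CREs grouped by the state whose signature owns the gene."""
    passing = links[links["passes"]]
    gene_state = {g: s for s, gs in signatures.items() for g in gs}
    out: dict = {s: [] for s in signatures}
    for p, g in zip(passing["peak"], passing["gene"]):
        s = gene_state.get(g)
        if s is not None:
            out[s].append(p)
    return out


def run_tf_analysis(
    expr_qc, Er, labels: pd.Series, regulons: dict, motif_hits: pd.DataFrame,
    links: pd.DataFrame, signatures: dict,
    tpm_min: float = 4.0, top_n: int = 30, alpha: float = 0.05,
):
    """Regulon activity/specificity, state-TF selection and GPC core TFs."""
    activity = tf_mod.regulon_activity(Er, regulons)
    keep = labels.isin(list(signatures))
    spec = tf_mod.regulon_specificity(activity[keep.to_numpy()], labels[keep])
    mean_tpm = pd.Series(
        {tf: float(expr_qc.tpm[expr_qc.genes.get_loc(tf), :].mean())
         for tf in activity.columns if tf in expr_qc.genes}
    )
    cre_by_state = state_cre_peaks(links, signatures)
    selected, evidence = tf_mod.select_state_tfs(
        mean_tpm, motif_hits, cre_by_state, spec,
        tpm_min=tpm_min, top_n=top_n, alpha=alpha,
    )
    gpc = links_mod.gpc_genes(links)
    core, core_evidence = tf_mod.gpc_core_tfs(gpc, links, regulons, motif_hits,
                                              alpha=alpha)
    return dict(activity=activity, specificity=spec, mean_tpm=mean_tpm,
                selected=selected, evidence=evidence, gpc=gpc, core=core,
                core_evidence=core_evidence)


def run_spatial_analysis(
    cells, marker_map: dict,
    min_malignant: float, max_nonmalignant: float,
    radius: float = 50.0, n_perm: int = 100, seed: int = 0,
    malignant_types: pd.Series | None = None,
):
    """IF gating, marker typing, neighbor graph, enrichment and centrality.

    ``malignant_types`` optionally supplies subtype labels for malignant
    cells (probabilistic typing of malignant cells is outside this package's
    scope; any source may provide the labels).
    """
    gated = spatial_mod.if_gate(cells, min_malignant, max_nonmalignant)
    typed = spatial_mod.type_nonmalignant(gated, marker_map)
    tab = typed.table.copy()
    mal = tab["cell_class"] == spatial_mod.MALIGNANT
    if malignant_types is not None:
        tab.loc[mal, "cell_type"] = malignant_types.reindex(tab.index[mal])
    else:
        tab.loc[mal, "cell_type"] = "malignant"
    keep = tab["cell_class"] != spatial_mod.AMBIGUOUS
    kept = spatial_mod.SpatialCellMap(
        table=tab[keep],
        reads=typed.reads.loc[keep] if typed.reads is not None else None,
    )
    graph = spatial_mod.build_graph(kept, radius=radius)
    labels = kept.table["cell_type"].astype(str)
    enrichment = spatial_mod.neighborhood_enrichment(graph, labels,
                                                     n_perm=n_perm, seed=seed)
    centrality = spatial_mod.centrality_scores(graph, labels)
    return dict(gated=typed, kept=kept, graph=graph, labels=labels,
                enrichment=enrichment, centrality=centrality)


def simulate_and_link(cfg: SimConfig, pseudobulk_seed: int = 0) -> dict:
    """Generate expression + ATAC under ``cfg`` and run the link analysis."""
    expr, truth = gen_expression(cfg)
    peak_mat, annotation, qc = gen_atac(cfg, truth)
    out = run_link_analysis(expr, peak_mat, annotation, qc,
                            pseudobulk_seed=pseudobulk_seed)
    out["truth"] = truth
    out["expr"] = expr
    out["annotation"] = annotation
    out["scores"] = score_links_against_truth(out["links"], truth)
    return out
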