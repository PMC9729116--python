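"""End-to-end pipeline orchestration with file-based stage handoff.

Stages run in dependency order (simulate -> rna-qc -> metaprograms -> atac ->
integrate -> links -> tfs -> spatial); each writes its outputs plus a JSON
provenance record (stage parameters, the global seed, SHA-256 hashes of its
inputs) into the run directory.  All randomness flows from one global seed
through fixed per-stage substreams, so a rerun with the same configuration is
bit-reproducible for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, io as sio
from . import expression as expr_mod, links as links_mod, metaprograms as mp_mod
from .simulate import DEFAULT_MARKER_MAP, SimConfig, gen_all

logger = logging.getLogger(__name__)

STAGES = ("simulate", "rna-qc", "metaprograms", "atac", "integrate",
          "links", "tfs", "spatial")


@dataclass
class PipelineConfig:
    """All pipeline parameters; numeric defaults are the published thresholds.

    Cell QC 2,000 genes / housekeeping 2.5 (fresh) and 1,000 genes / 0.4
    alignment (frozen); gene QC TPM > 16 in >= 10 cells; top 10,000
    over-dispersed genes; k = 6 NMF factors; score threshold 0.2; ATAC QC
    1,500-15,000 fragments / >15% reads in peaks / blacklist < 0.02 /
    nucleosome < 2 / TSS > 4; 200 pseudobulk seeds x 99 neighbors (100-cell
    pseudobulks); 250 kb candidate window; |PCC| > 0.2 and BH q < 0.05; top
    5% GPC rule; TF mean TPM > 4 and top-30 specificity; 50 um neighbor
    radius with 100 permutations.
    """

    workdir: str = "statescape_run"
    seed: int = 0
    stages: tuple = STAGES
    sim: dict = field(default_factory=dict)

    fresh_min_genes: int = 2000
    fresh_min_hk: float = 2.5
    frozen_min_genes: int = 1000
    frozen_min_align: float = 0.4
    gene_min_tpm: float = 16.0
    gene_min_cells: int = 10
    n_overdispersed: int = 10000
    nmf_k: int = 6
    n_meta: int | None = None
    score_threshold: float = 0.2

    atac_min_peaks: int = 200
    atac_min_nuclei_per_peak: int = 10
    atac_frag_lo: float = 1500
    atac_frag_hi: float = 15000
    atac_min_pct: float = 15
    atac_max_blacklist: float = 0.02
    atac_max_nucleosome: float = 2
    atac_min_tss: float = 4
    lsi_d: int = 30

    n_pseudobulk_seeds: int = 200
    k_neighbors: int = 99

    link_window: int = 250_000
    link_min_abs_r: float = 0.2
    link_alpha: float = 0.05
    gpc_top_frac: float = 0.05

    tf_tpm_min: float = 4.0
    tf_top_n: int = 30
    tf_alpha: float = 0.05

    spatial_radius: float = 50.0
    spatial_n_perm: int = 100
    if_min_malignant: float = 90.0
    if_max_nonmalignant: float = 60.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, val in raw.items():
            want = cls.__dataclass_fields__[key].type
            if key != "sim" and isinstance(val, str) and want not in ("str",):
                raise ValueError(f"config key {key} has non-numeric value {val!r}")
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _provenance(run: Path, stage: str, params: dict, inputs: list) -> None:
    rec = {
        "stage": stage,
        "params": params,
        "inputs": {
            str(Path(p).resolve().relative_to(run.resolve())): _hash_file(Path(p))
            for p in inputs
        },
    }
    sio.write_json(run / f"provenance_{stage.replace('-', '_')}.json", rec)


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' needs output of stage '{stage}' ({path}); "
            f"run '{stage}' first"
        )
    return path


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the requested stages in dependency order; returns the run dir."""
    run = Path(config.workdir)
    run.mkdir(parents=True, exist_ok=True)
    order = [s for s in STAGES if s in config.stages]
    for stage in order:
        logger.info("pipeline: running stage %s", stage)
        _STAGE_FUNCS[stage](config, run)
    return run


def stage_simulate(cfg: PipelineConfig, run: Path) -> None:
    sim = cfg.sim_config()
    expr, truth, peak_mat, annotation, qc, regulons, motifs, spatial_map = gen_all(sim)
    sio.write_expression(run / "expression", expr)
    sio.write_peak_matrix(run / "atac", peak_mat, qc=qc)
    sio.write_annotation(run / "atac" / "genes.tsv", annotation)
    sio.write_json(run / "regulons.json", regulons)
    sio.write_matrix(run / "motifs", motifs.to_numpy().astype(int),
                     motifs.index, motifs.columns, "motif_hits")
    sio.write_spatial(run / "spatial", spatial_map)
    sio.write_json(run / "ground_truth.json", {
        "cell_states": truth.cell_states.to_dict(),
        "signatures": truth.signatures,
        "state_tfs": truth.state_tfs,
        "nucleus_states": truth.nucleus_states.to_dict(),
        "true_links": truth.true_links,
        "planted_link_counts": truth.planted_link_counts,
        "gpc_genes": truth.gpc_genes,
        "spatial_types": truth.spatial_types.to_dict(),
        "housekeeping": truth.housekeeping,
        "decoy_tfs": truth.decoy_tfs,
    })
    _provenance(run, "simulate", {"seed": sim.seed, **dataclasses.asdict(sim)}, [])


def stage_rna_qc(cfg: PipelineConfig, run: Path) -> None:
    src = _require(run / "expression" / "tpm.mtx", "simulate", "rna-qc")
    expr = sio.read_expression(run / "expression")
    hk = None
    if "housekeeping" in expr.gene_meta.columns:
        hk = list(expr.genes[expr.gene_meta["housekeeping"].astype(bool)])
    mat = expr_mod.qc_filter_cells(
        expr, housekeeping_set=hk or expr_mod.DEFAULT_HOUSEKEEPING,
        fresh_min_genes=cfg.fresh_min_genes, fresh_min_hk=cfg.fresh_min_hk,
        frozen_min_genes=cfg.frozen_min_genes, frozen_min_align=cfg.frozen_min_align,
    )
    mat = expr_mod.qc_filter_genes(mat, min_tpm=cfg.gene_min_tpm,
                                   min_cells=cfg.gene_min_cells)
    sio.write_expression(run / "expression_qc", mat)
    _provenance(run, "rna-qc", {
        "fresh_min_genes": cfg.fresh_min_genes, "fresh_min_hk": cfg.fresh_min_hk,
        "frozen_min_genes": cfg.frozen_min_genes,
        "frozen_min_align": cfg.frozen_min_align,
        "gene_min_tpm": cfg.gene_min_tpm, "gene_min_cells": cfg.gene_min_cells,
    }, [src])


def stage_metaprograms(cfg: PipelineConfig, run: Path) -> None:
    src = _require(run / "expression_qc" / "tpm.mtx", "rna-qc", "metaprograms")
    mat = sio.read_expression(run / "expression_qc")
    _, Er = expr_mod.transform(mat)
    genes = expr_mod.select_overdispersed_genes(mat, n=cfg.n_overdispersed)
    frozen = (mat.cell_meta["protocol"] == "frozen").any()
    programs = mp_mod.run_all_samples_nmf(
        Er, mat.cell_meta["sample_id"], genes, k=cfg.nmf_k, seed=cfg.seed,
        exclude_prefixes=mp_mod.RIBOSOMAL_PREFIXES if frozen else (),
    )
    scores = mp_mod.score_programs(Er, programs)
    metas, detail = mp_mod.cluster_and_merge(programs, scores, n_meta=cfg.n_meta)
    meta_scores = expr_mod.score_signatures(Er, {m.name: m.top_genes for m in metas})
    labels = expr_mod.assign_state(meta_scores, threshold=cfg.score_threshold)
    sio.write_metaprograms(run / "metaprograms.json", metas)
    scores.to_csv(run / "program_scores.tsv", sep="\t")
    meta_scores.to_csv(run / "metaprogram_scores.tsv", sep="\t")
    labels.to_csv(run / "cell_states.csv")
    newick = sio.linkage_to_newick(
        detail["linkage"], [p.name for p in sorted(programs, key=lambda p: (p.sample_id, p.factor))]
    )
    (run / "program_dendrogram.nwk").write_text(newick + "\n")
    _provenance(run, "metaprograms", {
        "n_overdispersed": cfg.n_overdispersed, "k": cfg.nmf_k,
        "n_meta": detail["n_meta"], "score_threshold": cfg.score_threshold,
        "seed": cfg.seed,
    }, [src])


def stage_atac(cfg: PipelineConfig, run: Path) -> None:
    from . import atac as atac_mod
    src = _require(run / "atac" / "peaks.mtx", "simulate", "atac")
    peak_mat, qc = sio.read_peak_matrix(run / "atac")
    annotation = sio.read_annotation(run / "atac" / "genes.tsv")
    pm = atac_mod.qc_filter_atac(
        peak_mat, qc,
        min_peaks=cfg.atac_min_peaks,
        min_nuclei_per_peak=cfg.atac_min_nuclei_per_peak,
        frag_lo=cfg.atac_frag_lo, frag_hi=cfg.atac_frag_hi,
        min_pct=cfg.atac_min_pct, max_blacklist=cfg.atac_max_blacklist,
        max_nucleosome=cfg.atac_max_nucleosome, min_tss=cfg.atac_min_tss,
    )
    lsi = atac_mod.tfidf_lsi(pm, d=cfg.lsi_d)
    activity, act_genes = atac_mod.gene_activity(pm, annotation)
    sio.write_peak_matrix(run / "atac_qc", pm)
    pd.DataFrame(lsi.coords, index=pm.nuclei).to_csv(run / "lsi.tsv", sep="\t")
    sio.write_matrix(run / "activity", activity, act_genes, pm.nuclei, "activity")
    _provenance(run, "atac", {
        "min_peaks": cfg.atac_min_peaks, "frag_lo": cfg.atac_frag_lo,
        "frag_hi": cfg.atac_frag_hi, "min_pct": cfg.atac_min_pct,
        "max_blacklist": cfg.atac_max_blacklist,
        "max_nucleosome": cfg.atac_max_nucleosome, "min_tss": cfg.atac_min_tss,
        "lsi_d": cfg.lsi_d,
    }, [src])


def stage_integrate(cfg: PipelineConfig, run: Path) -> None:
    from . import integration
    _require(run / "atac_qc" / "peaks.mtx", "atac", "integrate")
    _require(run / "expression_qc" / "tpm.mtx", "rna-qc", "integrate")
    pm, _ = sio.read_peak_matrix(run / "atac_qc")
    mat = sio.read_expression(run / "expression_qc")
    _, Er = expr_mod.transform(mat)
    act, act_genes, act_nuclei = sio.read_matrix(run / "activity", "activity")
    act = act.toarray() if hasattr(act, "toarray") else np.asarray(act)
    lsi = pd.read_csv(run / "lsi.tsv", sep="\t", index_col=0)
    corrected = integration.center_by_sample(
        lsi.to_numpy(), pm.nucleus_meta["sample_id"]
    )
    joint = integration.joint_cca(Er.Er, act, Er.genes, pd.Index(act_genes),
                                  Er.cells, pm.nuclei)
    match = integration.match_modalities(
        joint, rna_samples=mat.cell_meta["sample_id"],
        atac_samples=pm.nucleus_meta["sample_id"],
    )
    pseudobulks = integration.build_pseudobulks(
        corrected, pm, match, mat.tpm, mat.cells,
        n_seeds=cfg.n_pseudobulk_seeds, k_neighbors=cfg.k_neighbors,
        seed=cfg.seed,
    )
    cpm, tpm = integration.pseudobulk_matrices(pseudobulks)
    match.to_csv(run / "match.csv")
    sio.write_json(run / "pseudobulk_members.json", [
        {"seed": p.seed_nucleus, "atac": list(p.member_atac), "rna": list(p.member_rna)}
        for p in pseudobulks
    ])
    sio.write_matrix(run / "pseudobulk", cpm, pm.peaks.index,
                     [p.seed_nucleus for p in pseudobulks], "peak_cpm")
    sio.write_matrix(run / "pseudobulk", tpm, mat.genes,
                     [p.seed_nucleus for p in pseudobulks], "gene_tpm")
    _provenance(run, "integrate", {
        "n_seeds": cfg.n_pseudobulk_seeds, "k_neighbors": cfg.k_neighbors,
        "seed": cfg.seed,
    }, [run / "atac_qc" / "peaks.mtx", run / "expression_qc" / "tpm.mtx"])


def stage_links(cfg: PipelineConfig, run: Path) -> None:
    _require(run / "pseudobulk" / "peak_cpm.mtx", "integrate", "links")
    pm, _ = sio.read_peak_matrix(run / "atac_qc")
    annotation = sio.read_annotation(run / "atac" / "genes.tsv")
    cpm, peak_ids, _ = sio.read_matrix(run / "pseudobulk", "peak_cpm")
    tpm, gene_ids, _ = sio.read_matrix(run / "pseudobulk", "gene_tpm")
    cpm = np.asarray(cpm.todense() if hasattr(cpm, "todense") else cpm)
    tpm = np.asarray(tpm.todense() if hasattr(tpm, "todense") else tpm)
    pairs = links_mod.candidate_pairs(pm.peaks, annotation,
                                      rna_genes=gene_ids, window=cfg.link_window)
    links = links_mod.link_correlation(cpm, tpm, pairs, pd.Index(peak_ids),
                                       pd.Index(gene_ids))
    links = links_mod.filter_links(links, min_abs_r=cfg.link_min_abs_r,
                                   alpha=cfg.link_alpha)
    gpc = links_mod.gpc_genes(links, top_frac=cfg.gpc_top_frac)
    links.to_csv(run / "links.tsv", sep="\t", index=False)
    sio.write_bed(run / "cres.bed",
                  pm.peaks.loc[sorted(set(links.loc[links["passes"], "peak"]))])
    sio.write_json(run / "gpc.json", {
        "threshold": gpc.threshold, "genes": gpc.genes,
        "counts": gpc.counts.to_dict(),
    })
    _provenance(run, "links", {
        "window": cfg.link_window, "min_abs_r": cfg.link_min_abs_r,
        "alpha": cfg.link_alpha, "gpc_top_frac": cfg.gpc_top_frac,
    }, [run / "pseudobulk" / "peak_cpm.mtx"])


def stage_tfs(cfg: PipelineConfig, run: Path) -> None:
    _require(run / "links.tsv", "links", "tfs")
    mat = sio.read_expression(run / "expression_qc")
    _, Er = expr_mod.transform(mat)
    regulons = sio.read_json(run / "regulons.json")
    hits, hit_peaks, hit_tfs = sio.read_matrix(run / "motifs", "motif_hits")
    motif_hits = pd.DataFrame(
        np.asarray(hits.todense() if hasattr(hits, "todense") else hits) > 0,
        index=hit_peaks, columns=hit_tfs,
    )
    links = pd.read_csv(run / "links.tsv", sep="\t")
    labels = pd.read_csv(run / "cell_states.csv", index_col=0).iloc[:, 0]
    # signature sets for per-state CREs: the merged metaprogram gene lists
    metas = sio.read_json(run / "metaprograms.json")
    signatures = {m["name"]: m["top_genes"] for m in metas}
    out = analysis.run_tf_analysis(
        mat, Er, labels, regulons, motif_hits, links, signatures,
        tpm_min=cfg.tf_tpm_min, top_n=cfg.tf_top_n, alpha=cfg.tf_alpha,
    )
    out["evidence"].to_csv(run / "tf_evidence.tsv", sep="\t", index=False)
    out["core_evidence"].to_csv(run / "gpc_core_tfs.tsv", sep="\t", index=False)
    sio.write_json(run / "tf_selection.json", out["selected"])
    _provenance(run, "tfs", {
        "tpm_min": cfg.tf_tpm_min, "top_n": cfg.tf_top_n, "alpha": cfg.tf_alpha,
    }, [run / "links.tsv"])


def stage_spatial(cfg: PipelineConfig, run: Path) -> None:
    _require(run / "spatial" / "cells.csv", "simulate", "spatial")
    cells = sio.read_spatial(run / "spatial")
    out = analysis.run_spatial_analysis(
        cells, DEFAULT_MARKER_MAP,
        min_malignant=cfg.if_min_malignant,
        max_nonmalignant=cfg.if_max_nonmalignant,
        radius=cfg.spatial_radius, n_perm=cfg.spatial_n_perm, seed=cfg.seed,
    )
    out["gated"].table.to_csv(run / "spatial_typed.csv")
    out["enrichment"].table.to_csv(run / "neighborhood_enrichment.csv")
    out["enrichment"].conditional_ratio.to_csv(run / "conditional_ratio.csv")
    out["centrality"].to_csv(run / "centrality.csv")
    _provenance(run, "spatial", {
        "radius": cfg.spatial_radius, "n_perm": cfg.spatial_n_perm,
        "if_min_malignant": cfg.if_min_malignant,
        "if_max_nonmalignant": cfg.if_max_nonmalignant, "seed": cfg.seed,
    }, [run / "spatial" / "cells.csv"])


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "rna-qc": stage_rna_qc,
    "metaprograms": stage_metaprograms,
    "atac": stage_atac,
    "integrate": stage_integrate,
    "links": stage_links,
    "tfs": stage_tfs,
    "spatial": stage_spatial,
}
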