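"""Self-contained validation studies on synthetic cohorts.

Each study generates data with planted structure (or none), runs the
corresponding analysis chain end to end, and scores the result against the
planted truth.  The same functions back the acceptance test suite and the
``scripts/acceptance.py`` reporting script.
"""

from __future__ import annotations

import logging

import numpy as np

from .analysis import (
    annotate_metaprograms,
    run_metaprogram_analysis,
    run_spatial_analysis,
    run_tf_analysis,
    simulate_and_link,
)
from .expression import SCORE_TOO_LOW, assign_state, score_signatures
from .simulate import (
    DEFAULT_MARKER_MAP,
    SimConfig,
    gen_expression,
    gen_motifs_regulons,
    gen_spatial,
    link_config,
    null_config,
    tf_config,
)
from .spatial import MALIGNANT, NONMALIGNANT

logger = logging.getLogger(__name__)


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1000 + k) % (2 ** 31)


# ---------------------------------------------------------------------------

def metaprogram_study(seed: int = 0) -> dict:
    """Consensus-NMF recovery of planted expression states.

    Default study conditions (6 samples x 400 cells, 5 states with 30-gene
    signatures at effect size 2, plus program-free cells).  Metaprograms are
    merged at n_states + 1 clusters and annotated to the planted signatures
    by best overlap -- the analyst-annotation step -- before scoring.
    """
    cfg = SimConfig(seed=seed)
    expr, truth = gen_expression(cfg)
    res = run_metaprogram_analysis(expr, n_meta=len(cfg.states) + 1, seed=seed)
    matched = annotate_metaprograms(res["metaprograms"], truth.signatures)

    recovery = {s: overlap / len(truth.signatures[s])
                for s, (_, overlap) in matched.items()}
    scores = score_signatures(res["Er"], {s: m.top_genes for s, (m, _) in matched.items()})
    labels = assign_state(scores)
    st = truth.cell_states.loc[res["matrix"].cells]
    state_mask = (st != "none").to_numpy()
    accuracy = float((labels[state_mask] == st[state_mask]).mean())
    noise_mask = (st == "none").to_numpy()
    too_low = float((labels[noise_mask] == SCORE_TOO_LOW).mean())
    return {
        "signature_recovery": recovery,
        "min_signature_recovery": float(min(recovery.values())),
        "assignment_accuracy": accuracy,
        "score_too_low_rate": too_low,
        "n_cells": int(res["matrix"].n_cells),
    }


def link_study(seed: int = 0) -> dict:
    """CRE-link recovery at cohort scale: 5,000 candidate pairs, 200 planted
    links at target pseudobulk correlation 0.6, 200 pseudobulks."""
    cfg = link_config(seed=seed)
    out = simulate_and_link(cfg, pseudobulk_seed=seed)
    scores = dict(out["scores"])
    scores["n_candidates"] = len(out["links"])
    scores["n_nuclei"] = int(out["peak_matrix"].n_nuclei)
    return scores


def tf_study(seed: int = 0, n_runs: int = 20) -> dict:
    """State-TF selection and GPC-core-TF identification over seeded runs."""
    state_ok, core_ok, precisions, recalls = [], [], [], []
    for k in range(n_runs):
        cfg = tf_config(seed=_sub_seed(seed, k))
        out = simulate_and_link(cfg, pseudobulk_seed=k)
        truth = out["truth"]
        regulons, motifs = gen_motifs_regulons(cfg, truth)
        labels = assign_state(score_signatures(out["Er"], truth.signatures))
        tf_out = run_tf_analysis(out["rna"], out["Er"], labels, regulons,
                                 motifs, out["links"], truth.signatures)
        sel = tf_out["selected"]
        state_ok.append(all(
            truth.state_tfs[s] in sel.get(s, []) for s in cfg.states
        ))
        gene_state = {g: s for s, gs in truth.signatures.items() for g in gs}
        hits = sum(
            1 for g in truth.gpc_genes
            if g in tf_out["core"]
            and truth.state_tfs[gene_state[g]] in tf_out["core"][g]
        )
        recall = hits / len(truth.gpc_genes) if truth.gpc_genes else float("nan")
        tp = fp = 0
        for gene, tfs in tf_out["core"].items():
            s = gene_state.get(gene)
            want = {truth.state_tfs[s]} if s else set()
            tp += len(set(tfs) & want)
            fp += len(set(tfs) - want)
        precision = tp / max(tp + fp, 1)
        precisions.append(precision)
        recalls.append(recall)
        core_ok.append(precision >= 0.9 and recall >= 0.9)
    return {
        "state_tf_all_correct_rate": float(np.mean(state_ok)),
        "core_tf_joint_rate": float(np.mean(core_ok)),
        "core_tf_precision": float(np.mean(precisions)),
        "core_tf_recall": float(np.mean(recalls)),
        "n_runs": n_runs,
    }


def spatial_study(seed: int = 0, n_runs: int = 20) -> dict:
    """Planted-niche detection, IF gating and marker-rule typing."""
    z_ok, gate_accs, type_accs, z_values = [], [], [], []
    for k in range(n_runs):
        cfg = SimConfig(seed=_sub_seed(seed, k))
        _, truth = gen_expression(cfg)
        cells = gen_spatial(cfg, truth)
        out = run_spatial_analysis(
            cells, DEFAULT_MARKER_MAP, min_malignant=90, max_nonmalignant=60,
            seed=k, malignant_types=truth.spatial_types,
        )
        tab = out["gated"].table
        true_mal = truth.spatial_types.isin(cfg.states)
        decided = tab["cell_class"] != "ambiguous"
        correct = ((tab["cell_class"] == MALIGNANT) & true_mal) | \
                  ((tab["cell_class"] == NONMALIGNANT) & ~true_mal)
        gate_accs.append(float(correct[decided].mean()))
        nonmal = tab["cell_class"] == NONMALIGNANT
        type_accs.append(float(
            (tab.loc[nonmal, "cell_type"] == truth.spatial_types[nonmal]).mean()
        ))
        pair = tuple(sorted(cfg.niche_pairs[0]))
        z = float(out["enrichment"].table.loc[pair, "z"])
        z_values.append(z)
        z_ok.append(z > 2)
    return {
        "niche_z_gt2_rate": float(np.mean(z_ok)),
        "mean_niche_z": float(np.mean(z_values)),
        "min_gate_accuracy": float(np.min(gate_accs)),
        "min_typing_accuracy": float(np.min(type_accs)),
        "n_runs": n_runs,
    }


# ---------------------------------------------------------------------------
# null calibration

def null_neighborhood_study(seed: int = 0, n_runs: int = 20) -> dict:
    """|z| > 3 rate for type pairs when no niche is planted."""
    fracs = []
    for k in range(n_runs):
        cfg = null_config(seed=_sub_seed(seed, k))
        _, truth = gen_expression(cfg)
        cells = gen_spatial(cfg, truth)
        out = run_spatial_analysis(
            cells, DEFAULT_MARKER_MAP, min_malignant=90, max_nonmalignant=60,
            seed=k, malignant_types=truth.spatial_types,
        )
        z = out["enrichment"].table["z"].dropna()
        fracs.append(float((z.abs() > 3).mean()))
    return {"frac_pairs_z_gt3": float(np.mean(fracs)), "n_runs": n_runs}


def null_tf_study(seed: int = 0, n_runs: int = 10) -> dict:
    """Selected-TF rate when motifs carry no signal (fg rate = bg rate)."""
    rates = []
    for k in range(n_runs):
        cfg = tf_config(seed=_sub_seed(seed, k), motif_fg_p=0.05, motif_bg_p=0.05)
        out = simulate_and_link(cfg, pseudobulk_seed=k)
        truth = out["truth"]
        regulons, motifs = gen_motifs_regulons(cfg, truth)
        labels = assign_state(score_signatures(out["Er"], truth.signatures))
        tf_out = run_tf_analysis(out["rna"], out["Er"], labels, regulons,
                                 motifs, out["links"], truth.signatures)
        n_sel = sum(len(v) for v in tf_out["selected"].values())
        n_tests = len(tf_out["mean_tpm"]) * len(cfg.states)
        rates.append(n_sel / n_tests)
    return {"selected_tf_rate": float(np.mean(rates)), "n_runs": n_runs}


def null_link_study(seed: int = 0, n_runs: int = 20) -> dict:
    """Realized FDP of the link pipeline when no link is planted.

    With no true links every discovery is false, so the per-seed FDP is 1
    whenever the pipeline calls anything at all and 0 otherwise; the mean
    over seeds is the any-discovery rate of the full resampling scheme.
    """
    fdps, n_called = [], []
    for k in range(n_runs):
        cfg = null_config(seed=_sub_seed(seed, k), n_peaks=1500, n_genes=3200,
                          nuclei_per_sample=2000, cells_per_sample=800)
        out = simulate_and_link(cfg, pseudobulk_seed=k)
        called = int(out["links"]["passes"].sum())
        n_called.append(called)
        fdps.append(1.0 if called > 0 else 0.0)
    return {
        "mean_fdp": float(np.mean(fdps)),
        "mean_n_called": float(np.mean(n_called)),
        "n_runs": n_runs,
    }
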