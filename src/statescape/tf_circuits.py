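"""Regulon activity and specificity, state-specific TF selection and per-GPC
core-TF identification.

Regulons (TF -> predicted target genes) and peak x TF motif hits are inputs;
this module implements the downstream integration: activity is the mean
relative expression of a regulon's targets, specificity is the RSS-style
``1 - sqrt(JSD)`` between the normalized activity distribution and a
cell-state indicator, and a TF is called for a state when it is expressed
(mean TPM > 4), its motif is over-represented in the state's CREs, and its
specificity ranks in the state's top 30.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .expression import RelativeExpression, score_signature
from .links import bh_adjust, motif_enrichment_p

logger = logging.getLogger(__name__)


def regulon_activity(rel: RelativeExpression, regulons: dict) -> pd.DataFrame:
    """Cell x TF activity: mean Er over each regulon's target genes.

    TFs whose targets are entirely absent from the gene universe are dropped
    with a warning.
    """
    cols = {}
    for tf, targets in regulons.items():
        try:
            cols[tf] = score_signature(rel, targets)
        except ValueError:
            logger.warning("regulon %s has no targets in the matrix; dropped", tf)
    if not cols:
        raise ValueError("no regulon overlaps the gene universe")
    return pd.DataFrame(cols, index=rel.cells)


def regulon_specificity(activity: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """TF x state regulon specificity scores (RSS).

    Each TF's activity vector is shifted to be nonnegative and normalized to
    a probability distribution over cells; the score against a state is
    ``1 - sqrt(JSD(activity, indicator))`` with base-2 logs (the
    Jensen-Shannon distance), where the indicator is uniform over the state's
    cells.  Scores lie in [0, 1], hitting 1 when the TF is uniformly active
    in exactly the state's cells and nowhere else.
    """
    labels = labels.loc[activity.index]
    states = sorted(pd.unique(labels))
    for s in states:
        if (labels == s).sum() == 0:
            raise ValueError(f"state {s} has no cells")
    if len(states) < 2:
        raise ValueError("need at least two states")

    A = activity.to_numpy(dtype=float)
    A = A - A.min(axis=0, keepdims=True)
    constant = A.sum(axis=0) == 0
    A[:, constant] = 1.0  # constant activity -> uniform over cells
    P = A / A.sum(axis=0, keepdims=True)

    out = pd.DataFrame(index=activity.columns, columns=states, dtype=float)
    for s in states:
        ind = (labels == s).to_numpy(dtype=float)
        ind = ind / ind.sum()
        for j, tf in enumerate(activity.columns):
            out.loc[tf, s] = 1.0 - jensenshannon(P[:, j], ind, base=2)
    return out


def select_state_tfs(
    mean_tpm: pd.Series,
    motif_hits: pd.DataFrame,
    cre_peaks_by_state: dict,
    specificity: pd.DataFrame,
    all_cre_peaks=None,
    tpm_min: float = 4.0,
    top_n: int = 30,
    alpha: float = 0.05,
) -> tuple[dict, pd.DataFrame]:
    """Intersect the three state-TF criteria.

    A TF is selected for a state iff (1) its mean TPM is strictly > ``tpm_min``,
    (2) its motif is over-represented in the state's CRE peaks against the
    all-CRE background (one-sided hypergeometric, BH over TFs within the
    state, q < alpha), and (3) its specificity rank within the state is <=
    ``top_n``.  Returns (state -> selected TF list, per-TF evidence table).
    """
    tfs = [t for t in specificity.index if t in motif_hits.columns and t in mean_tpm.index]
    if all_cre_peaks is None:
        all_cre_peaks = sorted({p for ps in cre_peaks_by_state.values() for p in ps})
    all_cre_peaks = [p for p in all_cre_peaks if p in motif_hits.index]
    bg = motif_hits.loc[all_cre_peaks, tfs]
    n_universe = len(all_cre_peaks)

    selected = {}
    rows = []
    for state, peaks in cre_peaks_by_state.items():
        peaks = [p for p in peaks if p in motif_hits.index]
        drawn = motif_hits.loc[peaks, tfs]
        pvals = np.array([
            motif_enrichment_p(
                n_universe, int(bg[t].sum()), len(peaks), int(drawn[t].sum())
            )
            for t in tfs
        ])
        qvals = bh_adjust(pvals)
        ranks = specificity[state].rank(ascending=False, method="min")
        sel = []
        for t, p, q in zip(tfs, pvals, qvals):
            ok_tpm = mean_tpm[t] > tpm_min
            ok_motif = q < alpha
            ok_spec = ranks[t] <= top_n
            rows.append((state, t, float(mean_tpm[t]), float(p), float(q),
                         float(specificity.loc[t, state]), int(ranks[t]),
                         bool(ok_tpm and ok_motif and ok_spec)))
            if ok_tpm and ok_motif and ok_spec:
                sel.append(t)
        selected[state] = sorted(sel)
    evidence = pd.DataFrame(
        rows, columns=["state", "tf", "mean_tpm", "motif_p", "motif_q",
                       "specificity", "specificity_rank", "selected"],
    )
    return selected, evidence


def gpc_core_tfs(
    gpc,
    links: pd.DataFrame,
    regulons: dict,
    motif_hits: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[dict, pd.DataFrame]:
    """Core TFs per GPC gene.

    A TF is a core regulator of a GPC gene iff (a) the gene is among the TF's
    regulon targets and (b) the TF's motif is over-represented in the gene's
    linked CREs against the all-CRE background (one-sided hypergeometric,
    BH-adjusted across the TFs tested for that gene, q < alpha).
    """
    passing = links[links["passes"]]
    all_cre = [p for p in pd.unique(passing["peak"]) if p in motif_hits.index]
    n_universe = len(all_cre)
    bg_counts = motif_hits.loc[all_cre].sum(axis=0)

    core = {}
    rows = []
    for gene in gpc.genes:
        gene_peaks = [
            p for p in passing.loc[passing["gene"] == gene, "peak"]
            if p in motif_hits.index
        ]
        if not gene_peaks:
            logger.warning("GPC gene %s has no linked CREs in the motif matrix", gene)
            continue
        tfs = sorted(t for t, targets in regulons.items()
                     if gene in targets and t in motif_hits.columns)
        if not tfs:
            core[gene] = []
            continue
        hits = motif_hits.loc[gene_peaks, tfs].sum(axis=0)
        pvals = np.array([
            motif_enrichment_p(n_universe, int(bg_counts[t]), len(gene_peaks), int(hits[t]))
            for t in tfs
        ])
        qvals = bh_adjust(pvals)
        sel = [t for t, q in zip(tfs, qvals) if q < alpha]
        core[gene] = sorted(sel)
        for t, p, q in zip(tfs, pvals, qvals):
            rows.append((gene, t, len(gene_peaks), int(hits[t]), float(p), float(q),
                         t in sel))
    evidence = pd.DataFrame(
        rows, columns=["gene", "tf", "n_linked_cres", "n_motif_hits", "p", "q", "core"],
    )
    return core, evidence


def filter_cres_near_tss(
    links: pd.DataFrame, max_distance: int = 10_000
) -> pd.DataFrame:
    """Restrict links to CREs within ±``max_distance`` of the TSS (the
    promoter-proximal motif scope); applied before enrichment when selected."""
    return links[links["distance"] <= max_distance]
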