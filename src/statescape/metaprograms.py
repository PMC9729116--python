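"""Per-sample NMF programs and their consensus merge into metaprograms.

Workflow: relative expression (negative values clipped to zero) restricted to
over-dispersed genes is factorized per sample with k nonnegative factors;
each factor is reduced to its top-30 weighted genes; all cells are scored
with every program; programs are hierarchically clustered (1 - Pearson on
score columns, Ward linkage) and each cluster is merged into a metaprogram by
highest average NMF weight.  Merged metaprograms are then matched across
cohorts (e.g. fresh vs frozen tissue) by pairwise score correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import NMF
from sklearn.metrics import silhouette_score

from .expression import RelativeExpression, score_signature

logger = logging.getLogger(__name__)

TOP_GENES = 30

#: gene-name prefixes excluded from frozen-tissue programs (nuclear capture of
#: ribosome-associated transcripts is a known artifact of frozen material)
RIBOSOMAL_PREFIXES = ("RPL", "RPS")


@dataclass
class NMFProgram:
    """One NMF factor of one sample, reduced to its top weighted genes."""

    sample_id: str
    factor: int
    top_genes: list
    weights: np.ndarray  # aligned with top_genes, nonincreasing

    @property
    def name(self) -> str:
        return f"{self.sample_id}.f{self.factor}"


@dataclass
class Metaprogram:
    """A consensus of correlated NMF programs."""

    name: str
    members: list  # member program names
    top_genes: list
    mean_weights: np.ndarray


def run_sample_nmf(
    rel: RelativeExpression,
    genes: list,
    sample_id: str = "sample",
    k: int = 6,
    seed: int = 0,
    max_iter: int = 400,
) -> list[NMFProgram]:
    """Factorize one sample's clipped relative expression into k programs.

    Initialization is the deterministic NNDSVD scheme, so results are
    reproducible for a given seed.  Each factor keeps its ``TOP_GENES``
    highest-weight genes (fewer if the gene list is shorter).
    """
    mask = rel.genes.isin(genes)
    V = np.maximum(rel.Er[mask, :], 0.0)
    used_genes = rel.genes[mask]
    if V.shape[1] < k or mask.sum() < k:
        logger.warning("sample %s has fewer than k=%d cells/genes; skipped", sample_id, k)
        return []
    if not np.any(V > 0):
        raise ValueError(f"sample {sample_id}: all-zero matrix after clipping")

    model = NMF(
        n_components=k, init="nndsvd", random_state=seed, max_iter=max_iter,
        tol=1e-4,
    )
    W = model.fit_transform(V)  # gene x k
    programs = []
    n_top = min(TOP_GENES, V.shape[0])
    for f in range(k):
        w = W[:, f]
        order = sorted(range(len(w)), key=lambda i: (-w[i], used_genes[i]))[:n_top]
        programs.append(
            NMFProgram(
                sample_id=sample_id,
                factor=f,
                top_genes=[used_genes[i] for i in order],
                weights=w[order],
            )
        )
    return programs


def run_all_samples_nmf(
    rel: RelativeExpression,
    sample_ids: pd.Series,
    genes: list,
    k: int = 6,
    seed: int = 0,
    exclude_prefixes: tuple = (),
) -> list[NMFProgram]:
    """Run per-sample NMF over every sample in the cohort.

    ``exclude_prefixes`` drops genes by name prefix before factorization (used
    for the ribosomal-protein guard on frozen tissue).
    """
    if exclude_prefixes:
        genes = [g for g in genes if not str(g).startswith(tuple(exclude_prefixes))]
    sample_ids = sample_ids.loc[rel.cells]
    programs = []
    for samp in pd.unique(sample_ids):
        mask = (sample_ids == samp).to_numpy()
        sub = RelativeExpression(
            Er=rel.Er[:, mask], genes=rel.genes, cells=rel.cells[mask]
        )
        programs += run_sample_nmf(sub, genes, sample_id=str(samp), k=k, seed=seed)
    return programs


def score_programs(
    rel: RelativeExpression, programs: list[NMFProgram]
) -> pd.DataFrame:
    """Cell x program score matrix (mean Er over each program's top genes)."""
    progs = sorted(programs, key=lambda p: (p.sample_id, p.factor))
    return pd.DataFrame(
        {p.name: score_signature(rel, p.top_genes) for p in progs},
        index=rel.cells,
    )


def _correlation_distance(scores: pd.DataFrame) -> np.ndarray:
    X = scores.to_numpy().T  # program x cell
    sd = X.std(axis=1)
    zero = sd == 0
    if zero.any():
        logger.warning("%d constant program score columns; correlation set to 0", int(zero.sum()))
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * X.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc @ Xc.T) / denom
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    # guard against correlations a few ulp outside [-1, 1]
    return np.clip(1.0 - corr, 0.0, 2.0)


def choose_n_meta(programs: list[NMFProgram], scores: pd.DataFrame,
                  lo: int = 2, hi: int = 10) -> int:
    """Pick the cluster count by silhouette on the 1 - correlation distances."""
    dist = _correlation_distance(scores)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = linkage(condensed, method="ward")
    best_n, best_s = lo, -np.inf
    for n in range(lo, min(hi, len(programs) - 1) + 1):
        cl = fcluster(Z, n, criterion="maxclust")
        if len(set(cl)) < 2:
            continue
        s = silhouette_score(dist, cl, metric="precomputed")
        if s > best_s:
            best_n, best_s = n, s
    logger.info("choose_n_meta: silhouette maximum at n=%d (s=%.3f)", best_n, best_s)
    return best_n


def cluster_and_merge(
    programs: list[NMFProgram],
    program_scores: pd.DataFrame,
    n_meta: int | None = None,
) -> tuple[list[Metaprogram], dict]:
    """Cluster programs and merge each cluster into a metaprogram.

    Distance is 1 - Pearson correlation between program score columns, with
    Ward linkage; the tree is cut into ``n_meta`` clusters (silhouette-chosen
    when None).  Within a cluster, genes are ranked by their average NMF
    weight over member programs, where a gene absent from a member's top list
    contributes weight 0; the metaprogram keeps the top 30.  Returns the
    metaprograms plus a dict with the linkage matrix and cluster labels.
    """
    progs = sorted(programs, key=lambda p: (p.sample_id, p.factor))
    if n_meta is None:
        n_meta = choose_n_meta(progs, program_scores)
    if len(progs) < n_meta:
        raise ValueError(f"{len(progs)} programs cannot form {n_meta} metaprograms")
    program_scores = program_scores[[p.name for p in progs]]

    dist = _correlation_distance(program_scores)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = linkage(condensed, method="ward")
    clusters = fcluster(Z, n_meta, criterion="maxclust")

    metas = []
    for c in sorted(set(clusters)):
        members = [p for p, ci in zip(progs, clusters) if ci == c]
        weight_sum: dict = {}
        for p in members:
            for g, w in zip(p.top_genes, p.weights):
                weight_sum[g] = weight_sum.get(g, 0.0) + float(w)
        mean_w = {g: w / len(members) for g, w in weight_sum.items()}
        top = sorted(mean_w, key=lambda g: (-mean_w[g], g))[:TOP_GENES]
        metas.append(
            Metaprogram(
                name=f"MP{c}",
                members=[p.name for p in members],
                top_genes=top,
                mean_weights=np.asarray([mean_w[g] for g in top]),
            )
        )
    detail = {"linkage": Z, "clusters": dict(zip([p.name for p in progs], clusters)),
              "n_meta": n_meta}
    return metas, detail


def crossmodal_match(
    metaprograms_a: list[Metaprogram],
    metaprograms_b: list[Metaprogram],
    rel: RelativeExpression,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Correlate two metaprogram sets on shared cells and pair them greedily.

    Both sets are scored on ``rel``; the Pearson correlation matrix of the
    score columns is returned together with a greedy highest-correlation
    pairing (ties broken by name order).
    """
    if rel.Er.shape[1] == 0:
        raise ValueError("no shared cells to score on")
    sa = pd.DataFrame({m.name: score_signature(rel, m.top_genes) for m in metaprograms_a})
    sb = pd.DataFrame({m.name: score_signature(rel, m.top_genes) for m in metaprograms_b})
    corr = pd.DataFrame(
        np.corrcoef(sa.to_numpy().T, sb.to_numpy().T)[: sa.shape[1], sa.shape[1]:],
        index=sa.columns, columns=sb.columns,
    )
    pairs = []
    remaining = corr.copy()
    while remaining.size and not remaining.empty:
        flat = remaining.stack().sort_values(ascending=False)
        best = flat.index[0]
        ties = flat[flat == flat.iloc[0]]
        if len(ties) > 1:
            best = sorted(ties.index)[0]
        pairs.append((best[0], best[1]))
        remaining = remaining.drop(index=best[0], columns=best[1])
    return corr, pairs
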