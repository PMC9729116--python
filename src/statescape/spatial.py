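"""Spatial cell maps: IF gating, marker typing, neighborhood enrichment and
per-type graph statistics.

Cells carry micrometer coordinates and a mean immunofluorescence (IF)
intensity for the oncohistone stain; malignant/nonmalignant classes come from
two IF thresholds, nonmalignant types from a dominant-marker rule, and
colocalization statistics from a fixed-radius neighbor graph compared against
label permutations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

MALIGNANT, NONMALIGNANT, AMBIGUOUS = "malignant", "nonmalignant", "ambiguous"
UNASSIGNED = "unassigned"


@dataclass
class SpatialCellMap:
    """Cells with coordinates (µm), IF intensity and optional marker reads.

    ``table`` is indexed by cell id with columns ``x``, ``y``,
    ``if_intensity`` and, once assigned, ``cell_class`` and ``cell_type``.
    ``reads`` is an optional cell x marker-gene count table.
    """

    table: pd.DataFrame
    reads: pd.DataFrame | None = None

    def __post_init__(self):
        if not np.isfinite(self.table[["x", "y"]].to_numpy()).all():
            raise ValueError("non-finite coordinates")
        if self.reads is not None and not self.reads.index.equals(self.table.index):
            raise ValueError("reads index must match the cell table")


@dataclass
class NeighborGraph:
    """Undirected neighbor graph: edge iff distance <= radius (µm)."""

    graph: nx.Graph
    radius: float
    cells: pd.Index


def if_gate(
    cells: SpatialCellMap, min_malignant: float, max_nonmalignant: float
) -> SpatialCellMap:
    """Gate cells on IF intensity into malignant / nonmalignant / ambiguous.

    Intensity >= ``min_malignant`` is malignant, <= ``max_nonmalignant`` is
    nonmalignant, strictly between the thresholds is ambiguous (excluded from
    downstream statistics).
    """
    if min_malignant < max_nonmalignant:
        raise ValueError("min_malignant must be >= max_nonmalignant")
    v = cells.table["if_intensity"].to_numpy(dtype=float)
    cls = np.full(len(v), AMBIGUOUS, dtype=object)
    cls[v >= min_malignant] = MALIGNANT
    cls[v <= max_nonmalignant] = NONMALIGNANT
    out = cells.table.copy()
    out["cell_class"] = cls
    counts = pd.Series(cls).value_counts().to_dict()
    logger.info("if_gate: %s", counts)
    return SpatialCellMap(table=out, reads=cells.reads)


def type_nonmalignant(cells: SpatialCellMap, marker_map: dict) -> SpatialCellMap:
    """Type each nonmalignant cell by its maximum-count key marker.

    ``marker_map`` maps type name -> marker gene (or list of genes, summed).
    Cells with zero reads across all markers, or an exact tie between two
    types, are labeled ``"unassigned"``.
    """
    if not marker_map:
        raise ValueError("empty marker_map")
    if cells.reads is None:
        raise ValueError("marker read counts are required")
    if "cell_class" not in cells.table.columns:
        raise ValueError("run if_gate first")

    types = list(marker_map)
    per_type = np.column_stack([
        cells.reads[
            [m] if isinstance(m := marker_map[t], str) else list(m)
        ].sum(axis=1).to_numpy()
        for t in types
    ])
    best = per_type.argmax(axis=1)
    maxval = per_type.max(axis=1)
    n_best = (per_type == maxval[:, None]).sum(axis=1)
    label = np.asarray(types, dtype=object)[best]
    label[(maxval == 0) | (n_best > 1)] = UNASSIGNED
    n_ties = int(((n_best > 1) & (maxval > 0)).sum())
    if n_ties:
        logger.info("type_nonmalignant: %d marker ties left unassigned", n_ties)

    out = cells.table.copy()
    if "cell_type" not in out.columns:
        out["cell_type"] = pd.array([None] * len(out), dtype=object)
    nonmal = out["cell_class"] == NONMALIGNANT
    out.loc[nonmal, "cell_type"] = label[nonmal.to_numpy()]
    return SpatialCellMap(table=out, reads=cells.reads)


def build_graph(cells: SpatialCellMap, radius: float = 50.0) -> NeighborGraph:
    """Neighbor graph over all cells: edge iff Euclidean distance <= radius."""
    tab = cells.table
    if len(tab) < 2:
        raise ValueError("need at least two cells")
    xy = tab[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=radius)
    g = nx.Graph()
    g.add_nodes_from(range(len(tab)))
    g.add_edges_from(pairs)
    return NeighborGraph(graph=g, radius=radius, cells=tab.index)


@dataclass
class EnrichmentResult:
    """Permutation neighborhood enrichment per unordered type pair."""

    table: pd.DataFrame  # index (type_a, type_b): observed, perm_mean, perm_sd, z
    conditional_ratio: pd.DataFrame  # ordered: ratio[a, b]


def _pair_edge_counts(edges: np.ndarray, labels: np.ndarray, types: list) -> dict:
    """Count edges joining each unordered type pair."""
    la, lb = labels[edges[:, 0]], labels[edges[:, 1]]
    out = {frozenset((a, b)) if a != b else frozenset((a,)): 0
           for a, b in itertools.combinations_with_replacement(types, 2)}
    for a, b in zip(la, lb):
        out[frozenset((a, b))] += 1
    return out


def neighborhood_enrichment(
    graph: NeighborGraph,
    labels: pd.Series,
    n_perm: int = 100,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation z-scores for type-pair adjacency.

    The observed statistic for a pair (a, b) is the number of graph edges
    joining an a-cell and a b-cell (unordered; within-type pairs count edges
    inside the type).  Labels are shuffled ``n_perm`` times; z = (obs - mean)
    / sd of the permuted counts, flagged NaN where the permutation sd is 0.
    The conditional colocalization ratio is the mean over a-cells of the
    fraction of their neighbors of type b, divided by the global fraction of
    b-cells (cells without neighbors do not contribute to the mean).
    """
    if not labels.index.equals(graph.cells):
        labels = labels.reindex(graph.cells)
        if labels.isna().any():
            raise ValueError("labels do not cover all graph cells")
    lab = labels.to_numpy(dtype=object)
    types = sorted(pd.unique(lab))
    if len(types) < 2:
        raise ValueError("need at least two cell types")
    edges = np.asarray(graph.graph.edges, dtype=int)
    if edges.size == 0:
        edges = edges.reshape(0, 2)

    observed = _pair_edge_counts(edges, lab, types)
    rng = np.random.default_rng(seed)
    perm_counts = {k: np.empty(n_perm) for k in observed}
    shuffled = lab.copy()
    for it in range(n_perm):
        rng.shuffle(shuffled)
        c = _pair_edge_counts(edges, shuffled, types)
        for k, v in c.items():
            perm_counts[k][it] = v

    rows = []
    for a, b in itertools.combinations_with_replacement(types, 2):
        k = frozenset((a, b)) if a != b else frozenset((a,))
        mean, sd = perm_counts[k].mean(), perm_counts[k].std(ddof=0)
        z = (observed[k] - mean) / sd if sd > 0 else np.nan
        rows.append((a, b, observed[k], mean, sd, z))
    table = pd.DataFrame(
        rows, columns=["type_a", "type_b", "observed", "perm_mean", "perm_sd", "z"]
    ).set_index(["type_a", "type_b"])

    # conditional colocalization ratio (ordered)
    adj = [[] for _ in range(len(lab))]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    global_frac = {t: (lab == t).mean() for t in types}
    ratio = pd.DataFrame(np.nan, index=types, columns=types)
    for a in types:
        a_idx = np.flatnonzero(lab == a)
        fracs = {t: [] for t in types}
        for i in a_idx:
            nbrs = adj[i]
            if not nbrs:
                continue
            nl = lab[nbrs]
            for t in types:
                fracs[t].append((nl == t).mean())
        for t in types:
            if fracs[t] and global_frac[t] > 0:
                ratio.loc[a, t] = float(np.mean(fracs[t])) / global_frac[t]
    return EnrichmentResult(table=table, conditional_ratio=ratio)


def centrality_scores(graph: NeighborGraph, labels: pd.Series) -> pd.DataFrame:
    """Per-type group degree centrality and clustering coefficient.

    Degree centrality of type T = fraction of non-T cells adjacent to at
    least one T cell.  The clustering coefficient is the transitivity of the
    subgraph induced by T (3 x triangles / connected triples; 0 when the
    subgraph has no triples).  A per-node average clustering variant is
    reported alongside.
    """
    if not labels.index.equals(graph.cells):
        labels = labels.reindex(graph.cells)
    lab = labels.to_numpy(dtype=object)
    g = graph.graph
    rows = []
    for t in sorted(pd.unique(lab)):
        members = set(np.flatnonzero(lab == t).tolist())
        outside = [v for v in g.nodes if v not in members]
        if not outside:
            logger.warning("type %s covers all cells; degree centrality undefined", t)
            deg = np.nan
        else:
            touched = {v for u in members for v in g.neighbors(u) if v not in members}
            deg = len(touched) / len(outside)
        sub = g.subgraph(members)
        trans = nx.transitivity(sub) if sub.number_of_nodes() else 0.0
        avg_clust = nx.average_clustering(sub) if sub.number_of_nodes() else 0.0
        rows.append((t, deg, trans, avg_clust))
    return pd.DataFrame(
        rows,
        columns=["cell_type", "degree_centrality", "clustering_coefficient",
                 "average_clustering"],
    ).set_index("cell_type")


def compare_group_proportions(
    per_sample_proportions: pd.Series, group_labels: pd.Series
) -> dict:
    """Welch two-sided t-test on per-sample type proportions between groups."""
    groups = pd.unique(group_labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    a = per_sample_proportions[group_labels == groups[0]].to_numpy(dtype=float)
    b = per_sample_proportions[group_labels == groups[1]].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two samples")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "groups": (groups[0], groups[1]),
        "means": (float(a.mean()), float(b.mean())),
        "t": float(t),
        "p": float(p),
    }
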