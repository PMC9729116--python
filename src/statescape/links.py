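"""Peak-gene linking: candidate pairing, correlation tests, BH adjustment,
high-confidence link filtering, GPC calling and gene-set overlap tests.

A peak is a candidate partner of its nearest RNA-profiled gene (by
peak-midpoint to TSS distance) within a 250 kb window; Pearson correlation of
pseudobulk peak CPM against pseudobulk gene TPM, with a t-distributed null,
produces per-pair p-values that are BH-adjusted over the full candidate set;
high-confidence links require |PCC| > 0.2 and q < 0.05.  Genes whose
linked-CRE count exceeds the top-5% threshold of the count distribution are
"genes with predictive chromatin" (GPCs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GPCSet:
    """Linked-CRE counts per gene, the top-5% threshold and the GPC list."""

    counts: pd.Series
    threshold: float
    genes: list


def candidate_pairs(
    peaks: pd.DataFrame,
    annotation,
    rna_genes=None,
    window: int = 250_000,
    anchor: str = "midpoint",
) -> pd.DataFrame:
    """Pair every peak with its nearest gene within ``window`` of the TSS.

    Distance is |peak midpoint - TSS| on the same chromosome (``anchor="edge"``
    uses the nearest peak edge instead).  Only genes profiled by RNA compete
    (pass ``rna_genes``); distance ties resolve to the lexicographically first
    gene id and are logged.  Peaks with no gene in range are excluded.
    """
    ann = annotation.table
    if rna_genes is not None:
        ann = ann.loc[ann.index.intersection(pd.Index(rna_genes))]
    if len(ann) == 0:
        raise ValueError("empty gene annotation")
    tss = pd.Series(
        np.where(ann["strand"] == "+", ann["start"], ann["end"] - 1), index=ann.index
    )

    rows = []
    n_ties = 0
    for chrom, ann_c in ann.groupby("chrom"):
        tss_c = tss.loc[ann_c.index]
        gene_ids = np.asarray(tss_c.index)
        tss_v = tss_c.to_numpy()
        # deterministic competitor order: sort by (tss, gene id)
        order = np.lexsort((gene_ids, tss_v))
        gene_ids, tss_v = gene_ids[order], tss_v[order]
        pk = peaks[peaks["chrom"] == chrom]
        if pk.empty:
            continue
        mids = ((pk["start"] + pk["end"]) // 2).to_numpy()
        for pid, start, end, mid in zip(pk.index, pk["start"], pk["end"], mids):
            if anchor == "midpoint":
                dist = np.abs(mid - tss_v)
            else:
                dist = np.minimum(np.abs(start - tss_v), np.abs(end - 1 - tss_v))
                dist[(tss_v >= start) & (tss_v < end)] = 0
            dmin = dist.min()
            if dmin > window:
                continue
            hits = np.flatnonzero(dist == dmin)
            if len(hits) > 1:
                n_ties += 1
                gene = min(gene_ids[hits])
            else:
                gene = gene_ids[hits[0]]
            rows.append((pid, gene, int(dmin)))
    if n_ties:
        logger.info("candidate_pairs: %d distance ties broken by gene id", n_ties)
    return pd.DataFrame(rows, columns=["peak", "gene", "distance"])


def link_correlation(
    peak_cpm: np.ndarray,
    gene_tpm: np.ndarray,
    pairs: pd.DataFrame,
    peak_ids: pd.Index,
    gene_ids: pd.Index,
) -> pd.DataFrame:
    """Pearson correlation across pseudobulks for each candidate pair.

    p is the two-sided tail of t = r sqrt((n-2)/(1-r^2)) with n-2 degrees of
    freedom; pairs with a zero-variance member are dropped with a warning.
    """
    n = peak_cpm.shape[1]
    if n < 3:
        raise ValueError("need at least three pseudobulks")
    if gene_tpm.shape[1] != n:
        raise ValueError("pseudobulk count mismatch between modalities")

    pi = pd.Index(peak_ids).get_indexer(pairs["peak"])
    gi = pd.Index(gene_ids).get_indexer(pairs["gene"])
    if (pi < 0).any() or (gi < 0).any():
        raise ValueError("pair members missing from the matrices")

    X = peak_cpm[pi, :]
    Y = gene_tpm[gi, :]
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc ** 2).sum(axis=1))
    sy = np.sqrt((Yc ** 2).sum(axis=1))
    ok = (sx > 0) & (sy > 0)
    if (~ok).any():
        logger.warning("link_correlation: dropping %d zero-variance pairs", int((~ok).sum()))
    r = np.full(len(pairs), np.nan)
    r[ok] = (Xc[ok] * Yc[ok]).sum(axis=1) / (sx[ok] * sy[ok])
    r = np.clip(r, -1.0, 1.0)

    p = np.full(len(pairs), np.nan)
    df = n - 2
    rr = r[ok]
    with np.errstate(divide="ignore"):
        t = rr * np.sqrt(df / np.maximum(1.0 - rr * rr, 1e-300))
    p[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    p[ok] = np.minimum(p[ok], 1.0)

    out = pairs.copy()
    out["pcc"] = r
    out["p"] = p
    return out[ok].reset_index(drop=True)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def filter_links(
    links: pd.DataFrame, min_abs_r: float = 0.2, alpha: float = 0.05
) -> pd.DataFrame:
    """Flag high-confidence links: |PCC| strictly > 0.2 and BH q strictly < 0.05.

    q is computed over ALL tested pairs (before any correlation filtering).
    """
    out = links.copy()
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["passes"] = (np.abs(out["pcc"]) > min_abs_r) & (out["q"] < alpha)
    logger.info("filter_links: %d/%d pairs pass", int(out["passes"].sum()), len(out))
    return out


def gpc_genes(links: pd.DataFrame, top_frac: float = 0.05) -> GPCSet:
    """Call genes with predictive chromatin.

    Counts passing links per gene (genes with >= 1 passing link), takes the
    nearest-rank (1 - top_frac) percentile of the count distribution as the
    threshold, and returns genes whose count strictly exceeds it.
    """
    passing = links[links["passes"]]
    if passing.empty:
        raise ValueError("no passing links")
    counts = passing.groupby("gene").size().sort_index()
    vals = np.sort(counts.to_numpy())
    rank = int(np.ceil((1.0 - top_frac) * len(vals)))  # nearest-rank percentile
    threshold = float(vals[max(rank - 1, 0)])
    genes = sorted(counts.index[counts > threshold])
    return GPCSet(counts=counts, threshold=threshold, genes=genes)


def hypergeom_overlap(
    set_a, set_b, universe, alternative: str = "two-sided"
) -> tuple[int, float]:
    """Overlap of two gene sets with a hypergeometric p-value.

    One-sided is the over-representation tail P(X >= overlap); the two-sided
    variant doubles it and caps at 1.
    """
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("sets must be subsets of the universe")
    k = len(a & b)
    M, nA, nB = len(universe), len(a), len(b)
    p1 = float(stats.hypergeom.sf(k - 1, M, nA, nB))
    if alternative == "one-sided":
        return k, min(p1, 1.0)
    if alternative == "two-sided":
        return k, min(2.0 * p1, 1.0)
    raise ValueError(f"unknown alternative: {alternative}")


def motif_enrichment_p(
    n_universe: int, n_with_motif: int, n_drawn: int, n_hit: int
) -> float:
    """One-sided over-representation p for motif hits among drawn CREs."""
    return float(stats.hypergeom.sf(n_hit - 1, n_universe, n_with_motif, n_drawn))
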