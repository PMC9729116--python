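"""Cross-modality integration: joint CCA embedding, ATAC-to-RNA matching and
100-cell pseudobulk construction.

Chromatin and expression are measured in different cells, so CRE-gene
correlation needs computationally matched cells: every ATAC nucleus is mapped
to its nearest RNA cell in a joint CCA L2 space, and pseudobulks aggregate a
seed nucleus with its 99 nearest ATAC neighbors (peak counts summed, CPM) and
the matched RNA cells (gene signal summed, TPM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atac import _sign_fix

logger = logging.getLogger(__name__)


@dataclass
class JointEmbedding:
    """L2-normalized CCA coordinates for both modalities."""

    rna_coords: np.ndarray
    atac_coords: np.ndarray
    rna_cells: pd.Index
    atac_nuclei: pd.Index


def center_by_sample(embedding: np.ndarray, sample_ids: pd.Series) -> np.ndarray:
    """Subtract the per-sample mean from each embedding dimension.

    A deliberately simple linear batch correction: it removes constant
    per-sample offsets (and, with one sample, reduces to global centering).
    """
    emb = np.asarray(embedding, dtype=float).copy()
    ids = np.asarray(sample_ids)
    for s in pd.unique(ids):
        mask = ids == s
        emb[mask] -= emb[mask].mean(axis=0, keepdims=True)
    return emb


def _standardize_genes(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (row) standardization; returns (Z, usable-row mask)."""
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    ok = (sd.ravel() > 0)
    Z = np.zeros_like(X, dtype=float)
    Z[ok] = (X[ok] - mean[ok]) / sd[ok]
    return Z, ok


def joint_cca(
    rna_E: np.ndarray,
    atac_activity: np.ndarray,
    rna_genes: pd.Index,
    atac_genes: pd.Index,
    rna_cells: pd.Index,
    atac_nuclei: pd.Index,
    shared_genes=None,
    d: int = 20,
) -> JointEmbedding:
    """Diagonal CCA of expression against gene activity.

    Both matrices (gene x cell) are restricted to the shared genes and
    standardized per gene (zero-variance genes dropped with a warning); the
    cross-product is decomposed by truncated SVD and the two singular-vector
    sides, L2-normalized per row, form the joint space.
    """
    if shared_genes is None:
        shared_genes = rna_genes.intersection(atac_genes)
    shared_genes = pd.Index(shared_genes)
    ri = rna_genes.get_indexer(shared_genes)
    ai = atac_genes.get_indexer(shared_genes)
    if (ri < 0).any() or (ai < 0).any():
        raise ValueError("shared_genes not present in both matrices")

    Zr, ok_r = _standardize_genes(np.asarray(rna_E, dtype=float)[ri])
    Za, ok_a = _standardize_genes(np.asarray(atac_activity, dtype=float)[ai])
    ok = ok_r & ok_a
    n_drop = int((~ok).sum())
    if n_drop:
        logger.warning("joint_cca: dropping %d zero-variance shared genes", n_drop)
    if ok.sum() < d:
        raise ValueError(f"only {int(ok.sum())} usable shared genes for d={d}")
    Zr, Za = Zr[ok], Za[ok]

    # randomized SVD of the cross-product Zr.T @ Za without forming it
    rng = np.random.default_rng(0)
    G = rng.standard_normal((Za.shape[1], d + 8))
    Y = Zr.T @ (Za @ G)  # range sketch of the cells x nuclei cross-product
    Y = Zr.T @ (Za @ (Za.T @ (Zr @ Y)))  # one power iteration for accuracy
    Q, _ = np.linalg.qr(Y)
    B = (Zr @ Q).T @ Za  # (d+8) x nuclei
    ub, s, vt = np.linalg.svd(B, full_matrices=False)
    u = Q @ ub
    order = np.argsort(-s)[:d]
    u, v = u[:, order], vt[order].T
    u, v = _sign_fix(u, v)

    def l2(x):
        n = np.linalg.norm(x, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return x / n

    return JointEmbedding(
        rna_coords=l2(u), atac_coords=l2(v),
        rna_cells=pd.Index(rna_cells), atac_nuclei=pd.Index(atac_nuclei),
    )


def match_modalities(
    joint: JointEmbedding,
    rna_samples: pd.Series | None = None,
    atac_samples: pd.Series | None = None,
) -> pd.Series:
    """Map each ATAC nucleus to its nearest RNA cell (Euclidean, L2 space).

    When per-sample labels are given for both modalities, each side of the
    joint space is sample-centered (the linear batch-correction stand-in) and
    re-normalized before the search, so matches are not driven by batch
    offsets.  RNA cells may be matched repeatedly.  Exact distance ties
    resolve to the lexicographically first cell id.
    """
    if len(joint.rna_cells) == 0:
        raise ValueError("empty RNA side")
    R, A = joint.rna_coords, joint.atac_coords
    if rna_samples is not None and atac_samples is not None:
        def renorm(x):
            n = np.linalg.norm(x, axis=1, keepdims=True)
            n[n == 0] = 1.0
            return x / n
        R = renorm(center_by_sample(R, rna_samples.loc[joint.rna_cells]))
        A = renorm(center_by_sample(A, atac_samples.loc[joint.atac_nuclei]))
    # sort RNA cells by id so argmin's first-hit rule is the id-order tie-break
    order = np.argsort(joint.rna_cells)
    R = R[order]
    ids = np.asarray(joint.rna_cells[order])
    r_sq = (R ** 2).sum(axis=1)
    out = np.empty(len(joint.atac_nuclei), dtype=object)
    chunk = 1024
    for lo in range(0, len(joint.atac_nuclei), chunk):
        a = A[lo:lo + chunk]
        d2 = r_sq[None, :] - 2.0 * (a @ R.T)  # + |a|^2, constant per row
        out[lo:lo + chunk] = ids[d2.argmin(axis=1)]
    return pd.Series(out, index=joint.atac_nuclei, name="matched_cell")


@dataclass
class Pseudobulk:
    """A 100-cell neighborhood aggregate across both modalities."""

    seed_nucleus: str
    member_atac: list
    member_rna: list  # multiset: image of member_atac under the match
    peak_cpm: np.ndarray
    gene_tpm: np.ndarray


def knn_indices(coords: np.ndarray, seeds: np.ndarray, k: int) -> np.ndarray:
    """Exact k nearest neighbors (self excluded) with (distance, index) ties
    resolved by index order; rows follow ``seeds``."""
    out = np.empty((len(seeds), k), dtype=int)
    for r, i in enumerate(seeds):
        d2 = ((coords - coords[i]) ** 2).sum(axis=1)
        d2[i] = np.inf
        idx = np.lexsort((np.arange(len(d2)), d2))
        out[r] = idx[:k]
    return out


def build_pseudobulks(
    atac_coords: np.ndarray,
    peak_mat,
    match: pd.Series,
    rna_tpm: np.ndarray,
    rna_cells: pd.Index,
    n_seeds: int = 200,
    k_neighbors: int = 99,
    seed: int = 0,
) -> list[Pseudobulk]:
    """Aggregate ``n_seeds`` random 100-nucleus neighborhoods.

    Seeds are drawn uniformly without replacement; each is joined with its
    ``k_neighbors`` nearest nuclei in the (batch-corrected) ATAC embedding.
    Peak counts are summed and CPM-normalized; the matched RNA cells' TPM
    columns are summed and rescaled to 1e6 (TPM).
    """
    n_nuc = peak_mat.n_nuclei
    if atac_coords.shape[0] != n_nuc:
        raise ValueError("embedding rows != nuclei")
    if n_seeds > n_nuc:
        logger.warning("n_seeds=%d > %d nuclei; reducing", n_seeds, n_nuc)
        n_seeds = n_nuc
    if k_neighbors >= n_nuc:
        raise ValueError("k_neighbors must be < number of nuclei")

    rng = np.random.default_rng(seed)
    seeds = np.sort(rng.choice(n_nuc, size=n_seeds, replace=False))
    nbrs = knn_indices(atac_coords, seeds, k_neighbors) if k_neighbors else \
        np.empty((n_seeds, 0), dtype=int)

    counts = peak_mat.counts.tocsc()
    rna_pos = {c: i for i, c in enumerate(rna_cells)}
    out = []
    for r, i in enumerate(seeds):
        members = np.concatenate(([i], nbrs[r]))
        member_ids = [peak_mat.nuclei[j] for j in members]
        pc = np.asarray(counts[:, members].sum(axis=1)).ravel().astype(float)
        tot = pc.sum()
        cpm = pc / tot * 1e6 if tot > 0 else pc
        matched = [match.loc[m] for m in member_ids]
        cols = [rna_pos[c] for c in matched]
        gt = rna_tpm[:, cols].sum(axis=1)
        gtot = gt.sum()
        tpm = gt / gtot * 1e6 if gtot > 0 else gt
        out.append(
            Pseudobulk(
                seed_nucleus=peak_mat.nuclei[i],
                member_atac=member_ids,
                member_rna=matched,
                peak_cpm=cpm,
                gene_tpm=tpm,
            )
        )
    return out


def pseudobulk_matrices(pseudobulks: list[Pseudobulk]) -> tuple[np.ndarray, np.ndarray]:
    """Stack pseudobulks into (peak x pb CPM, gene x pb TPM) arrays."""
    cpm = np.column_stack([p.peak_cpm for p in pseudobulks])
    tpm = np.column_stack([p.gene_tpm for p in pseudobulks])
    return cpm, tpm
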