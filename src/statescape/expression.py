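"""Expression data model, QC filters, transforms, signature scoring and markers.

The conventions used throughout: single-cell expression arrives as TPM
(gene x cell, Smart-seq2 style), log expression is ``E = log2(TPM/10 + 1)``,
aggregate expression is ``Ea(i) = log2(mean TPM_i + 1)`` and relative
expression ``Er`` is ``E`` centered per gene over cells.  All signature and
program scores downstream are means of ``Er`` over gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: cells whose protocol is one of these are held to the fresh-tissue QC rules
FRESH, FROZEN = "fresh", "frozen"

#: default housekeeping set used when the caller supplies none; a small list of
#: broadly expressed genes (configurable -- any real analysis should pass its own)
DEFAULT_HOUSEKEEPING = (
    "ACTB", "GAPDH", "B2M", "RPLP0", "TBP", "UBC", "PGK1", "PPIA",
    "HPRT1", "TFRC", "GUSB", "YWHAZ", "SDHA", "HMBS", "POLR2A", "LDHA",
)


@dataclass
class ExpressionMatrix:
    """Gene x cell TPM with per-cell metadata.

    ``tpm`` is a dense float array (genes x cells).  ``cell_meta`` is indexed
    by cell id and must contain ``sample_id`` and ``protocol``; frozen cells
    additionally need ``alignment_rate``.  ``gene_meta`` is indexed by gene id
    and may carry a boolean ``housekeeping`` column.
    """

    tpm: np.ndarray
    genes: pd.Index
    cells: pd.Index
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.genes = pd.Index(self.genes)
        self.cells = pd.Index(self.cells)
        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(index=self.genes)
        if self.tpm.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"tpm shape {self.tpm.shape} != (n_genes={len(self.genes)}, "
                f"n_cells={len(self.cells)})"
            )
        if np.any(self.tpm < 0):
            raise ValueError("TPM matrix has negative entries")
        if not self.genes.is_unique or not self.cells.is_unique:
            raise ValueError("gene/cell identifiers must be unique")
        if len(self.cell_meta) != len(self.cells):
            raise ValueError("cell_meta row count != cell count")
        self.cell_meta = self.cell_meta.loc[self.cells]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        return replace(
            self,
            tpm=self.tpm[:, mask],
            cells=self.cells[mask],
            cell_meta=self.cell_meta.loc[self.cells[mask]],
        )

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        return replace(
            self,
            tpm=self.tpm[mask, :],
            genes=self.genes[mask],
            gene_meta=self.gene_meta.loc[self.genes[mask]],
        )


@dataclass
class LogExpression:
    """E = log2(TPM/10 + 1) (gene x cell) plus per-gene aggregate Ea."""

    E: np.ndarray
    Ea: np.ndarray
    genes: pd.Index
    cells: pd.Index


@dataclass
class RelativeExpression:
    """Er = E - per-gene mean over cells.  Each gene row sums to ~0."""

    Er: np.ndarray
    genes: pd.Index
    cells: pd.Index

    def row(self, gene: str) -> np.ndarray:
        return self.Er[self.genes.get_loc(gene), :]


def detected_genes_per_cell(mat: ExpressionMatrix) -> np.ndarray:
    """Number of detected genes per cell; detection means TPM > 0."""
    return (mat.tpm > 0).sum(axis=0)


def qc_filter_cells(
    mat: ExpressionMatrix,
    housekeeping_set=DEFAULT_HOUSEKEEPING,
    fresh_min_genes: int = 2000,
    fresh_min_hk: float = 2.5,
    frozen_min_genes: int = 1000,
    frozen_min_align: float = 0.4,
) -> ExpressionMatrix:
    """Remove low-quality cells.

    Fresh cells are kept iff they detect at least ``fresh_min_genes`` genes
    (TPM > 0) and their mean housekeeping log-expression is at least
    ``fresh_min_hk``.  Frozen cells are kept iff they detect at least
    ``frozen_min_genes`` genes and their alignment rate is at least
    ``frozen_min_align``.  All "< x" removal thresholds are strict: a cell
    sitting exactly on a boundary is kept.
    """
    protocol = mat.cell_meta["protocol"].to_numpy()
    bad = ~np.isin(protocol, [FRESH, FROZEN])
    if bad.any():
        raise ValueError(f"unknown protocol values: {set(protocol[bad])}")

    n_detected = detected_genes_per_cell(mat)
    hk_mask = mat.genes.isin(housekeeping_set)
    if not hk_mask.any():
        raise ValueError("no housekeeping genes found in the matrix")
    hk_E = np.log2(mat.tpm[hk_mask, :] / 10.0 + 1.0).mean(axis=0)

    is_fresh = protocol == FRESH
    is_frozen = ~is_fresh
    keep = np.ones(mat.n_cells, dtype=bool)

    keep[is_fresh & (n_detected < fresh_min_genes)] = False
    keep[is_fresh & (hk_E < fresh_min_hk)] = False

    if is_frozen.any():
        if "alignment_rate" not in mat.cell_meta.columns:
            raise ValueError("frozen cells present but alignment_rate missing")
        align = mat.cell_meta["alignment_rate"].to_numpy(dtype=float)
        if np.isnan(align[is_frozen]).any():
            raise ValueError("frozen cell with missing alignment_rate")
        keep[is_frozen & (n_detected < frozen_min_genes)] = False
        keep[is_frozen & (align < frozen_min_align)] = False

    removed = {
        "fresh_gene_rule": int((is_fresh & (n_detected < fresh_min_genes)).sum()),
        "fresh_hk_rule": int((is_fresh & (hk_E < fresh_min_hk)).sum()),
        "frozen_gene_rule": int((is_frozen & (n_detected < frozen_min_genes)).sum()),
    }
    if is_frozen.any():
        align = mat.cell_meta["alignment_rate"].to_numpy(dtype=float)
        removed["frozen_alignment_rule"] = int((is_frozen & (align < frozen_min_align)).sum())
    logger.info("cell QC: %d/%d kept; per-rule removals %s",
                int(keep.sum()), mat.n_cells, removed)
    return mat.subset_cells(keep)


def qc_filter_genes(
    mat: ExpressionMatrix, min_tpm: float = 16.0, min_cells: int = 10
) -> ExpressionMatrix:
    """Keep genes with TPM strictly above ``min_tpm`` in at least ``min_cells`` cells."""
    n_high = (mat.tpm > min_tpm).sum(axis=1)
    keep = n_high >= min_cells
    logger.info("gene QC: %d/%d genes kept", int(keep.sum()), mat.n_genes)
    return mat.subset_genes(keep)


def transform(mat: ExpressionMatrix) -> tuple[LogExpression, RelativeExpression]:
    """Compute E, Ea and the per-gene centered Er from TPM."""
    if mat.n_cells == 0 or mat.n_genes == 0:
        raise ValueError("cannot transform an empty expression matrix")
    E = np.log2(mat.tpm / 10.0 + 1.0)
    Ea = np.log2(mat.tpm.mean(axis=1) + 1.0)
    Er = E - E.mean(axis=1, keepdims=True)
    return (
        LogExpression(E=E, Ea=Ea, genes=mat.genes, cells=mat.cells),
        RelativeExpression(Er=Er, genes=mat.genes, cells=mat.cells),
    )


def select_overdispersed_genes(
    mat: ExpressionMatrix, n: int = 10000
) -> list[str]:
    """Rank genes by over-dispersion and return the top ``n``.

    Over-dispersion is the excess of a gene's log variance over the typical
    log variance of genes with a similar mean: genes are grouped into
    mean-quantile bins and ranked by their within-bin log-variance residual
    (a deliberately simple dispersion ranking standing in for heavier
    variance-normalization machinery).  Ties are broken by gene id so the
    ranking is deterministic.
    """
    E = np.log2(mat.tpm / 10.0 + 1.0)
    mean = E.mean(axis=1)
    var = E.var(axis=1)
    expressed = mean > 0
    if expressed.sum() < n:
        logger.warning(
            "requested %d over-dispersed genes but only %d expressed; returning all",
            n, int(expressed.sum()),
        )
    lm = np.log1p(mean[expressed])
    lv = np.log1p(var[expressed])
    n_bins = max(1, min(20, len(lm) // 20))
    # quantile bins over the mean; stable for near-constant means
    edges = np.quantile(lm, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, lm, side="right") - 1, 0, n_bins - 1)
    resid = lv.copy()
    for b in range(n_bins):
        mask = bins == b
        if mask.any():
            resid[mask] = lv[mask] - np.median(lv[mask])
    genes = mat.genes[expressed]
    order = sorted(range(len(genes)), key=lambda i: (-resid[i], genes[i]))
    return [genes[i] for i in order[:n]]


def score_signature(rel: RelativeExpression, gene_set) -> np.ndarray:
    """Per-cell signature score: mean Er over the signature genes present."""
    gene_set = list(gene_set)
    mask = rel.genes.isin(gene_set)
    n_found = int(mask.sum())
    if n_found == 0:
        raise ValueError("signature has empty intersection with the gene universe")
    if n_found < len(set(gene_set)):
        logger.info("signature: %d/%d genes present in matrix", n_found, len(set(gene_set)))
    return rel.Er[mask, :].mean(axis=0)


SCORE_TOO_LOW = "score_too_low"


def score_signatures(rel: RelativeExpression, signatures: dict) -> pd.DataFrame:
    """Score every signature in a dict name -> gene list; cell x signature table."""
    cols = {name: score_signature(rel, genes) for name, genes in signatures.items()}
    return pd.DataFrame(cols, index=rel.cells)


def assign_state(scores: pd.DataFrame, threshold: float = 0.2) -> pd.Series:
    """Assign each cell to its highest-scoring signature.

    Cells whose maximum score is below ``threshold`` get the label
    ``"score_too_low"``.  Exact ties go to the first signature in column
    order and are logged.
    """
    vals = scores.to_numpy()
    idx = vals.argmax(axis=1)  # first occurrence wins on ties
    maxes = vals[np.arange(len(scores)), idx]
    n_ties = int((vals == maxes[:, None]).sum(axis=1).max(initial=1) > 1)
    if n_ties:
        tied = (vals == maxes[:, None]).sum(axis=1) > 1
        if tied.any():
            logger.info("assign_state: %d cells with tied top scores", int(tied.sum()))
    labels = pd.Series(
        np.asarray(scores.columns)[idx], index=scores.index, name="state"
    )
    labels[maxes < threshold] = SCORE_TOO_LOW
    return labels


def detect_markers(
    E: LogExpression,
    labels: pd.Series,
    min_frac: float = 0.3,
    min_lfc: float = 0.5,
    alpha: float = 0.05,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-group marker genes.

    A gene is a marker of a group when it is detected (E > 0) in at least
    ``min_frac`` of the group's cells, its in-group minus out-group mean E is
    at least ``min_lfc``, and a Wilcoxon rank-sum test (in vs out) survives
    Bonferroni correction at ``alpha``.  The snATAC differential-activity
    variant is this same operation with ``min_frac=0.2, min_lfc=0.1`` run on
    log gene activities.
    """
    labels = labels.loc[E.cells]
    groups = [g for g in pd.unique(labels) if (labels == g).sum() >= min_cells]
    skipped = set(pd.unique(labels)) - set(groups)
    if skipped:
        logger.warning("detect_markers: skipping groups with <%d cells: %s", min_cells, skipped)
    if len(groups) < 2:
        raise ValueError("need at least two groups with enough cells")

    n_tests = len(groups) * E.E.shape[0]
    rows = []
    for g in groups:
        in_mask = (labels == g).to_numpy()
        Ein, Eout = E.E[:, in_mask], E.E[:, ~in_mask]
        frac = (Ein > 0).mean(axis=1)
        lfc = Ein.mean(axis=1) - Eout.mean(axis=1)
        cand = np.flatnonzero((frac >= min_frac) & (lfc >= min_lfc))
        for i in cand:
            p = stats.mannwhitneyu(Ein[i], Eout[i], alternative="two-sided").pvalue
            p_adj = min(1.0, p * n_tests)
            if p_adj < alpha:
                rows.append((g, E.genes[i], frac[i], lfc[i], p, p_adj))
    return pd.DataFrame(
        rows, columns=["group", "gene", "detected_frac", "lfc", "p", "p_bonferroni"]
    )


UNCLASSIFIED = "unclassified"


def classify_tams(
    rel: RelativeExpression, microglia_set, macrophage_set
) -> pd.Series:
    """Classify myeloid cells as microglia vs macrophage by signature score.

    Each cell gets the label of the higher-scoring signature; exact ties are
    left ``"unclassified"``.
    """
    mg = score_signature(rel, microglia_set)
    mac = score_signature(rel, macrophage_set)
    out = np.where(mg > mac, "microglia", "macrophage")
    out = np.where(mg == mac, UNCLASSIFIED, out)
    return pd.Series(out, index=rel.cells, name="tam_class")
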