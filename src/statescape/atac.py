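"""snATAC data model, QC filtering, TF-IDF/LSI embedding and gene activities."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import sparse
from scipy.sparse.linalg import svds

logger = logging.getLogger(__name__)


@dataclass
class GeneAnnotation:
    """Gene intervals (0-based half-open) with strand; TSS derives from strand.

    The table is indexed by gene id with columns chrom, start, end, strand.
    TSS = start for '+' genes and end - 1 for '-' genes.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        missing = {"chrom", "start", "end", "strand"} - set(t.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if (t["start"] >= t["end"]).any():
            raise ValueError("annotation has intervals with start >= end")
        if not t["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")

    @property
    def tss(self) -> pd.Series:
        t = self.table
        return pd.Series(
            np.where(t["strand"] == "+", t["start"], t["end"] - 1),
            index=t.index, name="tss",
        )


@dataclass
class PeakMatrix:
    """Peak x nucleus integer counts (sparse) with BED-style peak intervals."""

    counts: sparse.csr_matrix
    peaks: pd.DataFrame  # indexed by peak id: chrom, start, end
    nuclei: pd.Index
    nucleus_meta: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self):
        self.nuclei = pd.Index(self.nuclei)
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.peaks), len(self.nuclei)):
            raise ValueError("counts shape does not match peaks x nuclei")
        if (self.peaks["start"] >= self.peaks["end"]).any():
            raise ValueError("malformed peak interval (start >= end)")
        if not self.peaks.index.is_unique:
            raise ValueError("peak ids must be unique")
        if self.nucleus_meta is None:
            self.nucleus_meta = pd.DataFrame(index=self.nuclei)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)

    def subset_nuclei(self, mask: np.ndarray) -> "PeakMatrix":
        return replace(
            self,
            counts=self.counts[:, mask],
            nuclei=self.nuclei[mask],
            nucleus_meta=self.nucleus_meta.loc[self.nuclei[mask]],
        )

    def subset_peaks(self, mask: np.ndarray) -> "PeakMatrix":
        return replace(self, counts=self.counts[mask, :], peaks=self.peaks.loc[mask])


#: required columns of the per-nucleus QC metrics table
QC_COLUMNS = (
    "peak_region_fragments",
    "pct_reads_in_peaks",
    "blacklist_ratio",
    "nucleosome_signal",
    "tss_enrichment",
)


def qc_filter_atac(
    mat: PeakMatrix,
    qc: pd.DataFrame,
    min_peaks: int = 200,
    min_nuclei_per_peak: int = 10,
    frag_lo: float = 1500,
    frag_hi: float = 15000,
    min_pct: float = 15,
    max_blacklist: float = 0.02,
    max_nucleosome: float = 2,
    min_tss: float = 4,
) -> PeakMatrix:
    """Apply the snATAC QC rules.

    Nuclei are kept iff they detect >= ``min_peaks`` peaks, their fragment
    count in peaks lies in [frag_lo, frag_hi] (inclusive at both ends), the
    percent of reads in peaks is strictly > ``min_pct``, the blacklist ratio
    strictly < ``max_blacklist``, the nucleosome signal strictly <
    ``max_nucleosome`` and the TSS enrichment strictly > ``min_tss``.  Peaks
    are then kept iff detected in >= ``min_nuclei_per_peak`` surviving nuclei.
    """
    missing = set(mat.nuclei) - set(qc.index)
    if missing:
        raise ValueError(f"{len(missing)} nuclei missing from the QC table")
    qc = qc.loc[mat.nuclei]

    detected = np.asarray((mat.counts > 0).sum(axis=0)).ravel()
    frags = qc["peak_region_fragments"].to_numpy(dtype=float)
    rules = {
        "min_detected_peaks": detected >= min_peaks,
        "fragments_in_range": (frags >= frag_lo) & (frags <= frag_hi),
        "pct_reads_in_peaks": qc["pct_reads_in_peaks"].to_numpy(dtype=float) > min_pct,
        "blacklist_ratio": qc["blacklist_ratio"].to_numpy(dtype=float) < max_blacklist,
        "nucleosome_signal": qc["nucleosome_signal"].to_numpy(dtype=float) < max_nucleosome,
        "tss_enrichment": qc["tss_enrichment"].to_numpy(dtype=float) > min_tss,
    }
    keep = np.ones(mat.n_nuclei, dtype=bool)
    for name, ok in rules.items():
        logger.info("atac QC: rule %s removes %d nuclei", name, int((~ok & keep).sum()))
        keep &= ok
    out = mat.subset_nuclei(keep)

    peak_detected = np.asarray((out.counts > 0).sum(axis=1)).ravel()
    peak_keep = peak_detected >= min_nuclei_per_peak
    logger.info(
        "atac QC: %d/%d nuclei kept, %d/%d peaks kept",
        out.n_nuclei, mat.n_nuclei, int(peak_keep.sum()), mat.n_peaks,
    )
    return out.subset_peaks(peak_keep)


@dataclass
class LSIEmbedding:
    """Nucleus x d LSI coordinates with bookkeeping on dropped components."""

    coords: np.ndarray
    nuclei: pd.Index
    components: list[int]
    depth_correlation: np.ndarray
    dropped: list[int]


def _sign_fix(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the SVD sign ambiguity: make each component's largest-|loading|
    entry (on the feature side) positive."""
    for j in range(u.shape[1]):
        i = np.argmax(np.abs(u[:, j]))
        if u[i, j] < 0:
            u[:, j] *= -1
            v[:, j] *= -1
    return u, v


def tfidf_lsi(
    mat: PeakMatrix,
    d: int = 30,
    scale: float = 1e4,
    drop_depth_corr: float = 0.5,
    top_feature_frac: float = 0.25,
) -> LSIEmbedding:
    """Log TF-IDF normalization followed by truncated SVD (LSI).

    Features are the top ``top_feature_frac`` of peaks by total accessibility.
    The TF-IDF value is ``ln(1 + tf * idf * scale)`` with tf = count /
    nucleus total and idf = n_nuclei / number of nuclei detecting the peak.
    Components whose |Pearson r| with log total fragments exceeds
    ``drop_depth_corr`` are dropped (sequencing-depth components; on real
    data this is typically component 1).
    """
    counts = mat.counts.tocsr()
    totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    if (totals == 0).any():
        raise ValueError("nucleus with zero total counts; run QC first")

    peak_totals = np.asarray(counts.sum(axis=1)).ravel()
    n_keep = max(int(np.ceil(top_feature_frac * mat.n_peaks)), d + 1)
    # ties at the accessibility cutoff resolve by peak id, so the feature set
    # does not depend on row order
    order = sorted(range(mat.n_peaks),
                   key=lambda i: (-peak_totals[i], mat.peaks.index[i]))
    sel = np.sort(order[:n_keep])
    sub = counts[sel, :].tocoo()

    if d > min(sub.shape) - 1:
        raise ValueError(f"d={d} too large for matrix of shape {sub.shape}")

    n_detect = np.asarray((counts[sel, :] > 0).sum(axis=1)).ravel().astype(float)
    n_detect[n_detect == 0] = 1.0
    tf = sub.data / totals[sub.col]
    idf = mat.n_nuclei / n_detect[sub.row]
    vals = np.log1p(tf * idf * scale)
    X = sparse.csr_matrix((vals, (sub.row, sub.col)), shape=sub.shape)

    # exact truncated SVD; ARPACK works on the feature-side Gram matrix (the
    # smaller dimension), and the all-ones start vector makes the result
    # deterministic and exactly invariant to peak reordering
    u, s, vt = svds(X, k=d, v0=np.ones(min(X.shape)))
    order = np.argsort(-s)
    u, s, v = u[:, order], s[order], vt[order].T
    u, v = _sign_fix(u, v)
    coords = v * s  # nucleus x d

    log_depth = np.log(totals)
    depth_corr = np.array([
        0.0 if np.std(coords[:, j]) == 0 else np.corrcoef(coords[:, j], log_depth)[0, 1]
        for j in range(d)
    ])
    keep = np.abs(depth_corr) <= drop_depth_corr
    dropped = [int(j) for j in np.flatnonzero(~keep)]
    if dropped:
        logger.info("tfidf_lsi: dropping depth-correlated components %s", dropped)
    if keep.sum() < 2:
        keep = np.ones(d, dtype=bool)
        dropped = []
        logger.warning("tfidf_lsi: depth rule would leave <2 components; keeping all")
    return LSIEmbedding(
        coords=coords[:, keep],
        nuclei=mat.nuclei,
        components=[int(j) for j in np.flatnonzero(keep)],
        depth_correlation=depth_corr,
        dropped=dropped,
    )


def gene_activity(
    mat: PeakMatrix,
    annotation: GeneAnnotation,
    upstream: int = 2000,
    normalize: bool = True,
) -> tuple[np.ndarray, pd.Index]:
    """Gene x nucleus activity: sum of peak counts over gene body + promoter.

    The promoter is ``upstream`` bp on the 5' side of the TSS, so the counted
    region is [start - upstream, end) for '+' genes and [start, end + upstream)
    for '-' genes (half-open; any nonempty intersection with the peak interval
    counts).  Peaks overlapping several gene regions count toward each.  When
    ``normalize`` is set, per-nucleus totals are scaled to the median total
    and log1p-transformed.  Genes whose region hosts no peak are omitted from
    the result (their activity is identically zero); the returned index names
    the genes kept.
    """
    ann = annotation.table
    trees: dict[str, IntervalTree] = {}
    for gi, (chrom, start, end, strand) in enumerate(
        zip(ann["chrom"], ann["start"], ann["end"], ann["strand"])
    ):
        lo = start - upstream if strand == "+" else start
        hi = end if strand == "+" else end + upstream
        trees.setdefault(chrom, IntervalTree()).addi(lo, hi, gi)

    # gene x peak incidence, then one sparse matmul
    rows, cols = [], []
    n_skipped = 0
    for pi, (chrom, start, end) in enumerate(
        zip(mat.peaks["chrom"], mat.peaks["start"], mat.peaks["end"])
    ):
        tree = trees.get(chrom)
        if tree is None:
            n_skipped += 1
            continue
        for h in tree.overlap(start, end):
            rows.append(h.data)
            cols.append(pi)
    if n_skipped:
        logger.warning("gene_activity: %d peaks on unknown chromosomes skipped", n_skipped)
    incidence = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(ann), mat.n_peaks)
    )
    covered = np.flatnonzero(np.diff(incidence.indptr) > 0)
    activity = np.asarray((incidence[covered] @ mat.counts).todense(), dtype=float)

    if normalize:
        totals = activity.sum(axis=0)
        med = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = np.where(totals > 0, activity / totals * med, 0.0)
        activity = np.log1p(scaled)
    return activity, ann.index[covered]
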