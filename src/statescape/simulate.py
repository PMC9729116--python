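"""Synthetic paired expression / ATAC / motif / spatial data with planted truth.

The generator emulates the statistical structure of a multi-omic tumor study:
cell states defined by disjoint gene signatures with batch effects and
dropout (Smart-seq2-like TPM), a single synthetic chromosome carrying every
gene at fixed spacing, accessible-chromatin peaks whose counts are coupled to
the cell-state factor for planted peak-gene links, per-state TF regulons with
motif hits enriched in true CREs, and an in situ cell map with colocalized
niches and bimodal immunofluorescence.  Every random draw flows from
``SimConfig.seed`` through named substreams, so identical configs produce
bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .atac import GeneAnnotation, PeakMatrix
from .expression import ExpressionMatrix
from .spatial import SpatialCellMap

logger = logging.getLogger(__name__)

DEFAULT_STATES = ("OPC-like", "OC-like", "AC-like", "MES-like", "cycling")

#: nonmalignant spatial types and their key marker gene (marker-rule typing)
DEFAULT_MARKER_MAP = {
    "oligodendrocyte": "MBP",
    "endothelial": "ESAM",
    "pericyte": "MYL9",
    "astrocyte": "GFAP",
    "TAM": "CD74",
    "neuron": "DLG4",
}

NOISE_STATE = "none"


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with the study-condition defaults.

    Expression: ``log2(TPM/10+1)`` is built as gene baseline + ``effect_size``
    for a cell's signature genes + a per-sample batch offset + Gaussian noise,
    back-transformed to TPM summing to 1e6 per cell, then zeroed gene-wise
    with probability ``dropout_p``.  ATAC: ``n_peaks`` candidate peaks within
    the gene span (of which ``frac_true_links`` are state-coupled true links
    targeting signature genes), plus per-type distal identity peaks placed
    beyond the 250 kb candidate window that give each cell type -- including
    the no-program type -- the same amount of type-specific accessibility.
    """

    n_samples: int = 6
    cells_per_sample: int = 400
    n_genes: int = 4000
    states: tuple = DEFAULT_STATES
    signature_size: int = 30
    effect_size: float = 2.0
    batch_sd: float = 0.3
    noise_sd: float = 0.4
    dropout_p: float = 0.3
    noise_frac: float = 0.15
    protocols: tuple | None = None  # per-sample; default all "fresh"
    n_housekeeping: int = 20
    hk_baseline: float = 6.0
    baseline_mean: float = 2.0
    baseline_sd: float = 1.0

    # --- ATAC ---
    nuclei_per_sample: int = 400
    n_peaks: int = 5000
    frac_true_links: float = 0.04
    link_strength: float = 0.6
    link_fold: float = 2.5
    link_base_rate: float = 0.25
    peak_base_rate: float = 0.12
    peak_base_sigma: float = 0.5
    hubs_per_state: tuple = (8, 6)
    n_identity_peaks: int = 100
    identity_peak_rate: float = 2.0
    identity_peak_fold: float = 4.0
    identity_noise: float = 0.0
    pseudobulk_size: int = 100
    gene_spacing: int = 100_000
    gene_length: int = 20_000
    peak_width: int = 500
    qc_fail_frac: float = 0.05

    # --- motifs / regulons ---
    motif_fg_p: float = 0.8
    motif_bg_p: float = 0.05
    n_decoy_tfs: int = 20

    # --- spatial ---
    n_spatial_cells: int = 2000
    field_size: float = 1000.0
    malignant_frac: float = 0.5
    niche_pairs: tuple = (("OPC-like", "OC-like"),)
    n_niches: int = 6
    niche_sd: float = 30.0
    marker_map: tuple = tuple(DEFAULT_MARKER_MAP.items())
    if_high_mean: float = 150.0
    if_low_mean: float = 30.0
    if_sd: float = 15.0
    marker_rate_fg: float = 5.0
    marker_rate_bg: float = 0.2

    seed: int = 0

    def __post_init__(self):
        for name in ("dropout_p", "frac_true_links", "motif_fg_p", "motif_bg_p",
                     "noise_frac", "malignant_frac", "qc_fail_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.signature_size * len(self.states) > self.n_genes:
            raise ValueError(
                f"{len(self.states)} signatures of {self.signature_size} genes "
                f"do not fit in {self.n_genes} genes"
            )
        if self.protocols is not None and len(self.protocols) != self.n_samples:
            raise ValueError("protocols must have one entry per sample")
        mal = set(self.states)
        nonmal = {t for t, _ in self.marker_map}
        if mal & nonmal:
            raise ValueError(f"overlapping type names: {mal & nonmal}")

    def rng(self, stream: int) -> np.random.Generator:
        """Named substream so each modality is independently reproducible."""
        return np.random.default_rng([self.seed % (2**31), stream])


@dataclass
class GroundTruth:
    """Planted structure, recorded as generated."""

    cell_states: pd.Series = None  # type: ignore[assignment]
    signatures: dict = field(default_factory=dict)
    housekeeping: list = field(default_factory=list)
    state_tfs: dict = field(default_factory=dict)
    nucleus_states: pd.Series = None  # type: ignore[assignment]
    true_links: list = field(default_factory=list)  # (peak_id, gene_id)
    link_states: dict = field(default_factory=dict)  # peak_id -> state
    planted_link_counts: dict = field(default_factory=dict)  # gene -> n links
    gpc_genes: list = field(default_factory=list)  # planted high-link genes
    identity_peaks: dict = field(default_factory=dict)  # type -> [peak ids]
    peak_ids: list = field(default_factory=list)
    decoy_tfs: list = field(default_factory=list)
    spatial_types: pd.Series = None  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# expression

def _dropout_scale(tpm: np.ndarray, target_zero_frac: float) -> float:
    """Solve for the detection scale tau with mean(exp(-TPM/tau)) = target.

    Dropout is expression-dependent (weakly expressed values are lost far
    more often than strong ones, as in real plate-based scRNA-seq);
    ``dropout_p`` is the overall fraction of values zeroed.
    """
    lo, hi = 1e-3, float(tpm.max()) + 1.0
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        frac = np.exp(-tpm / mid).mean()
        if frac > target_zero_frac:
            hi = mid
        else:
            lo = mid
        if hi / lo < 1.0001:
            break
    return float(np.sqrt(lo * hi))


def _gene_ids(cfg: SimConfig) -> tuple[list, list]:
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    hk = [f"hk{i:02d}" for i in range(cfg.n_housekeeping)]
    return genes, hk


def _signatures(cfg: SimConfig, genes: list) -> dict:
    """Disjoint contiguous signature blocks, one per state."""
    return {
        s: genes[k * cfg.signature_size:(k + 1) * cfg.signature_size]
        for k, s in enumerate(cfg.states)
    }


def _draw_states(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    states = np.asarray(list(cfg.states) + [NOISE_STATE], dtype=object)
    p = np.full(len(cfg.states), (1 - cfg.noise_frac) / len(cfg.states))
    p = np.append(p, cfg.noise_frac)
    return rng.choice(states, size=n, p=p)


def gen_expression(cfg: SimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate the TPM matrix with planted state signatures."""
    rng = cfg.rng(1)
    genes, hk = _gene_ids(cfg)
    all_genes = genes + hk
    signatures = _signatures(cfg, genes)

    protocols = list(cfg.protocols) if cfg.protocols is not None else ["fresh"] * cfg.n_samples
    samples = [f"S{j:02d}" for j in range(cfg.n_samples)]

    baseline = np.clip(
        rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(all_genes)), 0.1, None
    )
    baseline[len(genes):] = cfg.hk_baseline
    batch = rng.normal(0.0, cfg.batch_sd, size=(cfg.n_samples, len(all_genes)))
    batch[:, len(genes):] = 0.0  # housekeeping genes stay stable across batches

    sig_index = {s: np.asarray([all_genes.index(g) for g in gs]) for s, gs in signatures.items()}

    cell_ids, cell_sample, cell_proto, cell_state = [], [], [], []
    cols = []
    for j, (samp, proto) in enumerate(zip(samples, protocols)):
        states = _draw_states(cfg, rng, cfg.cells_per_sample)
        L = baseline[None, :] + batch[j][None, :] + rng.normal(
            0.0, cfg.noise_sd, size=(cfg.cells_per_sample, len(all_genes))
        )
        for s, idx in sig_index.items():
            rows = np.flatnonzero(states == s)
            if len(rows):
                L[np.ix_(rows, idx)] += cfg.effect_size
        tpm = np.clip((np.exp2(L) - 1.0) * 10.0, 0.0, None)
        tpm *= 1e6 / tpm.sum(axis=1, keepdims=True)
        if cfg.dropout_p > 0:
            tau = _dropout_scale(tpm, cfg.dropout_p)
            tpm[rng.random(tpm.shape) < np.exp(-tpm / tau)] = 0.0
        cols.append(tpm.T)  # gene x cell
        cell_ids += [f"{samp}_c{i:04d}" for i in range(cfg.cells_per_sample)]
        cell_sample += [samp] * cfg.cells_per_sample
        cell_proto += [proto] * cfg.cells_per_sample
        cell_state += list(states)

    tpm = np.concatenate(cols, axis=1)
    cells = pd.Index(cell_ids, name="cell_id")
    meta = pd.DataFrame(
        {"sample_id": cell_sample, "protocol": cell_proto}, index=cells
    )
    align = rng.uniform(0.85, 0.99, size=len(cells))
    meta["alignment_rate"] = np.where(
        np.asarray(cell_proto) == "frozen", align, np.nan
    )
    gene_meta = pd.DataFrame(
        {"housekeeping": [g in set(hk) for g in all_genes]},
        index=pd.Index(all_genes, name="gene_id"),
    )
    mat = ExpressionMatrix(
        tpm=tpm, genes=pd.Index(all_genes, name="gene_id"), cells=cells,
        cell_meta=meta, gene_meta=gene_meta,
    )
    truth = GroundTruth(
        cell_states=pd.Series(cell_state, index=cells, name="true_state"),
        signatures=signatures,
        housekeeping=hk,
        state_tfs={s: gs[0] for s, gs in signatures.items()},
    )
    return mat, truth


# ---------------------------------------------------------------------------
# ATAC

def link_noise_amplitude(cfg: SimConfig) -> float:
    """Noise amplitude b making planted links hit ``link_strength`` pseudobulks.

    A true-link peak for state s has per-nucleus Poisson rate
    ``mu * (1 + (fold-1) * x + b * u)`` with x the state indicator and u ~
    Exp(1) i.i.d. per peak and nucleus.  Across m-nucleus state-coherent
    pseudobulks the between-state variance of the summed count is
    B = (m mu (fold-1))^2 p(1-p) and the within variance is
    W = m (lambda_bar + mu^2 b^2); solving B/(B+W) = r^2 for b gives the
    closed form below.  b = 0 (with a warning) when the requested r exceeds
    what the Poisson floor permits.
    """
    r = cfg.link_strength
    if r <= 0:
        return 0.0
    mu = cfg.link_base_rate
    g = cfg.link_fold
    m = cfg.pseudobulk_size
    p = (1.0 - cfg.noise_frac) / len(cfg.states)
    B = (m * mu * (g - 1.0)) ** 2 * p * (1.0 - p)
    W_req = B * (1.0 - r * r) / (r * r)
    c = mu * (1.0 + (g - 1.0) * p)
    # mu^2 b^2 + mu b + (c - W_req/m) = 0
    disc = mu * mu - 4.0 * mu * mu * (c - W_req / m)
    if disc < 0 or (b := (-mu + np.sqrt(disc)) / (2.0 * mu * mu)) < 0:
        logger.warning(
            "link_strength %.2f above the Poisson ceiling for this config; "
            "using noise-free links", r,
        )
        return 0.0
    return float(b)


def _allocate_links(cfg: SimConfig, signatures: dict) -> list[tuple[str, int]]:
    """Per-gene planted link counts: a few hub genes per state plus singletons."""
    n_true = int(round(cfg.frac_true_links * cfg.n_peaks))
    if n_true == 0:
        return []
    n_states = len(cfg.states)
    per_state = [n_true // n_states] * n_states
    for k in range(n_true - sum(per_state)):
        per_state[k] += 1
    out = []
    for k, s in enumerate(cfg.states):
        gs = signatures[s]
        budget = per_state[k]
        hubs = [min(h, budget) for h in cfg.hubs_per_state]
        alloc = []
        for h, g in zip(hubs, gs):
            take = min(h, budget - sum(a for _, a in alloc))
            if take > 0:
                alloc.append((g, take))
        remaining = budget - sum(a for _, a in alloc)
        free = gs[len(cfg.hubs_per_state):]
        if remaining > len(free):
            raise ValueError(
                f"state {s}: {budget} links do not fit in a {cfg.signature_size}-gene "
                "signature with the configured hub pattern; lower frac_true_links "
                "or n_peaks, or enlarge signature_size"
            )
        alloc += [(g, 1) for g in free[:remaining]]
        out += alloc
    return out


def gen_atac(
    cfg: SimConfig, truth: GroundTruth
) -> tuple[PeakMatrix, GeneAnnotation, pd.DataFrame]:
    """Generate the peak x nucleus matrix, gene annotation and QC table.

    Genes sit on one synthetic chromosome at ``gene_spacing`` with alternating
    strand.  True-link peaks are placed inside their target gene's body (hence
    within 250 kb of, and nearest to, its TSS).  Background peak counts are
    independent Poisson.  Distal per-type identity peaks beyond the candidate
    window carry the cell-type chromatin signal that drives the LSI embedding,
    balanced across types so library size is uncoupled from state.
    """
    if truth.cell_states is None:
        raise ValueError("generate expression truth first")
    rng = cfg.rng(2)
    genes, hk = _gene_ids(cfg)
    all_genes = genes + hk

    ann = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": [10_000 + i * cfg.gene_spacing for i in range(len(all_genes))],
            "strand": ["+" if i % 2 == 0 else "-" for i in range(len(all_genes))],
        },
        index=pd.Index(all_genes, name="gene_id"),
    )
    ann["end"] = ann["start"] + cfg.gene_length
    ann = ann[["chrom", "start", "end", "strand"]]
    annotation = GeneAnnotation(ann)
    span = int(ann["end"].max()) + 10_000

    # --- nuclei ---
    samples = [f"S{j:02d}" for j in range(cfg.n_samples)]
    nuc_ids, nuc_sample, nuc_state = [], [], []
    for samp in samples:
        states = _draw_states(cfg, rng, cfg.nuclei_per_sample)
        nuc_ids += [f"{samp}_n{i:04d}" for i in range(cfg.nuclei_per_sample)]
        nuc_sample += [samp] * cfg.nuclei_per_sample
        nuc_state += list(states)
    nuclei = pd.Index(nuc_ids, name="nucleus_id")
    nuc_state = np.asarray(nuc_state, dtype=object)
    n_nuc = len(nuclei)

    alloc = _allocate_links(cfg, truth.signatures)
    n_true = sum(c for _, c in alloc)
    if n_true > cfg.n_peaks:
        raise ValueError("n_peaks too small to host all true links")
    n_bg = cfg.n_peaks - n_true

    gene_state = {g: s for s, gs in truth.signatures.items() for g in gs}
    half = cfg.peak_width // 2

    records = []  # (start, end, kind, payload)
    for g, c in alloc:
        gs, ge = int(ann.at[g, "start"]), int(ann.at[g, "end"])
        mids = rng.integers(gs + 1000, ge - 1000, size=c)
        for m in mids:
            records.append((int(m) - half, int(m) + half, "link", (g, gene_state[g])))
    bg_mids = rng.integers(half, span - half, size=n_bg)
    for m in bg_mids:
        records.append((int(m) - half, int(m) + half, "bg", None))
    far_start = span + 300_000
    id_types = list(cfg.states) + [NOISE_STATE]
    for t_i, t in enumerate(id_types):
        for k in range(cfg.n_identity_peaks):
            s0 = far_start + (t_i * cfg.n_identity_peaks + k) * 1_000
            records.append((s0, s0 + cfg.peak_width, "identity", t))

    order = sorted(range(len(records)), key=lambda i: records[i][0])
    peak_ids = [f"peak{i:05d}" for i in range(len(records))]
    peaks = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": [records[i][0] for i in order],
            "end": [records[i][1] for i in order],
        },
        index=pd.Index(peak_ids, name="peak_id"),
    )

    # --- counts (blocked by peak class; rates per row, nuclei in columns) ---
    b = link_noise_amplitude(cfg)
    mu = cfg.link_base_rate
    true_links, link_states = [], {}
    identity_peaks: dict = {t: [] for t in id_types}
    bg_rates = rng.lognormal(np.log(cfg.peak_base_rate), cfg.peak_base_sigma, size=n_bg)
    bg_seen = 0
    state_x = {s: (nuc_state == s).astype(float) for s in id_types}

    blocks = []
    block_size = max(1, int(4e7 // max(n_nuc, 1)))
    for lo in range(0, len(records), block_size):
        rows = order[lo:lo + block_size]
        lam = np.empty((len(rows), n_nuc))
        for k, i in enumerate(rows):
            _, _, kind, payload = records[i]
            pid = peak_ids[lo + k]
            if kind == "link":
                g, s = payload
                lam[k] = mu * (1.0 + (cfg.link_fold - 1.0) * state_x[s]
                               + b * rng.exponential(1.0, n_nuc))
                true_links.append((pid, g))
                link_states[pid] = s
            elif kind == "bg":
                lam[k] = bg_rates[bg_seen]
                bg_seen += 1
            else:
                t = payload
                lam[k] = cfg.identity_peak_rate * (
                    1.0 + (cfg.identity_peak_fold - 1.0) * state_x[t]
                    + (cfg.identity_noise * rng.exponential(1.0, n_nuc)
                       if cfg.identity_noise else 0.0)
                )
                identity_peaks[t].append(pid)
        blocks.append(sparse.csr_matrix(rng.poisson(lam).astype(np.int32)))
        del lam

    mat = PeakMatrix(
        counts=sparse.vstack(blocks, format="csr"),
        peaks=peaks,
        nuclei=nuclei,
        nucleus_meta=pd.DataFrame({"sample_id": nuc_sample}, index=nuclei),
    )

    # --- QC table with planted failure fractions ---
    totals = np.asarray(mat.counts.sum(axis=0)).ravel().astype(float)
    f = cfg.qc_fail_frac
    qc = pd.DataFrame(index=nuclei)
    fail = rng.random(n_nuc) < f
    low_or_high = rng.random(n_nuc) < 0.5
    frag = totals.copy()
    frag[fail & low_or_high] = rng.uniform(200, 1400, size=int((fail & low_or_high).sum()))
    frag[fail & ~low_or_high] = rng.uniform(15500, 30000, size=int((fail & ~low_or_high).sum()))
    qc["peak_region_fragments"] = frag
    fail = rng.random(n_nuc) < f
    qc["pct_reads_in_peaks"] = np.where(fail, rng.uniform(2, 14.9, n_nuc), rng.uniform(40, 90, n_nuc))
    fail = rng.random(n_nuc) < f
    qc["blacklist_ratio"] = np.where(fail, rng.uniform(0.025, 0.1, n_nuc), rng.uniform(0, 0.015, n_nuc))
    fail = rng.random(n_nuc) < f
    qc["nucleosome_signal"] = np.where(fail, rng.uniform(2.1, 4, n_nuc), rng.uniform(0.2, 1.5, n_nuc))
    fail = rng.random(n_nuc) < f
    qc["tss_enrichment"] = np.where(fail, rng.uniform(0.5, 3.9, n_nuc), rng.uniform(5, 12, n_nuc))

    truth.nucleus_states = pd.Series(nuc_state, index=nuclei, name="true_state")
    truth.true_links = true_links
    truth.link_states = link_states
    counts_per_gene: dict = {}
    for _, g in true_links:
        counts_per_gene[g] = counts_per_gene.get(g, 0) + 1
    truth.planted_link_counts = counts_per_gene
    if counts_per_gene:
        vals = sorted(counts_per_gene.values())
        rank = int(np.ceil(0.95 * len(vals))) - 1
        thr = vals[rank]
        truth.gpc_genes = sorted(g for g, c in counts_per_gene.items() if c > thr)
    truth.identity_peaks = identity_peaks
    truth.peak_ids = peak_ids
    return mat, annotation, qc


# ---------------------------------------------------------------------------
# motifs / regulons

def gen_motifs_regulons(
    cfg: SimConfig, truth: GroundTruth
) -> tuple[dict, pd.DataFrame]:
    """One planted TF per state plus decoys; motif hits enriched in true CREs.

    Returns (regulons, motif_hits) where regulons maps TF name -> target gene
    list and motif_hits is a boolean peak x TF DataFrame.  The planted TF of
    state s hits CREs linked to state-s signature genes with probability
    ``motif_fg_p`` and every other peak with ``motif_bg_p``; decoy TFs hit at
    background rate everywhere.
    """
    if not truth.link_states and cfg.frac_true_links > 0:
        raise ValueError("generate ATAC truth first")
    rng = cfg.rng(3)
    genes, _ = _gene_ids(cfg)
    sig_genes = {g for gs in truth.signatures.values() for g in gs}
    free = [g for g in genes if g not in sig_genes]

    regulons = {truth.state_tfs[s]: list(truth.signatures[s]) for s in cfg.states}
    decoys = list(rng.choice(free, size=cfg.n_decoy_tfs, replace=False))
    for tf in decoys:
        regulons[tf] = list(rng.choice(free, size=cfg.signature_size, replace=False))
    truth.decoy_tfs = decoys

    all_peaks = list(truth.peak_ids)
    tfs = [truth.state_tfs[s] for s in cfg.states] + decoys
    hits = rng.random((len(all_peaks), len(tfs))) < cfg.motif_bg_p
    peak_pos = {p: i for i, p in enumerate(all_peaks)}
    for k, s in enumerate(cfg.states):
        fg = [p for p, st in truth.link_states.items() if st == s]
        idx = [peak_pos[p] for p in fg]
        hits[idx, k] = rng.random(len(idx)) < cfg.motif_fg_p
    return regulons, pd.DataFrame(
        hits, index=pd.Index(all_peaks, name="peak_id"), columns=tfs
    )


# ---------------------------------------------------------------------------
# spatial

def gen_spatial(cfg: SimConfig, truth: GroundTruth) -> SpatialCellMap:
    """In situ cell map with planted colocalized niches and bimodal IF."""
    rng = cfg.rng(4)
    marker_map = dict(cfg.marker_map)
    mal_types = list(cfg.states)
    nonmal_types = list(marker_map)

    n = cfg.n_spatial_cells
    n_mal = int(round(cfg.malignant_frac * n))
    types = list(
        rng.choice(np.asarray(mal_types, dtype=object), size=n_mal)
    ) + list(
        rng.choice(np.asarray(nonmal_types, dtype=object), size=n - n_mal)
    )
    types = np.asarray(types, dtype=object)
    rng.shuffle(types)

    xy = rng.uniform(0, cfg.field_size, size=(n, 2))
    niched = {}
    for pair in cfg.niche_pairs:
        centers = rng.uniform(0, cfg.field_size, size=(cfg.n_niches, 2))
        for t in pair:
            niched[t] = centers
    for t, centers in niched.items():
        idx = np.flatnonzero(types == t)
        which = rng.integers(0, len(centers), size=len(idx))
        xy[idx] = centers[which] + rng.normal(0, cfg.niche_sd, size=(len(idx), 2))
    xy = np.clip(xy, 0, cfg.field_size)

    is_mal = np.isin(types, mal_types)
    intensity = np.where(
        is_mal,
        rng.normal(cfg.if_high_mean, cfg.if_sd, size=n),
        rng.normal(cfg.if_low_mean, cfg.if_sd, size=n),
    )
    intensity = np.clip(intensity, 0, None)

    markers = sorted(set(marker_map.values()))
    reads = pd.DataFrame(
        rng.poisson(cfg.marker_rate_bg, size=(n, len(markers))),
        columns=markers,
        index=pd.Index([f"sp{i:05d}" for i in range(n)], name="cell_id"),
    )
    for t, m in marker_map.items():
        idx = np.flatnonzero(types == t)
        reads.iloc[idx, reads.columns.get_loc(m)] = rng.poisson(
            cfg.marker_rate_fg, size=len(idx)
        )

    table = pd.DataFrame(
        {"x": xy[:, 0], "y": xy[:, 1], "if_intensity": intensity},
        index=reads.index,
    )
    truth.spatial_types = pd.Series(types, index=reads.index, name="true_type")
    return SpatialCellMap(table=table, reads=reads)


def link_config(**overrides) -> SimConfig:
    """Study conditions for the CRE-linking analysis.

    Cohort-scale cell and nucleus counts (~10,000 per modality) so that the
    200 random 100-nucleus pseudobulk neighborhoods reuse individual nuclei
    and matched cells only marginally; with a small pool, shared members
    would turn each null peak's realized per-state sample mean into a
    cluster-level intercept that chance-aligns with state-patterned genes
    and contaminates the null pairs.
    """
    kw = dict(cells_per_sample=1650, nuclei_per_sample=12000)
    kw.update(overrides)
    return SimConfig(**kw)


def tf_config(**overrides) -> SimConfig:
    """Compact conditions for the TF-circuit recovery study (run over many
    seeds): a smaller gene/peak universe with a higher planted-link fraction
    so each seeded run stays light while every state keeps ~24 true CREs."""
    # ~34 links per state (two hubs + ~20 singleton genes) keeps the planted
    # hub genes inside the top 5% of the linked-CRE count distribution
    kw = dict(
        n_samples=4, cells_per_sample=300, nuclei_per_sample=1500,
        n_genes=3000, n_peaks=1500, frac_true_links=0.115,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def null_config(**overrides) -> SimConfig:
    """No planted structure anywhere: flat expression, no correlated links,
    type-independent identity peaks, background-rate motifs, no planted
    spatial niches."""
    # flattening the type-specific boost (fold 1) removes the boost's share of
    # per-nucleus fragments; the higher flat rate keeps totals inside the
    # fragment QC window so the null cohort passes QC like the structured one
    kw = dict(
        effect_size=0.0, frac_true_links=0.0, identity_peak_fold=1.0,
        identity_peak_rate=3.0,
        motif_fg_p=0.05, motif_bg_p=0.05, niche_pairs=(),
    )
    kw.update(overrides)
    return SimConfig(**kw)


def gen_all(cfg: SimConfig):
    """Generate every modality; returns (expression, truth, atac, annotation, qc, regulons, motifs, spatial)."""
    expr, truth = gen_expression(cfg)
    peak_mat, annotation, qc = gen_atac(cfg, truth)
    regulons, motifs = gen_motifs_regulons(cfg, truth)
    spatial_map = gen_spatial(cfg, truth)
    return expr, truth, peak_mat, annotation, qc, regulons, motifs, spatial_map
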