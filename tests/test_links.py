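"""Link-calling statistics against brute-force oracles and hand computations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from statescape import bh_adjust, candidate_pairs, filter_links, gpc_genes, \
    hypergeom_overlap, link_correlation
from statescape.atac import GeneAnnotation
from statescape.links import motif_enrichment_p


# ---------------------------------------------------------------------------
# BH

def bh_oracle(pvals):
    """Literal step-up definition: q_i = min over j with p_(j) >= p_(i) of
    min(1, m p_(j) / j)."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, m * p[i] / rank)
        q[i] = min(1.0, prev)
    return np.asarray(q)


def test_bh_single_p_is_identity():
    assert bh_adjust([0.37])[0] == pytest.approx(0.37)


def test_bh_hand_example():
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


@given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
@settings(max_examples=200, deadline=None)
def test_bh_matches_oracle_and_statsmodels(pvals):
    q = bh_adjust(pvals)
    np.testing.assert_allclose(q, bh_oracle(pvals), atol=1e-12)
    from statsmodels.stats.multitest import multipletests
    _, q_sm, _, _ = multipletests(pvals, method="fdr_bh")
    np.testing.assert_allclose(q, q_sm, atol=1e-12)


def test_bh_permutation_stable():
    rng = np.random.default_rng(0)
    p = rng.random(40)
    perm = rng.permutation(40)
    np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# hypergeometric overlap

def hypergeom_oracle(set_a, set_b, universe):
    """Enumerate all draws of |B| elements from the universe and count those
    overlapping A at least as much as observed."""
    universe = sorted(universe)
    a = set(set_a)
    k_obs = len(a & set(set_b))
    total = hits = 0
    for draw in itertools.combinations(universe, len(set(set_b))):
        total += 1
        if len(a & set(draw)) >= k_obs:
            hits += 1
    return hits / total


def test_hypergeom_closed_form_example():
    # all five of A drawn among five of B from a universe of ten: C(5,5)/C(10,5)
    u = list(range(10))
    k, p = hypergeom_overlap(set(range(5)), set(range(5)), u, alternative="one-sided")
    assert k == 5
    assert p == pytest.approx(1 / 252)


def test_hypergeom_a_equals_universe():
    u = list(range(8))
    _, p = hypergeom_overlap(set(u), {1, 2, 3}, u, alternative="one-sided")
    assert p == pytest.approx(1.0)


@pytest.mark.parametrize("n_univ,n_a,n_b,seed", [
    (8, 3, 4, 0), (10, 5, 5, 1), (12, 6, 3, 2), (7, 2, 5, 3), (12, 4, 8, 4),
])
def test_hypergeom_matches_enumeration(n_univ, n_a, n_b, seed):
    rng = np.random.default_rng(seed)
    universe = list(range(n_univ))
    a = set(rng.choice(universe, n_a, replace=False).tolist())
    b = set(rng.choice(universe, n_b, replace=False).tolist())
    _, p1 = hypergeom_overlap(a, b, universe, alternative="one-sided")
    assert p1 == pytest.approx(hypergeom_oracle(a, b, universe), abs=1e-10)
    _, p2 = hypergeom_overlap(a, b, universe)
    assert p2 == pytest.approx(min(1.0, 2 * p1), abs=1e-12)


def test_hypergeom_requires_subsets():
    with pytest.raises(ValueError):
        hypergeom_overlap({1, 99}, {2}, {1, 2, 3})


def test_motif_enrichment_matches_scipy_tail():
    # 16 of 16 drawn CREs carry the motif, background rate 50/1000
    p = motif_enrichment_p(1000, 50, 16, 16)
    assert p == pytest.approx(stats.hypergeom.sf(15, 1000, 50, 16))
    assert p < 1e-10


# ---------------------------------------------------------------------------
# correlation p-values

def test_link_correlation_matches_pearsonr():
    rng = np.random.default_rng(5)
    n_pb = 30
    peaks = rng.random((20, n_pb))
    genes = rng.random((20, n_pb))
    pairs = pd.DataFrame({
        "peak": [f"p{i}" for i in range(20)],
        "gene": [f"g{i}" for i in range(20)],
        "distance": 0,
    })
    out = link_correlation(peaks, genes, pairs,
                           pd.Index([f"p{i}" for i in range(20)]),
                           pd.Index([f"g{i}" for i in range(20)]))
    for i in range(20):
        r_ref, p_ref = stats.pearsonr(peaks[i], genes[i])
        assert out["pcc"][i] == pytest.approx(r_ref, abs=1e-10)
        assert out["p"][i] == pytest.approx(p_ref, abs=1e-10)


def test_link_correlation_identical_vectors():
    x = np.arange(5.0)[None, :]
    pairs = pd.DataFrame({"peak": ["p0"], "gene": ["g0"], "distance": 0})
    out = link_correlation(x, x, pairs, pd.Index(["p0"]), pd.Index(["g0"]))
    assert out["pcc"][0] == pytest.approx(1.0)
    assert out["p"][0] < 1e-15


def test_link_correlation_exact_zero_r():
    # orthogonal residual construction: r = 0 exactly -> p = 1
    x = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
    y = np.array([[1.0, -1.0, 0.0, 1.0, -1.0]])
    y = y - (np.cov(x[0], y[0], bias=True)[0, 1] / np.var(x[0])) * x
    pairs = pd.DataFrame({"peak": ["p0"], "gene": ["g0"], "distance": 0})
    out = link_correlation(x, y, pairs, pd.Index(["p0"]), pd.Index(["g0"]))
    assert out["pcc"][0] == pytest.approx(0.0, abs=1e-12)
    assert out["p"][0] == pytest.approx(1.0, abs=1e-9)


def test_link_correlation_needs_three_pseudobulks():
    pairs = pd.DataFrame({"peak": ["p0"], "gene": ["g0"], "distance": 0})
    with pytest.raises(ValueError):
        link_correlation(np.ones((1, 2)), np.ones((1, 2)), pairs,
                         pd.Index(["p0"]), pd.Index(["g0"]))


# ---------------------------------------------------------------------------
# candidate pairing

def _annotation(rows):
    return GeneAnnotation(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand"],
        index=pd.Index([f"g{i}" for i in range(len(rows))], name="gene_id"),
    ))


def test_candidate_pairs_nearest_gene_and_window():
    ann = _annotation([
        ("chr1", 1000, 2000, "+"),      # TSS 1000
        ("chr1", 500_000, 501_000, "+"),  # TSS 500000
    ])
    peaks = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [10_000, 260_000, 1_000],
        "end": [10_500, 260_500, 1_500],
    }, index=["pk_near", "pk_mid", "pk_chr2"])
    pairs = candidate_pairs(peaks, ann).set_index("peak")
    assert set(pairs.index) == {"pk_near", "pk_mid"}  # other chromosome excluded
    assert pairs.loc["pk_near", "gene"] == "g0"
    assert pairs.loc["pk_near", "distance"] == 10_250 - 1000
    # midpoint 260,250 is nearer the second TSS even though it is further
    # along the chromosome from the first gene's body
    assert pairs.loc["pk_mid", "gene"] == "g1"


def test_candidate_pairs_window_excludes_distant_peak():
    ann = _annotation([("chr1", 1000, 2000, "+")])  # only TSS at 1000
    peaks = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [250_751, 250_749],
         "end": [251_251, 251_249]},
        index=["out", "edge"],
    )  # midpoints at distances 250,001 (excluded) and 249,999 (kept)
    pairs = candidate_pairs(peaks, ann)
    assert set(pairs["peak"]) == {"edge"}


def test_candidate_pairs_tie_broken_by_gene_id():
    ann = _annotation([
        ("chr1", 0, 100, "+"),        # TSS 0
        ("chr1", 19_900, 20_000, "-"),  # TSS 19999... use symmetric instead
    ])
    # construct exact midpoint tie: TSS at 0 and 20000
    ann = _annotation([
        ("chr1", 0, 100, "+"),
        ("chr1", 20_000, 20_100, "+"),
    ])
    peaks = pd.DataFrame(
        {"chrom": ["chr1"], "start": [9_750], "end": [10_250]}, index=["pk"]
    )  # midpoint 10000, equidistant
    pairs = candidate_pairs(peaks, ann)
    assert pairs.iloc[0]["gene"] == "g0"


def test_candidate_pairs_respects_rna_universe():
    ann = _annotation([
        ("chr1", 1000, 2000, "+"),
        ("chr1", 3000, 4000, "+"),
    ])
    peaks = pd.DataFrame(
        {"chrom": ["chr1"], "start": [1100], "end": [1200]}, index=["pk"]
    )
    pairs = candidate_pairs(peaks, ann, rna_genes=["g1"])
    assert pairs.iloc[0]["gene"] == "g1"


def test_candidate_pairs_brute_force(sim_small_atac):
    cfg, expr, truth, peak_mat, annotation, qc = sim_small_atac
    pairs = candidate_pairs(peak_mat.peaks, annotation)
    tss = annotation.tss
    got = {p: (g, d) for p, g, d in pairs.itertuples(index=False)}
    for pid, (chrom, start, end) in peak_mat.peaks.iterrows():
        mid = (start + end) // 2
        dists = {g: abs(mid - t) for g, t in tss.items()}
        gmin = min(sorted(dists), key=lambda g: dists[g])
        if dists[gmin] > 250_000:
            assert pid not in got
        else:
            assert got[pid] == (gmin, dists[gmin])


# ---------------------------------------------------------------------------
# filtering + GPC

def _links_frame(pcc, q_target_p):
    return pd.DataFrame({
        "peak": [f"p{i}" for i in range(len(pcc))],
        "gene": [f"g{i}" for i in range(len(pcc))],
        "distance": 0, "pcc": pcc, "p": q_target_p,
    })


def test_filter_links_boundaries_are_strict():
    links = _links_frame([0.2, 0.21, 0.5], [1e-6, 1e-6, 1e-6])
    out = filter_links(links)
    assert not out.loc[0, "passes"]  # |r| exactly 0.2 excluded
    assert out.loc[1, "passes"] and out.loc[2, "passes"]
    # q exactly at alpha excluded
    links2 = _links_frame([0.9], [0.05])
    assert not filter_links(links2)["passes"].any()


def test_gpc_nearest_rank_percentile():
    links = pd.DataFrame({
        "peak": [f"p{i}_{j}" for i in range(1, 101) for j in range(i)],
        "gene": [f"g{i}" for i in range(1, 101) for j in range(i)],
        "passes": True,
    })
    out = gpc_genes(links)
    assert out.threshold == 95
    assert set(out.genes) == {f"g{i}" for i in range(96, 101)}


def test_gpc_equal_counts_empty():
    links = pd.DataFrame({
        "peak": [f"p{i}" for i in range(10)],
        "gene": [f"g{i}" for i in range(10)],
        "passes": True,
    })
    assert gpc_genes(links).genes == []


def test_gpc_gene_order_invariant():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in rng.integers(0, 30, 200)]
    links = pd.DataFrame({
        "peak": [f"p{i}" for i in range(200)], "gene": genes, "passes": True,
    })
    a = gpc_genes(links)
    links2 = links.iloc[rng.permutation(200)].reset_index(drop=True)
    b = gpc_genes(links2)
    assert a.genes == b.genes and a.threshold == b.threshold
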