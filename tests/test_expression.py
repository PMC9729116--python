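"""Expression QC rules, transforms, scoring and marker detection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from statescape import (
    assign_state,
    classify_tams,
    detect_markers,
    qc_filter_cells,
    qc_filter_genes,
    score_signature,
    score_signatures,
    select_overdispersed_genes,
    transform,
)
from statescape.expression import SCORE_TOO_LOW

from .conftest import toy_expression


def _tpm_for_detected(n_detected, n_genes, value=100.0):
    col = np.zeros(n_genes)
    col[:n_detected] = value
    return col


class TestCellQC:
    def make(self, detected_per_cell, n_genes=2500, protocol="fresh",
             hk_value=100.0, align=None):
        # the two housekeeping rows are always detected: subtract them from
        # the requested per-cell detected-gene totals
        cols = [_tpm_for_detected(d - 2, n_genes) for d in detected_per_cell]
        tpm = np.column_stack(cols)
        genes = [f"g{i}" for i in range(n_genes - 2)] + ["ACTB", "GAPDH"]
        tpm[-2:, :] = hk_value  # housekeeping rows detected everywhere
        kw = {}
        if align is not None:
            kw["alignment_rate"] = align
        return toy_expression(tpm, genes=genes, protocol=protocol, **kw)

    def test_fresh_gene_count_boundary(self):
        # 1,999 detected genes removed; 2,000 kept (strict-less removal)
        mat = self.make([1999, 2000])
        out = qc_filter_cells(mat, housekeeping_set=["ACTB", "GAPDH"])
        assert list(out.cells) == ["c1"]

    def test_fresh_housekeeping_boundary(self):
        # mean housekeeping E exactly 2.5 is kept: E=2.5 at TPM = 10*(2^2.5-1)
        tpm_at_25 = 10 * (2 ** 2.5 - 1)
        mat = self.make([2400, 2400], hk_value=tpm_at_25)
        out = qc_filter_cells(mat, housekeeping_set=["ACTB", "GAPDH"])
        assert out.n_cells == 2
        mat_low = self.make([2400], hk_value=tpm_at_25 - 1)
        out = qc_filter_cells(mat_low, housekeeping_set=["ACTB", "GAPDH"])
        assert out.n_cells == 0

    def test_frozen_rules(self):
        mat = self.make([999, 1000, 1500, 1500], protocol="frozen",
                        align=[0.9, 0.9, 0.39, 0.4])
        out = qc_filter_cells(mat, housekeeping_set=["ACTB", "GAPDH"])
        assert list(out.cells) == ["c1", "c3"]

    def test_frozen_missing_alignment_errors(self):
        mat = self.make([1500], protocol="frozen")
        with pytest.raises(ValueError, match="alignment_rate"):
            qc_filter_cells(mat, housekeeping_set=["ACTB", "GAPDH"])

    def test_twelve_cell_fixture_matches_hand_rules(self):
        # mixed-protocol fixture; survivors computed by hand from the 4 rules
        detected = [2500, 1999, 2500, 2500, 1200, 900, 1200, 1200, 2500, 1999, 1200, 1100]
        protocol = ["fresh"] * 4 + ["frozen"] * 4 + ["fresh", "fresh", "frozen", "frozen"]
        align = [np.nan] * 4 + [0.8, 0.8, 0.39, 0.41] + [np.nan, np.nan, 0.5, 0.3]
        hk = [100, 100, 100, 30, 100, 100, 100, 100, 100, 100, 100, 100]
        n_genes = 2600
        tpm = np.column_stack([_tpm_for_detected(d - 1, n_genes) for d in detected])
        genes = [f"g{i}" for i in range(n_genes - 1)] + ["ACTB"]
        tpm[-1, :] = hk
        mat = toy_expression(tpm, genes=genes, protocol=protocol, alignment_rate=align)
        out = qc_filter_cells(mat, housekeeping_set=["ACTB"])
        # hand application: c0 ok, c1 <2000, c2 ok, c3 HK E=log2(4)=2<2.5,
        # c4 ok, c5 <1000, c6 align<0.4, c7 ok, c8 ok, c9 <2000, c10 ok, c11 align<0.4
        assert list(out.cells) == ["c0", "c2", "c4", "c7", "c8", "c10"]

    def test_idempotent(self):
        mat = self.make([1999, 2200, 2500])
        once = qc_filter_cells(mat, housekeeping_set=["ACTB", "GAPDH"])
        twice = qc_filter_cells(once, housekeeping_set=["ACTB", "GAPDH"])
        assert list(once.cells) == list(twice.cells)


class TestGeneQC:
    def test_boundary_at_ten_cells(self):
        tpm = np.zeros((2, 12))
        tpm[0, :10] = 16.5   # >16 in exactly 10 cells -> kept
        tpm[1, :] = 16.0     # never strictly >16 -> removed
        mat = toy_expression(tpm)
        out = qc_filter_genes(mat)
        assert list(out.genes) == ["g0"]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        tpm = rng.gamma(1.0, 20.0, size=(50, 40))
        mat = toy_expression(tpm)
        out = qc_filter_genes(mat)
        expected = [f"g{i}" for i in range(50) if (tpm[i] > 16).sum() >= 10]
        assert list(out.genes) == expected

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        mat = toy_expression(rng.gamma(1.0, 20.0, size=(30, 30)))
        once = qc_filter_genes(mat)
        twice = qc_filter_genes(once)
        assert list(once.genes) == list(twice.genes)


class TestTransform:
    def test_closed_forms(self):
        mat = toy_expression([[0.0, 10.0, 30.0]])
        E, Er = transform(mat)
        np.testing.assert_allclose(E.E[0], [0.0, 1.0, 2.0])
        assert E.Ea[0] == pytest.approx(np.log2(40 / 3 + 1))
        np.testing.assert_allclose(Er.Er[0], [-1.0, 0.0, 1.0])

    def test_er_rows_mean_zero(self):
        rng = np.random.default_rng(1)
        mat = toy_expression(rng.gamma(2.0, 50.0, size=(40, 25)))
        _, Er = transform(mat)
        np.testing.assert_allclose(Er.Er.mean(axis=1), 0.0, atol=1e-9)

    def test_constant_row_centered_to_zero(self):
        mat = toy_expression(np.full((1, 5), 42.0))
        _, Er = transform(mat)
        np.testing.assert_allclose(Er.Er, 0.0, atol=1e-12)

    def test_empty_errors(self):
        mat = toy_expression(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            transform(mat.subset_cells(np.zeros(2, dtype=bool)))


class TestOverdispersed:
    def test_high_variance_gene_ranked_first(self):
        rng = np.random.default_rng(0)
        base = rng.normal(100, 5, size=(30, 200)).clip(min=0)
        base[7] = rng.normal(100, 60, size=200).clip(min=0)  # same mean, 10x var
        mat = toy_expression(base)
        ranked = select_overdispersed_genes(mat, n=30)
        assert ranked[0] == "g7"

    def test_returns_all_when_n_exceeds(self):
        mat = toy_expression(np.random.default_rng(1).gamma(2, 50, (20, 30)))
        assert len(select_overdispersed_genes(mat, n=100)) == 20

    def test_recovers_planted_signatures(self, sim_small):
        cfg, expr, truth = sim_small
        top = set(select_overdispersed_genes(expr, n=200))
        sig = [g for gs in truth.signatures.values() for g in gs]
        hit = sum(g in top for g in sig) / len(sig)
        assert hit >= 0.9


class TestScoring:
    def test_constant_matrix_scores_zero(self):
        mat = toy_expression(np.full((10, 6), 50.0))
        _, Er = transform(mat)
        np.testing.assert_allclose(score_signature(Er, ["g0", "g3"]), 0.0, atol=1e-12)

    def test_single_gene_score_is_er_row(self):
        rng = np.random.default_rng(4)
        mat = toy_expression(rng.gamma(2, 50, (8, 10)))
        _, Er = transform(mat)
        np.testing.assert_allclose(score_signature(Er, ["g5"]), Er.Er[5])

    def test_empty_intersection_errors(self):
        mat = toy_expression(np.ones((3, 3)))
        _, Er = transform(mat)
        with pytest.raises(ValueError):
            score_signature(Er, ["absent"])

    def test_planted_states_score_own_signature_highest(self, sim_small):
        cfg, expr, truth = sim_small
        _, Er = transform(expr)
        scores = score_signatures(Er, truth.signatures)
        st = truth.cell_states
        frac_correct = []
        for s in cfg.states:
            sub = scores[(st == s).to_numpy()]
            frac_correct.append((sub.idxmax(axis=1) == s).mean())
        assert min(frac_correct) >= 0.95


class TestAssignState:
    def test_threshold_and_argmax(self):
        scores = pd.DataFrame(
            [[0.19, 0.1], [0.5, 0.3], [0.5, 0.5]],
            columns=["A", "B"], index=["c0", "c1", "c2"],
        )
        labels = assign_state(scores)
        assert labels["c0"] == SCORE_TOO_LOW
        assert labels["c1"] == "A"
        assert labels["c2"] == "A"  # tie -> first column


class TestMarkers:
    @staticmethod
    def brute_force(E, labels, min_frac, min_lfc, alpha):
        out = set()
        n_tests = len(set(labels)) * E.shape[0]
        for g in sorted(set(labels)):
            in_m = np.asarray([l == g for l in labels])
            for i in range(E.shape[0]):
                e_in, e_out = E[i, in_m], E[i, ~in_m]
                if (e_in > 0).mean() < min_frac:
                    continue
                if e_in.mean() - e_out.mean() < min_lfc:
                    continue
                U, p = stats.ranksums(e_in, e_out)  # independent rank-sum route
                p = stats.mannwhitneyu(e_in, e_out, alternative="two-sided").pvalue
                if p * n_tests < alpha:
                    out.add((g, f"g{i}"))
        return out

    def test_exclusive_gene_reported(self):
        tpm = np.zeros((5, 12)) + 1.0
        tpm[2, :6] = 500.0
        tpm[2, 6:] = 0.0
        mat = toy_expression(tpm)
        E, _ = transform(mat)
        labels = pd.Series(["A"] * 6 + ["B"] * 6, index=mat.cells)
        table = detect_markers(E, labels)
        assert ("A", "g2") in set(zip(table["group"], table["gene"]))

    def test_detection_fraction_rule(self):
        # gene detected in 29% of in-group cells is excluded
        tpm = np.zeros((2, 200)) + 1.0
        tpm[1, :] = 0.0
        det = np.arange(29)
        tpm[1, det] = 1000.0
        mat = toy_expression(tpm)
        E, _ = transform(mat)
        labels = pd.Series(["A"] * 100 + ["B"] * 100, index=mat.cells)
        table = detect_markers(E, labels)
        assert ("A", "g1") not in set(zip(table["group"], table["gene"]))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        tpm = rng.gamma(1.5, 40, size=(20, 60))
        tpm[rng.random(tpm.shape) < 0.3] = 0
        tpm[3, :20] *= 8  # planted marker for group A
        mat = toy_expression(tpm)
        E, _ = transform(mat)
        labels = pd.Series(["A"] * 20 + ["B"] * 20 + ["C"] * 20, index=mat.cells)
        table = detect_markers(E, labels, min_frac=0.3, min_lfc=0.5, alpha=0.05)
        got = set(zip(table["group"], table["gene"]))
        want = self.brute_force(E.E, list(labels), 0.3, 0.5, 0.05)
        assert got == want

    def test_small_group_skipped(self):
        tpm = np.random.default_rng(0).gamma(2, 50, (5, 10))
        mat = toy_expression(tpm)
        E, _ = transform(mat)
        labels = pd.Series(["A"] * 8 + ["B"] * 2, index=mat.cells)
        with pytest.raises(ValueError):
            detect_markers(E, labels)


class TestTams:
    def test_pure_populations(self):
        tpm = np.zeros((4, 2)) + 1.0
        tpm[0, 0] = 1000.0  # microglia marker in cell 0
        tpm[2, 1] = 1000.0  # macrophage marker in cell 1
        mat = toy_expression(tpm)
        _, Er = transform(mat)
        labels = classify_tams(Er, ["g0", "g1"], ["g2", "g3"])
        assert labels["c0"] == "microglia" and labels["c1"] == "macrophage"

    def test_tie_unclassified(self):
        mat = toy_expression(np.full((2, 3), 7.0))
        _, Er = transform(mat)
        labels = classify_tams(Er, ["g0"], ["g1"])
        assert (labels == "unclassified").all()

    def test_synthetic_mixture_accuracy(self):
        rng = np.random.default_rng(12)
        n = 200
        base = rng.normal(2, 0.5, size=(40, n))
        truth_lbl = np.array(["microglia"] * 100 + ["macrophage"] * 100)
        base[:10, :100] += 2.0   # microglia signature, effect 2
        base[10:20, 100:] += 2.0
        tpm = (np.exp2(base) - 1) * 10
        mat = toy_expression(tpm)
        _, Er = transform(mat)
        labels = classify_tams(Er, [f"g{i}" for i in range(10)],
                               [f"g{i}" for i in range(10, 20)])
        assert (labels.to_numpy() == truth_lbl).mean() >= 0.95
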