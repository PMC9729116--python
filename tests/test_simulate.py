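"""Generator contracts: determinism, planted structure, placement geometry."""

import numpy as np
import pandas as pd
import pytest

from statescape import SimConfig, gen_atac, gen_expression, gen_motifs_regulons, \
    gen_spatial, transform
from statescape.links import motif_enrichment_p
from statescape.simulate import link_noise_amplitude

from .conftest import small_config


class TestConfigValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValueError, match="dropout_p"):
            SimConfig(dropout_p=1.5)

    def test_signature_sizing(self):
        with pytest.raises(ValueError, match="do not fit"):
            SimConfig(n_genes=100, signature_size=30)

    def test_overlapping_type_names(self):
        with pytest.raises(ValueError, match="overlapping"):
            SimConfig(states=("TAM", "OPC-like", "a", "b", "c"))

    def test_link_allocation_overflow(self):
        cfg = small_config(frac_true_links=0.5)
        _, truth = gen_expression(cfg)
        with pytest.raises(ValueError, match="signature"):
            gen_atac(cfg, truth)


class TestDeterminism:
    def test_expression_bit_identical(self):
        cfg = small_config(seed=42)
        a, _ = gen_expression(cfg)
        b, _ = gen_expression(small_config(seed=42))
        np.testing.assert_array_equal(a.tpm, b.tpm)
        assert list(a.cells) == list(b.cells)

    def test_full_chain_bit_identical(self):
        outs = []
        for _ in range(2):
            cfg = small_config(seed=7)
            expr, truth = gen_expression(cfg)
            pm, ann, qc = gen_atac(cfg, truth)
            reg, motifs = gen_motifs_regulons(cfg, truth)
            sp = gen_spatial(cfg, truth)
            outs.append((pm, qc, motifs, sp))
        (pm1, qc1, m1, s1), (pm2, qc2, m2, s2) = outs
        assert (pm1.counts != pm2.counts).nnz == 0
        pd.testing.assert_frame_equal(qc1, qc2)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(s1.table, s2.table)

    def test_seed_changes_output(self):
        a, _ = gen_expression(small_config(seed=1))
        b, _ = gen_expression(small_config(seed=2))
        assert not np.array_equal(a.tpm, b.tpm)


class TestExpression:
    def test_no_signal_means_identical_cells(self):
        cfg = small_config(effect_size=0, noise_sd=0, batch_sd=0, dropout_p=0)
        mat, _ = gen_expression(cfg)
        # every cell has the same per-gene profile
        ref = np.tile(mat.tpm[:, [0]], (1, mat.n_cells))
        np.testing.assert_allclose(mat.tpm, ref, rtol=1e-9)

    def test_cell_sums_1e6_without_dropout(self):
        cfg = small_config(dropout_p=0)
        mat, _ = gen_expression(cfg)
        np.testing.assert_allclose(mat.tpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_dropout_zero_fraction_near_target(self):
        cfg = small_config(dropout_p=0.3)
        mat, _ = gen_expression(cfg)
        assert (mat.tpm == 0).mean() == pytest.approx(0.3, abs=0.02)

    def test_signature_relative_expression_elevated_in_own_state(self, sim_small):
        cfg, expr, truth = sim_small
        _, Er = transform(expr)
        st = truth.cell_states
        for s, sig in truth.signatures.items():
            idx = Er.genes.get_indexer(sig)
            own = Er.Er[np.ix_(idx, (st == s).to_numpy())].mean()
            others = Er.Er[np.ix_(idx, (st != s).to_numpy())].mean()
            assert own > others + 0.5

    def test_metadata_carries_sample_and_protocol(self, sim_small):
        _, expr, _ = sim_small
        assert {"sample_id", "protocol"} <= set(expr.cell_meta.columns)


class TestAtac:
    def test_true_link_peaks_nearest_to_target(self, sim_small_atac):
        cfg, expr, truth, pm, ann, qc = sim_small_atac
        tss = ann.tss
        for pid, gene in truth.true_links:
            start, end = pm.peaks.loc[pid, ["start", "end"]]
            mid = (start + end) // 2
            d = {g: abs(mid - t) for g, t in tss.items()}
            assert d[gene] <= 250_000
            assert min(d, key=lambda g: (d[g], g)) == gene

    def test_identity_peaks_outside_candidate_window(self, sim_small_atac):
        cfg, expr, truth, pm, ann, qc = sim_small_atac
        tss = ann.tss.to_numpy()
        for pids in truth.identity_peaks.values():
            for pid in pids:
                start, end = pm.peaks.loc[pid, ["start", "end"]]
                mid = (start + end) // 2
                assert np.abs(mid - tss).min() > 250_000

    def test_qc_fail_fraction_binomial(self):
        # fail fraction 0.1 per criterion: failing count within 3 SD of Binomial
        cfg = small_config(qc_fail_frac=0.1, seed=3)
        _, truth = gen_expression(cfg)
        _, _, qc = gen_atac(cfg, truth)
        n = len(qc)
        sd3 = 3 * np.sqrt(n * 0.1 * 0.9)
        fails = {
            "frag": ((qc.peak_region_fragments < 1500) | (qc.peak_region_fragments > 15000)).sum(),
            "pct": (qc.pct_reads_in_peaks <= 15).sum(),
            "blacklist": (qc.blacklist_ratio >= 0.02).sum(),
            "nucleosome": (qc.nucleosome_signal >= 2).sum(),
            "tss": (qc.tss_enrichment <= 4).sum(),
        }
        for name, k in fails.items():
            assert abs(k - 0.1 * n) <= sd3, name

    def test_no_links_when_fraction_zero(self):
        cfg = small_config(frac_true_links=0.0)
        _, truth = gen_expression(cfg)
        gen_atac(cfg, truth)
        assert truth.true_links == []

    def test_noise_calibration_closed_form(self):
        cfg = small_config()
        b = link_noise_amplitude(cfg)
        # plugging b back must reproduce the target variance budget
        mu, g = cfg.link_base_rate, cfg.link_fold
        p = (1 - cfg.noise_frac) / len(cfg.states)
        m = cfg.pseudobulk_size
        B = (m * mu * (g - 1)) ** 2 * p * (1 - p)
        lam_bar = mu * (1 + (g - 1) * p + b)
        W = m * (lam_bar + mu ** 2 * b ** 2)
        r = np.sqrt(B / (B + W))
        assert r == pytest.approx(cfg.link_strength, abs=1e-9)

    def test_unachievable_strength_clamps_to_zero(self):
        cfg = small_config(link_strength=0.999)
        assert link_noise_amplitude(cfg) == 0.0


class TestMotifsRegulons:
    def test_regulon_targets_within_universe(self, sim_small_full):
        d = sim_small_full
        genes = set(d["expr"].genes)
        for tf, targets in d["regulons"].items():
            assert set(targets) <= genes
            assert len(targets) > 0

    def test_planted_tf_is_top_enrichment_hit(self):
        hits_top = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = small_config(seed=50 + seed)
            _, truth = gen_expression(cfg)
            gen_atac(cfg, truth)
            regulons, motifs = gen_motifs_regulons(cfg, truth)
            ok = True
            for s in cfg.states:
                cres = [p for p, st in truth.link_states.items() if st == s]
                universe = list(motifs.index)
                pvals = {
                    tf: motif_enrichment_p(
                        len(universe), int(motifs[tf].sum()), len(cres),
                        int(motifs.loc[cres, tf].sum()))
                    for tf in motifs.columns
                }
                if min(pvals, key=pvals.get) != truth.state_tfs[s]:
                    ok = False
            hits_top += ok
        assert hits_top / n_seeds >= 0.95


class TestSpatial:
    def test_separable_intensity_gates_perfectly(self):
        cfg = small_config(if_sd=0.0)
        _, truth = gen_expression(cfg)
        cells = gen_spatial(cfg, truth)
        from statescape import if_gate
        gated = if_gate(cells, min_malignant=90, max_nonmalignant=60)
        is_mal = truth.spatial_types.isin(cfg.states).to_numpy()
        assert (gated.table["cell_class"][is_mal] == "malignant").all()
        assert (gated.table["cell_class"][~is_mal] == "nonmalignant").all()

    def test_all_cells_on_field(self, sim_small_full):
        cfg = sim_small_full["cfg"]
        tab = sim_small_full["spatial"].table
        assert tab[["x", "y"]].min().min() >= 0
        assert tab[["x", "y"]].max().max() <= cfg.field_size


class TestMonotonicity:
    def test_signature_recovery_monotone_in_effect_size(self):
        """Stronger planted signatures never hurt state-assignment recovery."""
        def recovery(effect, seed):
            cfg = small_config(effect_size=effect, seed=seed,
                               n_samples=2, cells_per_sample=100)
            expr, truth = gen_expression(cfg)
            _, Er = transform(expr)
            from statescape import score_signatures
            scores = score_signatures(Er, truth.signatures)
            st = truth.cell_states
            mask = (st != "none").to_numpy()
            return (scores.idxmax(axis=1)[mask] == st[mask]).mean()

        grid = [0.2, 0.8, 2.0]
        rates = [np.mean([recovery(e, s) for s in range(10)]) for e in grid]
        assert rates[0] <= rates[1] + 0.02
        assert rates[1] <= rates[2] + 0.02
        assert rates[2] > rates[0]

    def test_link_recovery_monotone_in_link_strength(self):
        """Stronger planted peak-gene coupling never hurts link recall."""
        from statescape.analysis import simulate_and_link
        from statescape.simulate import tf_config

        def recall(strength, seed):
            cfg = tf_config(link_strength=strength, seed=seed)
            out = simulate_and_link(cfg, pseudobulk_seed=seed)
            return out["scores"]["recall"]

        grid = [0.12, 0.3, 0.6]
        rates = [np.mean([recall(r, 60 + s) for s in range(2)]) for r in grid]
        assert rates[0] <= rates[1] + 0.02
        assert rates[1] <= rates[2] + 0.02
        assert rates[2] > rates[0] + 0.3  # weak coupling is genuinely missed
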