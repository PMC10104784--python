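"""The synthetic generator: determinism, regime statistics, round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epientropy.epiallele import entropy_table, enumerate_fourmers
from epientropy.io import assemble_reads, read_meth_calls
from epientropy.simulate import (
    SyntheticConfig,
    attach_likelihoods,
    reads_to_call_rows,
    simulate_clones,
    simulate_condition_pair,
    simulate_genome,
    simulate_long_reads,
    simulate_reads_disordered,
    simulate_reads_regime,
    write_call_table,
)


class TestGenome:
    def test_requested_number_of_cgis(self):
        cfg = SyntheticConfig(seed=1, n_cgis=10)
        _, cgis = simulate_genome(cfg)
        assert len(cgis) == 10
        assert all(c.feature_class == "cgi" for c in cgis)

    def test_same_seed_identical_positions(self):
        cfg = SyntheticConfig(seed=5)
        g1, _ = simulate_genome(cfg)
        g2, _ = simulate_genome(cfg)
        np.testing.assert_array_equal(g1[cfg.chrom], g2[cfg.chrom])
        g3, _ = simulate_genome(SyntheticConfig(seed=6))
        assert not np.array_equal(g1[cfg.chrom], g3[SyntheticConfig().chrom])

    def test_cgis_denser_than_background(self):
        cfg = SyntheticConfig(seed=2, cgi_density_multiplier=10.0)
        genome, cgis = simulate_genome(cfg)
        pos = genome[cfg.chrom]
        in_cgi = np.zeros(pos.size, dtype=bool)
        for c in cgis:
            in_cgi |= (pos >= c.start) & (pos < c.end)
        gaps = np.diff(pos)
        inside = gaps[in_cgi[:-1] & in_cgi[1:]]
        outside = gaps[~in_cgi[:-1] & ~in_cgi[1:]]
        assert inside.mean() < outside.mean() / 3

    def test_density_multiplier_one_is_indistinguishable(self):
        """At multiplier 1, island and background inter-CpG gaps come from
        the same distribution (KS test)."""
        cfg = SyntheticConfig(seed=3, cgi_density_multiplier=1.0,
                              n_cgis=40, cgi_length=2000)
        genome, cgis = simulate_genome(cfg)
        pos = genome[cfg.chrom]
        in_cgi = np.zeros(pos.size, dtype=bool)
        for c in cgis:
            in_cgi |= (pos >= c.start) & (pos < c.end)
        gaps = np.diff(pos)
        inside = gaps[in_cgi[:-1] & in_cgi[1:]]
        outside = gaps[~in_cgi[:-1] & ~in_cgi[1:]]
        assert stats.ks_2samp(inside, outside).pvalue > 0.01


class TestDisorderedReads:
    def test_m_zero_gives_no_methylation(self):
        cfg = SyntheticConfig(seed=1, disordered_m=0.0, coverage=20)
        reads = simulate_reads_disordered(cfg)
        assert all((r.states == 0).all() for r in reads)

    def test_per_cpg_rate_near_m(self):
        cfg = SyntheticConfig(seed=4, disordered_m=0.5, coverage=100)
        reads = simulate_reads_disordered(cfg)
        states = np.stack([r.states for r in reads])
        rates = states.mean(axis=0)
        # each CpG's rate is Binomial(100, 0.5)/100; check the global mean
        assert rates.mean() == pytest.approx(0.5, abs=0.02)

    def test_regime_selector(self):
        cfg = SyntheticConfig(seed=4, coverage=60)
        low = simulate_reads_regime(cfg, "bimodal_low")
        high = simulate_reads_regime(cfg, "bimodal_high")
        m_low = np.stack([r.states for r in low]).mean()
        m_high = np.stack([r.states for r in high]).mean()
        assert m_low < 0.1 < 0.7 < m_high
        with pytest.raises(ValueError):
            simulate_reads_regime(cfg, "nonsense")


class TestClones:
    def test_static_zero_error_clones_have_zero_entropy(self):
        cfg = SyntheticConfig(seed=2, clone_model="static", static_error=0.0,
                              n_clones=3, clone_fourmers=20, clone_coverage=15)
        reads_by_clone, truth = simulate_clones(cfg)
        for clone, reads in reads_by_clone.items():
            pos = np.unique(np.concatenate([r.positions for r in reads]))
            table = entropy_table(reads, enumerate_fourmers(pos, mode="disjoint"))
            assert (table["entropy"] == 0.0).all()

    def test_truth_pattern_matches_emitted_reads(self):
        cfg = SyntheticConfig(seed=3, clone_model="static", static_error=0.0,
                              n_clones=2, clone_fourmers=5, clone_coverage=4)
        reads_by_clone, truth = simulate_clones(cfg)
        for row in truth.itertuples():
            reads = [r for r in reads_by_clone[row.clone_id]
                     if r.read_id.startswith(f"{row.clone_id}_fm{row.fourmer_index:04d}_")]
            for r in reads:
                assert "".join(map(str, r.states.tolist())) == row.inherited_pattern

    def test_determinism(self):
        cfg = SyntheticConfig(seed=9, n_clones=2, clone_fourmers=10,
                              clone_coverage=5)
        r1, t1 = simulate_clones(cfg)
        r2, t2 = simulate_clones(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        for clone in r1:
            for a, b in zip(r1[clone], r2[clone]):
                np.testing.assert_array_equal(a.states, b.states)


class TestLongReads:
    def test_reads_span_every_island_of_their_block(self):
        cfg = SyntheticConfig(seed=1, n_blocks=2, reads_per_block=5)
        reads, cgis, truth = simulate_long_reads(cfg)
        by_block = {}
        for c in cgis:
            by_block.setdefault(c.id.split("_")[0], []).append(c)
        for r in reads:
            block = r.read_id.split("_")[0]
            for c in by_block[block]:
                assert r.spans(c.start, c.end)

    def test_full_coordination_with_extreme_propensities(self):
        """rho = 1 with near-degenerate Beta draws forces u_r to 0/1; every
        read is then all-methylated or all-unmethylated across islands and
        every pair is perfectly concordant."""
        from epientropy.concordance import cgi_pair_table

        cfg = SyntheticConfig(seed=8, coordination=1.0, beta_a=0.01,
                              beta_b=0.01, n_blocks=3, cgis_per_block=3,
                              reads_per_block=20)
        reads, cgis, _ = simulate_long_reads(cfg)
        pairs = cgi_pair_table(reads, cgis, seed=8)
        assert len(pairs) == 9
        assert (pairs["concordance"] == 1.0).all()

    def test_truth_flags_coordination(self):
        _, _, truth0 = simulate_long_reads(SyntheticConfig(seed=1, n_blocks=2))
        _, _, truth1 = simulate_long_reads(
            SyntheticConfig(seed=1, n_blocks=2, coordination=0.7))
        assert not truth0["coordinated"].any()
        assert truth1["coordinated"].all()


class TestConditionPair:
    def test_noise_free_tracks_match_planted_levels(self):
        cfg = SyntheticConfig(seed=5)
        epi, exe, truth = simulate_condition_pair(cfg)
        for row in truth.itertuples():
            inside = (epi["pos"] >= row.start) & (epi["pos"] < row.end)
            assert epi.loc[inside, "rate"].mean() == pytest.approx(row.epi_level, abs=1e-9)
            assert exe.loc[inside, "rate"].mean() == pytest.approx(row.exe_level, abs=1e-9)

    def test_excluded_class_marked_non_callable(self):
        _, _, truth = simulate_condition_pair(SyntheticConfig(seed=5))
        excluded = truth[truth["planted_class"] == "excluded"]
        assert not excluded.empty
        assert not excluded["callable_hyper"].any()
        assert (excluded["epi_level"] >= 0.2).all()

    def test_same_seed_identical_tracks(self):
        cfg = SyntheticConfig(seed=7, condition_noise=True)
        e1, x1, _ = simulate_condition_pair(cfg)
        e2, x2, _ = simulate_condition_pair(cfg)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(x1, x2)


class TestRoundTrip:
    def test_simulated_reads_survive_the_call_tsv_dialect(self, tmp_path):
        cfg = SyntheticConfig(seed=6, coverage=8)
        reads = simulate_reads_disordered(cfg)
        path = tmp_path / "calls.tsv"
        write_call_table(reads_to_call_rows(reads), path)
        back = {r.read_id: r for r in assemble_reads(read_meth_calls(path))}
        assert len(back) == len(reads)
        for r in reads:
            np.testing.assert_array_equal(back[r.read_id].positions, r.positions)
            np.testing.assert_array_equal(back[r.read_id].states, r.states)

    def test_likelihood_model_exercises_the_filter(self, tmp_path):
        cfg = SyntheticConfig(seed=6, coverage=30, likelihood_low_fraction=0.3)
        reads = simulate_reads_disordered(cfg)
        liks = [lik for _, lik in attach_likelihoods(reads, cfg)]
        path = tmp_path / "calls.tsv"
        write_call_table(reads_to_call_rows(reads, liks), path)
        total = sum(r.n_calls for r in reads)
        kept = sum(1 for _ in read_meth_calls(path, min_abs_likelihood=2.5))
        frac_dropped = 1 - kept / total
        assert frac_dropped == pytest.approx(0.3, abs=0.03)
        unfiltered = sum(1 for _ in read_meth_calls(path, min_abs_likelihood=0.0))
        assert unfiltered == total
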