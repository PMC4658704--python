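import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from popexpand import coalsim, seqio, sumstats
from popexpand.coalsim import (
    Genealogy,
    SubstitutionModel,
    TwoEpochModel,
    demographic_intensity,
    invert_intensity,
    simulate_genealogy,
    simulate_sequences,
)


class TestIntensity:
    def test_constant_size_closed_form(self):
        m = TwoEpochModel.constant(0.01)
        assert demographic_intensity(m, 0.0, 0.02) == pytest.approx(2.0)
        assert demographic_intensity(m, 0.01, 0.01) == 0.0

    @pytest.mark.parametrize(
        "model",
        [
            TwoEpochModel(n1=0.01, r=4000.0, n0=0.002, t_trans=5e-4),
            TwoEpochModel(n1=0.005, r=0.0, n0=0.02, t_trans=1e-3),
            TwoEpochModel(n1=0.02, r=900.0, n0=0.02, t_trans=2e-3),
        ],
    )
    @pytest.mark.parametrize("interval", [(0.0, 3e-4), (1e-4, 8e-4), (0.0, 5e-3), (2e-3, 4e-3)])
    def test_matches_adaptive_quadrature(self, model, interval):
        a, b = interval
        expected, _ = quad(lambda t: 1.0 / model.size_at(t), a, b,
                           points=[model.t_trans], limit=200)
        assert demographic_intensity(model, a, b) == pytest.approx(expected, abs=1e-8)

    def test_inversion_roundtrip(self):
        model = TwoEpochModel(n1=0.01, r=4901.0, n0=0.001, t_trans=4.7e-4)
        for a in (0.0, 2e-4, 6e-4):
            for target in (0.01, 0.5, 3.0, 50.0):
                b = invert_intensity(model, a, target)
                assert demographic_intensity(model, a, b) == pytest.approx(target, rel=1e-9)

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            demographic_intensity(TwoEpochModel.constant(0.01), 0.5, 0.1)


class TestGenealogySimulation:
    def test_tmrca_two_tips_matches_theory(self):
        n_size = 0.005
        rng = np.random.default_rng(21)
        model = TwoEpochModel.constant(n_size)
        t = [simulate_genealogy(2, model, rng).root_height for _ in range(2000)]
        se = np.std(t) / math.sqrt(len(t))
        assert abs(np.mean(t) - n_size) < 3 * se

    def test_tmrca_ten_tips_matches_theory(self):
        # E[TMRCA] = 2N (1 - 1/n)
        n_size = 0.005
        rng = np.random.default_rng(22)
        model = TwoEpochModel.constant(n_size)
        t = [simulate_genealogy(10, model, rng).root_height for _ in range(1500)]
        se = np.std(t) / math.sqrt(len(t))
        assert abs(np.mean(t) - 2 * n_size * 0.9) < 3 * se

    def test_tmrca_distribution_matches_msprime(self):
        # independent simulator cross-check (same constant demography)
        import msprime

        n_size = 0.004
        rng = np.random.default_rng(23)
        ours = np.array(
            [
                simulate_genealogy(10, TwoEpochModel.constant(n_size), rng).root_height
                for _ in range(1200)
            ]
        )
        theirs = np.array(
            [
                ts.max_root_time
                for ts in msprime.sim_ancestry(
                    samples=10, ploidy=1, population_size=n_size,
                    num_replicates=1200, random_seed=23,
                )
            ]
        )
        assert stats.ks_2samp(ours, theirs).pvalue > 0.01

    def test_growth_concentrates_coalescences_recently(self):
        growth = coalsim.STUDY_DEMOGRAPHY
        const = TwoEpochModel.constant(growth.n1)
        rng = np.random.default_rng(24)
        frac_growth, frac_const = [], []
        for _ in range(500):
            tg = simulate_genealogy(20, growth, rng).coalescent_times()
            tc = simulate_genealogy(20, const, rng).coalescent_times()
            frac_growth.append(np.mean(tg <= growth.t_trans))
            frac_const.append(np.mean(tc <= growth.t_trans))
        assert np.mean(frac_growth) > np.mean(frac_const)

    def test_zero_transition_time_equals_constant_n0(self):
        degenerate = TwoEpochModel(n1=0.5, r=3000.0, n0=0.002, t_trans=0.0)
        const = TwoEpochModel.constant(0.002)
        rng = np.random.default_rng(25)
        a = [simulate_genealogy(8, degenerate, rng).root_height for _ in range(2000)]
        b = [simulate_genealogy(8, const, rng).root_height for _ in range(2000)]
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_ultrametric_and_binary(self, rng):
        g = simulate_genealogy(30, coalsim.STUDY_DEMOGRAPHY, rng)
        assert np.all(np.abs(g.heights[:30]) < 1e-10)
        times = g.coalescent_times()
        assert len(times) == 29 and np.all(np.diff(times) >= 0)
        for i, p in enumerate(g.parent):
            if p >= 0:
                assert g.heights[p] >= g.heights[i]

    def test_newick_roundtrip(self, rng):
        g = simulate_genealogy(12, TwoEpochModel.constant(0.01), rng)
        g2 = Genealogy.from_newick(g.to_newick())
        assert sorted(g2.labels) == sorted(g.labels)
        assert np.allclose(np.sort(g2.coalescent_times()), g.coalescent_times(), atol=1e-8)
        assert g2.root_height == pytest.approx(g.root_height, abs=1e-8)


class TestSequenceSimulation:
    def test_zero_branch_lengths_copy_root(self):
        parent = np.array([4, 4, 5, 6, 5, 6, -1])
        heights = np.zeros(7)
        g = Genealogy(parent=parent, heights=heights, labels=["a", "b", "c", "d"])
        aln = simulate_sequences(g, 200, SubstitutionModel(), np.random.default_rng(0))
        assert len(set(aln.seqs)) == 1

    def test_jukes_cantor_special_case_expectation(self):
        # kappa=1 + equal freqs reduce HKY to JC: p = 3/4 (1 - e^{-4d/3})
        d = 0.3
        parent = np.array([2, 2, -1])
        heights = np.array([0.0, 0.0, d / 2])
        g = Genealogy(parent=parent, heights=heights, labels=["a", "b"])
        sub = SubstitutionModel(kappa=1.0, p_inv=0.0)
        length = 30_000
        aln = simulate_sequences(g, length, sub, np.random.default_rng(31))
        p_obs = seqio.pairwise_distance(aln, "p_distance").values[0, 1]
        p_exp = 0.75 * (1 - math.exp(-4 * d / 3))
        assert abs(p_obs - p_exp) < 4 * math.sqrt(p_exp * (1 - p_exp) / length)

    def test_base_composition_converges_to_stationary_freqs(self, rng):
        freqs = (0.35, 0.15, 0.2, 0.3)
        g = simulate_genealogy(6, TwoEpochModel.constant(0.02), rng)
        aln = simulate_sequences(g, 20_000, SubstitutionModel(kappa=6.0, base_freqs=freqs,
                                                              p_inv=0.0), rng)
        arr = aln.to_array()
        observed = np.array([np.mean(arr == b) for b in b"ACGT"])
        assert np.allclose(observed, freqs, atol=0.02)

    def test_transition_probabilities_are_stochastic(self):
        sub = SubstitutionModel(kappa=8.0, base_freqs=(0.4, 0.1, 0.1, 0.4), p_inv=0.2)
        for t in (0.0, 1e-4, 0.05, 2.0):
            p = sub.transition_probs(t)
            assert np.allclose(p.sum(axis=1), 1.0)
            assert np.all(p >= 0)
        assert np.allclose(sub.transition_probs(0.0), np.eye(4), atol=1e-12)

    def test_invariant_rate_convention_keeps_pi_at_2n(self):
        # branch lengths average over all sites; pi should not depend on p_inv
        n_size = 0.005
        rng = np.random.default_rng(32)
        model = TwoEpochModel.constant(n_size)
        pis = []
        for _ in range(250):
            g = simulate_genealogy(20, model, rng)
            aln = simulate_sequences(g, 600, SubstitutionModel(p_inv=0.5), rng)
            pis.append(sumstats.diversity(aln).pi)
        se = np.std(pis) / math.sqrt(len(pis))
        assert abs(np.mean(pis) - 2 * n_size) < 3 * se


class TestGenerateDataset:
    def test_study_configuration_shapes(self, simulated_study_dataset):
        aln, meta, truth = simulated_study_dataset
        assert (aln.n, aln.length) == (84, 352)
        assert meta.table["locality"].nunique() == 10
        assert truth["demography"]["t_trans"] == pytest.approx(4.6974e-4)

    def test_same_seed_is_byte_identical(self):
        cfg = coalsim.study_config(seed=3)
        a1, m1, t1 = coalsim.generate_dataset(cfg)
        a2, m2, t2 = coalsim.generate_dataset(coalsim.study_config(seed=3))
        assert a1.seqs == a2.seqs and a1.ids == a2.ids
        assert m1.table.equals(m2.table)
        assert t1 == t2

    def test_two_deme_stem_separates_demes(self):
        cfg = coalsim.study_config(seed=4, mode="two_deme", stem=0.05)
        aln, meta, truth = coalsim.generate_dataset(cfg)
        d = seqio.pairwise_distance(aln, "p_distance").values
        deme_a = set(cfg.localities.names[:5])
        in_a = np.array([meta.locality_of(i) in deme_a for i in aln.ids])
        between = d[np.ix_(in_a, ~in_a)]
        within = np.concatenate([
            d[np.ix_(in_a, in_a)][np.triu_indices(in_a.sum(), 1)],
            d[np.ix_(~in_a, ~in_a)][np.triu_indices((~in_a).sum(), 1)],
        ])
        assert between.min() > np.percentile(within, 95)

    def test_inconsistent_locality_counts_rejected(self):
        with pytest.raises(ValueError, match="locality counts"):
            coalsim.study_config(seed=0, n=10)

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = coalsim.study_config(seed=9)
        path = tmp_path / "cfg.yml"
        cfg.to_yaml(path)
        cfg2 = coalsim.SimulationConfig.from_yaml(path)
        assert cfg2 == cfg
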