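import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from popexpand import coalsim, demography, seqio
from popexpand.coalsim import Genealogy, TwoEpochModel
from popexpand.demography import Prior, ess, hpd, mh_sample, upgma_genealogy
from popexpand.seqio import Alignment, DistanceMatrix


def naive_upgma_heights(d):
    """O(n^3) textbook UPGMA; returns sorted merge heights."""
    clusters = {i: [i] for i in range(len(d))}
    dist = {(i, j): d[i][j] for i in range(len(d)) for j in range(i + 1, len(d))}
    heights = []
    nxt = len(d)
    while len(clusters) > 1:
        (a, b), dm = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(dm / 2)
        merged = clusters.pop(a) + clusters.pop(b)
        new = {}
        for (i, j), v in dist.items():
            if a in (i, j) or b in (i, j):
                continue
            new[(i, j)] = v
        for c, mem in clusters.items():
            num = sum(d[x][y] for x in merged for y in mem)
            new[(min(c, nxt), max(c, nxt))] = num / (len(merged) * len(mem))
        clusters[nxt] = merged
        dist = new
        nxt += 1
    return sorted(heights)


class TestUpgma:
    def test_textbook_three_taxon_case(self):
        d = DistanceMatrix(ids=["A", "B", "C"],
                           values=np.array([[0, 0.02, 0.04], [0.02, 0, 0.04], [0.04, 0.04, 0]]),
                           model="p_distance", units="substitutions/site")
        g = upgma_genealogy(d)
        assert np.allclose(np.sort(g.coalescent_times()), [0.01, 0.02])
        # A and B share the shallow ancestor
        ab_parent = g.parent[g.labels.index("A")]
        assert g.parent[g.labels.index("B")] == ab_parent
        assert g.heights[ab_parent] == pytest.approx(0.01)

    def test_identical_sequences_merge_at_zero(self):
        aln = Alignment(ids=list("abcd"), seqs=["ACGT"] * 4)
        g = upgma_genealogy(seqio.pairwise_distance(aln, "p_distance"))
        assert np.allclose(g.heights, 0.0)

    def test_matches_naive_oracle_on_random_matrices(self, rng):
        for _ in range(5):
            n = 8
            raw = rng.random((n, n)) * 0.1
            vals = (raw + raw.T) / 2
            np.fill_diagonal(vals, 0.0)
            d = DistanceMatrix(ids=[f"s{i}" for i in range(n)], values=vals,
                               model="p_distance", units="substitutions/site")
            g = upgma_genealogy(d)
            assert np.allclose(g.coalescent_times(), naive_upgma_heights(vals.tolist()),
                               atol=1e-12)

    def test_quantum_spreading_resolves_ties(self):
        aln = Alignment(ids=list("abcdef"),
                        seqs=["AAAA", "AAAA", "AAAA", "AAAT", "AAAT", "CCCC"])
        d = seqio.pairwise_distance(aln, "p_distance")
        g = upgma_genealogy(d, quantum=1 / 4)
        times = g.coalescent_times()
        assert np.all(times > 0)
        assert len(np.unique(times)) == len(times)
        for i, p in enumerate(g.parent):
            if p >= 0 and i >= g.n_tips:
                assert g.heights[p] > g.heights[i]


class TestCoalescentLoglik:
    def test_two_tip_constant_closed_form(self, rng):
        n_size = 0.01
        g = coalsim.simulate_genealogy(2, TwoEpochModel.constant(n_size), rng)
        t = g.root_height
        expected = -math.log(n_size) - t / n_size
        assert demography.coalescent_loglik(g, n_size) == pytest.approx(expected)

    def test_model_nesting_exact_equality(self, constant_genealogy_n40):
        g = constant_genealogy_n40
        nested = TwoEpochModel(n1=0.007, r=0.0, n0=0.007, t_trans=1e-3)
        assert demography.coalescent_loglik(g, nested) == pytest.approx(
            demography.coalescent_loglik(g, 0.007), rel=1e-12
        )

    def test_matches_quadrature_oracle(self, rng):
        g = coalsim.simulate_genealogy(15, coalsim.STUDY_DEMOGRAPHY, rng)
        model = TwoEpochModel(n1=0.02, r=2500.0, n0=0.004, t_trans=6e-4)
        h = g.coalescent_times()
        starts = np.concatenate([[0.0], h[:-1]])
        k = np.arange(15, 1, -1)
        total = 0.0
        for hj, sj, kj in zip(h, starts, k):
            cc = kj * (kj - 1) / 2
            lam, _ = quad(lambda t: 1.0 / model.size_at(t), sj, hj,
                          points=[model.t_trans], limit=200)
            total += math.log(cc / model.size_at(hj)) - cc * lam
        assert demography.coalescent_loglik(g, model) == pytest.approx(total, abs=1e-6)

    def test_two_epoch_mle_never_below_constant_mle(self, constant_genealogy_n40):
        g = constant_genealogy_n40
        n_grid = np.geomspace(1e-4, 0.1, 40)
        best_const = max(demography.coalescent_loglik(g, n) for n in n_grid)
        best_two = best_const
        for n1 in np.geomspace(1e-3, 0.05, 8):
            for tt in (1e-4, 1e-3):
                for r in (0.0, 500.0, 3000.0):
                    m = TwoEpochModel(n1=n1, r=r, n0=0.005, t_trans=tt)
                    best_two = max(best_two, demography.coalescent_loglik(g, m))
        assert best_two >= best_const


class TestMhSampler:
    def test_conjugate_posterior_mean(self, constant_genealogy_n40):
        g = constant_genealogy_n40
        h, s, cc, _ = demography._coal_data(g)
        a_stat = float(np.sum(cc * (h - s)))
        e = len(h)
        conj_mean = a_stat / (e - 1)
        trace = mh_sample(g, "constant", {"N": Prior("one_over_x", 1e-5, 1.0)},
                          iterations=30_000, thin=10, seed=2)
        assert trace["N"].mean() == pytest.approx(conj_mean, rel=0.05)

    def test_beta_zero_samples_the_prior(self, constant_genealogy_n40):
        prior = Prior("one_over_x", 1e-4, 1e-1)
        # wide proposal so thinned samples are nearly independent
        trace = mh_sample(constant_genealogy_n40, "constant", {"N": prior},
                          iterations=20_000, thin=20, seed=3, beta=0.0, size_step=1.5)
        # under 1/x, ln N is uniform on (ln lo, ln hi)
        u = (np.log(trace["N"]) - math.log(prior.lower)) / math.log(prior.upper / prior.lower)
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_samples_respect_prior_support(self, constant_genealogy_n40):
        priors = {
            "N0": Prior("one_over_x", 1e-4, 0.05),
            "N1": Prior("one_over_x", 1e-4, 0.05),
            "r": Prior("uniform", 0.0, 5000.0),
            "t_trans": Prior("uniform", 0.0, 2e-3),
        }
        trace = mh_sample(constant_genealogy_n40, "two_epoch", priors,
                          iterations=5_000, thin=10, seed=4)
        for nm in trace.names:
            assert trace[nm].min() >= priors[nm].lower
            assert trace[nm].max() <= priors[nm].upper

    def test_identical_seed_identical_trace(self, constant_genealogy_n40):
        kw = dict(iterations=3_000, thin=10, seed=8)
        pr = {"N": Prior("one_over_x", 1e-5, 1.0)}
        t1 = mh_sample(constant_genealogy_n40, "constant", pr, **kw)
        t2 = mh_sample(constant_genealogy_n40, "constant", pr, **kw)
        assert np.array_equal(t1.samples, t2.samples)
        assert np.array_equal(t1.loglik, t2.loglik)


class TestSkyline:
    def test_group_count_bounded_by_events(self, constant_genealogy_n40):
        with pytest.raises(ValueError, match="exceed"):
            demography.bayesian_skyline(constant_genealogy_n40, m=40)

    def test_constant_genealogy_flat_within_hpd(self, constant_genealogy_n40):
        sky, _ = demography.bayesian_skyline(constant_genealogy_n40, m=5,
                                             iterations=20_000, thin=20, seed=5)
        n_size = 0.005
        excluded = np.sum((sky.hpd_lower > n_size) | (sky.hpd_upper < n_size))
        assert excluded <= 2
        assert np.all(sky.hpd_lower <= sky.median) and np.all(sky.median <= sky.hpd_upper)

    def test_growth_genealogy_declines_into_past(self, rng):
        g = coalsim.simulate_genealogy(40, coalsim.STUDY_DEMOGRAPHY, rng)
        sky, _ = demography.bayesian_skyline(g, m=5, iterations=20_000, thin=20, seed=6)
        assert sky.median[0] > sky.median[-1]

    def test_single_group_matches_constant_model_posterior(self, constant_genealogy_n40):
        g = constant_genealogy_n40
        sky, trace = demography.bayesian_skyline(g, m=1, iterations=30_000, thin=20, seed=7)
        const = mh_sample(g, "constant", {"N": Prior("one_over_x", 1e-8, 100.0)},
                          iterations=30_000, thin=20, seed=7)
        assert np.median(trace["theta_1"]) == pytest.approx(np.median(const["N"]), rel=0.1)


class TestDiagnostics:
    def test_ess_iid_near_sample_size(self):
        x = np.random.default_rng(1).standard_normal(10_000)
        assert ess(x) == pytest.approx(10_000, rel=0.1)

    def test_ess_ar1_matches_closed_form(self):
        phi = 0.9
        rng = np.random.default_rng(2)
        n = 40_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        expected = n * (1 - phi) / (1 + phi)
        assert ess(x) == pytest.approx(expected, rel=0.2)

    def test_ess_alternating_series_finite_and_antithetic(self):
        x = np.array([1.0, -1.0] * 500)
        v = ess(x)
        assert np.isfinite(v) and v > 1000

    def test_ess_constant_series_undefined(self):
        with pytest.raises(ValueError):
            ess(np.ones(100))

    def test_hpd_uniform_width(self):
        x = np.random.default_rng(3).random(100_000)
        lo, hi = hpd(x, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.02)

    def test_hpd_degenerate_samples_zero_width(self):
        lo, hi = hpd(np.full(50, 3.14), 0.95)
        assert lo == hi == 3.14

    def test_hpd_exponential_starts_near_zero(self):
        x = np.random.default_rng(4).exponential(size=100_000)
        lo, hi = hpd(x, 0.95)
        assert lo < 0.01
        assert hi < np.max(x)

    def test_hpd_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            hpd(np.arange(100.0), 1.5)
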