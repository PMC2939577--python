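"""Simulator correctness: determinism, distributional limit cases,
subsampling artifacts, and the packaged demo bundle."""

import numpy as np
import pytest
from scipy import stats

import divtempo as dt
from divtempo.simulate import yule_branching_times, yule_subsampled_branching_times
from divtempo.tempo import gamma_from_ages


class TestYule:
    def test_two_tip_crown_age_matches_waiting_time_oracle(self):
        # for n=2 the construction is a single Exp(2*lam) interval; compare
        # the simulator against an independent Monte-Carlo draw of that law
        rng = np.random.default_rng(0)
        sim = np.array([yule_branching_times(2, 1.0, rng)[0] for _ in range(10_000)])
        oracle = np.random.default_rng(1).exponential(0.5, size=10_000)
        assert sim.mean() == pytest.approx(oracle.mean(), abs=0.02)
        assert stats.ks_2samp(sim, oracle).pvalue > 0.01

    def test_complete_tree_gamma_near_standard_normal_mean(self):
        rng = np.random.default_rng(7)
        gs = np.array([gamma_from_ages(yule_branching_times(100, 1.0, rng))
                       for _ in range(1000)])
        assert abs(gs.mean()) < 0.1

    def test_same_seed_identical_newick(self):
        assert (dt.simulate_yule(30, 0.5, 99).write_newick()
                == dt.simulate_yule(30, 0.5, 99).write_newick())

    def test_emits_valid_chronogram(self):
        t = dt.simulate_yule(40, 0.2, 3)  # constructor validates
        assert t.n_tips == 40
        assert t.branching_times().n == 40

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            dt.simulate_yule(1, 1.0, 0)
        with pytest.raises(ValueError):
            dt.simulate_yule(10, -1.0, 0)


class TestBirthDeath:
    def test_mu_zero_matches_yule_distribution(self):
        c_bd = [dt.simulate_bd_reconstructed(10, 1.0, 0.0, 1000 + s).crown_age
                for s in range(2000)]
        c_y = [dt.simulate_yule(10, 1.0, 100_000 + s).crown_age for s in range(2000)]
        assert stats.ks_2samp(c_bd, c_y).pvalue > 0.01

    def test_parameter_recovery(self):
        lams, mus = [], []
        for s in range(200):
            tr = dt.simulate_bd_reconstructed(200, 0.2, 0.1, 6000 + s)
            f = dt.fit_model(tr, "birth_death")
            lams.append(f.notes["lam"])
            mus.append(f.notes["mu"])
        assert np.median(lams) == pytest.approx(0.2, rel=0.25)
        assert np.median(mus) == pytest.approx(0.1, rel=0.25)

    def test_same_seed_reproducible(self):
        a = dt.simulate_bd_reconstructed(25, 0.3, 0.1, 5).write_newick()
        b = dt.simulate_bd_reconstructed(25, 0.3, 0.1, 5).write_newick()
        assert a == b

    def test_parameter_domain(self):
        with pytest.raises(ValueError):
            dt.simulate_bd_reconstructed(10, 0.1, 0.2, 0)


class TestPiecewiseYule:
    def test_single_rate_matches_yule_distribution(self):
        c_pw = [dt.simulate_piecewise_yule(10, (0.5,), (), seed=s).crown_age
                for s in range(2000)]
        c_y = [dt.simulate_yule(10, 0.5, 200_000 + s).crown_age for s in range(2000)]
        assert stats.ks_2samp(c_pw, c_y).pvalue > 0.01

    def test_rate_drop_slows_lineage_accumulation(self):
        # 0.08 -> 0.02 at 41 My: per-segment rate estimates should order
        from divtempo.model_fit import _segment_stats

        ratios = []
        for s in range(200):
            tr = dt.simulate_piecewise_yule(120, (0.08, 0.02), (41.0,), seed=s)
            B, L = _segment_stats(tr.branching_times(), np.array([41.0]))
            if np.all(B > 0):
                ratios.append((B[1] / L[1]) / (B[0] / L[0]))
        assert np.mean(ratios) < 1.0

    def test_same_seed_reproducible(self):
        a = dt.simulate_piecewise_yule(50, (0.1, 0.02), (20.0,), seed=4).write_newick()
        b = dt.simulate_piecewise_yule(50, (0.1, 0.02), (20.0,), seed=4).write_newick()
        assert a == b

    def test_parameter_domain(self):
        with pytest.raises(ValueError):
            dt.simulate_piecewise_yule(10, (0.1, 0.2), (5.0, 10.0), seed=0)
        with pytest.raises(ValueError):
            dt.simulate_piecewise_yule(10, (0.1,), (5.0,), seed=0)


class TestTimeVarying:
    def test_constant_rates_match_bd_distribution(self):
        c_tv = [dt.simulate_time_varying(10, lambda t: 0.3, lambda t: 0.1,
                                         t_max=500.0, seed=s).crown_age
                for s in range(2000)]
        c_bd = [dt.simulate_bd_reconstructed(10, 0.3, 0.1, 300_000 + s).crown_age
                for s in range(2000)]
        assert stats.ks_2samp(c_tv, c_bd).pvalue > 0.01

    def test_declining_speciation_gives_negative_gamma(self):
        gs = [dt.gamma_stat(dt.simulate_time_varying(
            100, lambda t: 0.5 * np.exp(-0.1 * t), lambda t: 0.0,
            t_max=400.0, seed=5000 + s)).gamma for s in range(200)]
        assert np.mean(gs) < 0.0

    def test_same_seed_reproducible(self):
        mk = lambda: dt.simulate_time_varying(
            20, lambda t: 0.4 * np.exp(-0.05 * t), lambda t: 0.05,
            t_max=200.0, seed=8).write_newick()
        assert mk() == mk()

    def test_unbounded_rate_rejected(self):
        with pytest.raises(ValueError, match="bounded"):
            dt.simulate_time_varying(
                10, lambda t: float("inf") if t <= 0 else 1.0 / t,
                lambda t: 0.0, t_max=10.0, seed=0)


class TestSubsampling:
    def test_identity_when_m_equals_n(self):
        t = dt.simulate_yule(20, 0.5, 1)
        s = dt.subsample_tips(t, 20, 2)
        np.testing.assert_allclose(s.branching_times().x, t.branching_times().x)

    def test_same_seed_same_tip_set(self):
        t = dt.simulate_yule(50, 0.5, 1)
        a = dt.subsample_tips(t, 10, 7)
        b = dt.subsample_tips(t, 10, 7)
        assert a.tip_labels == b.tip_labels

    def test_subsampling_generates_apparent_slowdown(self):
        # random tip removal pushes gamma negative even under pure birth
        rng = np.random.default_rng(12)
        gs = np.array([gamma_from_ages(
            yule_subsampled_branching_times(1000, 50, 1.0, rng))
            for _ in range(300)])
        assert gs.mean() < -1.0

    def test_fast_subsampled_times_match_tree_level_pruning(self):
        # the flat-array induced-age path must agree with dendropy pruning
        t = dt.simulate_yule(60, 0.5, 21)
        labels = t.tip_labels
        keep = set(np.random.default_rng(3).choice(labels, 15, replace=False).tolist())
        sub = t.prune_to_tips(keep)
        assert sub.n_tips == 15
        orig = t.internal_ages()
        for a in sub.internal_ages():
            assert np.min(np.abs(orig - a)) < 1e-9

    def test_depth_biased_option(self):
        t = dt.simulate_yule(40, 0.5, 2)
        s = dt.subsample_tips(t, 10, 3, depth_bias_exponent=2.0)
        assert s.n_tips == 10

    def test_m_out_of_range(self):
        t = dt.simulate_yule(10, 0.5, 1)
        with pytest.raises(ValueError):
            dt.subsample_tips(t, 11, 0)


class TestGammaScaleInvariance:
    def test_gamma_invariant_under_time_rescaling(self, random_trees):
        for tree in random_trees:
            bt = tree.branching_times()
            if bt.n < 3:
                continue
            for c in (0.1, 7.0, 1e3):
                assert dt.gamma_stat(bt.scaled(c)).gamma == pytest.approx(
                    dt.gamma_stat(bt).gamma, rel=1e-9)


class TestDemoBundle:
    def test_sample_sizes_and_richness(self, demo_bundle):
        assert demo_bundle["harpaline_sampled"].n_tips == 193
        assert demo_bundle["brachinine_sampled"].n_tips == 10
        assert demo_bundle["harpaline_full"].n_tips == 19811
        assert demo_bundle["brachinine_full"].n_tips == 655
        assert list(demo_bundle["richness"].values()) == [19811, 655, 100]

    def test_regeneration_is_byte_identical(self, demo_bundle):
        again = dt.harpaline_fixture(11)
        for key in ("harpaline_sampled", "brachinine_sampled"):
            assert again[key].write_newick() == demo_bundle[key].write_newick()

    def test_sister_clades_share_crown_age(self, demo_bundle):
        assert demo_bundle["harpaline_full"].crown_age == pytest.approx(98.5)
        assert demo_bundle["brachinine_full"].crown_age == pytest.approx(98.5)
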