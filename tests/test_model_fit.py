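"""Diversification-model likelihoods: hand values, nesting/limit identities,
closed-form-vs-optimizer agreement, and parameter recovery."""

import numpy as np
import pytest
from scipy import optimize

import divtempo as dt
from divtempo.model_fit import _piecewise_profile_lnL, _segment_stats
from divtempo.simulate import yule_branching_times


class TestPureBirth:
    def test_hand_value_comb4(self, comb4):
        lnL = dt.loglik_pure_birth(comb4, 1.0)
        assert lnL == pytest.approx(np.log(2) + np.log(3) - 9.0, rel=1e-12)

    def test_closed_form_mle_matches_numeric_optimum(self, random_trees):
        for tree in random_trees:
            bt = tree.branching_times()
            lam_hat = (bt.n - 2) / bt.T
            res = optimize.minimize_scalar(
                lambda l: -dt.loglik_pure_birth(bt, l),
                bounds=(1e-6, 50.0), method="bounded",
                options={"xatol": 1e-12})
            assert res.x == pytest.approx(lam_hat, rel=1e-6)

    def test_rate_recovery_on_simulated_trees(self):
        rng = np.random.default_rng(123)
        lam_hats = []
        for _ in range(200):
            x = yule_branching_times(200, 0.1, rng)
            k = np.arange(2, 201, dtype=float)
            g = -np.diff(np.append(x, 0.0))
            lam_hats.append(198 / float(np.sum(k * g)))
        assert np.median(lam_hats) == pytest.approx(0.1, rel=0.10)


class TestBirthDeath:
    def test_reduces_to_pure_birth_at_zero_extinction(self, random_trees):
        for tree in random_trees:
            bt = tree.branching_times()
            for r in (0.05, 0.3, 1.7):
                assert dt.loglik_bd(bt, r, 0.0) == pytest.approx(
                    dt.loglik_pure_birth(bt, r), abs=1e-9)

    def test_nests_pure_birth_at_optimum(self, random_trees):
        for tree in random_trees[:4]:
            bt = tree.branching_times()
            pb = dt.fit_model(bt, "pure_birth")
            bd = dt.fit_model(bt, "birth_death")
            assert bd.lnL >= pb.lnL - 1e-9

    def test_reports_extinction_rate(self, random_trees):
        f = dt.fit_model(random_trees[3], "birth_death")
        assert f.notes["mu"] == pytest.approx(f.notes["lam"] * f.params["a"], rel=1e-9)

    def test_domain(self, comb4):
        with pytest.raises(ValueError):
            dt.loglik_bd(comb4, -0.1, 0.0)
        with pytest.raises(ValueError):
            dt.loglik_bd(comb4, 0.1, 1.0)


class TestTimeVaryingLimits:
    def test_spvar_constant_limit_equals_bd(self, random_trees):
        for tree in random_trees:
            bt = tree.branching_times()
            assert dt.loglik_spvar(bt, 0.3, 0.0, 0.1) == pytest.approx(
                dt.loglik_bd(bt, 0.2, 1.0 / 3.0), abs=1e-6)

    def test_spvar_double_limit_equals_pure_birth(self, random_trees):
        for tree in random_trees[:5]:
            bt = tree.branching_times()
            assert dt.loglik_spvar(bt, 0.4, 0.0, 0.0) == pytest.approx(
                dt.loglik_pure_birth(bt, 0.4), abs=1e-6)

    def test_exvar_zero_extinction_equals_pure_birth(self, random_trees):
        for tree in random_trees:
            bt = tree.branching_times()
            assert dt.loglik_exvar(bt, 0.3, 0.0, 1.0) == pytest.approx(
                dt.loglik_pure_birth(bt, 0.3), abs=1e-6)

    def test_exvar_saturation_limit_equals_bd(self, random_trees):
        for tree in random_trees:
            bt = tree.branching_times()
            assert dt.loglik_exvar(bt, 0.3, 0.1, 1e6) == pytest.approx(
                dt.loglik_bd(bt, 0.2, 1.0 / 3.0), abs=1e-4)

    def test_exvar_monotone_decreasing_in_extinction(self, random_trees):
        bt = random_trees[2].branching_times()
        vals = [dt.loglik_exvar(bt, 0.3, m, 2.0) for m in (0.20, 0.25, 0.29)]
        assert np.all(np.isfinite(vals))
        assert vals[0] > vals[1] > vals[2]

    def test_spvar_decay_recovery(self):
        ks = []
        for s in range(40):
            tv = dt.simulate_time_varying(
                200, lambda t: 0.3 * np.exp(-0.05 * t), lambda t: 0.05,
                t_max=400.0, seed=7000 + s)
            ks.append(dt.fit_model(tv, "spvar").params["kdecay"])
        assert np.mean(np.asarray(ks) > 0) >= 0.9
        assert np.median(ks) > 0


class TestPiecewiseYule:
    def test_single_segment_equals_pure_birth(self, random_trees):
        for tree in random_trees[:5]:
            bt = tree.branching_times()
            assert dt.loglik_piecewise_yule(bt, (0.7,), ()) == pytest.approx(
                dt.loglik_pure_birth(bt, 0.7), rel=1e-12)

    def test_equal_rates_collapse(self, comb4):
        bt = comb4.branching_times()
        assert dt.loglik_piecewise_yule(bt, (1.0, 1.0), (1.5,)) == pytest.approx(
            dt.loglik_pure_birth(bt, 1.0), rel=1e-12)

    def test_closed_form_mles_match_numeric_optimizer(self, random_trees):
        for tree in random_trees[:6]:
            bt = tree.branching_times()
            shift = np.array([0.5 * bt.crown_age])
            lnL_cf, lam_cf = _piecewise_profile_lnL(bt, shift)
            if not np.isfinite(lnL_cf):
                continue
            res = optimize.minimize(
                lambda p: -dt.loglik_piecewise_yule(bt, np.exp(p), shift),
                np.log(lam_cf), method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12})
            assert -res.fun == pytest.approx(lnL_cf, rel=1e-5)

    def test_boundary_event_belongs_to_older_segment(self, comb4):
        bt = comb4.branching_times()
        B, L = _segment_stats(bt, np.array([2.0]))  # shift exactly at an event
        assert B.tolist() == [1, 1]  # event at age 2 counted in the older segment

    def test_shift_recovery(self):
        shifts_hat, order = [], 0
        for s in range(100):
            tr = dt.simulate_piecewise_yule(193, (0.08, 0.02), (41.0,), seed=100 + s)
            f = dt.fit_model(tr, "yule2rate")
            shifts_hat.append(f.params["st1"])
            order += f.params["lam1"] > f.params["lam2"]
        assert abs(np.median(shifts_hat) - 41.0) <= 3.0
        assert order >= 90


class TestFitModelAndAIC:
    def test_pure_birth_fit_is_closed_form(self, random_trees):
        for tree in random_trees[:5]:
            bt = tree.branching_times()
            f = dt.fit_model(bt, "pure_birth")
            assert f.params["lam"] == pytest.approx((bt.n - 2) / bt.T, rel=1e-12)

    def test_aic_arithmetic(self):
        assert dt.ModelFit("yule3rate", {}, 6.30, 5).AIC == pytest.approx(-2.60)
        assert dt.ModelFit("pure_birth", {}, -26.21, 1).AIC == pytest.approx(54.42)

    def test_unknown_model_rejected(self, comb4):
        with pytest.raises(ValueError):
            dt.fit_model(comb4, "logistic")

    def test_fit_all_table_shape_and_delta(self, random_trees):
        tab = dt.fit_all(random_trees[4], grid_step=1.0)
        assert list(tab["model"]) == list(dt.MODELS)
        assert tab.loc[tab["best"], "delta_AIC"].iloc[0] == 0.0
        assert (tab["delta_AIC"].dropna() >= 0).all()
        lrt = tab.attrs["lrt"]
        assert set(lrt["df"]) <= {1, 2}
        assert ((lrt["p"].dropna() >= 0) & (lrt["p"].dropna() <= 1)).all()

    def test_conditioning_consistency_where_models_coincide(self, random_trees):
        # identical lnL at parameter settings where models reduce to the
        # same process => the shared constants are consistent and AIC
        # differences are meaningful
        bt = random_trees[1].branching_times()
        lam = 0.25
        vals = [
            dt.loglik_pure_birth(bt, lam),
            dt.loglik_bd(bt, lam, 0.0),
            dt.loglik_piecewise_yule(bt, (lam,), ()),
            dt.loglik_spvar(bt, lam, 0.0, 0.0),
            dt.loglik_exvar(bt, lam, 0.0, 1.0),
        ]
        assert np.ptp(vals) < 1e-6

    def test_lrt_calibration_and_constant_rate_preference(self):
        # on Yule data the PB-vs-BD LRT should reject at roughly the nominal
        # rate, and BD (which nests PB) should never beat PB by AIC margin 2
        rejects, bd_wins = 0, 0
        for s in range(40):
            tr = dt.simulate_yule(100, 0.1, 90_000 + s)
            bt = tr.branching_times()
            pb = dt.fit_model(bt, "pure_birth")
            bd = dt.fit_model(bt, "birth_death")
            from scipy import stats as ss
            p = ss.chi2.sf(max(0.0, 2 * (bd.lnL - pb.lnL)), 1)
            rejects += p < 0.05
            bd_wins += bd.AIC < pb.AIC
        assert rejects / 40 <= 0.125
        assert bd_wins / 40 <= 0.5
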