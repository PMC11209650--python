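import numpy as np
import pytest
from scipy.stats import multivariate_normal

import reachadapt as ra
from reachadapt import _engine
from reachadapt.cohort import PARAM_NAMES
from reachadapt.model import HierarchicalDualRateResults, McmcConfig
from reachadapt.schedule import ScheduleConfig, build_schedule, perturbation_sequence


def joint_gaussian_loglik(th, schedule, y_obs):
    """Independent oracle: assemble the joint Gaussian of the observed probe
    AIs by propagating means/covariances of the linear system directly, and
    evaluate its density with scipy."""
    f, ec = perturbation_sequence(schedule)
    f, ec = np.array(f), np.array(ec)
    obs_trials = np.array(schedule.ec_trial_indices) - 1
    Rf, Rs, Lf, Ls, ss, so = th
    L = np.array([Lf, Ls])
    mu = np.zeros(2)
    C = np.zeros((2, 2))
    M = len(obs_trials)
    mu_y = np.empty(M)
    Cyy = np.zeros((M, M))
    Cxy = np.zeros((2, M))
    j = 0
    obs_set = set(obs_trials)
    H = np.ones(2)
    for n in range(len(f)):
        if n in obs_set:
            mu_y[j] = H @ mu
            Cyy[j, j] = H @ C @ H + so**2
            for k in range(j):
                Cyy[j, k] = Cyy[k, j] = H @ Cxy[:, k]
            Cxy[:, j] = C @ H
            j += 1
        if ec[n]:
            A = np.diag([Rf, Rs])
            Q = ss**2 * np.eye(2)
            u = np.zeros(2)
        else:
            A = np.array([[Rf - Lf, -Lf], [-Ls, Rs - Ls]])
            Q = ss**2 * np.eye(2) + so**2 * np.outer(L, L)
            u = L * f[n]
        mu = A @ mu + u
        C = A @ C @ A.T + Q
        Cxy = A @ Cxy
    return multivariate_normal.logpdf(y_obs, mean=mu_y, cov=Cyy)


class TestLikelihood:
    def test_matches_joint_gaussian_oracle(self):
        """Kalman-filter likelihood equals the brute-force joint-Gaussian
        density of the probe observations."""
        cfg = ScheduleConfig(n_baseline=20, n_cw=30, n_ccw=10, n_final_ec=10,
                             probe_every=5, probe_window=(5, 60))
        sch = build_schedule(cfg)
        th = np.array([0.88, 0.9967, 0.0649, 0.0169, 0.03, 0.10])
        rng = np.random.default_rng(0)
        sim = ra.simulate(ra.DualRateParams(*th[:4], th[4], th[5]), sch, seed=rng)
        y = sim.loc[sim["trial_type"] == "error_clamp", "y"].to_numpy()
        obs = sim.assign(i=np.arange(len(sch)))
        model = ra.HierarchicalDualRate(
            sim.loc[sim["trial_type"] == "error_clamp", ["index", "y"]]
            .rename(columns={"index": "trial_index", "y": "ai"})
            .assign(participant_id="p1"),
            sch,
        )
        got = model.loglike(th)
        want = joint_gaussian_loglik(th, sch, y)
        assert got == pytest.approx(want, abs=1e-9)

    def test_rejects_probes_at_non_ec_trials(self, schedule):
        import pandas as pd

        df = pd.DataFrame({"participant_id": ["p1"], "trial_index": [101], "ai": [0.2]})
        with pytest.raises(ValueError):
            ra.HierarchicalDualRate(df, schedule)


class TestJointDensity:
    def test_rate_outside_truncation_is_minus_inf(self, small_cohort):
        model = ra.HierarchicalDualRate.from_cohort(small_cohort)
        rng = np.random.default_rng(1)
        theta = model._initial_theta(rng)
        assert np.isfinite(model.logpost(theta))
        bad = theta.copy()
        bad[1] = 1.2  # participant Rs above 1
        assert model.logpost(bad) == -np.inf
        bad2 = theta.copy()
        bad2[6 * model.n_participants] = 1.2  # hyper Rf_mu above 1
        assert model.logpost(bad2) == -np.inf

    def test_ordering_violation_is_minus_inf(self, small_cohort):
        model = ra.HierarchicalDualRate.from_cohort(small_cohort)
        theta = model._initial_theta(np.random.default_rng(1))
        bad = theta.copy()
        bad[0], bad[1] = 0.99, 0.8  # Rf > Rs
        assert model.logpost(bad) == -np.inf


class TestFit:
    def test_seed_reproducibility(self, small_cohort):
        model = ra.HierarchicalDualRate.from_cohort(small_cohort)
        cfg = McmcConfig(n_chains=2, n_warmup=200, n_iter=300, seed=17)
        a = model.fit(mcmc=cfg)
        b = model.fit(mcmc=cfg)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_draws_respect_constraints(self, reduced_fit):
        """Every posterior draw satisfies the truncations and orderings."""
        model = reduced_fit.model
        d = reduced_fit.draws.reshape(-1, model.n_dim)
        for p in range(model.n_participants):
            blk = d[:, 6 * p : 6 * p + 6]
            assert (blk[:, 0] < blk[:, 1]).all() and (blk[:, 1] < 1).all()
            assert (blk[:, 3] < blk[:, 2]).all() and (blk[:, 0] > 0).all()
            assert (blk[:, 4] > 0).all() and (blk[:, 5] > 0).all()
        hyp = d[:, 6 * model.n_participants :]
        assert (hyp[:, 1::2] > 0).all()  # all group SDs positive
        assert ((hyp[:, 0:8:2] > 0) & (hyp[:, 0:8:2] < 1)).all()  # rate means in (0,1)

    def test_identical_priors_for_independent_groups(self):
        """Both groups are fitted with the same model and the same priors."""
        assert ra.HierarchicalPriorConfig() == ra.HierarchicalPriorConfig()

    def test_posterior_contraction_with_more_participants(self):
        """Group-mean posteriors tighten as the cohort grows."""
        sds = {}
        for n in (4, 16):
            cohort = ra.recovery_dataset(n, seed=3)
            res = ra.HierarchicalDualRate.from_cohort(cohort).fit(profile="reduced", seed=2)
            sds[n] = np.array([res.samples(f"{nm}_mu").std() for nm in PARAM_NAMES])
        ratio = sds[16] / sds[4]
        assert (ratio < 1).sum() >= 4
        assert ratio.mean() < 1


def _dummy_results(small_cohort, draws):
    model = ra.HierarchicalDualRate.from_cohort(small_cohort)
    return HierarchicalDualRateResults(
        model=model, draws=draws, acceptance=np.ones((draws.shape[0], 1)),
        mcmc=McmcConfig(n_chains=max(2, draws.shape[0]), n_warmup=0, n_iter=draws.shape[1]),
    )


class TestDiagnostics:
    def test_iid_chains_give_unit_rhat_and_mcse(self, small_cohort):
        model = ra.HierarchicalDualRate.from_cohort(small_cohort)
        rng = np.random.default_rng(0)
        n = 2000
        draws = 0.2 + 0.05 * rng.standard_normal((4, n, model.n_dim))
        res = _dummy_results(small_cohort, draws)
        d = res.diagnostics()
        hyper = d[d["parameter"].str.endswith("_mu")]
        assert (hyper["rhat"] < 1.01).all()
        # for iid draws ESS ~ total n and MCSE ~ sd / sqrt(ESS)
        sd = 0.05
        assert hyper["mcse"].mean() == pytest.approx(sd / np.sqrt(4 * n), rel=0.25)

    def test_shifted_chains_raise_rhat(self, small_cohort):
        model = ra.HierarchicalDualRate.from_cohort(small_cohort)
        rng = np.random.default_rng(1)
        draws = 0.1 * rng.standard_normal((4, 500, model.n_dim))
        draws[0] += 1.0
        res = _dummy_results(small_cohort, draws)
        d = res.diagnostics()
        assert (d[d["parameter"].str.endswith("_mu")]["rhat"] > 1.2).all()

    def test_single_chain_rejected(self, small_cohort):
        model = ra.HierarchicalDualRate.from_cohort(small_cohort)
        draws = np.zeros((1, 100, model.n_dim))
        res = _dummy_results(small_cohort, draws)
        with pytest.raises(ValueError):
            res.diagnostics()

    def test_summary_layout(self, reduced_fit):
        s = reduced_fit.summary()
        assert list(s.columns) == ["parameter", "mean", "hdi_low", "hdi_high"]
        # 12 hyperparameter rows + 6 across-participant rows
        assert len(s) == 18
        assert (s["hdi_low"] <= s["mean"]).all() and (s["mean"] <= s["hdi_high"]).all()


class TestPosteriorPredictive:
    def test_degenerate_posterior_equals_deterministic_simulation(self, small_cohort):
        model = ra.HierarchicalDualRate.from_cohort(small_cohort)
        th = np.array([0.9092, 0.9967, 0.0649, 0.0169, 0.0, 0.0])
        draws = np.tile(np.r_[np.tile(th, model.n_participants), np.tile([0.5, 0.1], 6)],
                        (2, 10, 1))
        res = _dummy_results(small_cohort, draws)
        pred = res.posterior_predictive(n_draws=3, seed=0)
        det = ra.simulate(ra.DualRateParams(*th[:4]), model.schedule)
        one = pred[pred["participant_id"] == model.participant_ids[0]]
        np.testing.assert_allclose(one["x_mean"].to_numpy(), det["x"].to_numpy(), atol=1e-12)

    def test_baseline_prediction_near_zero(self, reduced_fit):
        pred = reduced_fit.posterior_predictive(n_draws=40, seed=1)
        base = pred[pred["index"] <= 100]
        assert abs(base["x_mean"].mean()) < 0.05

    def test_zigzag_probe_decay_in_cw_phase(self, reduced_fit):
        """During force-field adaptation the predicted net state dips right
        after each probe (error-clamp decay) relative to field-trial steps."""
        pred = reduced_fit.posterior_predictive(n_draws=40, seed=2)
        one = pred[pred["participant_id"] == reduced_fit.model.participant_ids[0]]
        x = one.sort_values("index")["x_mean"].to_numpy()
        sch = reduced_fit.model.schedule
        probes = [i for i in sch.ec_trial_indices if 105 <= i <= 330]
        post_probe_steps = np.array([x[p] - x[p - 1] for p in probes])  # step after EC
        field_steps = np.array(
            [x[i] - x[i - 1] for i in range(105, 330) if (i not in probes and i + 1 not in probes)]
        )
        assert post_probe_steps.mean() < 0
        assert field_steps.mean() > 0


class TestParameterRecoveryScoring:
    def test_degenerate_fit_scores_zero(self, small_cohort):
        model = ra.HierarchicalDualRate.from_cohort(small_cohort)
        draws = np.zeros((2, 5, model.n_dim))
        for p, part in enumerate(small_cohort.participants):
            draws[:, :, 6 * p : 6 * p + 6] = part.true_params.as_array()
        res = _dummy_results(small_cohort, draws)
        mae = res.parameter_recovery(small_cohort)
        assert (mae < 1e-12).all()

    def test_mismatched_participants_rejected(self, small_cohort):
        model = ra.HierarchicalDualRate.from_cohort(small_cohort)
        res = _dummy_results(small_cohort, np.zeros((2, 5, model.n_dim)))
        other = ra.recovery_dataset(3, seed=99)
        with pytest.raises(ValueError):
            res.parameter_recovery(other)
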