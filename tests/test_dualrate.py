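import numpy as np
import pytest

import reachadapt as ra
from reachadapt.dualrate import DualRateParams, DualRateState, probe_series
from reachadapt.schedule import ScheduleConfig, build_schedule, perturbation_sequence


def naive_simulate(params, f, is_ec):
    """Independent trial-by-trial recursion, written directly from the
    update equations (oracle for simulate)."""
    xf = xs = 0.0
    out = []
    for fi, eci in zip(f, is_ec):
        y = xf + xs
        out.append((xf, xs, y))
        e = 0.0 if eci else fi - y
        xf, xs = params.Rf * xf + params.Lf * e, params.Rs * xs + params.Ls * e
    return np.array(out)


class TestStep:
    def test_pure_decay_on_error_clamp(self):
        p = DualRateParams.unchecked(Rf=0.5, Rs=0.99, Lf=0.2, Ls=0.1)
        nxt, y = ra.step(DualRateState(0.4, 0.5), p, f=1.0, is_error_clamp=True)
        assert (nxt.xf, nxt.xs) == (pytest.approx(0.2), pytest.approx(0.495))
        assert y == pytest.approx(0.9)

    def test_one_step_learning_from_unit_error(self):
        p = DualRateParams(Rf=0.9092, Rs=0.9967, Lf=0.0649, Ls=0.0169)
        nxt, _ = ra.step(DualRateState(0.0, 0.0), p, f=1.0, is_error_clamp=False)
        assert nxt.xf == pytest.approx(0.0649)
        assert nxt.xs == pytest.approx(0.0169)

    def test_identity_dynamics_boundary(self):
        p = DualRateParams.unchecked(Rf=1.0, Rs=1.0, Lf=0.0, Ls=0.0)
        state = DualRateState(0.3, -0.2)
        for f in (-1.0, 0.0, 1.0):
            nxt, _ = ra.step(state, p, f, is_error_clamp=False)
            assert (nxt.xf, nxt.xs) == (state.xf, state.xs)

    def test_rejects_nonfinite_state(self):
        with pytest.raises(ValueError):
            DualRateState(np.nan, 0.0)

    def test_param_ordering_enforced(self):
        with pytest.raises(ValueError):
            DualRateParams(Rf=0.99, Rs=0.9, Lf=0.1, Ls=0.01)
        with pytest.raises(ValueError):
            DualRateParams(Rf=0.8, Rs=0.99, Lf=0.01, Ls=0.1)


class TestSimulate:
    def test_all_null_zero_noise_stays_zero(self):
        cfg = ScheduleConfig(n_baseline=50, n_cw=1, n_ccw=0, n_final_ec=0,
                             probe_every=0, probe_window=(1, 1))
        sim = ra.simulate(DualRateParams.fig6("control"), build_schedule(cfg))
        np.testing.assert_allclose(sim["x"][:50], 0.0)

    def test_matches_naive_recursion_on_random_parameters(self):
        """simulate() agrees with an independent naive loop to 1e-12 on
        random parameter draws and short random schedules."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            rs = rng.uniform(0.9, 0.999)
            rf = rng.uniform(0.3, rs - 1e-3)
            lf = rng.uniform(0.05, 0.5)
            ls = rng.uniform(1e-3, lf - 1e-4)
            p = DualRateParams(rf, rs, lf, ls)
            f = rng.choice([-1.0, 0.0, 1.0], size=50)
            ec = rng.random(50) < 0.2
            cfg_trials = []
            from reachadapt.schedule import TrialSpec, TrialType

            for i, (fi, eci) in enumerate(zip(f, ec), start=1):
                if eci:
                    cfg_trials.append(TrialSpec(i, TrialType.ERROR_CLAMP, 0.0, float(fi)))
                elif fi == 0.0:
                    cfg_trials.append(TrialSpec(i, TrialType.NULL, 0.0, 0.0))
                else:
                    cfg_trials.append(TrialSpec(i, TrialType.FORCE, 13.0 * fi, float(fi)))
            sch = ra.TrialSchedule(trials=tuple(cfg_trials))
            sim = ra.simulate(p, sch)
            f_eff = [t.perturbation_f if t.trial_type is not TrialType.ERROR_CLAMP else t.perturbation_f for t in cfg_trials]
            oracle = naive_simulate(p, [t.perturbation_f for t in cfg_trials],
                                    [t.trial_type is TrialType.ERROR_CLAMP for t in cfg_trials])
            np.testing.assert_allclose(sim[["xf", "xs", "y"]].to_numpy(), oracle, atol=1e-12)

    def test_linearity_in_perturbation(self):
        """Zero-noise dynamics are linear: scaling f scales the trajectory."""
        p = DualRateParams.fig6("patient")
        sch = ra.build_schedule()
        base = ra.simulate(p, sch)["x"].to_numpy()
        f, is_ec = perturbation_sequence(sch)
        half = naive_simulate(p, [0.5 * v for v in f], is_ec)[:, 0:2].sum(axis=1)
        np.testing.assert_allclose(0.5 * base, half, atol=1e-12)

    def test_seeded_reproducibility(self):
        p = DualRateParams(0.85, 0.9967, 0.0649, 0.0169, 0.02, 0.1)
        sch = ra.build_schedule()
        a = ra.simulate(p, sch, seed=42)
        b = ra.simulate(p, sch, seed=42)
        assert (a["y"] == b["y"]).all()


class TestPublishedSimulation:
    """Noise-free simulation with the published parameter sets."""

    def test_end_of_ccw_separates_groups(self, fig6_sims):
        hc = fig6_sims["control"].loc[369, "x"]  # trial 370, last CCW-phase trial
        ad = fig6_sims["patient"].loc[369, "x"]
        assert hc < -0.1
        assert abs(ad) < 0.1

    def test_common_final_recovery_level(self, fig6_sims):
        hc = fig6_sims["control"].loc[419, "x"]
        ad = fig6_sims["patient"].loc[419, "x"]
        assert abs(hc - ad) < 0.02

    def test_spontaneous_recovery_rebound(self, fig6_sims):
        """Net adaptation rebounds toward the first-learned (CW) sign during
        the final EC block before decaying, for both parameter sets."""
        for sim in fig6_sims.values():
            ec = sim["x"].to_numpy()[370:420]
            assert ec.max() > ec[0]  # rises from the end-of-CCW level
            assert ec.max() > 0.0  # crosses into CW-compensation territory


class TestFixedPoint:
    def test_single_state_reduction(self):
        # slow-process-only limit: x* = Ls f / (1 - Rs + Ls)
        p = DualRateParams.unchecked(Rf=0.5, Rs=0.99, Lf=0.0, Ls=0.02)
        got = ra.fixed_point_oracle(p, 1.0)
        assert got == pytest.approx(0.02 / (1 - 0.99 + 0.02))

    def test_simulation_converges_to_fixed_point(self):
        p = DualRateParams.fig6("control")
        cfg = ScheduleConfig(n_baseline=0, n_cw=3000, n_ccw=0, n_final_ec=0,
                             probe_every=0, probe_window=(1, 1))
        sim = ra.simulate(p, build_schedule(cfg))
        assert sim["x"].iloc[-1] == pytest.approx(ra.fixed_point_oracle(p, 1.0), abs=1e-9)

    def test_zero_input_zero_fixed_point(self):
        assert ra.fixed_point_oracle(DualRateParams.fig6("patient"), 0.0) == 0.0

    def test_rejects_unstable_dynamics(self):
        p = DualRateParams.unchecked(Rf=1.2, Rs=1.3, Lf=0.0, Ls=0.0)
        with pytest.raises(ValueError):
            ra.fixed_point_oracle(p, 1.0)


def test_probe_series_selects_error_clamps(fig6_sims, schedule):
    ps = probe_series(fig6_sims["control"], observed=False)
    assert list(ps["index"]) == schedule.ec_trial_indices
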