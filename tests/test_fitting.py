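"""Unit tests of the inference steps at desk-scale budgets."""

import numpy as np
import pandas as pd
import pytest

from opsinkit import (
    FeatureSet,
    FitConfig,
    approximate_time_constant_targets,
    fit_equilibria,
    fit_time_constants,
    global_refine_pso,
    model_features,
    recovery_scale,
    tau_O,
    tau_R,
)
from opsinkit.fitting import ScalingInvalidError, _multistart_ls, _tau_model


class TestRecoveryScale:
    def test_hand_evaluated(self):
        # tau_recov = 3 s at I_ratio = 0.4 -> tau_R(0,V) target ~ 6.13 s
        assert 3.0 * recovery_scale(0.4) == pytest.approx(6.132, abs=5e-3)

    def test_small_ratio_limit(self):
        assert recovery_scale(1e-9) == pytest.approx(1.0, rel=1e-6)

    def test_undefined_above_recovery_threshold(self):
        with pytest.raises(ScalingInvalidError):
            recovery_scale(0.7)    # ln(1/0.3) > 1


class TestTargetTable:
    def test_feature_to_gate_mapping(self):
        fs = FeatureSet()
        fs.add(1000.0, -60.0, "tau_on", 3e-4)
        fs.add(1000.0, -60.0, "tau_off", 0.02)
        fs.add(1000.0, -60.0, "tau_inact", 0.03)
        fs.add(1000.0, -60.0, "I_ratio", 0.4)
        fs.add(1000.0, -60.0, "tau_recov", 3.0)
        t = approximate_time_constant_targets(fs)
        o = t[t.gate == "O"]
        r = t[t.gate == "R"]
        assert set(zip(o.irradiance_W_m2, o.tau)) == {(1000.0, 3e-4), (0.0, 0.02)}
        assert (1000.0, 0.03) in set(zip(r.irradiance_W_m2, r.tau))
        dark_r = r[r.irradiance_W_m2 == 0.0].tau.iloc[0]
        assert dark_r == pytest.approx(3.0 * recovery_scale(0.4))

    def test_invalid_ratio_propagates(self):
        fs = FeatureSet()
        fs.add(1000.0, -60.0, "I_ratio", 0.7)
        fs.add(1000.0, -60.0, "tau_recov", 3.0)
        with pytest.raises(ScalingInvalidError):
            approximate_time_constant_targets(fs)

    def test_empty_features_rejected(self):
        from opsinkit.fitting import FitStageError
        with pytest.raises(FitStageError):
            approximate_time_constant_targets(FeatureSet())


def _tau_targets_from(params, config, irradiances, voltages):
    rows = []
    for V in voltages:
        for I in irradiances:
            rows.append(("O", I, V, float(tau_O(I, V, params))))
            rows.append(("R", I, V, float(tau_R(I, V, params))))
        rows.append(("O", 0.0, V, float(tau_O(0.0, V, params))))
        rows.append(("R", 0.0, V, float(tau_R(0.0, V, params))))
    return pd.DataFrame(rows, columns=["gate", "irradiance_W_m2", "voltage_mV", "tau"])


class TestTimeConstantFit:
    def test_noiseless_parameter_recovery_reproduces_targets(self, rsrs_final):
        cfg = FitConfig.test(seed=2)
        targets = _tau_targets_from(rsrs_final, cfg,
                                    np.logspace(2, 4, 5), (-80.0, -40.0, 0.0, 40.0))
        tauO_I, tauO_V, tauR_I, tauR_V = fit_time_constants(targets, cfg)
        for gate, theta in (("O", np.r_[tauO_I, tauO_V]), ("R", np.r_[tauR_I, tauR_V])):
            sub = targets[targets.gate == gate]
            m = _tau_model(gate, theta, sub.irradiance_W_m2.to_numpy(),
                           sub.voltage_mV.to_numpy(), cfg)
            rel = np.abs(m - sub.tau.to_numpy()) / sub.tau.to_numpy()
            assert rel.max() < 0.01

    def test_single_voltage_degenerate_fit_still_matches(self, rsrs_final):
        cfg = FitConfig.test(seed=2, step2_starts=30)
        targets = _tau_targets_from(rsrs_final, cfg, np.logspace(2, 4, 5), (-60.0,))
        with pytest.warns(UserWarning, match="conditions for"):
            tauO_I, tauO_V, *_ = fit_time_constants(targets, cfg)
        sub = targets[targets.gate == "O"]
        m = _tau_model("O", np.r_[tauO_I, tauO_V], sub.irradiance_W_m2.to_numpy(),
                       sub.voltage_mV.to_numpy(), cfg)
        assert (np.abs(m - sub.tau) / sub.tau).max() < 0.02

    def test_constant_targets_fit_flat(self):
        cfg = FitConfig.test(seed=3, step2_starts=30)
        rows = [("O", I, V, 0.1) for I in (1e2, 1e3, 1e4) for V in (-60.0, 0.0)]
        rows += [("O", 0.0, V, 0.1) for V in (-60.0, 0.0)]
        rows += [("R", I, V, 5.0) for I in (1e2, 1e3, 1e4) for V in (-60.0, 0.0)]
        targets = pd.DataFrame(rows, columns=["gate", "irradiance_W_m2",
                                              "voltage_mV", "tau"])
        with pytest.warns(UserWarning):
            tauO_I, tauO_V, *_ = fit_time_constants(targets, cfg)
        sub = targets[targets.gate == "O"]
        m = _tau_model("O", np.r_[tauO_I, tauO_V], sub.irradiance_W_m2.to_numpy(),
                       sub.voltage_mV.to_numpy(), cfg)
        assert (np.abs(m - 0.1) / 0.1).max() < 0.05

    def test_seeded_determinism(self, rsrs_final):
        cfg = FitConfig.test(seed=9, step2_starts=20)
        targets = _tau_targets_from(rsrs_final, cfg, np.logspace(2, 4, 3), (-60.0, 0.0))
        a = fit_time_constants(targets, cfg)
        b = fit_time_constants(targets, FitConfig.test(seed=9, step2_starts=20))
        assert a == b


class TestMultistart:
    def test_lexicographic_tie_break(self):
        # two symmetric minima at +-1 with identical cost: the smaller wins
        resid = lambda x: np.atleast_1d(x[0] ** 2 - 1.0)
        rng = np.random.default_rng(0)
        best = _multistart_ls(resid, [-2.0], [2.0], [0.5], 40, rng)
        assert best.x[0] == pytest.approx(-1.0, abs=1e-8)


@pytest.fixture(scope="module")
def small_equilibria_problem(rsrs_final):
    """Noise-free current features on a reduced grid, true taus supplied."""
    cfg = FitConfig.test(seed=4, step3_starts=40)
    I = np.logspace(2, 4, 3)
    V = (-80.0, -40.0, 20.0)
    fs = FeatureSet()
    from opsinkit.model import _gating_on, driving_force
    t = np.arange(0.0, cfg.pulse_s + 1e-12, cfg.dt_single)
    for v in V:
        K = rsrs_final.g * float(driving_force(v, rsrs_final))
        for i in I:
            O, R = _gating_on(t, i, v, rsrs_final, 0.0, 1.0)
            cur = np.abs(K * O * R)
            fs.add(i, v, "I_peak", cur.max())
            fs.add(i, v, "I_ss", cur[-1])
            fs.add(i, v, "I_ratio", cur[-1] / cur.max())
    taus = (rsrs_final.tauO_I, rsrs_final.tauO_V,
            rsrs_final.tauR_I, rsrs_final.tauR_V)
    return cfg, taus, fs


class TestEquilibriaFit:
    def test_recovery_and_constraints(self, small_equilibria_problem, rsrs_final):
        cfg, taus, fs = small_equilibria_problem
        p = fit_equilibria(taus, fs, cfg)
        # recovered equilibria reproduce every current feature
        from opsinkit.model import _gating_on, driving_force, O_inf
        t = np.arange(0.0, cfg.pulse_s + 1e-12, cfg.dt_single)
        for I, V in fs.conditions("I_peak"):
            K = p.g * float(driving_force(V, p))
            O, R = _gating_on(t, I, V, p, 0.0, 1.0)
            cur = np.abs(K * O * R)
            assert cur.max() == pytest.approx(fs.get(I, V, "I_peak"), rel=0.02)
            assert cur[-1] == pytest.approx(fs.get(I, V, "I_ss"), rel=0.02)
        assert float(O_inf(5500.0, p)) > 0.6
        from opsinkit import check_decay_constraint
        ok, _ = check_decay_constraint(p, np.asarray([-80.0, -40.0, 20.0]),
                                       np.logspace(2, 4, 3))
        assert ok


@pytest.fixture(scope="module")
def tiny_refine_problem(rsrs_final):
    """Target features = the generating model's own extracted features, so
    the true parameter vector is a global optimum of the refinement cost."""
    cfg = FitConfig.test(seed=5, pso_particles=6, pso_budget_s=4.0, polish=False)
    conditions = FeatureSet()
    for I in (316.0, 3162.0):
        for V in (-60.0, -20.0):
            conditions.add(I, V, "I_peak", 1.0)   # marks which (I, V) to probe
    target = model_features(rsrs_final, conditions, cfg)
    return cfg, target


class TestGlobalRefine:
    def test_descent_from_perturbed_intermediate(self, tiny_refine_problem, rsrs_final):
        from opsinkit.fitting import _feature_cost
        cfg, features = tiny_refine_problem
        lb, ub = cfg.full_bounds()
        theta = cfg.vector_of(rsrs_final) * 1.05
        perturbed = cfg.params_of(np.clip(theta, lb, ub))
        cost_perturbed, _ = _feature_cost(
            model_features(perturbed, features, cfg), features, cfg.weights)
        final, info = global_refine_pso(perturbed, features, cfg)
        assert info["cost"] <= cost_perturbed + 1e-12

    def test_box_clipped_to_global_bounds(self, tiny_refine_problem, rsrs_final):
        cfg, features = tiny_refine_problem
        lb, ub = cfg.full_bounds()
        # push the intermediate onto a bound: the reduced box must stay inside
        theta = cfg.vector_of(rsrs_final)
        theta[20] = ub[20]                     # rectification gain at its cap
        at_bound = cfg.params_of(theta)
        final, info = global_refine_pso(at_bound, features, cfg)
        box_lb, box_ub = info["box"]
        assert np.all(box_lb >= lb - 1e-12) and np.all(box_ub <= ub + 1e-12)
        assert np.all(cfg.vector_of(final) >= lb - 1e-9)
        assert np.all(cfg.vector_of(final) <= ub + 1e-9)
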