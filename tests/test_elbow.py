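"""Forward torque map and static-optimization inverse."""

import numpy as np
import pytest
from scipy import optimize

from fatiguetl.anthropometry import ActuatorParams, ScaledElbowModel
from fatiguetl.elbow import (ActivationTrace, TorqueTarget, TorqueTrace,
                             build_target_profile, forward_torque,
                             solve_activation_matrix, solve_activations)


def make_model(ref_subject, flexor_caps):
    """7-actuator model whose flexor torque capacities are prescribed."""
    names = [("BIC_long", "BIC"), ("BIC_short", "BIC"), ("BRA", "BRA"),
             ("BRD", "BRD")]
    flexors = [ActuatorParams(n, g, fmax=c / 0.05, moment_arm=0.05)
               for (n, g), c in zip(names, flexor_caps)]
    extensors = [ActuatorParams(f"TRI_{k}", "TRI", 500.0, -0.02)
                 for k in ("long", "lat", "med")]
    return ScaledElbowModel(statics=ref_subject,
                            actuators=tuple(extensors + flexors))


class TestTargetProfile:
    def test_ramp_start_and_peak(self):
        prof = build_target_profile(TorqueTarget(peak=60.0), dt=0.1)
        assert prof.values[0] == pytest.approx(10.0)
        after_ramp = prof.values[prof.times >= 1.5]
        assert np.allclose(after_ramp, 60.0)

    def test_ramp_midpoint(self):
        prof = build_target_profile(TorqueTarget(peak=60.0), dt=0.05)
        i = np.argmin(np.abs(prof.times - 0.75))
        assert prof.values[i] == pytest.approx(35.0)

    def test_flat_profile_when_peak_equals_start(self):
        prof = build_target_profile(
            TorqueTarget(peak=10.0, ramp_start=10.0), dt=0.1)
        assert np.allclose(prof.values, 10.0)

    def test_duration_and_dt_validation(self):
        prof = build_target_profile(TorqueTarget(peak=40.0), dt=0.1)
        assert prof.times[-1] == pytest.approx(30.0)
        with pytest.raises(ValueError):
            build_target_profile(TorqueTarget(peak=40.0), dt=0.0)
        with pytest.raises(ValueError):
            TorqueTarget(peak=5.0)  # below the 10 Nm ramp start


class TestForwardTorque:
    def test_zero_activation_zero_torque(self, ref_model):
        times = np.linspace(0, 1, 11)
        act = ActivationTrace(times, np.zeros((11, 7)))
        assert np.allclose(forward_torque(ref_model, act).values, 0.0)

    def test_single_flexor_closed_form(self, ref_subject):
        model = make_model(ref_subject, [50.0, 0.001, 0.001, 0.001])
        times = np.linspace(0, 1, 5)
        a = np.zeros((5, 7))
        a[:, 3] = 0.5  # the 50 Nm-capacity flexor (fmax 1000 N, r 0.05 m)
        torque = forward_torque(model, ActivationTrace(times, a)).values
        assert np.allclose(torque, 25.0)

    def test_group_channels_broadcast(self, ref_model):
        times = np.linspace(0, 1, 4)
        act4 = ActivationTrace(times, np.full((4, 4), 0.3))
        act7 = ActivationTrace(times, np.full((4, 7), 0.3))
        t4 = forward_torque(ref_model, act4).values
        t7 = forward_torque(ref_model, act7).values
        assert np.allclose(t4, t7)

    def test_wrong_channel_count_rejected(self, ref_model):
        times = np.linspace(0, 1, 3)
        with pytest.raises(ValueError):
            forward_torque(ref_model, ActivationTrace(times, np.zeros((3, 5))))


class TestSolveActivations:
    def test_zero_target_zero_solution(self, ref_model):
        times = np.linspace(0, 1, 6)
        act, converged = solve_activations(
            ref_model, TorqueTrace(times, np.zeros(6)))
        assert converged
        assert np.allclose(act.values, 0.0)

    def test_two_flexor_least_norm_closed_form(self):
        a, feasible = solve_activation_matrix(np.array([50.0, 25.0]),
                                              np.array([25.0]))
        assert feasible.all()
        assert np.allclose(a[0], [0.4, 0.2])
        assert a[0] @ np.array([50.0, 25.0]) == pytest.approx(25.0)

    def test_infeasible_target_flagged(self, ref_subject):
        model = make_model(ref_subject, [30.0, 20.0, 15.0, 10.0])
        ceiling = model.strength_ceiling
        times = np.linspace(0, 1, 3)
        _, converged = solve_activations(
            model, TorqueTrace(times, np.full(3, 1.05 * ceiling)))
        assert not converged

    def test_inverse_forward_round_trip(self, ref_model):
        profile = build_target_profile(TorqueTarget(peak=40.0), dt=0.01)
        act, converged = solve_activations(ref_model, profile)
        assert converged
        torque = forward_torque(ref_model, act).values
        assert np.max(np.abs(torque - profile.values)) < 1e-6

    def test_matches_quadratic_programming_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            c = rng.uniform(5.0, 40.0, size=5)
            T = rng.uniform(0.1, 0.95) * c.sum()
            a, feasible = solve_activation_matrix(c, np.array([T]))
            assert feasible.all()
            res = optimize.minimize(
                lambda x: np.sum(x ** 2), np.full(5, 0.5),
                jac=lambda x: 2 * x, method="SLSQP",
                bounds=[(0, 1)] * 5,
                constraints={"type": "eq", "fun": lambda x: x @ c - T,
                             "jac": lambda x: c},
                options={"ftol": 1e-12, "maxiter": 200})
            assert res.success
            assert np.max(np.abs(a[0] - res.x)) < 2e-3

    def test_matches_two_flexor_grid_brute_force(self):
        c = np.array([30.0, 12.0])
        T = 20.0
        grid = np.arange(0.0, 1.0 + 1e-12, 1e-3)
        A1, A2 = np.meshgrid(grid, grid, indexing="ij")
        torque = A1 * c[0] + A2 * c[1]
        feas = np.abs(torque - T) <= 0.02  # one grid step of torque slack
        norm = np.where(feas, A1 ** 2 + A2 ** 2, np.inf)
        i, j = np.unravel_index(np.argmin(norm), norm.shape)
        a, _ = solve_activation_matrix(c, np.array([T]))
        assert abs(a[0, 0] - grid[i]) < 2e-3
        assert abs(a[0, 1] - grid[j]) < 2e-3

    def test_minimum_norm_against_random_perturbations(self, ref_model):
        times = np.array([0.0])
        target = TorqueTrace(times, np.array([45.0]))
        act, _ = solve_activations(ref_model, target)
        a = act.values[0]
        flex_idx = [i for i, m in enumerate(ref_model.actuators)
                    if m.group != "TRI"]
        c = np.array([ref_model.actuators[i].torque_capacity
                      for i in flex_idx])
        base = a[flex_idx]
        rng = np.random.default_rng(0)
        norm0 = np.sum(base ** 2)
        for _ in range(1000):
            d = rng.normal(0, 0.05, size=len(c))
            d -= (d @ c) / (c @ c) * c  # stay on the constraint plane
            cand = np.clip(base + d, 0.0, 1.0)
            if abs(cand @ c - 45.0) > 1e-9:
                continue
            assert np.sum(cand ** 2) >= norm0 - 1e-12

    def test_extensors_rest_at_coactivation_floor(self, ref_model):
        profile = build_target_profile(TorqueTarget(peak=50.0), dt=0.1)
        act, _ = solve_activations(ref_model, profile)
        tri_idx = [i for i, m in enumerate(ref_model.actuators)
                   if m.group == "TRI"]
        assert np.allclose(act.values[:, tri_idx], 0.0)
        act2, _ = solve_activations(ref_model, profile,
                                    coactivation_floor=0.05)
        assert np.allclose(act2.values[:, tri_idx], 0.05)
        torque = forward_torque(ref_model, act2).values
        assert np.max(np.abs(torque - profile.values)) < 1e-6

    def test_monotone_in_target(self, ref_model):
        times = np.array([0.0])
        lo, _ = solve_activations(ref_model, TorqueTrace(times, [30.0]))
        hi, _ = solve_activations(ref_model, TorqueTrace(times, [60.0]))
        assert np.all(hi.values >= lo.values - 1e-12)

    def test_negative_target_rejected(self, ref_model):
        with pytest.raises(ValueError):
            solve_activations(ref_model,
                              TorqueTrace(np.array([0.0]), [-1.0]))
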