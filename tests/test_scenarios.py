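"""End-to-end control scenarios: steady state = optimum, robust initial
conditions, flux reversal through equilibrium, sensed parameters, and the
documented sensor-choice failure mode."""

import warnings

import numpy as np
import pytest

import qorac
from qorac.optimum import ObjectiveSpec, minimize_objective, optimal_enzymes
from qorac.simulator import (EnvironmentSchedule, detect_steady_state,
                             distance_to_optimum, flux_reversal_run,
                             simulate)


def _true_optimum(fix, env):
    net = fix.network
    ext = {k: v for k, v in env.items() if k in net.species_index}
    par = {k: v for k, v in env.items() if k in net.adjustable_params}
    spec = ObjectiveSpec(net, fix.mode, ext, params=par or None)
    res = minimize_objective(spec)
    return res.x_opt, optimal_enzymes(spec, res.x_opt, "total_1")


def test_example1_steady_states_match_direct_optima(example1):
    """Three step changes in the external carbon source; each segment is
    long enough to equilibrate and its terminal state must coincide with
    the directly minimised optimum — steady state implies optimality."""
    sched = EnvironmentSchedule(
        [(0.0, {"x1": 3.0}), (200.0, {"x1": 1.2}), (400.0, {"x1": 6.0})],
        t_end=600.0)
    traj = simulate(example1.network, example1.mode,
                    example1.sensor_config, sched,
                    example1.init_x_I, example1.init_e)
    assert not traj.truncated
    flags = detect_steady_state(traj, window=5.0, tol=1e-6)
    assert all(f.steady for f in flags)
    for f in flags:
        env = sched.active_values(f.segment)
        x_opt, e_opt = _true_optimum(example1, env)
        assert np.abs(f.x_I - x_opt).max() < 1e-5
        assert np.abs(f.e - e_opt).max() < 1e-5


def test_example1_predicted_external_recovers_truth(example1):
    """After each step change the controller's estimate of the unseen
    carbon concentration converges to the scheduled true value."""
    sched = EnvironmentSchedule(
        [(0.0, {"x1": 3.0}), (250.0, {"x1": 1.2}), (500.0, {"x1": 6.0})],
        t_end=750.0)
    traj = simulate(example1.network, example1.mode,
                    example1.sensor_config, sched,
                    example1.init_x_I, example1.init_e)
    for k in range(3):
        i = np.where(traj.segment_index == k)[0][-1]
        true_C = sched.active_values(k)["x1"]
        assert abs(traj.xi_unknowns[i, 0] - true_C) < 1e-4


def test_example1_distance_decays_within_each_segment(example1):
    traj = simulate(example1.network, example1.mode,
                    example1.sensor_config, example1.schedule,
                    example1.init_x_I, example1.init_e)
    d = distance_to_optimum(traj)
    for k in sorted(set(traj.segment_index)):
        sel = np.where(traj.segment_index == k)[0]
        # monotone-ish decay: the terminal value is well below the level
        # just after the step change
        assert d[sel[-1]] < 0.1 * d[sel[2]] + 1e-12


def test_branched_steady_state_matches_optimum_after_each_change(branched):
    """Fig-5-style scenario: each external stepped once, four sensors; the
    re-equilibrated state matches the direct optimum."""
    sched = EnvironmentSchedule(
        [(0.0, {"x1": 4.0, "x2": 3.5, "x9": 0.4, "x10": 0.3}),
         (600.0, {"x1": 2.0}),
         (1200.0, {"x9": 0.8})],
        t_end=1800.0)
    traj = simulate(branched.network, branched.mode,
                    branched.sensor_config, sched,
                    branched.init_x_I, branched.init_e)
    assert not traj.truncated
    flags = detect_steady_state(traj, window=10.0, tol=1e-6)
    assert all(f.steady for f in flags)
    for f in flags:
        x_opt, e_opt = _true_optimum(branched, sched.active_values(f.segment))
        assert np.abs(f.x_I - x_opt).max() < 1e-5
        assert np.abs(f.e - e_opt).max() < 1e-5


def test_zero_enzyme_sensor_only_start_reaches_same_optimum(example1):
    """Extreme robustness: enzymes absent and every internal metabolite
    except the sensor absent; the pathway is still steered to the same
    steady state as a well-mixed start."""
    sched = EnvironmentSchedule([(0.0, {"x1": 3.0})], t_end=300.0)
    minimal = simulate(example1.network, example1.mode,
                       example1.sensor_config, sched,
                       np.array([0.5, 0.0, 0.0]), np.zeros(4))
    benign = simulate(example1.network, example1.mode,
                      example1.sensor_config, sched,
                      example1.init_x_I, example1.init_e)
    assert not minimal.truncated
    assert np.abs(minimal.x_I[-1] - benign.x_I[-1]).max() < 1e-5
    assert np.abs(minimal.e[-1] - benign.e[-1]).max() < 1e-5


class TestFluxReversal:
    def test_reversed_prediction_straightens_out(self, chain7):
        """Start adapted to backward flow on the seven-species chain; the
        predicted optimum passes through thermodynamic equilibrium and
        the run converges to the forward optimum without solver failure."""
        sched = EnvironmentSchedule([(0.0, {"x1": 4.0, "x7": 0.3})],
                                    t_end=1500.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            traj = flux_reversal_run(chain7, {"x2": 0.2, "x6": 2.0},
                                     schedule=sched)
        assert not traj.truncated
        x_opt, e_opt = _true_optimum(chain7, {"x1": 4.0, "x7": 0.3})
        assert np.abs(traj.x_I[-1] - x_opt).max() < 1e-5
        assert np.abs(traj.e[-1] - e_opt).max() < 1e-5
        # the initial prediction really is reversed
        assert traj.xi_unknowns[0, 0] < 0.3          # predicted source
        assert traj.xi_unknowns[0, 1] > 2.0          # predicted sink
        # predicted-optimum curves pass through a common near-equilibrium
        # point: somewhere along a densely sampled early stretch all
        # predicted rates are simultaneously tiny
        short = EnvironmentSchedule([(0.0, {"x1": 4.0, "x7": 0.3})],
                                    t_end=20.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dense = flux_reversal_run(chain7, {"x2": 0.2, "x6": 2.0},
                                      schedule=short, store_points=400)
        net = chain7.network
        min_over_t = np.inf
        for i in range(len(dense.times)):
            if not np.all(np.isfinite(dense.xi_I[i])):
                continue
            x = np.zeros(len(net.species))
            x[net.internal_indices] = dense.xi_I[i]
            x[net.species_index["x1"]] = dense.xi_unknowns[i, 0]
            x[net.species_index["x7"]] = dense.xi_unknowns[i, 1]
            f = net.rate_factors(x)
            min_over_t = min(min_over_t, np.abs(f).max())
        assert min_over_t < 0.05

    def test_fluxes_do_not_all_cross_zero(self, chain7):
        """Actual reaction fluxes need not pass through zero together:
        some reverse, others stay one-signed."""
        sched = EnvironmentSchedule([(0.0, {"x1": 4.0, "x7": 0.3})],
                                    t_end=600.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            traj = flux_reversal_run(chain7, {"x2": 0.2, "x6": 2.0},
                                     schedule=sched)
        flips = [(np.diff(np.sign(traj.v[:, j])) != 0).sum()
                 for j in range(chain7.network.n_reactions)]
        assert any(fl > 0 for fl in flips)
        assert any(fl == 0 for fl in flips)

    def test_already_correct_sensors_do_not_cross_equilibrium(self, chain7):
        """Control run: forward-adapted start, no equilibrium crossing."""
        sched = EnvironmentSchedule([(0.0, {"x1": 4.0, "x7": 0.3})],
                                    t_end=400.0)
        x_opt, e_opt = _true_optimum(chain7, {"x1": 4.0, "x7": 0.3})
        traj = simulate(chain7.network, chain7.mode, chain7.sensor_config,
                        sched, chain7.init_x_I, chain7.init_e)
        assert not traj.truncated
        assert np.all(traj.v > 0)   # flux stays forward throughout


class TestSensedParameter:
    def test_predicted_km_converges_to_scheduled_truth(self, km_valid):
        sched = EnvironmentSchedule(
            [(0.0, {"x1": 4.0, "x6": 0.3, "K3": 2.0}),
             (400.0, {"x1": 2.0}),
             (800.0, {"K3": 5.0})],
            t_end=1600.0)
        traj = simulate(km_valid.network, km_valid.mode,
                        km_valid.sensor_config, sched,
                        km_valid.init_x_I, km_valid.init_e)
        assert not traj.truncated
        ik3 = list(km_valid.sensor_config.unknowns).index("K3")
        for k in range(3):
            i = np.where(traj.segment_index == k)[0][-1]
            true_K3 = sched.active_values(k)["K3"]
            assert abs(traj.xi_unknowns[i, ik3] - true_K3) < 1e-4

    def test_swapped_sensors_terminate_with_ift_diagnostic(self, km_invalid):
        """The pathological sensor choice does not silently mis-steer: the
        run is truncated at the singularity with the diagnostic attached."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            traj = simulate(km_invalid.network, km_invalid.mode,
                            km_invalid.sensor_config, km_invalid.schedule,
                            km_invalid.init_x_I, km_invalid.init_e)
        assert traj.truncated
        assert "implicit-function-theorem" in (traj.failure or "")
        events = [ev for ev in traj.event_log
                  if ev["event"] == "controller_failure"]
        assert events and events[0]["error"] == "IFTViolationError"
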