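"""The qORAC control law: predicted optimum, synthesis rates, diagnostics."""

from fractions import Fraction

import numpy as np
import pytest

import qorac
from qorac.controller import (ControllerSystem, SensorConfig,
                              PredictedOptimum, check_sensor_validity,
                              io_relation, predicted_optimum,
                              synthesis_rates)
from qorac.efm import FluxMode
from qorac.network import MetabolicNetwork, RateLaw, Species
from qorac.optimum import ObjectiveSpec, minimize_objective


def _sensor_coords(fix, x_opt):
    idx = [fix.network.internal_names.index(s)
           for s in fix.sensor_config.sensors]
    return np.asarray(x_opt)[idx]


class TestPredictedOptimum:
    @pytest.mark.parametrize("C", [3.0, 1.2, 6.0])
    def test_roundtrip_identity_example1(self, example1, C):
        """The defining property: the optimum's own sensor values predict
        the optimum — internals and the unknown external alike."""
        spec = ObjectiveSpec(example1.network, example1.mode, {"x1": C})
        res = minimize_objective(spec)
        xi = predicted_optimum(example1.network, example1.mode,
                               example1.sensor_config,
                               _sensor_coords(example1, res.x_opt))
        assert xi.converged and xi.residual_norm < 1e-9
        assert xi.xi_unknowns["x1"] == pytest.approx(C, abs=1e-6)
        assert np.abs(xi.xi_I - res.x_opt).max() < 1e-6

    def test_roundtrip_identity_branched(self, branched):
        env = branched.schedule.active_values(0)
        ext = {k: v for k, v in env.items()
               if k in branched.network.species_index}
        spec = ObjectiveSpec(branched.network, branched.mode, ext)
        res = minimize_objective(spec)
        xi = predicted_optimum(branched.network, branched.mode,
                               branched.sensor_config,
                               _sensor_coords(branched, res.x_opt))
        for name, true_val in ext.items():
            assert xi.xi_unknowns[name] == pytest.approx(true_val,
                                                         abs=1e-6)
        assert np.abs(xi.xi_I - res.x_opt).max() < 1e-6

    def test_roundtrip_recovers_kinetic_parameter(self, km_valid):
        """An unknown Michaelis constant is estimated exactly like an
        unknown external concentration."""
        net, mode, cfg = km_valid.network, km_valid.mode, \
            km_valid.sensor_config
        for K3 in (2.0, 5.0):
            spec = ObjectiveSpec(net, mode, {"x1": 4.0, "x6": 0.3},
                                 params={"K3": K3})
            res = minimize_objective(spec)
            xi = predicted_optimum(net, mode, cfg,
                                   _sensor_coords(km_valid, res.x_opt))
            assert xi.xi_unknowns["K3"] == pytest.approx(K3, abs=1e-6)
            assert xi.xi_unknowns["x1"] == pytest.approx(4.0, abs=1e-6)

    def test_example1_system_is_three_by_three(self, example1):
        sys_ = ControllerSystem(example1.network, example1.mode,
                                example1.sensor_config)
        # three optimality equations (one per internal metabolite) in the
        # two non-sensor internals plus the one unknown external
        assert len(sys_.internal_syms) == 3
        assert len(sys_.solve_syms) == 3
        assert sys_.free_internal_names == ["x3", "x4"]
        assert [str(s) for s in sys_.unknown_syms] == ["x1"]

    def test_sensor_pinning_is_exact(self, example1):
        xi = predicted_optimum(example1.network, example1.mode,
                               example1.sensor_config, [1.2345])
        i = example1.network.internal_names.index("x2")
        assert xi.xi_I[i] == 1.2345

    def test_warm_start_fixed_point(self, example1):
        cfg = example1.sensor_config
        xi = predicted_optimum(example1.network, example1.mode, cfg, [1.5])
        for _ in range(3):
            xi2 = predicted_optimum(example1.network, example1.mode, cfg,
                                    [1.5], warm_start=xi)
            assert np.abs(xi2.xi_I - xi.xi_I).max() < 1e-12
            assert xi2.xi_unknowns["x1"] == pytest.approx(
                xi.xi_unknowns["x1"], abs=1e-12)
            xi = xi2

    def test_nonsquare_config_rejected(self, example1):
        cfg = SensorConfig(["x2", "x3"], ["x1"])
        with pytest.raises(qorac.ModelError, match="square"):
            predicted_optimum(example1.network, example1.mode, cfg,
                              [1.0, 1.0])

    def test_nonpositive_sensor_rejected(self, example1):
        with pytest.raises(qorac.ModelError):
            predicted_optimum(example1.network, example1.mode,
                              example1.sensor_config, [0.0])


class TestSynthesisRates:
    def _xi(self, net, x_I, unknowns, knowns):
        return PredictedOptimum(
            xi_I=np.asarray(x_I, dtype=float), xi_unknowns=dict(unknowns),
            known_inputs=dict(knowns), residual_norm=0.0,
            jacobian_condition=1.0, converged=True)

    def test_sum_equals_mu(self, example1):
        xi = predicted_optimum(example1.network, example1.mode,
                               example1.sensor_config, [1.5])
        for mu in (1.0, 0.3, 2.7):
            E = synthesis_rates(example1.network, example1.mode, xi, mu)
            assert E.sum() == pytest.approx(mu, abs=1e-12 * max(1, mu))
            assert np.all(E >= 0)

    def test_equal_rates_split_by_mode_coefficients(self):
        net = MetabolicNetwork(
            [Species("m", "internal")],
            [RateLaw("r1", "2.0 + 0*m"), RateLaw("r2", "2.0 + 0*m")],
            {"r1": {"m": 1}, "r2": {"m": -2}})
        mode = FluxMode((Fraction(2), Fraction(1)), output_reaction=1)
        xi = self._xi(net, [1.0], {}, {})
        E = synthesis_rates(net, mode, xi, mu=1.0)
        # all f equal: E_j = mu V_j / sum V
        assert E == pytest.approx([2 / 3, 1 / 3], rel=1e-14)

    def test_vanishing_rate_concentrates_synthesis(self, example1):
        """As one f_j -> 0+ that reaction's synthesis share -> mu and all
        others -> 0 (checked along a shrinking sequence; the guarded
        product form stays finite at f_j = 0 exactly)."""
        net, mode = example1.network, example1.mode
        prev_share = 0.0
        for eps in (1e-2, 1e-4, 1e-6, 1e-8):
            x4 = 0.0025 + eps * 1.0025 / (1 - 0.33 * 0.0)  # f4 ~ eps
            xi = self._xi(net, [1.0, 1.0, x4], {"x1": 3.0}, {})
            E = synthesis_rates(net, mode, xi, 1.0)
            assert E[3] > prev_share
            prev_share = E[3]
        assert prev_share > 0.999
        xi = self._xi(net, [1.0, 1.0, 0.0025], {"x1": 3.0}, {})
        E = synthesis_rates(net, mode, xi, 1.0)
        assert E == pytest.approx([0, 0, 0, 1.0], abs=1e-12)

    def test_reversed_flow_keeps_rates_positive(self, chain7):
        """With every specific rate negative (reversed flow) the ratio of
        negatives keeps all synthesis rates positive."""
        net, mode, cfg = chain7.network, chain7.mode, chain7.sensor_config
        xi = predicted_optimum(net, mode, cfg, [0.2, 2.0])
        assert xi.orientation == -1
        E = synthesis_rates(net, mode, xi, 1.0)
        assert np.all(E > 0)
        assert E.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unconverged_prediction_rejected(self, example1):
        xi = self._xi(example1.network, [1, 1, 1], {"x1": 3.0}, {})
        xi.converged = False
        with pytest.raises(qorac.ControllerSolverError):
            synthesis_rates(example1.network, example1.mode, xi, 1.0)


class TestSensorValidity:
    def test_counting_rule_violation_reported(self, example1):
        cfg = SensorConfig(["x2", "x3"], ["x1"])
        rep = check_sensor_validity(example1.network, example1.mode, cfg)
        assert not rep.ok
        assert any("sensor count" in r for r in rep.reasons)

    def test_example1_passes_at_operating_points(self, example1):
        net, mode, cfg = example1.network, example1.mode, \
            example1.sensor_config
        probes = []
        for C in (3.0, 1.2, 6.0):
            spec = ObjectiveSpec(net, mode, {"x1": C})
            res = minimize_objective(spec)
            probe = dict(zip(net.internal_names, res.x_opt))
            probe["x1"] = C
            probes.append(probe)
        rep = check_sensor_validity(net, mode, cfg, probes)
        assert rep.ok
        assert (rep.records["condition_number"] < 1e3).all()

    def test_swapped_sensor_set_passes_static_but_fails_dynamic(
            self, km_invalid):
        """The pathological sensor choice is combinatorially fine (square
        system, nonsingular at the initial state); its failure is only
        dynamical — covered by the simulator scenario tests."""
        net, mode, cfg = km_invalid.network, km_invalid.mode, \
            km_invalid.sensor_config
        probe = dict(zip(net.internal_names, km_invalid.init_x_I))
        probe.update({"x1": 4.0, "K3": 2.0})
        rep = check_sensor_validity(net, mode, cfg, [probe])
        assert rep.ok


class TestIORelation:
    def test_grid_rows_sum_to_mu_and_order_preserved(self, example1):
        net, mode, cfg = example1.network, example1.mode, \
            example1.sensor_config
        grid = [[v] for v in np.linspace(0.8, 2.4, 9)]
        table = io_relation(net, mode, cfg, grid, mu=1.0)
        assert list(table["x2"]) == [g[0] for g in grid]
        rates = table[[r for r in net.reaction_ids]].to_numpy()
        assert np.allclose(rates.sum(axis=1), 1.0, atol=1e-10)
        # smooth: no jumps between adjacent grid points
        assert np.abs(np.diff(rates, axis=0)).max() < 0.2

    def test_single_point_equals_direct_synthesis(self, example1):
        net, mode, cfg = example1.network, example1.mode, \
            example1.sensor_config
        table = io_relation(net, mode, cfg, [[1.5]], mu=1.0)
        xi = predicted_optimum(net, mode, cfg, [1.5])
        E = synthesis_rates(net, mode, xi, 1.0)
        assert table.iloc[0][list(net.reaction_ids)].to_numpy() == \
            pytest.approx(E, rel=1e-9)

    def test_reversed_grid_gives_reversed_table(self, example1):
        net, mode, cfg = example1.network, example1.mode, \
            example1.sensor_config
        grid = [[v] for v in np.linspace(1.0, 2.0, 5)]
        fwd = io_relation(net, mode, cfg, grid, mu=1.0)
        rev = io_relation(net, mode, cfg, grid[::-1], mu=1.0)
        assert np.allclose(fwd.to_numpy()[::-1], rev.to_numpy(),
                           atol=1e-9)
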