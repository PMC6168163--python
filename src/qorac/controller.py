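"""The qORAC control law.

From the current sensor concentrations alone the controller solves the
*sensor-pinned optimality system*

    xi_S = x_S,          dO/dxi_i = 0   for every internal metabolite i,

for all remaining internal concentrations *and* the unknown quantities
(external concentrations and/or kinetic parameters).  The solution
xi(x_S) — "the optimum as predicted by the sensors" — is well defined
wherever the Implicit Function Theorem holds, i.e. the Jacobian of the
system with respect to the solved-for variables is nonsingular.  A direct
consequence is the counting rule: the number of sensors must equal the
number of unknowns for the system to be square.

The controller then emits enzyme synthesis rates

    E_j(x_S) = mu * (V_j / f_j(xi)) / sum_l (V_l / f_l(xi)),

normalised so that sum_j E_j = mu, which pins the steady-state total enzyme
concentration at 1 and keeps every E_j positive whichever direction the
pathway runs.  Near thermodynamic equilibrium (all f_j -> 0) the ratio is
evaluated in a product form that never divides by a vanishing rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import sympy as sp

from .efm import FluxMode
from .errors import (ControllerSolverError, DegenerateStateError,
                     IFTViolationError, ModelError)
from .network import MetabolicNetwork

__all__ = ["SensorConfig", "PredictedOptimum", "predicted_optimum",
           "synthesis_rates", "check_sensor_validity", "io_relation",
           "SensorValidityReport", "ControllerSystem",
           "COND_WARN_CEILING", "COND_FAIL_CEILING"]

#: condition-number ceilings for the optimality-system Jacobian; crossing
#: the fail ceiling raises IFTViolationError, the warn ceiling only warns
COND_WARN_CEILING = 1e8
COND_FAIL_CEILING = 1e12


@dataclass(frozen=True)
class SensorConfig:
    """Which internal metabolites are sensed, and which quantities the
    controller must estimate from them.

    ``unknowns`` entries are external species names or adjustable kinetic
    parameter names; ``known_externals`` holds externals treated as fixed
    and known to the controller.  A well-posed configuration has exactly as
    many sensors as unknowns (the counting rule) — deliberately *not*
    enforced at construction so that :func:`check_sensor_validity` can
    report the violation.
    """

    sensors: tuple[str, ...]
    unknowns: tuple[str, ...]
    known_externals: Mapping[str, float] = field(default_factory=dict)

    def __init__(self, sensors: Sequence[str], unknowns: Sequence[str],
                 known_externals: Mapping[str, float] | None = None):
        object.__setattr__(self, "sensors", tuple(sensors))
        object.__setattr__(self, "unknowns", tuple(unknowns))
        object.__setattr__(self, "known_externals",
                           dict(known_externals or {}))
        if set(self.unknowns) & set(self.known_externals):
            raise ModelError("an unknown cannot also be a known external")

    @property
    def is_square(self) -> bool:
        return len(self.sensors) == len(self.unknowns)


@dataclass
class PredictedOptimum:
    """Solution of the sensor-pinned optimality system.

    ``xi_I`` is indexed like the network's internal species (sensor
    coordinates coincide with the sensed values by construction);
    ``xi_unknowns`` maps each unknown name to its predicted value.
    """

    xi_I: np.ndarray
    xi_unknowns: dict[str, float]
    known_inputs: dict[str, float]
    residual_norm: float
    jacobian_condition: float
    converged: bool
    n_iter: int = 0
    #: +1 all supported rates run with the mode, -1 all against (reversed
    #: flow), 0 mixed (only transiently, at the equilibrium crossing)
    orientation: int = 0

    def full_concentrations(self, net: MetabolicNetwork) -> np.ndarray:
        """Full species vector at the predicted optimum (externals from the
        predicted unknowns where estimated, otherwise from known inputs)."""
        x = np.zeros(len(net.species))
        x[net.internal_indices] = self.xi_I
        for n in net.external_names:
            if n in self.xi_unknowns:
                x[net.species_index[n]] = self.xi_unknowns[n]
            elif n in self.known_inputs:
                x[net.species_index[n]] = self.known_inputs[n]
            else:
                raise ModelError(f"no value for external {n!r}")
        return x

    def params(self, net: MetabolicNetwork) -> dict[str, float]:
        p = dict(net.adjustable_params)
        p.update({k: v for k, v in self.known_inputs.items() if k in p})
        p.update({k: v for k, v in self.xi_unknowns.items() if k in p})
        return p


class ControllerSystem:
    """Cached symbolic assembly of the optimality system for one
    (network, mode, sensor-config) triple."""

    def __init__(self, net: MetabolicNetwork, mode: FluxMode,
                 cfg: SensorConfig):
        self.net, self.mode, self.cfg = net, mode, cfg
        for s in cfg.sensors:
            if s not in net.internal_names:
                raise ModelError(f"sensor {s!r} is not an internal species")
        for u in cfg.unknowns:
            if u not in net.external_names and u not in net.adjustable_params:
                raise ModelError(f"unknown {u!r} is neither an external "
                                 "species nor an adjustable parameter")
        if not cfg.is_square:
            raise ModelError(
                f"sensor count {len(cfg.sensors)} != unknown count "
                f"{len(cfg.unknowns)}: the optimality system is not square")

        sym = {n: s for n, s in zip(net.species_names, net.species_symbols)}
        sym.update({n: s for n, s in
                    zip(net.adjustable_params, net.param_symbols)})

        self.internal_syms = [sym[n] for n in net.internal_names]
        self.sensor_syms = [sym[n] for n in cfg.sensors]
        self.free_internal_names = [n for n in net.internal_names
                                    if n not in cfg.sensors]
        self.free_internal_syms = [sym[n] for n in self.free_internal_names]
        self.unknown_syms = [sym[n] for n in cfg.unknowns]
        self.known_names = ([n for n in net.external_names
                             if n not in cfg.unknowns] +
                            [n for n in net.adjustable_params
                             if n not in cfg.unknowns])
        self.known_syms = [sym[n] for n in self.known_names]
        self.solve_syms = self.free_internal_syms + self.unknown_syms

        support = sorted(mode.support)
        self.support = support
        self.V_support = np.array([float(mode.V[j]) for j in support])
        f_sup = [net.f_exprs[j] for j in support]
        O = sum(sp.Rational(mode.V[j].numerator, mode.V[j].denominator) / f
                for j, f in zip(support, f_sup))
        F = [sp.diff(O, s) for s in self.internal_syms]
        J = sp.Matrix(F).jacobian(self.solve_syms)

        args = self.solve_syms + self.sensor_syms + self.known_syms
        self._F_fn = sp.lambdify(args, F, modules="numpy")
        self._J_fn = sp.lambdify(args, J, modules="numpy")
        self._fsup_fn = sp.lambdify(args, f_sup, modules="numpy")
        self._fsupJ_fn = sp.lambdify(
            args, sp.Matrix(f_sup).jacobian(self.solve_syms),
            modules="numpy")
        self._O_fn = sp.lambdify(args, O, modules="numpy")
        # row indices of the optimality equations belonging to the free
        # (non-sensor) internals, used by the cold-start inner minimisation
        self.free_eq_rows = np.array(
            [i for i, n in enumerate(net.internal_names)
             if n not in cfg.sensors], dtype=int)

    # -- argument plumbing ---------------------------------------------------

    def known_values(self, known_inputs: Mapping[str, float] | None) -> list[float]:
        merged = dict(self.cfg.known_externals)
        merged.update({n: self.net.adjustable_params[n]
                       for n in self.net.adjustable_params
                       if n not in self.cfg.unknowns})
        if known_inputs:
            merged.update({k: v for k, v in known_inputs.items()
                           if k in self.known_names})
        missing = [n for n in self.known_names if n not in merged]
        if missing:
            raise ModelError(f"no value supplied for known inputs {missing}")
        return [float(merged[n]) for n in self.known_names]

    def default_guess(self) -> np.ndarray:
        g = np.ones(len(self.solve_syms))
        for k, u in enumerate(self.cfg.unknowns):
            if u in self.net.adjustable_params:
                g[len(self.free_internal_syms) + k] = \
                    self.net.adjustable_params[u]
        return g

    def pack_result(self, u: np.ndarray, x_S, knowns: list[float],
                    residual: float, cond: float, converged: bool,
                    n_iter: int) -> PredictedOptimum:
        xi_I = np.empty(len(self.net.internal_names))
        free = {n: u[i] for i, n in enumerate(self.free_internal_names)}
        sens = {n: v for n, v in zip(self.cfg.sensors, x_S)}
        for i, n in enumerate(self.net.internal_names):
            xi_I[i] = sens[n] if n in sens else free[n]
        n_free = len(self.free_internal_names)
        return PredictedOptimum(
            xi_I=xi_I,
            xi_unknowns={n: float(u[n_free + k])
                         for k, n in enumerate(self.cfg.unknowns)},
            known_inputs=dict(zip(self.known_names, knowns)),
            residual_norm=residual, jacobian_condition=cond,
            converged=converged, n_iter=n_iter,
            orientation=self.orientation_of(u, x_S, knowns))

    def orientation_of(self, u, x_S, knowns) -> int:
        with np.errstate(all="ignore"):
            fs = self.f_support_at(u, x_S, knowns)
        s = fs * self.V_support
        if np.all(s > 0):
            return 1
        if np.all(s < 0):
            return -1
        return 0

    def unpack_guess(self, warm: PredictedOptimum) -> np.ndarray:
        idx = {n: i for i, n in enumerate(self.net.internal_names)}
        u = [warm.xi_I[idx[n]] for n in self.free_internal_names]
        u += [warm.xi_unknowns[n] for n in self.cfg.unknowns]
        return np.array(u, dtype=float)

    def residual(self, u, x_S, knowns):
        return np.array(self._F_fn(*u, *x_S, *knowns), dtype=float)

    def jacobian(self, u, x_S, knowns):
        return np.array(self._J_fn(*u, *x_S, *knowns), dtype=float)

    def f_support_at(self, u, x_S, knowns):
        return np.array(self._fsup_fn(*u, *x_S, *knowns), dtype=float)


_SYSTEM_CACHE: dict[tuple[int, int, SensorConfig], ControllerSystem] = {}


def _get_system(net, mode, cfg) -> ControllerSystem:
    key = (id(net), id(mode), cfg.sensors, cfg.unknowns,
           tuple(sorted(cfg.known_externals.items())))
    sys_ = _SYSTEM_CACHE.get(key)
    if sys_ is None:
        sys_ = ControllerSystem(net, mode, cfg)
        _SYSTEM_CACHE[key] = sys_
    return sys_


def _newton(sys_: ControllerSystem, u0: np.ndarray, x_S, knowns,
            tol: float, max_iter: int):
    """Damped Newton on the optimality system; returns (u, residual,
    condition, iterations) or raises IFTViolationError /
    ControllerSolverError.

    Convergence demands the residual infinity-norm below ``tol``, relaxed
    only by the floating-point noise floor |J|·|u|·eps of the evaluated
    system — the relaxation matters solely near thermodynamic equilibrium,
    where the optimality equations blow up like 1/f^3 while their root
    stays smooth.
    """
    u = np.array(u0, dtype=float)
    with np.errstate(all="ignore"):
        for it in range(1, max_iter + 1):
            F = sys_.residual(u, x_S, knowns)
            if not np.all(np.isfinite(F)):
                raise ControllerSolverError(
                    "optimality residual not finite at the current iterate "
                    "(a rate law hit a pole or zero rate)")
            J = sys_.jacobian(u, x_S, knowns)
            if not np.all(np.isfinite(J)):
                raise ControllerSolverError("optimality Jacobian not finite")
            noise = np.abs(J) @ np.abs(u) * 1e-14
            if np.all(np.abs(F) <= tol + noise):
                return u, float(np.linalg.norm(F, np.inf)), \
                    float(np.linalg.cond(J)), it
            try:
                step = np.linalg.solve(J, -F)
            except np.linalg.LinAlgError:
                raise IFTViolationError(float(np.linalg.cond(J))) from None
            # damped update: keep all concentrations/parameters positive,
            # shrink until the residual (noise-scaled) decreases
            base = float(np.max(np.abs(F) / (1.0 + noise)))
            t = 1.0
            accepted = False
            for _ in range(50):
                u_new = u + t * step
                if np.all(u_new > 0):
                    F_new = sys_.residual(u_new, x_S, knowns)
                    if np.all(np.isfinite(F_new)) and \
                            float(np.max(np.abs(F_new) / (1.0 + noise))) \
                            < base * (1 - 1e-4 * t) + 1e-300:
                        accepted = True
                        break
                t *= 0.5
            if not accepted:
                # last resort: tiny positive step to escape a plateau
                u_new = u + t * step
                if not np.all(u_new > 0):
                    cond = float(np.linalg.cond(J))
                    if cond > COND_FAIL_CEILING:
                        raise IFTViolationError(cond)
                    raise ControllerSolverError(
                        "Newton step could not keep the predicted state "
                        "positive")
            u = u_new
    cond = float(np.linalg.cond(J))
    if cond > COND_FAIL_CEILING:
        raise IFTViolationError(cond)
    raise ControllerSolverError(
        f"predicted-optimum Newton iteration did not converge in "
        f"{max_iter} steps (residual {np.linalg.norm(F, np.inf):.3e}, "
        f"Jacobian condition {cond:.3e})")


#: absolute specific-rate magnitude below which the predicted optimum is
#: treated as being at the thermodynamic-equilibrium crossing
_EQUILIBRIUM_F_CEILING = 0.1


def _equilibrium_hop(sys_: ControllerSystem, u_warm, x_S, knowns,
                     tol: float, max_iter: int):
    """Carry the predicted optimum across thermodynamic equilibrium.

    During flux reversal the solution path of the optimality system passes
    smoothly through the point where every supported rate vanishes, but the
    equations themselves blow up like 1/f^3 there and plain Newton
    stagnates.  This routine locates the nearby all-rates-zero state by
    Gauss-Newton on f(xi) = 0, reflects the stranded iterate through it in
    log coordinates, and restarts Newton on the far side of the crossing.
    """
    u_eq = np.array(u_warm, dtype=float)
    with np.errstate(all="ignore"):
        for _ in range(40):
            fs = sys_.f_support_at(u_eq, x_S, knowns)
            if not np.all(np.isfinite(fs)):
                raise ControllerSolverError("rates not finite during the "
                                            "equilibrium search")
            if np.max(np.abs(fs)) < 1e-12:
                break
            Jf = np.asarray(sys_._fsupJ_fn(*u_eq, *x_S, *knowns),
                            dtype=float)
            step, *_ = np.linalg.lstsq(Jf, -fs, rcond=None)
            t = 1.0
            while t > 1e-8 and np.any(u_eq + t * step <= 0):
                t *= 0.5
            if t <= 1e-8:
                break
            u_eq = u_eq + t * step
    # point reflection through the crossing, in log coordinates so the
    # reflected guess stays positive; widen the reflection if Newton falls
    # straight back into the singular neighbourhood
    log_eq = np.log(u_eq)
    log_warm = np.log(np.maximum(u_warm, 1e-300))
    last_exc: Exception | None = None
    for alpha in (1.0, 2.0, 4.0, 0.5):
        u0 = np.exp(log_eq + alpha * (log_eq - log_warm))
        try:
            u, res, cond, it = _newton(sys_, u0, x_S, knowns, tol, max_iter)
        except (ControllerSolverError, IFTViolationError) as exc:
            last_exc = exc
            continue
        if sys_.orientation_of(u, x_S, knowns) != 0:
            return u, res, cond, it
    if last_exc is not None:
        raise last_exc
    raise ControllerSolverError(
        "equilibrium traversal found only mixed-sign roots")


def _sign_consistent(sys_: ControllerSystem, u, x_S, knowns) -> bool:
    """True when every supported rate runs with (or every rate against)
    its mode direction at the predicted state — the physically meaningful
    branch of the optimality system.  Mixed-sign roots are spurious
    critical points outside the objective's feasible domain."""
    fs = sys_.f_support_at(u, x_S, knowns)
    s = fs * sys_.V_support
    return bool(np.all(s > 0) or np.all(s < 0))


def _inner_feasible_free(sys_: ControllerSystem, theta, x_S, knowns,
                         rng, orientation: int = 1) -> np.ndarray | None:
    """A free-internal vector making every supported rate run with
    (orientation=+1) or against (-1) the mode direction, for fixed
    unknowns ``theta`` (None if not found)."""
    n_free = len(sys_.free_internal_names)
    if n_free == 0:
        u = np.array(theta, dtype=float)
        fs = sys_.f_support_at(u, x_S, knowns)
        ok = np.all(orientation * fs * sys_.V_support > 0)
        return np.empty(0) if ok else None
    cands = [np.full(n_free, s) for s in (1.0, 0.3, 0.1, 3.0, 0.03, 0.01)]
    # log-interpolated profiles spanning the sensed range (and reversed),
    # which seed monotone chains whose feasible cones are narrow
    x_S = np.asarray(x_S, dtype=float)
    lo, hi = float(np.min(x_S)), float(np.max(x_S))
    ramp = np.exp(np.linspace(np.log(max(lo, 1e-6)),
                              np.log(max(hi, 1e-6)), n_free + 2))[1:-1]
    for scale in (1.0, 0.5, 2.0):
        cands.append(scale * ramp)
        cands.append(scale * ramp[::-1])
    cands += [np.exp(rng.uniform(np.log(1e-4), np.log(30.0), n_free))
              for _ in range(60)]
    for xf in cands:
        u = np.concatenate([xf, theta])
        with np.errstate(all="ignore"):
            fs = sys_.f_support_at(u, x_S, knowns)
        if np.all(np.isfinite(fs)) and \
                np.all(orientation * fs * sys_.V_support > 0):
            return xf
    return None


def _inner_minimize(sys_: ControllerSystem, xf0, theta, x_S, knowns,
                    orientation: int = 1, max_iter: int = 80) -> np.ndarray:
    """For fixed unknowns, minimise the objective over the free internals
    with sensors pinned — a strictly convex sub-problem whose solution
    seeds the full Newton solve on the correct branch.  For the reversed
    orientation the enzyme cost of the opposite mode (-V) is minimised,
    which has the same critical points."""
    n_free = len(xf0)
    if n_free == 0:
        return np.asarray(xf0, dtype=float)
    rows = sys_.free_eq_rows
    xf = np.array(xf0, dtype=float)
    theta = np.asarray(theta, dtype=float)

    def Oval(xf_):
        with np.errstate(all="ignore"):
            u = np.concatenate([xf_, theta])
            fs = sys_.f_support_at(u, x_S, knowns)
            if not (np.all(np.isfinite(fs))
                    and np.all(orientation * fs * sys_.V_support > 0)):
                return np.inf
            return orientation * float(sys_._O_fn(*u, *x_S, *knowns))

    with np.errstate(all="ignore"):
        for _ in range(max_iter):
            u = np.concatenate([xf, theta])
            F = sys_.residual(u, x_S, knowns)[rows]
            if not np.all(np.isfinite(F)) or np.max(np.abs(F)) < 1e-11:
                break
            J = sys_.jacobian(u, x_S, knowns)[np.ix_(rows, range(n_free))]
            try:
                step = np.linalg.solve(J, -F)
            except np.linalg.LinAlgError:
                step = -F
            base = Oval(xf)
            t = 1.0
            for _ in range(40):
                xf_new = xf + t * step
                if np.all(xf_new > 0) and Oval(xf_new) <= base + 1e-14:
                    break
                t *= 0.5
            else:
                break
            if np.max(np.abs(t * step)) < 1e-14 * max(1.0, np.max(np.abs(xf))):
                xf = xf_new
                break
            xf = xf_new
    return xf


def _cold_start_solve(sys_: ControllerSystem, x_S, knowns, tol, max_iter):
    """Without a warm start: guess the unknowns, solve the sensor-pinned
    inner minimisation over the free internals (convex, hence
    branch-selecting), then run the full Newton iteration; retry with
    fresh deterministic pseudo-random unknown guesses until the root is
    sign-consistent."""
    from itertools import product

    rng = np.random.default_rng(12345)
    n_free = len(sys_.free_internal_names)
    n_unk = len(sys_.cfg.unknowns)
    last_exc = None
    fallback_root = None

    # deterministic grid of unknown guesses scaled by the sensor magnitude,
    # then wide random draws; the grid makes sparse corners (e.g. one tiny
    # external and one large, as during flow reversal) reachable
    s_scale = float(np.exp(np.mean(np.log(np.asarray(x_S, dtype=float)))))
    grid_axes = []
    for name in sys_.cfg.unknowns:
        if name in sys_.net.adjustable_params:
            d = sys_.net.adjustable_params[name]
            grid_axes.append([d, 0.5 * d, 2.0 * d])
        else:
            grid_axes.append([s_scale, 0.1 * s_scale, 10.0 * s_scale])
    grid = list(product(*grid_axes)) if n_unk <= 4 else []

    def theta_guess(trial):
        if trial < len(grid):
            return np.array(grid[trial], dtype=float)
        th = np.empty(n_unk)
        for k, name in enumerate(sys_.cfg.unknowns):
            if name in sys_.net.adjustable_params:
                d = sys_.net.adjustable_params[name]
                th[k] = d * np.exp(rng.uniform(np.log(0.2), np.log(5.0)))
            else:
                th[k] = s_scale * np.exp(rng.uniform(np.log(0.01),
                                                     np.log(100.0)))
        return th

    n_trials = max(60, len(grid) + 40)
    for orientation in (1, -1):  # forward branch preferred
        for trial in range(n_trials):
            theta = theta_guess(trial)
            xf = _inner_feasible_free(sys_, theta, x_S, knowns, rng,
                                      orientation)
            if xf is None:
                if trial > 0:
                    continue
                u0 = np.concatenate([np.ones(n_free), theta])
            else:
                xf = _inner_minimize(sys_, xf, theta, x_S, knowns,
                                     orientation)
                u0 = np.concatenate([xf, theta])
            try:
                u, res, cond, it = _newton(sys_, u0, x_S, knowns, tol,
                                           max_iter)
            except (ControllerSolverError, IFTViolationError) as exc:
                last_exc = exc
                continue
            if _sign_consistent(sys_, u, x_S, knowns):
                return u, res, cond, it
            if fallback_root is None:
                fallback_root = (u, res, cond, it)
    if fallback_root is not None:
        warnings.warn("predicted optimum: only sign-inconsistent roots "
                      "found from cold start; returning the first root",
                      RuntimeWarning, stacklevel=3)
        return fallback_root
    raise last_exc if last_exc is not None else ControllerSolverError(
        "no root of the optimality system found from any cold start")


def predicted_optimum(net: MetabolicNetwork, mode: FluxMode,
                      cfg: SensorConfig, x_S,
                      warm_start: PredictedOptimum | None = None,
                      known_inputs: Mapping[str, float] | None = None,
                      tol: float = 1e-9, max_iter: int = 60,
                      check_condition: bool = True) -> PredictedOptimum:
    """Solve the sensor-pinned optimality system by damped Newton iteration.

    ``x_S`` holds the sensed concentrations in the order of
    ``cfg.sensors``; ``warm_start`` (a previous solution at nearby sensor
    values) is used as the initial iterate when given.  Convergence demands
    the residual infinity-norm below ``tol``, relaxed only by the
    floating-point noise floor |J|·|u|·eps of the evaluated system — the
    relaxation matters solely near thermodynamic equilibrium, where the
    optimality equations blow up like 1/f^3 while their root stays smooth.

    Raises :class:`IFTViolationError` when the Jacobian condition number
    exceeds the hard ceiling, and :class:`ControllerSolverError` when the
    iteration fails for any other reason.
    """
    sys_ = _get_system(net, mode, cfg)
    x_S = np.asarray(x_S, dtype=float)
    if x_S.shape != (len(cfg.sensors),):
        raise ModelError(f"expected {len(cfg.sensors)} sensor values")
    if np.any(x_S <= 0):
        raise ModelError("sensor concentrations must be strictly positive")
    knowns = sys_.known_values(known_inputs)

    if warm_start is not None:
        # continuation from a nearby solution: accept whatever branch the
        # path is on (during flux reversal all rate signs legitimately
        # flip); if the path runs into the equilibrium crossing — Newton
        # stalls, or lands on a mixed-sign near-singular root — carry it
        # across by reflection through the all-rates-zero state
        u_warm = sys_.unpack_guess(warm_start)

        def near_equilibrium(u_):
            with np.errstate(all="ignore"):
                fs = sys_.f_support_at(u_, x_S, knowns)
            return np.all(np.isfinite(fs)) and \
                np.max(np.abs(fs)) < _EQUILIBRIUM_F_CEILING

        try:
            u, res, cond, it = _newton(sys_, u_warm, x_S, knowns, tol,
                                       max_iter)
            if sys_.orientation_of(u, x_S, knowns) == 0:
                # a mixed-sign root is never the predicted optimum: inside
                # the equilibrium tube, reflect across; otherwise fail
                if not near_equilibrium(u):
                    raise ControllerSolverError(
                        "warm continuation converged to a mixed-sign "
                        "(spurious) root of the optimality system")
                u, res, cond, it = _equilibrium_hop(
                    sys_, u_warm, x_S, knowns, tol, max_iter)
        except (ControllerSolverError, IFTViolationError):
            if near_equilibrium(u_warm):
                u, res, cond, it = _equilibrium_hop(
                    sys_, u_warm, x_S, knowns, tol, max_iter)
            else:
                raise
    else:
        u, res, cond, it = _cold_start_solve(sys_, x_S, knowns, tol,
                                             max_iter)

    if check_condition:
        if cond > COND_FAIL_CEILING:
            raise IFTViolationError(cond)
        if cond > COND_WARN_CEILING:
            warnings.warn(
                f"optimality Jacobian poorly conditioned ({cond:.3e}): "
                "sensor choice close to an IFT violation", RuntimeWarning,
                stacklevel=2)
    return sys_.pack_result(u, x_S, knowns, res, cond, True, it)


def synthesis_rates(net: MetabolicNetwork, mode: FluxMode,
                    xi: PredictedOptimum, mu: float | None = None) -> np.ndarray:
    """Enzyme synthesis rates E_j = mu (V_j/f_j(xi)) / sum_l V_l/f_l(xi).

    Evaluated in the product form E_j = mu V_j prod_{l != j} f_l /
    sum_l V_l prod_{k != l} f_k (products over the mode support), which is
    finite when a single rate factor crosses zero: that reaction's synthesis
    share tends to mu and all others to 0.  The rates sum to mu exactly.
    """
    if mu is None:
        mu = net.mu
    if not xi.converged:
        raise ControllerSolverError("predicted optimum did not converge; "
                                    "synthesis rates undefined")
    x_full = xi.full_concentrations(net)
    f = net.rate_factors(x_full, xi.params(net))
    support = sorted(mode.support)
    fs = f[support]
    Vs = np.array([float(mode.V[j]) for j in support])
    k = len(support)
    # prod_{l != j} f_l via prefix/suffix products (no division)
    pre = np.ones(k + 1)
    suf = np.ones(k + 1)
    for i in range(k):
        pre[i + 1] = pre[i] * fs[i]
        suf[k - 1 - i] = suf[k - i] * fs[k - 1 - i]
    others = pre[:k] * suf[1:]
    w = Vs * others
    denom = w.sum()
    if denom == 0.0:
        raise DegenerateStateError(
            "synthesis-rate normalisation sum vanished (simultaneous "
            "thermodynamic equilibrium of several reactions)")
    E = np.zeros(net.n_reactions)
    E[support] = mu * w / denom
    return E


def continue_prediction(net: MetabolicNetwork, mode: FluxMode,
                        cfg: SensorConfig, xi: PredictedOptimum,
                        x_S_target, known_inputs: Mapping[str, float] | None = None,
                        tol: float = 1e-9, max_substeps: int = 2000,
                        check_condition: bool = True) -> PredictedOptimum:
    """Warm continuation of a predicted optimum to new sensor values.

    The sensor step is subdivided adaptively (bisecting on solver failure,
    and never moving more than a few percent at once) so the solution
    tracks its branch instead of hopping to a different root of the
    optimality system — the predicted optimum is generally multivalued in
    the sensors, and which branch is meant is determined by history, as in
    the underlying differential-algebraic problem.
    """
    x_cur = np.array([xi.xi_I[net.internal_names.index(s)]
                      for s in cfg.sensors], dtype=float)
    target = np.asarray(x_S_target, dtype=float)
    steps = 0
    while np.max(np.abs(target - x_cur)) > 0:
        remaining = target - x_cur
        scale = max(1.0, float(np.max(np.abs(x_cur))))
        frac = min(1.0, 0.05 * scale / max(1e-300,
                                           float(np.max(np.abs(remaining)))))
        while True:
            x_try = x_cur + frac * remaining
            try:
                xi = predicted_optimum(net, mode, cfg, x_try,
                                       warm_start=xi,
                                       known_inputs=known_inputs, tol=tol,
                                       check_condition=check_condition)
                break
            except (ControllerSolverError, IFTViolationError):
                frac *= 0.5
                if frac < 1e-6:
                    raise
        x_cur = x_try
        steps += 1
        if steps > max_substeps:
            raise ControllerSolverError(
                "sensor-path continuation exceeded the substep budget")
    return xi


def near_equilibrium_prediction(net: MetabolicNetwork, mode: FluxMode,
                                xi: PredictedOptimum,
                                ceiling: float = _EQUILIBRIUM_F_CEILING
                                ) -> bool:
    """True when every supported specific rate at the predicted optimum is
    within ``ceiling`` of zero — the thermodynamic-equilibrium
    neighbourhood in which the optimality equations are singular although
    the underlying solution path is smooth."""
    with np.errstate(all="ignore"):
        f = net.rate_factors(xi.full_concentrations(net), xi.params(net))
    support = sorted(mode.support)
    return bool(np.all(np.isfinite(f[support]))
                and np.max(np.abs(f[support])) < ceiling)


def prediction_orientation(net: MetabolicNetwork, mode: FluxMode,
                           xi: PredictedOptimum) -> int:
    """+1 when every supported rate at the predicted optimum runs with the
    mode, -1 when every one runs against it (reversed flow), 0 for a
    mixed-sign (spurious or exactly-at-equilibrium) state."""
    f = net.rate_factors(xi.full_concentrations(net), xi.params(net))
    support = sorted(mode.support)
    s = f[support] * np.array([float(mode.V[j]) for j in support])
    if np.all(s > 0):
        return 1
    if np.all(s < 0):
        return -1
    return 0


@dataclass
class SensorValidityReport:
    ok: bool
    reasons: list[str]
    records: pd.DataFrame

    def __str__(self):
        head = "sensor configuration OK" if self.ok else \
            "sensor configuration INVALID: " + "; ".join(self.reasons)
        return head + ("\n" + self.records.to_string(index=False)
                       if len(self.records) else "")


def check_sensor_validity(net: MetabolicNetwork, mode: FluxMode,
                          cfg: SensorConfig,
                          probe_points: Sequence[Mapping[str, float]] = (),
                          known_inputs: Mapping[str, float] | None = None,
                          cond_ceiling: float = COND_FAIL_CEILING
                          ) -> SensorValidityReport:
    """Diagnose a sensor choice: the counting rule plus the Jacobian
    condition number of the optimality system at each probe point.

    Each probe point maps names to values and must cover the non-sensor
    internals and the unknowns (sensor entries are also required since the
    equations involve them).
    """
    reasons: list[str] = []
    if not cfg.is_square:
        reasons.append(
            f"sensor count: {len(cfg.sensors)} sensors cannot track "
            f"{len(cfg.unknowns)} unknowns (the counting rule requires "
            "equality)")
        return SensorValidityReport(False, reasons, pd.DataFrame())

    sys_ = _get_system(net, mode, cfg)
    knowns = sys_.known_values(known_inputs)
    rows = []
    for p, point in enumerate(probe_points):
        u = np.array([point[n] for n in sys_.free_internal_names] +
                     [point[n] for n in cfg.unknowns], dtype=float)
        x_S = np.array([point[n] for n in cfg.sensors], dtype=float)
        J = sys_.jacobian(u, x_S, knowns)
        cond = (float(np.linalg.cond(J)) if np.all(np.isfinite(J))
                else float("inf"))
        rows.append({"probe": p, "condition_number": cond,
                     "pass": cond <= cond_ceiling})
    records = pd.DataFrame(rows)
    if len(records) and not records["pass"].all():
        bad = records.loc[~records["pass"], "probe"].tolist()
        reasons.append(f"IFT condition: Jacobian condition number above "
                       f"{cond_ceiling:.0e} at probe points {bad}")
    return SensorValidityReport(not reasons, reasons, records)


def io_relation(net: MetabolicNetwork, mode: FluxMode, cfg: SensorConfig,
                sensor_grid: Sequence[Sequence[float]],
                mu: float | None = None,
                known_inputs: Mapping[str, float] | None = None,
                warm_start: PredictedOptimum | None = None) -> pd.DataFrame:
    """The optimal input-output relation: enzyme synthesis rates as a
    function of sensor concentration, computed by warm-started continuation
    along ``sensor_grid``.

    This table *is* the target curve a gene circuit must implement.  Grid
    order is preserved; an IFT violation is re-raised annotated with the
    offending grid point.
    """
    if mu is None:
        mu = net.mu
    rows = []
    xi = warm_start
    for gi, x_S in enumerate(sensor_grid):
        try:
            xi = predicted_optimum(net, mode, cfg, x_S, warm_start=xi,
                                   known_inputs=known_inputs)
        except IFTViolationError as exc:
            raise IFTViolationError(
                exc.condition_number,
                f"IFT violation at grid point {gi} (sensors "
                f"{list(map(float, x_S))}): condition number "
                f"{exc.condition_number:.3e}") from exc
        E = synthesis_rates(net, mode, xi, mu)
        row = {name: float(v) for name, v in zip(cfg.sensors, x_S)}
        row.update({rid: E[j] for j, rid in enumerate(net.reaction_ids)})
        rows.append(row)
    return pd.DataFrame(rows,
                        columns=list(cfg.sensors) + list(net.reaction_ids))
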