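"""Coupled metabolic / gene-expression dynamics under qORAC control.

The state is (x_I, e): internal metabolite concentrations and enzyme
concentrations.  Their dynamics are

    dx_i/dt = sum_j N_ij e_j f_j(x_I; x_E),
    de_j/dt = E_j(x_S) - mu e_j,

with the synthesis rates E_j(x_S) obtained by solving the sensor-pinned
optimality system at every right-hand-side evaluation (warm-started Newton
— an embedded algebraic solve rather than a monolithic DAE, which keeps the
controller a pure, separately testable function).  Metabolite dilution is
neglected; enzyme dilution at rate mu is not.

External concentrations and scheduled kinetic parameters are piecewise
constant: the integrator is restarted at each schedule boundary with state
continuity and no smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.integrate

from .controller import (PredictedOptimum, SensorConfig,
                         continue_prediction, near_equilibrium_prediction,
                         prediction_orientation, predicted_optimum,
                         synthesis_rates)
from .efm import FluxMode
from .errors import (ControllerSolverError, IFTViolationError, ModelError,
                     ObjectiveDomainError, QoracError, SimulationError)
from .network import MetabolicNetwork
from .optimum import ObjectiveSpec, minimize_objective, optimal_enzymes

__all__ = ["EnvironmentSchedule", "Trajectory", "simulate",
           "distance_to_optimum", "detect_steady_state", "flux_reversal_run",
           "SteadyStateFlag"]


@dataclass(frozen=True)
class EnvironmentSchedule:
    """Piecewise-constant environment: ordered (t_start, values) segments.

    ``values`` maps external species names and/or adjustable parameter
    names to constants; entries omitted from a segment fall back to the
    previous segment's value (and before that, to network defaults).
    """

    segments: tuple[tuple[float, dict[str, float]], ...]
    t_end: float

    def __init__(self, segments: Sequence[tuple[float, Mapping[str, float]]],
                 t_end: float):
        segs = tuple((float(t), dict(v)) for t, v in segments)
        if not segs:
            raise ModelError("schedule needs at least one segment")
        if segs[0][0] != 0.0:
            raise ModelError("first schedule segment must start at t = 0")
        starts = [t for t, _ in segs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ModelError("segment start times must be strictly "
                             "increasing")
        if t_end <= starts[-1]:
            raise ModelError("t_end must exceed the last segment start")
        for _, vals in segs:
            if any(v <= 0 for v in vals.values()):
                raise ModelError("scheduled values must be positive")
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "t_end", float(t_end))

    def __len__(self):
        return len(self.segments)

    def bounds(self, k: int) -> tuple[float, float]:
        t0 = self.segments[k][0]
        t1 = (self.segments[k + 1][0] if k + 1 < len(self.segments)
              else self.t_end)
        return t0, t1

    def active_values(self, k: int) -> dict[str, float]:
        """Cumulative environment for segment k (later segments override)."""
        vals: dict[str, float] = {}
        for t, v in self.segments[:k + 1]:
            vals.update(v)
        return vals

    def segment_at(self, t: float) -> int:
        for k in range(len(self.segments) - 1, -1, -1):
            if t >= self.segments[k][0]:
                return k
        return 0


@dataclass
class Trajectory:
    """Stored time series of a qORAC run plus per-segment diagnostics."""

    times: np.ndarray
    x_I: np.ndarray              # (nt, n_internal)
    e: np.ndarray                # (nt, m)
    v: np.ndarray                # (nt, m) fluxes e*f
    xi_I: np.ndarray             # (nt, n_internal) predicted internals
    xi_unknowns: np.ndarray      # (nt, n_unknown) predicted unknowns
    unknown_names: tuple[str, ...]
    segment_index: np.ndarray
    event_log: list[dict] = field(default_factory=list)
    truncated: bool = False
    failure: str | None = None
    net: MetabolicNetwork | None = None
    mode: FluxMode | None = None
    cfg: SensorConfig | None = None
    schedule: EnvironmentSchedule | None = None
    mu: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: one row per stored time point."""
        net = self.net
        cols = {"time": self.times, "segment": self.segment_index}
        for i, n in enumerate(net.internal_names):
            cols[f"x_{n}"] = self.x_I[:, i]
        for j, r in enumerate(net.reaction_ids):
            cols[f"e_{r}"] = self.e[:, j]
        for j, r in enumerate(net.reaction_ids):
            cols[f"v_{r}"] = self.v[:, j]
        for i, n in enumerate(net.internal_names):
            cols[f"xi_{n}"] = self.xi_I[:, i]
        for k, n in enumerate(self.unknown_names):
            cols[f"xi_{n}"] = self.xi_unknowns[:, k]
        return pd.DataFrame(cols)

    def write_csv(self, path, log_path=None) -> None:
        self.to_frame().to_csv(path, index=False)
        if log_path is not None:
            with open(log_path, "w") as fh:
                for ev in self.event_log:
                    fh.write(" ".join(f"{k}={v}" for k, v in ev.items())
                             + "\n")


def _env_split(net: MetabolicNetwork, cfg: SensorConfig,
               env: Mapping[str, float]):
    """Split a cumulative environment into (externals map, params map,
    controller-visible knowns)."""
    ext = dict(cfg.known_externals)
    par = dict(net.adjustable_params)
    for k, v in env.items():
        if k in net.species_index:
            ext[k] = v
        elif k in par:
            par[k] = v
        else:
            raise ModelError(f"scheduled name {k!r} is neither an external "
                             "species nor an adjustable parameter")
    missing = set(net.external_names) - set(ext)
    if missing:
        raise ModelError(f"externals without scheduled or known value: "
                         f"{sorted(missing)}")
    knowns = {k: v for k, v in {**ext, **par}.items()
              if k not in cfg.unknowns}
    return ext, par, knowns


def simulate(net: MetabolicNetwork, mode: FluxMode, cfg: SensorConfig,
             schedule: EnvironmentSchedule, init_x_I, init_e,
             mu: float | None = None, rtol: float = 1e-8,
             atol: float = 1e-10, store_points: int = 200,
             method: str = "LSODA",
             controller_tol: float = 1e-9) -> Trajectory:
    """Integrate the qORAC-controlled system over the whole schedule.

    ``init_x_I`` may contain zeros for non-sensor metabolites (an
    "everything absent" start); sensor coordinates must be positive since
    the control law reads them.  ``init_e`` may be all zeros.  On an IFT
    violation or controller failure mid-run the trajectory is truncated at
    the failure time with the diagnostic recorded in ``event_log`` and
    ``failure``; an integrator breakdown raises :class:`SimulationError`.
    """
    if mu is None:
        mu = net.mu
    x = np.array(init_x_I, dtype=float)
    e = np.array(init_e, dtype=float)
    nI, m = net.n_internal, net.n_reactions
    if x.shape != (nI,) or e.shape != (m,):
        raise ModelError("initial condition dimensions do not match the "
                         "network")
    if np.any(x < 0) or np.any(e < 0):
        raise ModelError("initial concentrations must be nonnegative")
    sensor_idx = np.array([net.internal_names.index(s)
                           for s in cfg.sensors], dtype=int)
    if np.any(x[sensor_idx] <= 0):
        raise ModelError("initial sensor concentrations must be positive")

    log: list[dict] = []
    times_all, X_all, E_all, seg_all = [], [], [], []
    truncated = False
    failure = None

    # cold start for the algebraic solve: direct optimum at the initial
    # environment (the controller only uses it as a Newton seed)
    env0 = schedule.active_values(0)
    ext0, par0, knowns0 = _env_split(net, cfg, env0)
    warm: PredictedOptimum | None = None
    try:
        spec0 = ObjectiveSpec(net, mode, ext0, params=par0)
        r0 = minimize_objective(spec0, np.ones(nI))
        warm = predicted_optimum(
            net, mode, cfg, r0.x_opt[sensor_idx],
            warm_start=None, known_inputs=knowns0, tol=controller_tol)
        # re-seed from the solved state but at the actual initial sensors
        warm = continue_prediction(
            net, mode, cfg, warm, x[sensor_idx],
            known_inputs=knowns0, tol=controller_tol)
        if prediction_orientation(net, mode, warm) == 0:
            # continuation jumped to a mixed-sign root: discard the seed
            # and let the first right-hand-side call cold-start properly
            log.append({"event": "cold_start_reseed",
                        "detail": "mixed-sign seed discarded"})
            warm = None
    except QoracError as exc:
        log.append({"event": "cold_start_fallback", "detail": str(exc)})
        warm = None

    undershoot = {"worst": 0.0}

    for k in range(len(schedule)):
        t0, t1 = schedule.bounds(k)
        env = schedule.active_values(k)
        ext, par, knowns = _env_split(net, cfg, env)
        state = {"warm": warm, "E": None, "frozen": 0}

        def rhs(t, y, _state=state, _ext=ext, _par=par, _knowns=knowns):
            xI = y[:nI].copy()
            ee = y[nI:].copy()
            low = min(xI.min(initial=0.0), ee.min(initial=0.0))
            if low < undershoot["worst"]:
                undershoot["worst"] = low
            np.clip(xI, 0.0, None, out=xI)
            np.clip(ee, 0.0, None, out=ee)
            x_full = net.full_concentrations(xI, _ext)
            f = net.rate_factors(x_full, _par)
            x_S = np.maximum(xI[sensor_idx], 1e-12)
            try:
                xi = predicted_optimum(net, mode, cfg, x_S,
                                       warm_start=_state["warm"],
                                       known_inputs=_knowns,
                                       tol=controller_tol)
                _state["warm"] = xi
                _state["E"] = synthesis_rates(net, mode, xi, mu)
                _state["frozen"] = 0
            except (ControllerSolverError, IFTViolationError):
                # inside the thermodynamic-equilibrium tube the optimality
                # equations are singular although the underlying solution
                # path is smooth: hold the last synthesis rates briefly
                # while the metabolic state carries the sensors across
                if (_state["E"] is None or _state["warm"] is None
                        or not near_equilibrium_prediction(
                            net, mode, _state["warm"])
                        or _state["frozen"] >= 2000):
                    raise
                _state["frozen"] += 1
            E = _state["E"]
            dx = net.N_float @ (ee * f)
            de = E - mu * ee
            return np.concatenate([dx, de])

        t_eval = np.linspace(t0, t1, store_points + 1)
        try:
            sol = scipy.integrate.solve_ivp(
                rhs, (t0, t1), np.concatenate([x, e]), method=method,
                rtol=rtol, atol=atol, t_eval=t_eval, dense_output=False)
        except (IFTViolationError, ControllerSolverError) as exc:
            truncated = True
            failure = f"segment {k}: {exc}"
            log.append({"event": "controller_failure", "segment": k,
                        "error": type(exc).__name__, "detail": str(exc)})
            break
        if not sol.success:
            raise SimulationError(
                f"integrator failed in segment {k}: {sol.message}",
                segment=k, time=float(sol.t[-1]) if len(sol.t) else t0)
        times_all.append(sol.t)
        X_all.append(sol.y[:nI].T)
        E_all.append(sol.y[nI:].T)
        seg_all.append(np.full(len(sol.t), k, dtype=int))
        x = sol.y[:nI, -1].copy()
        e = sol.y[nI:, -1].copy()
        warm = state["warm"]
        log.append({"event": "segment_done", "segment": k,
                    "t0": t0, "t1": t1, "nfev": sol.nfev,
                    "controller_residual":
                        warm.residual_norm if warm else float("nan"),
                    "jacobian_condition":
                        warm.jacobian_condition if warm else float("nan")})

    if undershoot["worst"] < -1e-12:
        log.append({"event": "negativity_clip",
                    "worst_undershoot": undershoot["worst"]})
        warnings.warn(f"integrator undershoot below zero "
                      f"({undershoot['worst']:.2e}) was clipped",
                      RuntimeWarning, stacklevel=2)
    if undershoot["worst"] < -1e-6:
        raise SimulationError("persistent negativity violation "
                              f"({undershoot['worst']:.2e})")

    if not times_all:
        times = np.array([schedule.segments[0][0]])
        X = np.array(init_x_I, dtype=float)[None, :]
        E = np.array(init_e, dtype=float)[None, :]
        segs = np.array([0])
    else:
        times = np.concatenate(times_all)
        X = np.vstack(X_all)
        E = np.vstack(E_all)
        segs = np.concatenate(seg_all)

    # post-pass: fluxes and predicted optimum at the stored points
    V = np.empty_like(E)
    XI = np.empty((len(times), nI))
    UNK = np.empty((len(times), len(cfg.unknowns)))
    warm2: PredictedOptimum | None = None
    for i, (t, kseg) in enumerate(zip(times, segs)):
        ext, par, knowns = _env_split(net, cfg,
                                      schedule.active_values(int(kseg)))
        xI = np.clip(X[i], 0.0, None)
        x_full = net.full_concentrations(xI, ext)
        V[i] = np.clip(E[i], 0.0, None) * net.rate_factors(x_full, par)
        try:
            x_S_i = np.maximum(xI[sensor_idx], 1e-12)
            if warm2 is None:
                warm2 = predicted_optimum(
                    net, mode, cfg, x_S_i, known_inputs=knowns,
                    tol=controller_tol)
            else:
                warm2 = continue_prediction(
                    net, mode, cfg, warm2, x_S_i, known_inputs=knowns,
                    tol=controller_tol)
            XI[i] = warm2.xi_I
            UNK[i] = [warm2.xi_unknowns[n] for n in cfg.unknowns]
        except QoracError:
            XI[i] = np.nan
            UNK[i] = np.nan
            warm2 = None

    return Trajectory(
        times=times, x_I=X, e=E, v=V, xi_I=XI, xi_unknowns=UNK,
        unknown_names=tuple(cfg.unknowns), segment_index=segs,
        event_log=log, truncated=truncated, failure=failure,
        net=net, mode=mode, cfg=cfg, schedule=schedule, mu=mu)


def _segment_optima(traj: Trajectory):
    """Direct optimum (x_opt, e_opt under total-1) per schedule segment."""
    net, mode, cfg, schedule = traj.net, traj.mode, traj.cfg, traj.schedule
    optima = {}
    x0 = np.ones(net.n_internal)
    for k in range(len(schedule)):
        ext, par, _ = _env_split(net, cfg, schedule.active_values(k))
        spec = ObjectiveSpec(net, mode, ext, params=par)
        try:
            r = minimize_objective(spec, x0)
        except ObjectiveDomainError:
            r = minimize_objective(spec, None)  # re-seed after a step change
        e_tot1 = optimal_enzymes(spec, r.x_opt, normalisation="total_1")
        optima[k] = (r.x_opt, e_tot1)
        x0 = r.x_opt
    return optima


def distance_to_optimum(traj: Trajectory, net=None, mode=None,
                        schedule=None) -> np.ndarray:
    """Euclidean distance of (x_I, e) from the true optimum of the
    environment active at each stored time (enzymes compared under the
    total-enzyme-1 normalisation that the synthesis law enforces)."""
    if net is not None:
        traj = Trajectory(**{**traj.__dict__, "net": net,
                             "mode": mode or traj.mode,
                             "schedule": schedule or traj.schedule})
    optima = _segment_optima(traj)
    d = np.empty(len(traj.times))
    for i, k in enumerate(traj.segment_index):
        x_opt, e_opt = optima[int(k)]
        d[i] = np.sqrt(np.sum((traj.x_I[i] - x_opt) ** 2)
                       + np.sum((traj.e[i] - e_opt) ** 2))
    return d


@dataclass
class SteadyStateFlag:
    segment: int
    steady: bool
    max_rate: float
    x_I: np.ndarray
    e: np.ndarray
    time: float


def detect_steady_state(traj: Trajectory, window: float = 5.0,
                        tol: float = 1e-6) -> list[SteadyStateFlag]:
    """Flag segments whose terminal window has all state derivatives below
    ``tol``; derivatives are recomputed exactly from the stored states (not
    finite-differenced)."""
    net, mode, cfg, schedule = traj.net, traj.mode, traj.cfg, traj.schedule
    mu = traj.mu
    out = []
    sensor_idx = np.array([net.internal_names.index(s)
                           for s in cfg.sensors], dtype=int)
    for k in sorted(set(traj.segment_index.tolist())):
        t0, t1 = schedule.bounds(k)
        sel = np.where((traj.segment_index == k)
                       & (traj.times >= t1 - window))[0]
        if len(sel) == 0:
            continue
        ext, par, knowns = _env_split(net, cfg, schedule.active_values(k))
        max_rate = 0.0
        warm = None
        for i in sel:
            xI = np.clip(traj.x_I[i], 0.0, None)
            ee = traj.e[i]
            x_full = net.full_concentrations(xI, ext)
            f = net.rate_factors(x_full, par)
            dx = net.N_float @ (ee * f)
            try:
                warm = predicted_optimum(
                    net, mode, cfg, np.maximum(xI[sensor_idx], 1e-12),
                    warm_start=warm, known_inputs=knowns)
                E = synthesis_rates(net, mode, warm, mu)
                de = E - mu * ee
            except QoracError:
                de = np.full_like(ee, np.inf)
            max_rate = max(max_rate, float(np.max(np.abs(dx))),
                           float(np.max(np.abs(de))))
        i_last = sel[-1]
        out.append(SteadyStateFlag(
            segment=int(k), steady=max_rate < tol, max_rate=max_rate,
            x_I=traj.x_I[i_last].copy(), e=traj.e[i_last].copy(),
            time=float(traj.times[i_last])))
    return out


def flux_reversal_run(fixture, reversed_sensor_state: Mapping[str, float],
                      init_e=None, schedule: EnvironmentSchedule | None = None,
                      **sim_kwargs) -> Trajectory:
    """Run a chain fixture from a state whose sensors predict flow in the
    wrong direction, forcing the predicted optimum to straighten out
    through thermodynamic equilibrium.

    ``reversed_sensor_state`` gives the initial sensor concentrations by
    species name; the remaining internals and (unless ``init_e`` is given)
    the enzymes are initialised self-consistently at the corresponding
    predicted optimum — the pathway starts adapted to the flow direction
    its sensors wrongly indicate, while the schedule's true externals
    drive it the other way.
    """
    net, mode, cfg = fixture.network, fixture.mode, fixture.sensor_config
    schedule = schedule or fixture.schedule
    missing = set(cfg.sensors) - set(reversed_sensor_state)
    if missing:
        raise ModelError(f"reversed state must give every sensor a value; "
                         f"missing {sorted(missing)}")
    x_S = [float(reversed_sensor_state[s]) for s in cfg.sensors]
    _, _, knowns = _env_split(net, cfg, schedule.active_values(0))
    xi0 = predicted_optimum(net, mode, cfg, x_S, known_inputs=knowns)
    x0 = xi0.xi_I.copy()
    if init_e is not None:
        e0 = np.array(init_e, dtype=float)
    else:
        f0 = net.rate_factors(xi0.full_concentrations(net), xi0.params(net))
        support = sorted(mode.support)
        e0 = np.zeros(net.n_reactions)
        e0[support] = np.array([float(mode.V[j]) for j in support]) \
            / f0[support]
        e0 = e0 / e0.sum()
    return simulate(net, mode, cfg, schedule, x0, e0, **sim_kwargs)
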