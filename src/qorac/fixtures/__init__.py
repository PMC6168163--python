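"""Packaged model fixtures and a reproducible fixture generator.

Two fixtures ship as YAML model files in ``data/`` (the four-step pathway
with printed kinetics, and a branched two-input/two-output network with
cross-inhibition); linear chains of arbitrary length are generated from a
seed.  Every numeric value in a fixture is tagged in its ``provenance``
block as transcribed-from-print or fixture-chosen.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from ..controller import SensorConfig
from ..efm import FluxMode
from ..errors import ModelError
from ..network import MetabolicNetwork, RateLaw, Species, load_model
from ..simulator import EnvironmentSchedule

__all__ = ["Fixture", "example1", "branched_network", "linear_chain",
           "km_sensing_fixture", "load_builtin", "builtin_names"]


@dataclass
class Fixture:
    name: str
    network: MetabolicNetwork
    mode: FluxMode
    sensor_config: SensorConfig
    schedule: EnvironmentSchedule
    provenance: dict
    init_x_I: np.ndarray
    init_e: np.ndarray


def _data_text(fname: str) -> str:
    return (resources.files(__package__) / "data" / fname).read_text()


def _fixture_from_yaml(text: str, name: str | None = None) -> Fixture:
    doc = yaml.safe_load(text)
    net = load_model(text)
    fx = doc["fixture"]
    rid_index = {r: j for j, r in enumerate(net.reaction_ids)}
    V = tuple(Fraction(c) for c in fx["mode"])
    mode = FluxMode(V, output_reaction=rid_index[fx["output_reaction"]])
    cfg = SensorConfig(fx["sensors"], fx["unknowns"],
                       fx.get("known_externals") or {})
    sched = EnvironmentSchedule(
        [(seg["t"], seg["values"]) for seg in fx["schedule"]["segments"]],
        t_end=fx["schedule"]["t_end"])
    x0 = np.array([fx["init"]["x_I"][n] for n in net.internal_names])
    e0 = np.array([fx["init"]["e"][r] for r in net.reaction_ids])
    return Fixture(name or doc.get("name", "fixture"), net, mode, cfg, sched,
                   doc.get("provenance", {}), x0, e0)


def example1() -> Fixture:
    """The four-step pathway with fully printed kinetics: external carbon
    source x1, intermediates x2 (the sensor), x3, x4, unit-flux mode through
    all four reactions, one unknown external (x1) tracked by one sensor."""
    return _fixture_from_yaml(_data_text("example1.yaml"))


def branched_network() -> Fixture:
    """Two inputs, two outputs, allosteric cross-inhibition; all four
    external concentrations vary, tracked by four sensors (x3, x4, x7, x8).
    Kinetic parameter values are fixture-chosen (see provenance)."""
    return _fixture_from_yaml(_data_text("branched.yaml"))


def km_sensing_fixture(valid_sensors: bool = True) -> Fixture:
    """A six-species chain whose third reaction carries an adjustable
    Michaelis constant K3, tracked by the controller alongside the input
    concentration x1 (two sensors for two unknowns; the sink x6 is known).

    ``valid_sensors=True`` senses (x3, x4) — the substrate and product
    flanking the K3-bearing reaction — which steers the pathway to the
    optimum and recovers K3 after its step change.
    ``valid_sensors=False`` swaps sensor x3 for x2.  That configuration
    passes every static requirement (the counting rule, a nonsingular
    Jacobian at the initial operating point) but the controlled dynamics
    drive the optimality system into a singular point after the first
    environmental change: the run terminates with an IFT-violation
    diagnostic instead of silently mis-steering.
    """
    n, m = 6, 5
    rng = np.random.default_rng(42)
    kf = rng.uniform(0.8, 1.5, m)
    kr = kf * rng.uniform(0.65, 0.9, m)
    a = rng.uniform(0.1, 0.4, m)
    b = rng.uniform(0.1, 0.4, m)
    species = [Species("x1", "external")]
    species += [Species(f"x{i}", "internal") for i in range(2, n)]
    species += [Species(f"x{n}", "external")]
    reactions = []
    stoich: dict[str, dict[str, int]] = {}
    for i in range(m):
        s, p = f"x{i + 1}", f"x{i + 2}"
        if i == 2:  # saturation of the third reaction governed by K3
            expr = (f"({float(kf[i])!r}*{s} - {float(kr[i])!r}*{p}) / "
                    f"(({s}/K3 + 1)*({float(b[i])!r}*{p} + 1))")
        else:
            expr = (f"({float(kf[i])!r}*{s} - {float(kr[i])!r}*{p}) / "
                    f"(({float(a[i])!r}*{s} + 1)*({float(b[i])!r}*{p} + 1))")
        rid = f"r{i + 1}"
        reactions.append(RateLaw(rid, expr))
        stoich[rid] = {}
        if i > 0:
            stoich[rid][s] = -1
        if i < m - 1:
            stoich[rid][p] = 1
    net = MetabolicNetwork(species, reactions, stoich, mu=1.0,
                           adjustable_params={"K3": 2.0},
                           name="km_sensing_chain")
    mode = FluxMode(tuple(Fraction(1) for _ in range(m)),
                    output_reaction=m - 1)
    sensors = ["x3", "x4"] if valid_sensors else ["x2", "x4"]
    cfg = SensorConfig(sensors, ["x1", "K3"], {"x6": 0.3})
    sched = EnvironmentSchedule(
        [(0.0, {"x1": 4.0, "x6": 0.3, "K3": 2.0}),
         (60.0, {"x1": 2.0}),
         (120.0, {"K3": 5.0})],
        t_end=400.0)
    from ..optimum import ObjectiveSpec, minimize_objective, optimal_enzymes
    spec = ObjectiveSpec(net, mode, {"x1": 4.0, "x6": 0.3},
                         params={"K3": 2.0})
    r = minimize_objective(spec)
    prov = {"printed": ["a Michaelis constant of the third reaction as the "
                        "sensed parameter; a sensor swap that breaks the "
                        "control dynamically"],
            "fixture_chosen": ["all kinetic parameter values (seeded)",
                               "schedule", "initial conditions"]}
    return Fixture(
        "km_sensing_valid" if valid_sensors else "km_sensing_invalid",
        net, mode, cfg, sched, prov, r.x_opt,
        optimal_enzymes(spec, r.x_opt, normalisation="total_1"))


def linear_chain(n_species: int = 7, kinetics_params: Mapping | None = None,
                 seed: int = 0) -> Fixture:
    """A reversible saturable chain x1 -> x2 -> ... -> xn (x1 and xn
    external), with rate laws of the same functional family as the printed
    four-step pathway:

        f_i = (kf_i x_i - kr_i x_{i+1}) / ((a_i x_i + 1)(b_i x_{i+1} + 1)).

    Parameters are drawn reproducibly from ``seed`` within documented
    ranges (kf in [0.8, 1.5], kr/kf in [0.65, 0.9], a and b in
    [0.1, 0.4]) unless overridden via ``kinetics_params`` (maps parameter
    name -> array over reactions).  The reactions operate near
    thermodynamic equilibrium (kr/kf close to 1), which keeps both flow
    orientations attainable — the regime in which flux reversal through
    equilibrium is meaningful.  Sensors sit adjacent to the two external
    ends (x2 and x_{n-1}), tracking the unknown externals x1 and x_n;
    n = 7 reproduces the seven-species flux-reversal topology.
    """
    if n_species < 3:
        raise ModelError("a chain needs at least 3 species "
                         "(two externals and one internal)")
    n = n_species
    m = n - 1
    rng = np.random.default_rng(seed)
    kf = rng.uniform(0.8, 1.5, size=m)
    kr = kf * rng.uniform(0.65, 0.9, size=m)
    a = rng.uniform(0.1, 0.4, size=m)
    b = rng.uniform(0.1, 0.4, size=m)
    if kinetics_params:
        kf = np.asarray(kinetics_params.get("kf", kf), dtype=float)
        kr = np.asarray(kinetics_params.get("kr", kr), dtype=float)
        a = np.asarray(kinetics_params.get("a", a), dtype=float)
        b = np.asarray(kinetics_params.get("b", b), dtype=float)

    species = [Species("x1", "external")]
    species += [Species(f"x{i}", "internal") for i in range(2, n)]
    species += [Species(f"x{n}", "external")]
    reactions = []
    stoich: dict[str, dict[str, int]] = {}
    for i in range(m):
        s, p = f"x{i + 1}", f"x{i + 2}"
        expr = (f"({float(kf[i])!r}*{s} - {float(kr[i])!r}*{p}) / "
                f"(({float(a[i])!r}*{s} + 1)*({float(b[i])!r}*{p} + 1))")
        rid = f"r{i + 1}"
        reactions.append(RateLaw(rid, expr))
        stoich[rid] = {}
        if i > 0:
            stoich[rid][s] = -1
        if i < m - 1:
            stoich[rid][p] = 1
    net = MetabolicNetwork(species, reactions, stoich, mu=1.0,
                           name=f"chain{n}_seed{seed}")
    mode = FluxMode(tuple(Fraction(1) for _ in range(m)),
                    output_reaction=m - 1)
    # one sensor adjacent to each (unknown) external end of the chain
    cfg = SensorConfig(["x2", f"x{n - 1}"], ["x1", f"x{n}"])
    sched = EnvironmentSchedule(
        [(0.0, {"x1": 4.0, f"x{n}": 0.3}),
         (60.0, {"x1": 2.0}),
         (120.0, {"x1": 6.0})],
        t_end=180.0)
    prov = {"printed": ["seven-species chain topology for the "
                        "flux-reversal scenario"],
            "fixture_chosen": ["all kinetic parameters (seeded)",
                               "schedule", "initial conditions"]}
    # start adapted to a previous environment so the initial sensor values
    # lie in the attainable range of the control law
    from ..optimum import ObjectiveSpec, minimize_objective, optimal_enzymes
    pre_env = {"x1": 2.0, f"x{n}": 0.3}
    spec = ObjectiveSpec(net, mode, pre_env)
    r = minimize_objective(spec)
    x0 = r.x_opt
    e0 = optimal_enzymes(spec, r.x_opt, normalisation="total_1")
    return Fixture(net.name, net, mode, cfg, sched, prov, x0, e0)


_BUILTINS = {
    "example1": example1,
    "branched": branched_network,
    "km_sensing_valid": lambda: km_sensing_fixture(True),
    "km_sensing_invalid": lambda: km_sensing_fixture(False),
    "chain7": lambda: linear_chain(7, seed=0),
}


def builtin_names() -> list[str]:
    return sorted(_BUILTINS)


def load_builtin(name: str) -> Fixture:
    """Load a fixture by name (``builtin:`` prefix tolerated)."""
    key = name.removeprefix("builtin:")
    if key not in _BUILTINS:
        raise ModelError(f"unknown builtin fixture {name!r}; available: "
                         f"{builtin_names()}")
    return _BUILTINS[key]()
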