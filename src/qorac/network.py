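"""Kinetic metabolic networks.

A network couples a stoichiometry matrix ``N`` (rows = internal species) to
per-reaction kinetic rate laws of the separable form

    v_j = e_j * f_j(x; params),

where ``e_j`` is the enzyme concentration catalysing reaction ``j`` and
``f_j`` is the specific rate (flux per unit enzyme) as a closed-form
function of the species concentrations.  Metabolite dilution by growth is
neglected, so the internal balances are ``x_I' = N v``; the enzyme balances
(with dilution) live in :mod:`qorac.simulator`.

Rate laws are stored as symbolic expressions (sympy).  Ordinary kinetic
parameters are substituted numerically when the network is built; parameters
declared *adjustable* stay symbolic so they can be scheduled by the
environment or estimated by the controller (e.g. a Michaelis constant that
changes over time).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import sympy as sp
import yaml

from .errors import ModelError, RateDomainError

__all__ = [
    "Species",
    "RateLaw",
    "MetabolicNetwork",
    "ValidationIssue",
    "ValidationReport",
    "validate_network",
    "reaction_rates",
    "metabolite_balances",
    "read_model",
    "write_model",
    "load_model",
    "dump_model",
]


@dataclass(frozen=True)
class Species:
    """A chemical species; ``role`` is ``"internal"`` or ``"external"``."""

    name: str
    role: str

    def __post_init__(self):
        if self.role not in ("internal", "external"):
            raise ModelError(f"species {self.name!r}: role must be "
                             f"'internal' or 'external', got {self.role!r}")


@dataclass(frozen=True)
class RateLaw:
    """Specific rate f_j of one reaction.

    ``expression`` is the textual formula in species and parameter names;
    ``parameters`` maps the reaction's own parameter names to values.
    """

    reaction_id: str
    expression: str
    parameters: Mapping[str, float] = field(default_factory=dict)


class MetabolicNetwork:
    """Species + stoichiometry + rate laws + growth rate.

    Parameters
    ----------
    species:
        All species, internal and external; their order defines the
        concentration-vector indexing used throughout.
    reactions:
        Ordered rate laws, one per stoichiometry column.
    stoichiometry:
        Either a dense matrix with one row per *internal* species (in
        species order restricted to internals) or a per-reaction mapping
        ``{reaction_id: {species_name: coefficient}}``.  Coefficients may
        be ints, floats or :class:`fractions.Fraction`; they are kept as
        exact rationals.
    mu:
        Growth rate (1/time); used downstream for enzyme dilution.
    adjustable_params:
        Name -> default value for parameters that stay symbolic (scheduled
        or controller-estimated).  Names must not collide with species.
    """

    def __init__(self, species: Sequence[Species], reactions: Sequence[RateLaw],
                 stoichiometry, mu: float = 1.0,
                 adjustable_params: Mapping[str, float] | None = None,
                 name: str = "network"):
        self.name = name
        self.species = list(species)
        self.reactions = list(reactions)
        self.mu = float(mu)
        self.adjustable_params = dict(adjustable_params or {})

        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ModelError("duplicate species names")
        self.species_names = names
        self.species_index = {n: i for i, n in enumerate(names)}
        self.internal_names = [s.name for s in self.species if s.role == "internal"]
        self.external_names = [s.name for s in self.species if s.role == "external"]
        self.internal_indices = np.array(
            [self.species_index[n] for n in self.internal_names], dtype=int)

        self.reaction_ids = [r.reaction_id for r in self.reactions]
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            raise ModelError("duplicate reaction ids")

        self.N = self._build_stoichiometry(stoichiometry)
        self.N_float = np.array([[float(c) for c in row] for row in self.N])

        bad = set(self.adjustable_params) & set(names)
        if bad:
            raise ModelError(f"adjustable parameter names collide with "
                             f"species names: {sorted(bad)}")

        self._build_symbolic()

    # -- construction helpers -------------------------------------------------

    def _build_stoichiometry(self, stoich) -> list[list[Fraction]]:
        nI, m = len(self.internal_names), len(self.reactions)
        rows = [[Fraction(0)] * m for _ in range(nI)]
        row_of = {n: i for i, n in enumerate(self.internal_names)}
        if isinstance(stoich, Mapping):
            for rid, contrib in stoich.items():
                if rid not in self.reaction_ids:
                    raise ModelError(f"stoichiometry refers to unknown "
                                     f"reaction {rid!r}")
                j = self.reaction_ids.index(rid)
                for sname, coef in contrib.items():
                    if sname not in self.species_index:
                        raise ModelError(f"stoichiometry refers to unknown "
                                         f"species {sname!r}")
                    if sname in row_of:  # external rows are identically zero
                        rows[row_of[sname]][j] = _as_fraction(coef)
        else:
            arr = list(stoich)
            if len(arr) != nI:
                raise ModelError(f"stoichiometry has {len(arr)} rows, "
                                 f"expected {nI} (one per internal species)")
            for i, row in enumerate(arr):
                row = list(row)
                if len(row) != m:
                    raise ModelError(f"stoichiometry row {i} has {len(row)} "
                                     f"columns, expected {m} reactions")
                rows[i] = [_as_fraction(c) for c in row]
        return rows

    def _build_symbolic(self):
        self.species_symbols = [sp.Symbol(n, positive=True)
                                for n in self.species_names]
        self.param_symbols = [sp.Symbol(n, positive=True)
                              for n in self.adjustable_params]
        ns = {n: s for n, s in zip(self.species_names, self.species_symbols)}
        ns.update({n: s for n, s in
                   zip(self.adjustable_params, self.param_symbols)})

        self.f_exprs = []
        for r in self.reactions:
            local = dict(ns)
            # ordinary parameters are substituted numerically up front;
            # adjustable ones keep their symbol even if a default is also
            # listed in the reaction's own parameter map
            for pname, pval in r.parameters.items():
                if pname not in self.adjustable_params:
                    local[pname] = sp.Float(pval)
            try:
                expr = sp.sympify(r.expression, locals=local)
            except (sp.SympifyError, TypeError, SyntaxError) as exc:
                raise ModelError(f"cannot parse rate law of "
                                 f"{r.reaction_id!r}: {exc}") from exc
            free = expr.free_symbols - set(self.species_symbols) \
                - set(self.param_symbols)
            if free:
                raise ModelError(f"rate law of {r.reaction_id!r} contains "
                                 f"unbound names {sorted(map(str, free))}")
            self.f_exprs.append(expr)

        args = self.species_symbols + self.param_symbols
        self._f_lambdas = [sp.lambdify(args, e, modules="numpy")
                           for e in self.f_exprs]

    # -- evaluation -----------------------------------------------------------

    def param_values(self, params: Mapping[str, float] | None = None) -> list[float]:
        """Adjustable-parameter values: defaults overridden by ``params``."""
        vals = dict(self.adjustable_params)
        if params:
            unknown = set(params) - set(vals)
            if unknown:
                raise ModelError(f"unknown adjustable parameters: "
                                 f"{sorted(unknown)}")
            vals.update(params)
        return [vals[n] for n in self.adjustable_params]

    def rate_factors(self, x, params: Mapping[str, float] | None = None) -> np.ndarray:
        """Evaluate the specific rates f_j(x) for a full concentration vector
        ``x`` ordered like ``species``."""
        x = np.asarray(x, dtype=float)
        if x.shape != (len(self.species),):
            raise ModelError(f"expected concentration vector of length "
                             f"{len(self.species)}, got shape {x.shape}")
        pvals = self.param_values(params)
        out = np.empty(len(self.reactions))
        with np.errstate(divide="ignore", invalid="ignore"):
            for j, fl in enumerate(self._f_lambdas):
                val = fl(*x, *pvals)
                if not np.isfinite(val):
                    raise RateDomainError(self.reaction_ids[j])
                out[j] = val
        return out

    @property
    def n_internal(self) -> int:
        return len(self.internal_names)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def full_concentrations(self, x_internal, external: Mapping[str, float]) -> np.ndarray:
        """Assemble the full species vector from internal values plus a map
        of external concentrations."""
        x = np.zeros(len(self.species))
        x[self.internal_indices] = np.asarray(x_internal, dtype=float)
        for n in self.external_names:
            if n not in external:
                raise ModelError(f"external species {n!r} has no value")
            x[self.species_index[n]] = float(external[n])
        return x

    def __repr__(self):
        return (f"MetabolicNetwork({self.name!r}, "
                f"{len(self.internal_names)} internal + "
                f"{len(self.external_names)} external species, "
                f"{len(self.reactions)} reactions)")


def _as_fraction(c) -> Fraction:
    if isinstance(c, Fraction):
        return c
    if isinstance(c, str):
        return Fraction(c)
    if isinstance(c, (int, np.integer)):
        return Fraction(int(c))
    return Fraction(c).limit_denominator(10**12)


# -- operations ---------------------------------------------------------------


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "fatal" | "warning" | "info"
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue]

    @property
    def passed(self) -> bool:
        return not any(i.severity == "fatal" for i in self.issues)

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def __str__(self):
        if not self.issues:
            return "validation passed (no issues)"
        return "\n".join(f"[{i.severity}] {i.message}" for i in self.issues)


def validate_network(net: MetabolicNetwork) -> ValidationReport:
    """Structural and symbolic checks; a passing report (no fatal issues)
    is expected by every downstream operation."""
    issues: list[ValidationIssue] = []

    nI, m = len(net.internal_names), len(net.reactions)
    if len(net.N) != nI or (nI and len(net.N[0]) != m):
        issues.append(ValidationIssue(
            "fatal", f"stoichiometry is {len(net.N)}x"
            f"{len(net.N[0]) if net.N else 0}, expected {nI}x{m}"))
        return ValidationReport(issues)

    if net.mu <= 0:
        issues.append(ValidationIssue("fatal", f"mu must be > 0, got {net.mu}"))

    # orphan internal species: in no reaction with nonzero stoichiometry
    for i, name in enumerate(net.internal_names):
        if all(c == 0 for c in net.N[i]):
            issues.append(ValidationIssue(
                "warning", f"orphan species {name!r}: zero row in N"))
    # externals that appear in no rate law are inert
    used = set()
    for expr in net.f_exprs:
        used |= {str(s) for s in expr.free_symbols}
    for name in net.external_names:
        if name not in used:
            issues.append(ValidationIssue(
                "warning", f"external species {name!r} appears in no rate law"))

    # row rank of N (rational arithmetic)
    if nI:
        Nmat = sp.Matrix([[sp.Rational(c) for c in row] for row in net.N])
        if Nmat.rank() < nI:
            issues.append(ValidationIssue(
                "warning", "stoichiometry matrix is row-rank deficient "
                "(conserved moiety or redundant balance)"))

    # differentiability of each rate law in every species on the open
    # positive orthant: symbolic differentiation must succeed
    for rid, expr in zip(net.reaction_ids, net.f_exprs):
        for s in net.species_symbols:
            try:
                sp.diff(expr, s)
            except Exception:  # pragma: no cover - sympy rarely fails here
                issues.append(ValidationIssue(
                    "fatal", f"rate law {rid!r} not symbolically "
                    f"differentiable in {s}"))
    return ValidationReport(issues)


def reaction_rates(net: MetabolicNetwork, x, e,
                   params: Mapping[str, float] | None = None) -> np.ndarray:
    """v_j = e_j * f_j(x) for a full concentration vector ``x`` and enzyme
    vector ``e`` (one entry per reaction)."""
    e = np.asarray(e, dtype=float)
    if e.shape != (net.n_reactions,):
        raise ModelError(f"expected enzyme vector of length "
                         f"{net.n_reactions}, got shape {e.shape}")
    return e * net.rate_factors(x, params)


def metabolite_balances(net: MetabolicNetwork, x, e,
                        params: Mapping[str, float] | None = None) -> np.ndarray:
    """dx_I/dt = N v, restricted to internal species (externals are held
    fixed by the environment, their balance is identically zero)."""
    v = reaction_rates(net, x, e, params)
    return net.N_float @ v


# -- config file I/O ----------------------------------------------------------

def _coef_repr(c: Fraction):
    return int(c) if c.denominator == 1 else f"{c.numerator}/{c.denominator}"


def dump_model(net: MetabolicNetwork) -> str:
    """Serialise a network to the YAML model format (lossless for rational
    stoichiometric coefficients; rate-law expression strings are written
    back verbatim)."""
    stoich = {}
    for j, rid in enumerate(net.reaction_ids):
        contrib = {}
        for i, sname in enumerate(net.internal_names):
            c = net.N[i][j]
            if c != 0:
                contrib[sname] = _coef_repr(c)
        stoich[rid] = contrib
    doc = {
        "name": net.name,
        "mu": net.mu,
        "species": [{"name": s.name, "role": s.role} for s in net.species],
        "reactions": [
            {"id": r.reaction_id, "expression": r.expression,
             "parameters": dict(r.parameters)}
            for r in net.reactions
        ],
        "stoichiometry": stoich,
    }
    if net.adjustable_params:
        doc["adjustable_parameters"] = dict(net.adjustable_params)
    return yaml.safe_dump(doc, sort_keys=False)


def load_model(text: str) -> MetabolicNetwork:
    """Parse a network from YAML model text (inverse of :func:`dump_model`)."""
    doc = yaml.safe_load(text)
    species = [Species(d["name"], d["role"]) for d in doc["species"]]
    reactions = [RateLaw(d["id"], d["expression"],
                         dict(d.get("parameters") or {}))
                 for d in doc["reactions"]]
    stoich = {rid: {s: _as_fraction(c) for s, c in (contrib or {}).items()}
              for rid, contrib in doc["stoichiometry"].items()}
    return MetabolicNetwork(
        species, reactions, stoich, mu=float(doc.get("mu", 1.0)),
        adjustable_params=doc.get("adjustable_parameters"),
        name=doc.get("name", "network"))


def write_model(net: MetabolicNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write(dump_model(net))


def read_model(path) -> MetabolicNetwork:
    with open(path) as fh:
        return load_model(fh.read())
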