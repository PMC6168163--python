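"""Elementary Flux Modes.

An EFM is a steady-state flux vector V (N·V = 0) whose support — the set of
active reactions — is minimal: no other steady-state vector uses a strict
subset of its reactions.  The enzyme-cost optimisation is always carried out
within one EFM, with the remaining flux degree of freedom fixed by
normalising the designated output reaction to unit flux.

Enumeration uses exact rational arithmetic (sympy) and a combinatorial
support-minimality search, which is exhaustive and fast in the small-network
regime this package targets (m ≲ 12 reactions).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Sequence

import numpy as np
import sympy as sp

from .errors import ModelError, QoracError
from .network import MetabolicNetwork

__all__ = ["FluxMode", "enumerate_efms", "is_elementary", "modes_to_table"]


class NotInNullspaceError(QoracError):
    """The candidate flux vector does not satisfy N·V = 0."""


@dataclass(frozen=True)
class FluxMode:
    """A support-minimal steady-state flux vector.

    ``V`` holds exact rational relative fluxes; when the designated output
    reaction is in the support the vector is normalised so V_r = 1.
    """

    V: tuple[Fraction, ...]
    output_reaction: int = 0

    @property
    def support(self) -> frozenset[int]:
        return frozenset(j for j, v in enumerate(self.V) if v != 0)

    @property
    def V_float(self) -> np.ndarray:
        return np.array([float(v) for v in self.V])

    def normalised(self, r: int | None = None) -> "FluxMode":
        """Rescale so flux through reaction ``r`` equals 1 (requires r in
        the support)."""
        r = self.output_reaction if r is None else r
        if self.V[r] == 0:
            raise ModelError(f"cannot normalise: reaction {r} not in support")
        scale = self.V[r]
        return FluxMode(tuple(v / scale for v in self.V), output_reaction=r)


def _rational_matrix(net: MetabolicNetwork) -> sp.Matrix:
    return sp.Matrix([[sp.Rational(c.numerator, c.denominator)
                       for c in row] for row in net.N])


def _nullspace_cols(Nmat: sp.Matrix, cols: Sequence[int]) -> list[sp.Matrix]:
    if not cols:
        return []
    sub = Nmat[:, list(cols)]
    return sub.nullspace()


def _sign_ok(vec: Sequence[Fraction], cols: Sequence[int],
             reversibilities: Sequence[bool]) -> bool:
    return all(reversibilities[j] or vec[k] > 0
               for k, j in enumerate(cols))


def enumerate_efms(net: MetabolicNetwork,
                   reversibilities: Sequence[bool] | None = None,
                   output_reaction: int | None = None) -> list[FluxMode]:
    """All elementary flux modes of ``net``, exact and up to scaling.

    Parameters
    ----------
    reversibilities:
        Per-reaction flags; an irreversible reaction (False) must carry
        nonnegative flux.  Default: all reversible.
    output_reaction:
        Column index whose flux is normalised to 1 whenever it lies in a
        mode's support; modes not containing it keep the canonical sign
        convention (first support entry positive).

    Returns supports in increasing size; infeasible sign constraints simply
    yield an empty list.  Each geometric mode of a fully reversible network
    is returned once (canonical sign), since the control framework handles
    flow reversal dynamically rather than by duplicating orientations.
    """
    m = net.n_reactions
    if m > 24:
        raise ModelError("combinatorial EFM enumeration is limited to small "
                         f"networks (m <= 24), got m = {m}")
    if reversibilities is None:
        reversibilities = [True] * m
    Nmat = _rational_matrix(net)

    modes: list[FluxMode] = []
    found_supports: list[frozenset[int]] = []
    for size in range(1, m + 1):
        for cols in combinations(range(m), size):
            cset = frozenset(cols)
            if any(s <= cset for s in found_supports):
                continue  # a smaller steady-state support fits inside
            null = _nullspace_cols(Nmat, cols)
            if len(null) != 1:
                continue  # empty: no steady state; >1: support not minimal
            vec = [Fraction(sp.nsimplify(x).p, sp.nsimplify(x).q)
                   for x in null[0]]
            if any(v == 0 for v in vec):
                continue  # true support is smaller; found at a smaller size
            found_supports.append(cset)
            full = [Fraction(0)] * m
            for k, j in enumerate(cols):
                full[j] = vec[k]
            # orient: sign constraints first, else canonical
            if _sign_ok(vec, cols, reversibilities):
                pass
            elif _sign_ok([-v for v in vec], cols, reversibilities):
                full = [-v for v in full]
            else:
                continue  # infeasible under the sign constraints
            if full[min(cols)] < 0 and all(reversibilities[j] for j in cols):
                full = [-v for v in full]
            mode = FluxMode(tuple(full),
                            output_reaction=output_reaction
                            if output_reaction is not None else min(cols))
            if output_reaction is not None and full[output_reaction] != 0:
                mode = mode.normalised(output_reaction)
            modes.append(mode)
    return modes


def is_elementary(net: MetabolicNetwork, V: Sequence,
                  tol: float = 1e-10) -> tuple[bool, frozenset[int] | None]:
    """Support-minimality test with certificate.

    Returns ``(True, None)`` when no steady-state vector lives on a strict
    sub-support of V, else ``(False, sub_support)`` naming a violating
    sub-support.  The zero vector is not elementary by convention.
    Raises :class:`NotInNullspaceError` when N·V ≠ 0.
    """
    Vf = [_to_fraction(v) for v in V]
    if len(Vf) != net.n_reactions:
        raise ModelError("flux vector length mismatch")
    Nmat = _rational_matrix(net)
    resid = Nmat * sp.Matrix(
        [sp.Rational(v.numerator, v.denominator) for v in Vf])
    if any(abs(float(r)) > tol for r in resid):
        raise NotInNullspaceError("N·V != 0 for the candidate flux vector")
    support = [j for j, v in enumerate(Vf) if v != 0]
    if not support:
        return False, frozenset()
    for size in range(1, len(support)):
        for cols in combinations(support, size):
            if _nullspace_cols(Nmat, cols):
                return False, frozenset(cols)
    return True, None


def _to_fraction(v) -> Fraction:
    if isinstance(v, Fraction):
        return v
    if isinstance(v, (int, np.integer)):
        return Fraction(int(v))
    if isinstance(v, str):
        return Fraction(v)
    return Fraction(v).limit_denominator(10**9)


def modes_to_table(net: MetabolicNetwork, modes: Sequence[FluxMode]):
    """EFMs as a tidy table (one row per mode x reaction coefficient)."""
    import pandas as pd

    rows = []
    for k, mode in enumerate(modes):
        for j, rid in enumerate(net.reaction_ids):
            rows.append({"mode": k, "reaction": rid,
                         "coefficient": float(mode.V[j])})
    return pd.DataFrame(rows)
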