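"""Conservation laws (non-negative P-invariants) and species amount bounds.

A conservation law is a non-negative integer vector y with yᵀN = 0, where
N is the net stoichiometric matrix; the linear combination y·x is then
constant along every trajectory of either semantics.  Laws are enumerated
exactly over the integers with a Farkas-style elimination, one reaction
column at a time, so bounds are exact for integer initial amounts.
"""

from __future__ import annotations

import math
from math import gcd

import numpy as np

from .network import ReactionNetwork

__all__ = ["conservation_laws", "conservation_bounds"]

_MAX_ROWS = 200_000  # guard against combinatorial blow-up


def _reduce(row: tuple[int, ...]) -> tuple[int, ...]:
    g = 0
    for v in row:
        g = gcd(g, v)
    return row if g in (0, 1) else tuple(v // g for v in row)


def conservation_laws(net: ReactionNetwork) -> list[tuple[int, ...]]:
    """Non-negative integer left-null vectors of the net stoichiometry.

    Returns generating vectors y (length n_species, entries >= 0, not all
    zero) with yᵀN = 0, scaled to smallest integers.  The result is
    deterministic for a given network.
    """
    n = net.net_stoichiometry()  # (n_species, n_reactions)
    ns, nr = n.shape
    # rows: (y, image = yᵀN), all exact ints
    rows: list[tuple[tuple[int, ...], tuple[int, ...]]] = [
        (tuple(int(i == k) for i in range(ns)), tuple(int(v) for v in n[k]))
        for k in range(ns)
    ]
    for j in range(nr):
        zero = [(y, im) for y, im in rows if im[j] == 0]
        pos = [(y, im) for y, im in rows if im[j] > 0]
        neg = [(y, im) for y, im in rows if im[j] < 0]
        combos = []
        for yp, imp in pos:
            for yn, imn in neg:
                a, b = imp[j], -imn[j]
                y = _reduce(tuple(b * p + a * q for p, q in zip(yp, yn)))
                im = tuple(b * p + a * q for p, q in zip(imp, imn))
                g = 0
                for v in y:
                    g = gcd(g, v)
                combos.append((y, tuple(v // max(g, 1) for v in im) if g > 1 else im))
        rows = zero + combos
        # dedupe on the invariant vector
        seen: dict[tuple[int, ...], tuple[int, ...]] = {}
        for y, im in rows:
            seen.setdefault(y, im)
        rows = list(seen.items())
        if len(rows) > _MAX_ROWS:
            raise RuntimeError(
                f"conservation-law enumeration exceeded {_MAX_ROWS} intermediate rows"
            )
    return [y for y, _ in rows if any(y)]


def conservation_bounds(net: ReactionNetwork) -> dict[str, float]:
    """Upper bounds on reachable species amounts from conservation laws.

    For each species i, the bound is min over laws y with y_i > 0 of
    floor((y · x0) / y_i); species covered by no law are reported as
    ``math.inf`` (unbounded), never as an exception.  Requires integer
    initial amounts.
    """
    x0 = net.integer_initial_state()
    laws = conservation_laws(net)
    bounds: dict[str, float] = {}
    for i, name in enumerate(net.species_names):
        best = math.inf
        for y in laws:
            if y[i] > 0:
                total = int(np.dot(y, x0))
                best = min(best, total // y[i])
        bounds[name] = best
    return bounds
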