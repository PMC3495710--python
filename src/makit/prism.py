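"""Export of a reaction network as a CTMC model in the PRISM input language.

One bounded integer variable per species, one guarded command per
reaction.  Variable bounds come from exact conservation analysis
(:func:`makit.conservation.conservation_bounds`); a species not covered by
any conservation law has no finite bound and the export is refused.
The output is byte-stable for a given network, so it can be kept under a
golden-file test.
"""

from __future__ import annotations

import math

from .conservation import conservation_bounds
from .network import NetworkValidationError, Reaction, ReactionNetwork

__all__ = ["UnboundedSpeciesError", "to_prism_language"]


class UnboundedSpeciesError(NetworkValidationError):
    """A species has no finite reachable-amount bound."""


def _propensity_expr(r: Reaction) -> str:
    """Stochastic mass-action propensity: k * falling factorials."""
    factors = [f"k_{r.label}"]
    for name, s in sorted(r.reactants.items()):
        for i in range(s):
            factors.append(name if i == 0 else f"({name}-{i})")
    return "*".join(factors)


def to_prism_language(net: ReactionNetwork, model_name: str = "network") -> str:
    """Render the network as PRISM-language CTMC source text."""
    bounds = conservation_bounds(net)
    unbounded = [n for n, b in bounds.items() if not math.isfinite(b)]
    if unbounded:
        raise UnboundedSpeciesError(
            f"species without a finite conservation bound: {', '.join(unbounded)}; "
            "cannot declare bounded PRISM variables"
        )
    x0 = net.integer_initial_state()

    lines = ["ctmc", ""]
    for r in net.reactions:
        lines.append(f"const double k_{r.label} = {r.rate!r};")
    if net.reactions:
        lines.append("")
    lines.append(f"module {model_name}")
    for i, s in enumerate(net.species):
        lines.append(f"  {s.name} : [0..{int(bounds[s.name])}] init {int(x0[i])};")
    if net.reactions:
        lines.append("")
    for r in net.reactions:
        guards = []
        for name, s in sorted(r.reactants.items()):
            guards.append(f"({name}>={s})")
        net_change = {}
        for name, s in r.reactants.items():
            net_change[name] = net_change.get(name, 0) - s
        for name, s in r.products.items():
            net_change[name] = net_change.get(name, 0) + s
        for name in sorted(net_change):
            if net_change[name] > 0:
                guards.append(f"({name}<={int(bounds[name]) - net_change[name]})")
        if not guards:
            guards.append("true")
        updates = [
            f"({name}'={name}{net_change[name]:+d})"
            for name in sorted(net_change)
            if net_change[name] != 0
        ]
        if not updates:  # catalytic no-op reaction: self-loop
            updates = [f"({net.species_names[0]}'={net.species_names[0]})"]
        lines.append(
            f"  [{r.label}] {' & '.join(guards)} -> "
            f"{_propensity_expr(r)} : {' & '.join(updates)};"
        )
    lines.append("endmodule")
    lines.append("")
    return "\n".join(lines)
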