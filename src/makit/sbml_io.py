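"""Restricted SBML Level 2 import.

Supported subset: a single compartment, species given as amounts
(``initialAmount``), and irreversible reactions whose kinetic law is a
pure mass-action product ``k * reactant_1 * ... * reactant_m`` (with
``power`` allowed for stoichiometries > 1).  The rate constant may be a
local kinetic-law parameter, a global model parameter, or a numeric
literal.  Anything outside this subset is rejected with
:class:`SBMLImportError` rather than approximated.
"""

from __future__ import annotations

from collections import Counter

from lxml import etree

from .network import NetworkValidationError, Reaction, ReactionNetwork, Species

__all__ = ["SBMLImportError", "network_from_sbml"]

_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


class SBMLImportError(NetworkValidationError):
    """The document is not valid restricted SBML."""


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _children(node, name: str):
    if node is None:
        return []
    return [c for c in node if isinstance(c.tag, str) and _local(c.tag) == name]


def _find(node, *path):
    for name in path:
        hits = _children(node, name)
        if not hits:
            return None
        node = hits[0]
    return node


def _parse_mass_action_factors(math_root, label: str):
    """Decompose the kinetic-law MathML into (constant factors, species powers).

    Accepts a bare <ci>/<cn>, or <apply><times/> over <ci>, <cn> and
    <apply><power/><ci/><cn/></apply> factors.  Returns a list of constant
    identifiers/values and a Counter of species-name exponents.
    """
    exprs = [c for c in math_root if isinstance(c.tag, str)]
    if len(exprs) != 1:
        raise SBMLImportError(f"reaction {label!r}: kinetic law math must be a single expression")
    expr = exprs[0]

    if _local(expr.tag) in ("ci", "cn"):
        factors = [expr]
    elif _local(expr.tag) == "apply":
        op = next(iter(expr), None)
        if op is None or _local(op.tag) != "times":
            raise SBMLImportError(
                f"reaction {label!r}: kinetic law is not a mass-action product"
            )
        factors = list(expr)[1:]
    else:
        raise SBMLImportError(f"reaction {label!r}: kinetic law is not a mass-action product")

    constants: list = []
    powers: Counter[str] = Counter()
    for f in factors:
        tag = _local(f.tag)
        if tag == "ci":
            constants.append(f.text.strip())  # may be a species; resolved by caller
        elif tag == "cn":
            constants.append(float(f.text))
        elif tag == "apply":
            parts = list(f)
            if (
                len(parts) != 3
                or _local(parts[0].tag) != "power"
                or _local(parts[1].tag) != "ci"
                or _local(parts[2].tag) != "cn"
            ):
                raise SBMLImportError(
                    f"reaction {label!r}: only integer powers of species are supported"
                )
            exponent = float(parts[2].text)
            if exponent != int(exponent) or exponent < 1:
                raise SBMLImportError(
                    f"reaction {label!r}: non-integer power in kinetic law"
                )
            powers[parts[1].text.strip()] += int(exponent)
        else:
            raise SBMLImportError(
                f"reaction {label!r}: unsupported kinetic law term <{tag}>"
            )
    return constants, powers


def network_from_sbml(text: str) -> ReactionNetwork:
    """Parse a restricted-SBML document into a :class:`ReactionNetwork`."""
    try:
        root = etree.fromstring(text.encode() if isinstance(text, str) else text)
    except etree.XMLSyntaxError as exc:
        raise SBMLImportError(f"malformed XML: {exc}") from exc
    model = _find(root, "model")
    if model is None:
        raise SBMLImportError("no <model> element")

    compartments = _children(_find(model, "listOfCompartments"), "compartment")
    if len(compartments) > 1:
        raise SBMLImportError("only single-compartment models are supported")

    species: list[Species] = []
    for s in _children(_find(model, "listOfSpecies"), "species"):
        sid = s.get("id")
        if sid is None:
            raise SBMLImportError("species without id")
        if s.get("initialConcentration") is not None:
            raise SBMLImportError(
                f"species {sid!r}: concentrations are not supported, use initialAmount"
            )
        species.append(Species(sid, float(s.get("initialAmount", 0.0))))
    species_ids = {s.name for s in species}

    global_params = {
        p.get("id"): float(p.get("value"))
        for p in _children(_find(model, "listOfParameters"), "parameter")
        if p.get("id") is not None and p.get("value") is not None
    }
    compartment_ids = {c.get("id") for c in compartments}

    reactions: list[Reaction] = []
    for rx in _children(_find(model, "listOfReactions"), "reaction"):
        label = rx.get("id")
        if label is None:
            raise SBMLImportError("reaction without id")
        # SBML defaults reversible="true"; the subset needs it explicit and false.
        if rx.get("reversible", "true").lower() != "false":
            raise SBMLImportError(
                f"reaction {label!r}: reversible reactions are not supported; "
                "split into two irreversible reactions"
            )

        def _refs(list_name: str) -> dict[str, int]:
            out: Counter[str] = Counter()
            for ref in _children(_find(rx, list_name), "speciesReference"):
                stoich = float(ref.get("stoichiometry", 1))
                if stoich != int(stoich) or stoich < 1:
                    raise SBMLImportError(
                        f"reaction {label!r}: non-integer stoichiometry"
                    )
                out[ref.get("species")] += int(stoich)
            return dict(out)

        reactants = _refs("listOfReactants")
        products = _refs("listOfProducts")

        klaw = _find(rx, "kineticLaw")
        if klaw is None:
            raise SBMLImportError(f"reaction {label!r}: missing kinetic law")
        local_params = {
            p.get("id"): float(p.get("value"))
            for p in _children(_find(klaw, "listOfParameters"), "parameter")
            if p.get("id") is not None and p.get("value") is not None
        }
        math = _find(klaw, "math")
        if math is None or math.tag != f"{{{_MATHML_NS}}}math":
            raise SBMLImportError(f"reaction {label!r}: missing MathML kinetic law")

        raw_constants, powers = _parse_mass_action_factors(math, label)

        # Resolve bare <ci> factors: species contribute a power, parameters
        # the rate constant; compartment factors are rejected (amount scale).
        constants: list[float] = []
        for c in raw_constants:
            if isinstance(c, float):
                constants.append(c)
            elif c in species_ids:
                powers[c] += 1
            elif c in local_params:
                constants.append(local_params[c])
            elif c in global_params:
                constants.append(global_params[c])
            elif c in compartment_ids:
                raise SBMLImportError(
                    f"reaction {label!r}: compartment-scaled kinetic laws are not "
                    "supported (models must be on the amount scale)"
                )
            else:
                raise SBMLImportError(
                    f"reaction {label!r}: unresolved identifier {c!r} in kinetic law"
                )
        if len(constants) != 1:
            raise SBMLImportError(
                f"reaction {label!r}: kinetic law must have exactly one rate "
                f"constant factor, found {len(constants)}"
            )
        if dict(powers) != reactants:
            raise SBMLImportError(
                f"reaction {label!r}: kinetic law {dict(powers)} does not match "
                f"the mass-action form for reactants {reactants}"
            )
        reactions.append(Reaction(label, reactants, products, constants[0]))

    return ReactionNetwork(species, reactions)
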