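"""Reaction-network models with mass-action kinetics.

A :class:`ReactionNetwork` is an ordered list of species (with initial
amounts) and an ordered list of irreversible reactions, each carrying a
single mass-action rate constant.  Species order is fixed and defines the
coordinates of every state vector in the toolkit, for both the
deterministic (ODE) and the stochastic (CTMC) semantics.

Amounts are molecule-count-like numbers shared by both semantics (volume
factor 1), so rate constants carry over verbatim between the ODE and the
CTMC interpretation of the same model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "NetworkValidationError",
    "enzymatic_fixture",
    "set_parameters",
    "save_network",
    "load_network",
]


class NetworkValidationError(ValueError):
    """A model document or network violates a structural invariant."""


@dataclass(frozen=True)
class Species:
    """A chemical species with its initial amount.

    ``initial`` is a non-negative real; stochastic analyses additionally
    require it to be integer-valued (a molecule count).
    """

    name: str
    initial: float

    def __post_init__(self) -> None:
        if not self.name:
            raise NetworkValidationError("species name must be non-empty")
        if not np.isfinite(self.initial) or self.initial < 0:
            raise NetworkValidationError(
                f"initial amount of {self.name!r} must be finite and >= 0, "
                f"got {self.initial}"
            )


def _validate_stoichiometry(label: str, side: str, stoich: Mapping[str, int]) -> dict:
    out = {}
    for name, s in stoich.items():
        if not (isinstance(s, (int, np.integer)) and s > 0):
            raise NetworkValidationError(
                f"reaction {label!r}: {side} stoichiometry of {name!r} "
                f"must be a positive integer, got {s!r}"
            )
        out[name] = int(s)
    return out


@dataclass(frozen=True)
class Reaction:
    """An irreversible reaction with a mass-action rate constant.

    ``reactants`` and ``products`` map species names to positive integer
    stoichiometries; they may not both be empty.  The reaction fires at
    rate ``rate * prod_j x_j^{s_j}`` in the ODE semantics and at propensity
    ``rate * prod_j x_j (x_j-1) ... (x_j-s_j+1)`` in the CTMC semantics.
    """

    label: str
    reactants: Mapping[str, int] = field(default_factory=dict)
    products: Mapping[str, int] = field(default_factory=dict)
    rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.label:
            raise NetworkValidationError("reaction label must be non-empty")
        object.__setattr__(
            self, "reactants", _validate_stoichiometry(self.label, "reactant", self.reactants)
        )
        object.__setattr__(
            self, "products", _validate_stoichiometry(self.label, "product", self.products)
        )
        if not self.reactants and not self.products:
            raise NetworkValidationError(
                f"reaction {self.label!r}: reactants and products cannot both be empty"
            )
        if not np.isfinite(self.rate) or self.rate < 0:
            raise NetworkValidationError(
                f"reaction {self.label!r}: rate constant must be finite and >= 0, "
                f"got {self.rate}"
            )


class ReactionNetwork:
    """An ordered collection of species and mass-action reactions."""

    def __init__(self, species: Iterable[Species], reactions: Iterable[Reaction]):
        self.species: tuple[Species, ...] = tuple(species)
        self.reactions: tuple[Reaction, ...] = tuple(reactions)

        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise NetworkValidationError("duplicate species names")
        labels = [r.label for r in self.reactions]
        if len(set(labels)) != len(labels):
            raise NetworkValidationError("duplicate reaction labels")

        self._index = {n: i for i, n in enumerate(names)}
        known = set(names)
        for r in self.reactions:
            for name in (*r.reactants, *r.products):
                if name not in known:
                    raise NetworkValidationError(
                        f"reaction {r.label!r} references undeclared species {name!r}"
                    )

    # -- basic accessors -------------------------------------------------

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown species {name!r}") from None

    def reaction(self, label: str) -> Reaction:
        for r in self.reactions:
            if r.label == label:
                return r
        raise KeyError(f"unknown reaction {label!r}")

    def rate_constants(self) -> dict[str, float]:
        """Rate constants keyed by reaction label, in reaction order."""
        return {r.label: r.rate for r in self.reactions}

    # -- state vectors and stoichiometry ---------------------------------

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial for s in self.species], dtype=float)

    def integer_initial_state(self) -> np.ndarray:
        x0 = self.initial_state()
        if not np.all(x0 == np.round(x0)):
            raise NetworkValidationError(
                "stochastic semantics requires integer initial amounts"
            )
        return x0.astype(np.int64)

    def reactant_matrix(self) -> np.ndarray:
        """Reactant stoichiometries, shape (n_species, n_reactions)."""
        m = np.zeros((self.n_species, self.n_reactions), dtype=np.int64)
        for j, r in enumerate(self.reactions):
            for name, s in r.reactants.items():
                m[self._index[name], j] = s
        return m

    def product_matrix(self) -> np.ndarray:
        m = np.zeros((self.n_species, self.n_reactions), dtype=np.int64)
        for j, r in enumerate(self.reactions):
            for name, s in r.products.items():
                m[self._index[name], j] = s
        return m

    def net_stoichiometry(self) -> np.ndarray:
        """Net stoichiometric matrix N = products - reactants."""
        return self.product_matrix() - self.reactant_matrix()

    # -- functional updates ----------------------------------------------

    def with_initial(self, name: str, amount: float) -> "ReactionNetwork":
        """A copy with one species' initial amount replaced."""
        i = self.species_index(name)
        species = list(self.species)
        species[i] = Species(name, amount)
        return ReactionNetwork(species, self.reactions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return self.species == other.species and self.reactions == other.reactions

    def __repr__(self) -> str:
        return (
            f"ReactionNetwork({self.n_species} species, "
            f"{self.n_reactions} reactions)"
        )


def set_parameters(net: ReactionNetwork, assignments: Mapping[str, float]) -> ReactionNetwork:
    """Return a new network with the given rate constants replaced.

    ``assignments`` maps reaction labels to new non-negative rate
    constants.  The input network is left unmodified; unknown labels and
    negative values raise :class:`NetworkValidationError`.
    """
    labels = {r.label for r in net.reactions}
    for label, value in assignments.items():
        if label not in labels:
            raise NetworkValidationError(f"unknown reaction label {label!r}")
        if not np.isfinite(value) or value < 0:
            raise NetworkValidationError(
                f"rate constant for {label!r} must be finite and >= 0, got {value}"
            )
    reactions = [
        Reaction(r.label, r.reactants, r.products, float(assignments.get(r.label, r.rate)))
        for r in net.reactions
    ]
    return ReactionNetwork(net.species, reactions)


def enzymatic_fixture() -> ReactionNetwork:
    """The built-in enzymatic reaction model E + S <-> ES -> E + P.

    Reaction r1 (association, k1 = 0.184) binds enzyme and substrate into
    the complex ES, r2 (dissociation, k2 = 0.016) releases them, and r3
    (conversion, k3 = 0.211) turns the complex into enzyme plus product.
    Initial amounts: S = 12, E = 10, ES = 0, P = 0.
    """
    return ReactionNetwork(
        species=[
            Species("S", 12),
            Species("E", 10),
            Species("ES", 0),
            Species("P", 0),
        ],
        reactions=[
            Reaction("r1", {"E": 1, "S": 1}, {"ES": 1}, 0.184),
            Reaction("r2", {"ES": 1}, {"E": 1, "S": 1}, 0.016),
            Reaction("r3", {"ES": 1}, {"E": 1, "P": 1}, 0.211),
        ],
    )


# -- native JSON serialization -------------------------------------------


def save_network(net: ReactionNetwork) -> str:
    """Serialize a network to the native JSON dialect.

    Species and reaction order are preserved; order is semantically
    meaningful (it fixes state-vector coordinates).
    """
    doc = {
        "species": [{"name": s.name, "initial": s.initial} for s in net.species],
        "reactions": [
            {
                "label": r.label,
                "reactants": dict(r.reactants),
                "products": dict(r.products),
                "k": r.rate,
            }
            for r in net.reactions
        ],
    }
    return json.dumps(doc, indent=2)


def _network_from_json(text: str) -> ReactionNetwork:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise NetworkValidationError(f"malformed JSON model: {exc}") from exc
    if not isinstance(doc, dict) or "species" not in doc or "reactions" not in doc:
        raise NetworkValidationError("JSON model must have 'species' and 'reactions'")
    try:
        species = [Species(s["name"], float(s["initial"])) for s in doc["species"]]
        reactions = [
            Reaction(
                r["label"],
                {k: int(v) for k, v in r.get("reactants", {}).items()},
                {k: int(v) for k, v in r.get("products", {}).items()},
                float(r["k"]),
            )
            for r in doc["reactions"]
        ]
    except (KeyError, TypeError) as exc:
        raise NetworkValidationError(f"malformed JSON model: {exc}") from exc
    return ReactionNetwork(species, reactions)


def load_network(text: str, format: str = "native-json") -> ReactionNetwork:
    """Parse a model document into a validated :class:`ReactionNetwork`.

    ``format`` is ``"native-json"`` or ``"sbml"`` (restricted subset; see
    :mod:`makit.sbml_io`).  Round-trips with :func:`save_network` for
    native JSON.
    """
    if format == "native-json":
        return _network_from_json(text)
    if format == "sbml":
        from .sbml_io import network_from_sbml

        return network_from_sbml(text)
    raise ValueError(f"unknown model format {format!r}")
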