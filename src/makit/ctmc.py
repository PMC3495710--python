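"""Stochastic (CTMC) semantics and expected-reward model checking.

States are integer species-amount vectors; each reaction fires at the
stochastic mass-action propensity ``k * prod_j x_j (x_j-1)...(x_j-s_j+1)``
(falling factorial per reactant stoichiometry, no volume scaling).  The
module provides:

* exhaustive breadth-first enumeration of the reachable state space,
* the almost-sure limiting amount of a species via bottom strongly
  connected components (BSCCs),
* the expected accumulated count of a designated reaction's firings until
  a target predicate first holds (an impulse-reward reachability query,
  R{#r}=? [F target]), solved exactly as a sparse linear system on the
  embedded jump chain, and
* a Gillespie direct-method simulator as an independent stochastic
  estimator of the same quantity.

The half-max query builder realizes the EC50-motivated question "how many
firings of the association reaction before the product reaches 50% of its
limiting amount".
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix, identity
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .network import ReactionNetwork

__all__ = [
    "Transition",
    "StateSpace",
    "TargetPredicate",
    "RewardSpec",
    "StateSpaceCapExceeded",
    "LimitUndefinedError",
    "enumerate_states",
    "limiting_amount",
    "expected_reward_to_target",
    "make_half_max_query",
    "half_max_expected_reward",
    "ssa_expected_count",
    "efficiency_sweep",
]


class StateSpaceCapExceeded(RuntimeError):
    def __init__(self, cap: int, reached: int):
        super().__init__(
            f"state-space cap of {cap} states exceeded (enumerated {reached} so far)"
        )
        self.cap = cap
        self.reached = reached


class LimitUndefinedError(ValueError):
    """The species amount has no almost-sure long-run constant value."""


class Transition(NamedTuple):
    src: int
    dst: int
    rate: float
    label: str


@dataclass
class StateSpace:
    """Enumerated CTMC: states in BFS discovery order plus rate transitions."""

    species: tuple[str, ...]
    states: np.ndarray  # (n_states, n_species) integer amounts
    initial_index: int
    transitions: list[Transition]

    @property
    def n_states(self) -> int:
        return len(self.states)

    def species_index(self, name: str) -> int:
        try:
            return self.species.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def adjacency(self) -> csr_matrix:
        """Boolean adjacency of the transition graph."""
        n = self.n_states
        if not self.transitions:
            return csr_matrix((n, n))
        src = [t.src for t in self.transitions]
        dst = [t.dst for t in self.transitions]
        return csr_matrix((np.ones(len(src)), (src, dst)), shape=(n, n))

    def states_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.species))
        df.insert(0, "state", np.arange(self.n_states))
        return df

    def transitions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [t._asdict() for t in self.transitions],
            columns=["src", "dst", "rate", "label"],
        )


@dataclass(frozen=True)
class TargetPredicate:
    """Target state set: amount of one species >= (or >) a threshold."""

    species: str
    comparator: str  # ">=" or ">"
    threshold: int

    def __post_init__(self) -> None:
        if self.comparator not in (">=", ">"):
            raise ValueError(f"comparator must be '>=' or '>', got {self.comparator!r}")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")

    def holds(self, amount: int) -> bool:
        return amount >= self.threshold if self.comparator == ">=" else amount > self.threshold

    def mask(self, space: StateSpace) -> np.ndarray:
        col = space.states[:, space.species_index(self.species)]
        return col >= self.threshold if self.comparator == ">=" else col > self.threshold


@dataclass(frozen=True)
class RewardSpec:
    """Impulse reward: 1 per firing of the counted reaction."""

    counted_reaction: str


def _propensity(k: float, state: np.ndarray, reactant_stoich: np.ndarray) -> float:
    """Stochastic mass-action propensity with falling factorials."""
    a = k
    for j in np.nonzero(reactant_stoich)[0]:
        s = reactant_stoich[j]
        x = state[j]
        if x < s:
            return 0.0
        for i in range(s):
            a *= x - i
    return a


def enumerate_states(net: ReactionNetwork, cap: int = 1_000_000) -> StateSpace:
    """Breadth-first closure of the reachable state space.

    States are discovered in BFS order (deterministic for a given
    network); each transition stores its exact propensity and reaction
    label.  Raises :class:`StateSpaceCapExceeded` past ``cap`` states.
    """
    x0 = net.integer_initial_state()
    react = net.reactant_matrix().T  # (nr, ns)
    delta = net.net_stoichiometry().T  # (nr, ns)
    rates = [r.rate for r in net.reactions]
    labels = [r.label for r in net.reactions]

    index: dict[tuple, int] = {tuple(x0): 0}
    states: list[tuple] = [tuple(x0)]
    transitions: list[Transition] = []
    queue = deque([0])
    while queue:
        i = queue.popleft()
        x = np.array(states[i], dtype=np.int64)
        for r in range(len(rates)):
            a = _propensity(rates[r], x, react[r])
            if a <= 0:
                continue
            y = tuple(x + delta[r])
            j = index.get(y)
            if j is None:
                if len(states) >= cap:
                    raise StateSpaceCapExceeded(cap, len(states))
                j = len(states)
                index[y] = j
                states.append(y)
                queue.append(j)
            transitions.append(Transition(i, j, a, labels[r]))
    return StateSpace(
        species=net.species_names,
        states=np.array(states, dtype=np.int64),
        initial_index=0,
        transitions=transitions,
    )


def _bsccs(space: StateSpace) -> list[np.ndarray]:
    """Bottom strongly connected components (no edge leaving the SCC)."""
    n = space.n_states
    adj = space.adjacency()
    n_comp, comp = connected_components(adj, directed=True, connection="strong")
    leaves = np.zeros(n_comp, dtype=bool)
    for t in space.transitions:
        if comp[t.src] != comp[t.dst]:
            leaves[comp[t.src]] = True
    return [np.nonzero(comp == c)[0] for c in range(n_comp) if not leaves[c]]


def limiting_amount(space: StateSpace, species: str) -> int:
    """Almost-sure limit of a species amount as t -> infinity.

    The chain settles into some BSCC with probability 1; the limit is
    well defined only if the species is constant within every BSCC and
    that constant agrees across BSCCs.  Otherwise
    :class:`LimitUndefinedError` is raised.
    """
    col = space.states[:, space.species_index(species)]
    values = set()
    for members in _bsccs(space):
        vals = np.unique(col[members])
        if len(vals) > 1:
            raise LimitUndefinedError(
                f"species {species!r} varies within a recurrent class: {vals.tolist()}"
            )
        values.add(int(vals[0]))
    if len(values) != 1:
        raise LimitUndefinedError(
            f"species {species!r} has different long-run values across recurrent "
            f"classes: {sorted(values)}"
        )
    return values.pop()


def expected_reward_to_target(
    space: StateSpace, reward: RewardSpec, target: TargetPredicate
) -> float:
    """Expected firings of the counted reaction before the target holds.

    Computed on the embedded jump chain: for a non-target state s with
    exit rate E_s, x_s = sum over transitions s->s' of (rate/E_s) *
    (1[label == counted] + x_{s'}); x = 0 on target states.  If the target
    is reached with probability < 1 from the initial state (including
    deadlock first), the expected reward is ``math.inf``.
    """
    tmask = target.mask(space)
    if tmask[space.initial_index]:
        return 0.0
    n = space.n_states

    # which states can reach the target? (reverse BFS from target states)
    can_reach = tmask.copy()
    rev: list[list[int]] = [[] for _ in range(n)]
    for t in space.transitions:
        rev[t.dst].append(t.src)
    stack = list(np.nonzero(tmask)[0])
    while stack:
        v = stack.pop()
        for u in rev[v]:
            if not can_reach[u]:
                can_reach[u] = True
                stack.append(u)
    # every enumerated state is reachable from the initial state, so any
    # state that cannot reach the target witnesses reachability prob < 1
    if not can_reach.all():
        return math.inf

    nontarget = np.nonzero(~tmask)[0]
    pos = -np.ones(n, dtype=np.int64)
    pos[nontarget] = np.arange(len(nontarget))

    exit_rate = np.zeros(n)
    for t in space.transitions:
        exit_rate[t.src] += t.rate
    if np.any(exit_rate[nontarget] == 0):
        # deadlock before the target: unreachable, already excluded above,
        # but guard against a zero pivot regardless
        return math.inf

    rows, cols, vals = [], [], []
    b = np.zeros(len(nontarget))
    counted = reward.counted_reaction
    for t in space.transitions:
        if tmask[t.src]:
            continue
        i = pos[t.src]
        p = t.rate / exit_rate[t.src]
        if t.label == counted:
            b[i] += p
        if not tmask[t.dst]:
            rows.append(i)
            cols.append(pos[t.dst])
            vals.append(p)
    m = len(nontarget)
    P = csr_matrix((vals, (rows, cols)), shape=(m, m))
    A = (identity(m, format="csr") - P).tocsc()
    x = spsolve(A, b)
    if not np.all(np.isfinite(x)):
        raise RuntimeError("linear solve for expected reward produced non-finite values")
    return float(x[pos[space.initial_index]])


def make_half_max_query(
    net: ReactionNetwork,
    species: str = "P",
    counted_reaction: str = "r1",
    strict: bool = False,
    cap: int = 1_000_000,
) -> tuple[RewardSpec, TargetPredicate]:
    """Build the EC50-motivated half-max reward query for a network.

    Default (non-strict) reading: the species *reaches* 50% of its
    limiting amount, target ``species >= ceil(0.5 * limit)``.  With
    ``strict=True`` the target is ``species > 0.5 * limit``, i.e.
    ``species >= floor(0.5 * limit) + 1``.
    """
    net.reaction(counted_reaction)  # validate label
    limit = limiting_amount(enumerate_states(net, cap), species)
    if strict:
        threshold = math.floor(0.5 * limit) + 1
    else:
        threshold = math.ceil(0.5 * limit)
    return RewardSpec(counted_reaction), TargetPredicate(species, ">=", threshold)


def half_max_expected_reward(
    net: ReactionNetwork,
    species: str = "P",
    counted_reaction: str = "r1",
    strict: bool = False,
    cap: int = 1_000_000,
) -> float:
    """Convenience: expected counted-reaction firings to the half-max target."""
    space = enumerate_states(net, cap)
    limit = limiting_amount(space, species)
    threshold = math.floor(0.5 * limit) + 1 if strict else math.ceil(0.5 * limit)
    return expected_reward_to_target(
        space, RewardSpec(counted_reaction), TargetPredicate(species, ">=", threshold)
    )


def ssa_expected_count(
    net: ReactionNetwork,
    reward: RewardSpec,
    target: TargetPredicate,
    n_runs: int,
    seed: int,
    event_cap: int = 1_000_000,
) -> tuple[float, float]:
    """Gillespie direct-method estimate of the expected reward.

    Runs ``n_runs`` trajectories from the initial state, each counting
    firings of the counted reaction until the target first holds, and
    returns (sample mean, standard error).  Deterministic for a fixed
    seed.  A run that deadlocks or exceeds ``event_cap`` events without
    reaching the target aborts with ``RuntimeError`` — this indicates the
    target is reached with probability < 1 (infinite expected reward).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    x0 = net.integer_initial_state()
    react = net.reactant_matrix().T
    delta = net.net_stoichiometry().T
    rates = np.array([r.rate for r in net.reactions])
    labels = [r.label for r in net.reactions]
    counted = [i for i, lab in enumerate(labels) if lab == reward.counted_reaction]
    if not counted:
        raise KeyError(f"unknown reaction {reward.counted_reaction!r}")
    counted_idx = counted[0]
    sidx = net.species_index(target.species)
    nr = len(rates)

    counts = np.empty(n_runs)
    for run in range(n_runs):
        x = x0.copy()
        count = 0
        events = 0
        while not target.holds(int(x[sidx])):
            a = np.array([_propensity(rates[r], x, react[r]) for r in range(nr)])
            total = a.sum()
            if total <= 0:
                raise RuntimeError(
                    "SSA run deadlocked before reaching the target "
                    "(target reached with probability < 1)"
                )
            r = int(np.searchsorted(np.cumsum(a), rng.random() * total, side="right"))
            r = min(r, nr - 1)
            x += delta[r]
            if r == counted_idx:
                count += 1
            events += 1
            if events > event_cap:
                raise RuntimeError(
                    f"SSA run exceeded {event_cap} events without reaching the target"
                )
        counts[run] = count
    mean = float(np.mean(counts))
    se = float(np.std(counts, ddof=1) / math.sqrt(n_runs)) if n_runs > 1 else 0.0
    return mean, se


def efficiency_sweep(
    net: ReactionNetwork,
    e0_values: list[int],
    enzyme: str = "E",
    species: str = "P",
    counted_reaction: str = "r1",
    strict: bool = False,
    cap: int = 1_000_000,
) -> pd.DataFrame:
    """Half-max expected reward for a range of initial enzyme amounts.

    For each E0 the network is re-built with that initial enzyme amount
    and the half-max query re-evaluated from scratch.  Returns a frame
    with columns e0, expected_reward, reward_per_enzyme (the per-enzyme
    efficiency the sweep is after).
    """
    if not e0_values:
        raise ValueError("e0_values must be non-empty")
    rows = []
    for e0 in e0_values:
        reward = half_max_expected_reward(
            net.with_initial(enzyme, e0), species, counted_reaction, strict, cap
        )
        rows.append(
            {
                "e0": e0,
                "expected_reward": reward,
                "reward_per_enzyme": reward / e0 if e0 > 0 else math.nan,
            }
        )
    return pd.DataFrame(rows)
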