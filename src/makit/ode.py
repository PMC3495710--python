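"""Deterministic (mass-action ODE) semantics.

ODEs are derived automatically from the reaction stoichiometry:

    dx_i/dt = sum_r (prod_ir - react_ir) * k_r * prod_j x_j^{react_jr}

The right-hand side and its analytic Jacobian are generated from the
network, and integrated with a stiff-capable solver on a uniform output
grid.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import ReactionNetwork

__all__ = [
    "ODESystem",
    "Trajectory",
    "IntegrationError",
    "derive_odes",
    "integrate",
    "simulate",
    "peak_time",
    "trajectory_mse",
]


class IntegrationError(RuntimeError):
    """The ODE solver failed or produced a non-finite state."""


@dataclass(frozen=True)
class ODESystem:
    """Mass-action ODE right-hand side in monomial form.

    ``net_matrix[i, r]`` is the signed net stoichiometry of species i in
    reaction r, ``rates[r]`` the rate constant and ``exponents[i, r]`` the
    reactant stoichiometry (the exponent of x_i in reaction r's rate
    monomial).
    """

    species: tuple[str, ...]
    net_matrix: np.ndarray
    rates: np.ndarray
    exponents: np.ndarray

    @property
    def terms(self) -> dict[str, list[tuple[int, float, dict[str, int]]]]:
        """Per-species monomials: (net coefficient, k, exponent map)."""
        out: dict[str, list[tuple[int, float, dict[str, int]]]] = {}
        for i, name in enumerate(self.species):
            monos = []
            for r in range(len(self.rates)):
                coeff = int(self.net_matrix[i, r])
                if coeff == 0:
                    continue
                expo = {
                    self.species[j]: int(self.exponents[j, r])
                    for j in range(len(self.species))
                    if self.exponents[j, r] > 0
                }
                monos.append((coeff, float(self.rates[r]), expo))
            out[name] = monos
        return out

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        # negative round-off is clipped so fractional powers of tiny
        # negative values cannot poison the integration
        xc = np.maximum(x, 0.0)
        v = self.rates * np.prod(
            np.power(xc[:, None], self.exponents), axis=0
        )
        return self.net_matrix @ v

    def jacobian(self, t: float, x: np.ndarray) -> np.ndarray:
        xc = np.maximum(x, 0.0)
        ns, nr = self.exponents.shape
        powers = np.power(xc[:, None], self.exponents)  # (ns, nr)
        dv = np.zeros((nr, ns))
        for r in range(nr):
            for j in range(ns):
                e = self.exponents[j, r]
                if e == 0:
                    continue
                rest = self.rates[r]
                for m in range(ns):
                    if m != j:
                        rest *= powers[m, r]
                dv[r, j] = e * xc[j] ** (e - 1) * rest
        return self.net_matrix @ dv


@dataclass
class Trajectory:
    """Time series of species amounts on a shared time grid."""

    times: np.ndarray
    amounts: np.ndarray  # shape (len(times), n_species)
    species: tuple[str, ...]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amounts = np.asarray(self.amounts, dtype=float)
        if self.amounts.shape != (len(self.times), len(self.species)):
            raise ValueError("amounts shape does not match times/species")

    def series(self, name: str) -> np.ndarray:
        try:
            return self.amounts[:, self.species.index(name)]
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.amounts, columns=list(self.species))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self) -> str:
        buf = io.StringIO()
        self.to_frame().to_csv(buf, index=False)
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "Trajectory":
        df = pd.read_csv(io.StringIO(text))
        if df.columns[0] != "time":
            raise ValueError("trajectory CSV must start with a 'time' column")
        return cls(
            df["time"].to_numpy(),
            df.iloc[:, 1:].to_numpy(),
            tuple(df.columns[1:]),
        )


def derive_odes(net: ReactionNetwork) -> ODESystem:
    """Build the mass-action ODE system of a network."""
    return ODESystem(
        species=net.species_names,
        net_matrix=net.net_stoichiometry().astype(float),
        rates=np.array([r.rate for r in net.reactions], dtype=float),
        exponents=net.reactant_matrix().astype(float),
    )


def integrate(
    sys: ODESystem,
    x0: np.ndarray,
    t_end: float = 30.0,
    n_points: int = 300,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate on the uniform grid 0..t_end with n_points+1 points.

    Uses a stiff-capable solver (LSODA) with the analytic Jacobian.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial state must be non-negative")
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    times = np.linspace(0.0, t_end, n_points + 1)
    sol = solve_ivp(
        sys.rhs,
        (0.0, t_end),
        x0,
        method="LSODA",
        jac=sys.jacobian,
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    return Trajectory(times, sol.y.T.copy(), sys.species)


def simulate(
    net: ReactionNetwork,
    t_end: float = 30.0,
    n_points: int = 300,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Derive and integrate the network's ODEs from its initial amounts."""
    return integrate(derive_odes(net), net.initial_state(), t_end, n_points, rtol, atol)


def peak_time(traj: Trajectory, species: str) -> float:
    """Grid time of the species' maximum amount (earliest on ties)."""
    return float(traj.times[int(np.argmax(traj.series(species)))])


def trajectory_mse(a: Trajectory, b: Trajectory, species: str) -> float:
    """Mean squared difference of one species between two trajectories.

    Both trajectories must share an identical time grid (including t=0).
    """
    if a.times.shape != b.times.shape or not np.array_equal(a.times, b.times):
        raise ValueError("trajectories must share an identical time grid")
    d = a.series(species) - b.series(species)
    return float(np.mean(d * d))
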