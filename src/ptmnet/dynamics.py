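"""Steady-state relaxation of derived networks.

Initial conditions are drawn so that every conservation law holds exactly:
complexes start at zero and each law's conserved total is spread over its
merged-species members by a flat Dirichlet draw.  The system is then
integrated in windows of tau seconds with a stiff solver; after each window
the per-species change relative to the species' conserved total is compared
against the tolerance eps, and integration stops at convergence or after
kappa windows (tau * kappa = 3600 s by default, the reference response time
of a cellular signalling system).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .network import RateConstants, ReactionNetwork
from .partitions import RandomSource

__all__ = [
    "SolverProtocol",
    "TotalsAssignment",
    "RelaxationResult",
    "random_initial_state",
    "relax_to_steady_state",
]


@dataclass(frozen=True)
class SolverProtocol:
    """Stepwise convergence protocol: window length tau (s), max windows
    kappa, relative tolerance eps, and integrator tolerances."""

    tau: float = 10.0
    kappa: int = 360
    eps: float = 1e-3
    rtol: float = 1e-6
    atol: float = 1e-9
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.kappa < 1 or not (0 < self.eps < 1):
            raise ValueError("require tau > 0, kappa >= 1, 0 < eps < 1")


class TotalsAssignment:
    """Conserved total per conservation law, in law order (mmol/m^3)."""

    def __init__(self, totals):
        self.totals = tuple(float(t) for t in totals)
        if any(t < 0 for t in self.totals):
            raise ValueError("conserved totals must be non-negative")

    def __getitem__(self, i: int) -> float:
        return self.totals[i]

    def __len__(self) -> int:
        return len(self.totals)

    def replace(self, i: int, value: float) -> "TotalsAssignment":
        vals = list(self.totals)
        vals[i] = float(value)
        return TotalsAssignment(vals)


@dataclass
class RelaxationResult:
    state: np.ndarray
    converged: bool
    steps_used: int
    diagnostic: str = ""


def reference_totals(network: ReactionNetwork, totals: TotalsAssignment) -> np.ndarray:
    """Per-species normalization scale for the convergence test.

    Each species is normalized by the conserved total of the law containing
    it; a complex belonging to several laws uses the smallest of its totals
    (the tightest scale).  Zero totals fall back to 1 so that frozen species
    never block convergence.
    """
    if len(totals) != len(network.conservation):
        raise ValueError("totals do not cover every conservation law")
    ref = np.full(network.n_species, np.inf)
    for li, law in enumerate(network.conservation):
        for idx, _ in law.entries:
            ref[idx] = min(ref[idx], totals[li])
    ref[~np.isfinite(ref)] = 1.0
    ref[ref == 0.0] = 1.0
    return ref


def random_initial_state(
    network: ReactionNetwork,
    totals: TotalsAssignment,
    rng: RandomSource,
) -> np.ndarray:
    """Draw a random initial state satisfying every conservation law exactly.

    All complexes start at 0; each law's total is distributed over its
    merged-species members by a uniform draw on the simplex (flat Dirichlet),
    so the multiplicity-weighted law sums equal their totals exactly (merged
    species always carry multiplicity 1).
    """
    if len(totals) != len(network.conservation):
        raise ValueError("totals do not cover every conservation law")
    state = np.zeros(network.n_species)
    m = network.n_merged
    for li, law in enumerate(network.conservation):
        members = [idx for idx, _ in law.entries if idx < m]
        if not members:
            continue
        if len(members) == 1:
            state[members[0]] = totals[li]
        else:
            frac = rng.rng.dirichlet(np.ones(len(members)))
            state[members] = totals[li] * frac
    return state


def relax_to_steady_state(
    network: ReactionNetwork,
    rates: RateConstants,
    state: np.ndarray,
    protocol: SolverProtocol = SolverProtocol(),
    totals: TotalsAssignment | None = None,
) -> RelaxationResult:
    """Integrate in tau-second windows until the scaled change is below eps.

    Convergence after a window requires |delta x| / T_ref < eps for every
    dynamic species, where T_ref is the conserved total of the species' law
    (min over laws for complexes).  When ``totals`` is omitted the reference
    totals are computed from the initial state.  Integrator failures yield a
    non-converged result with a diagnostic, never an exception.
    """
    x = np.asarray(state, dtype=float).copy()
    if x.shape != (network.n_species,):
        raise ValueError("state dimension does not match network")
    if totals is None:
        totals = TotalsAssignment(
            [law.total(x) for law in network.conservation]
        )
    ref = reference_totals(network, totals)
    fun, jac = network.compile(rates)
    for step in range(1, protocol.kappa + 1):
        try:
            sol = solve_ivp(
                fun,
                (0.0, protocol.tau),
                x,
                method=protocol.method,
                jac=jac,
                rtol=protocol.rtol,
                atol=protocol.atol,
            )
        except Exception as exc:  # defensive: LSODA can raise on hard failures
            return RelaxationResult(x, False, step, f"integrator error: {exc}")
        if not sol.success:
            return RelaxationResult(x, False, step, f"integrator failure: {sol.message}")
        new = sol.y[:, -1]
        # clamp tiny negative round-off
        new[(new < 0) & (new > -10 * protocol.atol)] = 0.0
        delta = np.abs(new - x) / ref
        x = new
        if np.all(delta < protocol.eps):
            return RelaxationResult(x, True, step)
    return RelaxationResult(x, False, protocol.kappa, "window budget exhausted")
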