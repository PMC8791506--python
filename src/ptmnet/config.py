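"""Default hyperparameters of the resettable-bistability search.

All concentrations are in mmol/m^3 and times in seconds.  The candidate value
set Lambda and the input-total sweep grid Omega both cover 2^-5 .. 2^5 in
half-octave steps — the range of protein concentrations (and MAPK-cascade
kinase rate constants) expected in the cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = ["default_lambda", "default_omega", "InputOutputSpec", "SearchConfig"]


def _half_octaves() -> tuple[float, ...]:
    return tuple(float(2.0**e) for e in np.arange(-5.0, 5.0 + 0.25, 0.5))


def default_lambda() -> tuple[float, ...]:
    """Candidate values for rate constants and conserved totals (21 values)."""
    return _half_octaves()


def default_omega() -> tuple[float, ...]:
    """Sweep grid for the input species' conserved total (21 values)."""
    return _half_octaves()


@dataclass(frozen=True)
class InputOutputSpec:
    """Input and output chemical species of the response being scored."""

    input_species: str = "E1"
    output_species: str = "P2"

    def __post_init__(self) -> None:
        if self.input_species == self.output_species:
            raise ValueError("input and output species must be distinct")


@dataclass
class SearchConfig:
    """Full hyperparameter set for the topology search.

    n_reactions   N, number of PTM reactions (4)
    depth         sigma, recursion depth of the partition search psi (4)
    max_iterations gamma, main-loop budget (150)
    score_threshold rho, stop when the score exceeds it (0.8)
    n_parameter_draws lambda, random parameter points per partition (5)
    candidate_values Lambda; sweep_grid Omega; n_replicates theta (5)
    tau/kappa/eps  relaxation protocol (10 s / 360 / 1e-3)
    """

    n_reactions: int = 4
    depth: int = 4
    max_iterations: int = 150
    score_threshold: float = 0.8
    n_parameter_draws: int = 5
    candidate_values: tuple[float, ...] = field(default_factory=default_lambda)
    sweep_grid: tuple[float, ...] = field(default_factory=default_omega)
    n_replicates: int = 5
    input_species: str = "E1"
    output_species: str = "P2"
    tau: float = 10.0
    kappa: int = 360
    eps: float = 1e-3
    rtol: float = 1e-6
    atol: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0 or self.max_iterations < 0:
            raise ValueError("depth and max_iterations must be >= 0")
        if not (0 < self.score_threshold <= 1):
            raise ValueError("score_threshold must be in (0, 1]")
        grid = tuple(self.sweep_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("sweep_grid must be strictly increasing")

    @property
    def io(self):
        return InputOutputSpec(self.input_species, self.output_species)

    def solver_protocol(self):
        from .dynamics import SolverProtocol

        return SolverProtocol(
            tau=self.tau, kappa=self.kappa, eps=self.eps,
            rtol=self.rtol, atol=self.atol,
        )

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self) -> str:
        obj = asdict(self)
        obj["candidate_values"] = list(self.candidate_values)
        obj["sweep_grid"] = list(self.sweep_grid)
        return yaml.safe_dump(obj, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SearchConfig":
        obj = yaml.safe_load(text) or {}
        if "candidate_values" in obj:
            obj["candidate_values"] = tuple(obj["candidate_values"])
        if "sweep_grid" in obj:
            obj["sweep_grid"] = tuple(obj["sweep_grid"])
        return cls(**obj)
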