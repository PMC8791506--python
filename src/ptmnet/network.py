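"""Derivation of mass-action ODE systems and conservation laws from partitions.

Each PTM reaction i is the Michaelis-Menten mechanism

    S_i + E_i  <=>[a_i][d_i]  C_i  ->[k_i]  P_i + E_i

modelled with the law of mass action only (no quasi-steady-state
approximation).  Merging the species of each partition block into one dynamic
species y_k turns the 4N elementary rate equations into the network's ODE
system; the per-reaction substrate and enzyme conservation lists are merged by
concatenation into the network's conservation laws, whose multiplicities make
the weighted derivative sum an identically zero polynomial.

Rate terms are stored as structured signed monomials (rate-constant symbol x
product of dynamic species) so that conservation can be verified symbolically,
and a compiled numeric evaluator (with analytic Jacobian) is generated from
them for the integrator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .partitions import Partition, SpeciesLabel

__all__ = [
    "RateConstants",
    "Term",
    "MergedSpecies",
    "ConservationLaw",
    "ReactionNetwork",
    "base_equations",
    "merge_network",
    "conservation_laws",
    "rhs",
    "combine_terms",
    "law_residual",
    "network_to_json",
]


@dataclass(frozen=True)
class RateConstants:
    """Per-reaction rate constants: a (association, m^3/mmol/s), d
    (dissociation, 1/s), k (catalysis, 1/s)."""

    a: tuple[float, ...]
    d: tuple[float, ...]
    k: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.a) == len(self.d) == len(self.k)):
            raise ValueError("a, d, k must have equal length")
        if any(v <= 0 for v in (*self.a, *self.d, *self.k)):
            raise ValueError("rate constants must be strictly positive")

    @property
    def n_reactions(self) -> int:
        return len(self.a)

    def value(self, symbol: str) -> float:
        """Value of a rate-constant symbol such as ``"a2"``."""
        kind, idx = symbol[0], int(symbol[1:]) - 1
        return {"a": self.a, "d": self.d, "k": self.k}[kind][idx]

    @classmethod
    def uniform(cls, n: int, a: float = 1.0, d: float = 1.0, k: float = 1.0):
        return cls((a,) * n, (d,) * n, (k,) * n)


class Term(NamedTuple):
    """Signed mass-action monomial: coeff * rate_constant * prod(factors)."""

    coeff: int
    rate: str            # rate-constant symbol, e.g. "a1", "d2", "k1"
    factors: tuple       # dynamic-species identifiers, sorted


def _sorted_factors(factors: Iterable) -> tuple:
    return tuple(sorted(factors, key=str))


def combine_terms(terms: Iterable[Term]) -> tuple[Term, ...]:
    """Canonical form: sum coefficients of like monomials, drop zeros, sort."""
    acc: Counter = Counter()
    for t in terms:
        acc[(t.rate, _sorted_factors(t.factors))] += t.coeff
    out = [
        Term(c, rate, factors)
        for (rate, factors), c in acc.items()
        if c != 0
    ]
    out.sort(key=lambda t: (t.rate, tuple(map(str, t.factors))))
    return tuple(out)


# ---------------------------------------------------------------------------
# Unmerged (elementary) equations
# ---------------------------------------------------------------------------

def base_equations(n_reactions: int) -> dict[str, list[Term]]:
    """Elementary rate equations for the 4N unmerged species.

    Returns a mapping from species name ("S1", "E1", "C1", "P1", ...) to its
    list of signed monomials; the composite (d_i + k_i) coefficients are kept
    as separate d- and k-monomials.
    """
    if n_reactions < 1:
        raise ValueError("n_reactions must be a positive integer")
    eqs: dict[str, list[Term]] = {}
    for i in range(1, n_reactions + 1):
        S, E, C, P = f"S{i}", f"E{i}", f"C{i}", f"P{i}"
        a, d, k = f"a{i}", f"d{i}", f"k{i}"
        bind = _sorted_factors((S, E))
        eqs[S] = [Term(-1, a, bind), Term(+1, d, (C,))]
        eqs[E] = [Term(-1, a, bind), Term(+1, d, (C,)), Term(+1, k, (C,))]
        eqs[C] = [Term(+1, a, bind), Term(-1, d, (C,)), Term(-1, k, (C,))]
        eqs[P] = [Term(+1, k, (C,))]
    return eqs


# ---------------------------------------------------------------------------
# Derived network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MergedSpecies:
    """One dynamic species y_k identifying all members of a partition block."""

    block: tuple[SpeciesLabel, ...]
    name: str

    @classmethod
    def from_block(cls, block: Sequence[SpeciesLabel]) -> "MergedSpecies":
        labels = tuple(sorted(block))
        if len(labels) == 1:
            name = str(labels[0])
        else:
            name = "[" + ",".join(str(l) for l in labels) + "]"
        return cls(labels, name)


@dataclass(frozen=True)
class ConservationLaw:
    """Multiplicity-weighted species list whose weighted sum is invariant."""

    entries: tuple[tuple[int, int], ...]  # (dynamic species index, multiplicity)

    def __post_init__(self) -> None:
        seen = set()
        for idx, mult in self.entries:
            if mult < 1:
                raise ValueError("multiplicities must be >= 1")
            if idx in seen:
                raise ValueError("duplicate species in conservation law")
            seen.add(idx)

    def species(self) -> tuple[int, ...]:
        return tuple(idx for idx, _ in self.entries)

    def total(self, state: np.ndarray) -> float:
        return float(sum(m * state[i] for i, m in self.entries))


@dataclass
class ReactionNetwork:
    """A mass-action network derived from a partition.

    Dynamic species are indexed 0..m-1 for the merged species (one per block,
    canonical block order) followed by m..m+N-1 for the complexes C_1..C_N.
    """

    partition: Partition
    merged_species: list[MergedSpecies]
    species_names: list[str]
    role_map: dict[str, int]          # "S1"/"E1"/"P1"/"C1" -> dynamic index
    rate_terms: dict[int, tuple[Term, ...]]  # index -> canonical monomials
    conservation: list[ConservationLaw] = field(default_factory=list)

    @property
    def n_reactions(self) -> int:
        return self.partition.universe.n_reactions

    @property
    def n_merged(self) -> int:
        return len(self.merged_species)

    @property
    def n_species(self) -> int:
        return self.n_merged + self.n_reactions

    def complex_index(self, i: int) -> int:
        """Dynamic index of complex C_i (1-based reaction index)."""
        return self.n_merged + i - 1

    def species_of_label(self, label: SpeciesLabel) -> int:
        """Dynamic index of the merged species a universe label resolves to."""
        return self.role_map[str(label)]

    def law_of_species(self) -> dict[int, list[int]]:
        """Map dynamic species index -> indices of laws containing it."""
        out: dict[int, list[int]] = {i: [] for i in range(self.n_species)}
        for li, law in enumerate(self.conservation):
            for idx, _ in law.entries:
                out[idx].append(li)
        return out

    # -- numeric evaluation ------------------------------------------------

    def compile(self, rates: RateConstants):
        """Build fast callables f(t, x) and jac(t, x) from the rate terms."""
        if rates.n_reactions != self.n_reactions:
            raise ValueError("rate-constant vector does not match network size")
        targets, coeffs, f1, f2 = [], [], [], []
        for idx, terms in self.rate_terms.items():
            for t in terms:
                targets.append(idx)
                coeffs.append(t.coeff * rates.value(t.rate))
                fs = list(t.factors)
                f1.append(fs[0])
                f2.append(fs[1] if len(fs) > 1 else -1)
        targets = np.asarray(targets, dtype=np.intp)
        coeffs = np.asarray(coeffs, dtype=float)
        f1 = np.asarray(f1, dtype=np.intp)
        f2 = np.asarray(f2, dtype=np.intp)
        has2 = f2 >= 0
        n = self.n_species

        def fun(t, x):
            vals = coeffs * x[f1]
            vals[has2] *= x[f2[has2]]
            out = np.zeros(n)
            np.add.at(out, targets, vals)
            return out

        def jac(t, x):
            J = np.zeros((n, n))
            # d/d f1 and d/d f2 of coeff * x[f1] * x[f2]
            v1 = coeffs.copy()
            v1[has2] *= x[f2[has2]]
            np.add.at(J, (targets, f1), v1)
            v2 = coeffs[has2] * x[f1[has2]]
            np.add.at(J, (targets[has2], f2[has2]), v2)
            return J

        return fun, jac


def merge_network(P: Partition, rates: RateConstants | None = None) -> ReactionNetwork:
    """Derive the merged mass-action ODE system for a partition.

    Every occurrence of a block member in the elementary equations is replaced
    by the block's merged species y_k (including self-referential merges such
    as autocatalysis and dimer formation, where the binding monomial becomes a
    squared concentration); the merged species' rate is the sum of its
    members' elementary rates.  Conservation laws are attached.
    """
    N = P.universe.n_reactions
    if rates is not None and rates.n_reactions != N:
        raise ValueError("rate constants do not match partition size")
    merged = [MergedSpecies.from_block(b) for b in P.blocks]
    m = len(merged)
    names = [sp.name for sp in merged] + [f"C{i}" for i in range(1, N + 1)]

    role_map: dict[str, int] = {}
    for bi, block in enumerate(P.blocks):
        for lab in block:
            role_map[str(lab)] = bi
    for i in range(1, N + 1):
        role_map[f"C{i}"] = m + i - 1

    base = base_equations(N)

    def substitute(terms: list[Term]) -> list[Term]:
        return [
            Term(t.coeff, t.rate, _sorted_factors(role_map[f] for f in t.factors))
            for t in terms
        ]

    rate_terms: dict[int, tuple[Term, ...]] = {}
    for bi, block in enumerate(P.blocks):
        summed: list[Term] = []
        for lab in block:
            summed.extend(substitute(base[str(lab)]))
        rate_terms[bi] = combine_terms(summed)
    for i in range(1, N + 1):
        rate_terms[m + i - 1] = combine_terms(substitute(base[f"C{i}"]))

    net = ReactionNetwork(
        partition=P,
        merged_species=merged,
        species_names=names,
        role_map=role_map,
        rate_terms=rate_terms,
    )
    net.conservation = conservation_laws(P, _network=net)
    return net


def conservation_laws(
    P: Partition, _network: ReactionNetwork | None = None
) -> list[ConservationLaw]:
    """Derive the network's conservation laws with multiplicities.

    Starts from the 2N per-reaction lists {S_i, C_i, P_i} (substrate
    conservation) and {E_i, C_i} (enzyme conservation).  For each block, all
    current lists sharing a member with the block are concatenated (not
    summed: repeats of a complex are intrinsic overlap and become
    multiplicity), the block's members are removed and the merged species
    added once.  The result is independent of block processing order.
    """
    N = P.universe.n_reactions
    # token lists over unmerged names; "Y<k>" marks merged species of block k
    Q: list[list[str]] = []
    for i in range(1, N + 1):
        Q.append([f"S{i}", f"C{i}", f"P{i}"])
        Q.append([f"E{i}", f"C{i}"])

    for bi, block in enumerate(P.blocks):
        members = {str(lab) for lab in block}
        touching = [q for q in Q if members & set(q)]
        rest = [q for q in Q if not (members & set(q))]
        r = [tok for q in touching for tok in q if tok not in members]
        r.append(f"Y{bi}")
        Q = rest + [r]

    net = _network if _network is not None else merge_network(P)
    laws = []
    for q in Q:
        counts = Counter(q)
        entries = []
        for tok, mult in counts.items():
            if tok.startswith("Y"):
                idx = int(tok[1:])
            else:
                idx = net.role_map[tok]
            entries.append((idx, mult))
        entries.sort()
        laws.append(ConservationLaw(tuple(entries)))
    laws.sort(key=lambda l: l.entries)
    return laws


def law_residual(network: ReactionNetwork, law: ConservationLaw) -> tuple[Term, ...]:
    """Multiplicity-weighted sum of rate terms over a law, canonically combined.

    Empty iff the weighted derivative is the zero polynomial — the master
    invariant of the derivation.
    """
    acc: list[Term] = []
    for idx, mult in law.entries:
        for t in network.rate_terms[idx]:
            acc.append(Term(t.coeff * mult, t.rate, t.factors))
    return combine_terms(acc)


def rhs(network: ReactionNetwork, rates: RateConstants, state: np.ndarray) -> np.ndarray:
    """Derivative vector of all dynamic species at ``state``."""
    state = np.asarray(state, dtype=float)
    if state.shape != (network.n_species,):
        raise ValueError(
            f"state has shape {state.shape}, expected ({network.n_species},)"
        )
    fun, _ = network.compile(rates)
    return fun(0.0, state)


def network_to_json(network: ReactionNetwork) -> str:
    """Export dynamic species, signed monomials and conservation laws as JSON."""
    import json

    obj = {
        "n_reactions": network.n_reactions,
        "species": network.species_names,
        "rate_terms": {
            network.species_names[idx]: [
                {
                    "coeff": t.coeff,
                    "rate": t.rate,
                    "factors": [network.species_names[f] for f in t.factors],
                }
                for t in terms
            ]
            for idx, terms in network.rate_terms.items()
        },
        "conservation": [
            [
                {"species": network.species_names[i], "multiplicity": m}
                for i, m in law.entries
            ]
            for law in network.conservation
        ],
    }
    return json.dumps(obj, indent=1)
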