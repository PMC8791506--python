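"""Set-partition representation of enzymatic PTM reaction networks.

The universe of N post-translational modification (PTM) reactions consists of
the 3N species S_1, E_1, P_1, ..., S_N, E_N, P_N (substrate, enzyme, product
of each Michaelis-Menten unit).  A partition of that universe — species sharing
a block are identified as one chemical species — is the sole specification of
a network topology.  This module provides the partition container with a
canonical form, exhaustive enumeration and Bell-number counting, the partition
distance metric, the two stochastic partition modifiers (separate / join) used
by the topology search, and JSON serialization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "ROLES",
    "SpeciesLabel",
    "SpeciesUniverse",
    "Partition",
    "RandomSource",
    "build_universe",
    "count_networks",
    "bell_number",
    "enumerate_partitions",
    "block_difference",
    "partition_distance",
    "distance_matrix",
    "separate_modifier",
    "join_modifier",
    "partition_to_json",
    "partition_from_json",
]

#: role sort order: substrate < enzyme < product.  Complexes (C) exist only in
#: derived networks, never in a partition universe.
ROLES = ("S", "E", "P")
_ROLE_ORDER = {r: i for i, r in enumerate(ROLES)}


@dataclass(frozen=True, order=False)
class SpeciesLabel:
    """One substrate/enzyme/product of one PTM reaction, e.g. ``E1``."""

    role: str
    reaction_index: int

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"invalid role {self.role!r}; expected one of {ROLES}")
        if self.reaction_index < 1:
            raise ValueError("reaction_index must be >= 1")

    @property
    def sort_key(self) -> tuple[int, int]:
        return (_ROLE_ORDER[self.role], self.reaction_index)

    def __lt__(self, other: "SpeciesLabel") -> bool:
        return self.sort_key < other.sort_key

    def __str__(self) -> str:
        return f"{self.role}{self.reaction_index}"

    @classmethod
    def parse(cls, text: str) -> "SpeciesLabel":
        """Parse a label string such as ``"S1"`` or ``"E12"``."""
        text = text.strip()
        if len(text) < 2 or text[0] not in ROLES:
            raise ValueError(f"cannot parse species label {text!r}")
        try:
            idx = int(text[1:])
        except ValueError as exc:
            raise ValueError(f"cannot parse species label {text!r}") from exc
        return cls(text[0], idx)


@dataclass(frozen=True)
class SpeciesUniverse:
    """The ordered 3N-species set M = {S_1, E_1, P_1, ..., S_N, E_N, P_N}."""

    n_reactions: int
    labels: tuple[SpeciesLabel, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_reactions < 1:
            raise ValueError("n_reactions must be a positive integer")
        labels = tuple(
            SpeciesLabel(role, i)
            for i in range(1, self.n_reactions + 1)
            for role in ("S", "E", "P")
        )
        object.__setattr__(self, "labels", labels)

    @property
    def size(self) -> int:
        return 3 * self.n_reactions

    def __contains__(self, label: SpeciesLabel) -> bool:
        return (
            label.role in ROLES and 1 <= label.reaction_index <= self.n_reactions
        )

    def __iter__(self) -> Iterator[SpeciesLabel]:
        return iter(self.labels)


def build_universe(n_reactions: int) -> SpeciesUniverse:
    """Build the species universe for ``n_reactions`` PTM reactions."""
    return SpeciesUniverse(n_reactions)


class Partition:
    """A partition of a species universe into non-empty disjoint blocks.

    Blocks are stored in canonical form: within a block labels are sorted
    (role order S < E < P, then reaction index); blocks are sorted by their
    smallest label.  Two partitions are equal iff their canonical forms are.
    """

    __slots__ = ("universe", "blocks", "_key")

    def __init__(
        self, universe: SpeciesUniverse, blocks: Iterable[Iterable[SpeciesLabel]]
    ):
        canon = []
        seen: set[SpeciesLabel] = set()
        for block in blocks:
            b = tuple(sorted(set(block)))
            if not b:
                raise ValueError("empty block")
            for lab in b:
                if lab not in universe:
                    raise ValueError(f"label {lab} not in universe (N={universe.n_reactions})")
                if lab in seen:
                    raise ValueError(f"label {lab} appears in more than one block")
                seen.add(lab)
            canon.append(b)
        if len(seen) != universe.size:
            missing = sorted(set(universe.labels) - seen)
            raise ValueError(f"blocks do not cover the universe; missing {missing}")
        canon.sort(key=lambda b: b[0].sort_key)
        self.universe = universe
        self.blocks = tuple(canon)
        self._key = (universe.n_reactions, tuple(tuple(str(l) for l in b) for b in self.blocks))

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_of(self, label: SpeciesLabel) -> tuple[SpeciesLabel, ...]:
        for b in self.blocks:
            if label in b:
                return b
        raise KeyError(str(label))

    def block_index_of(self, label: SpeciesLabel) -> int:
        for i, b in enumerate(self.blocks):
            if label in b:
                return i
        raise KeyError(str(label))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Partition) and self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __repr__(self) -> str:
        inner = ", ".join(
            "{" + ",".join(str(l) for l in b) + "}" for b in self.blocks
        )
        return f"Partition(N={self.universe.n_reactions}, {{{inner}}})"

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def from_strings(
        cls, n_reactions: int, blocks: Sequence[Sequence[str]]
    ) -> "Partition":
        """Build from string labels, e.g. ``Partition.from_strings(2, [["S1"], ["E1"], ...])``."""
        uni = build_universe(n_reactions)
        return cls(uni, [[SpeciesLabel.parse(s) for s in b] for b in blocks])

    @classmethod
    def discrete(cls, universe: SpeciesUniverse) -> "Partition":
        """The all-singletons partition (every species its own block)."""
        return cls(universe, [[lab] for lab in universe.labels])


class RandomSource:
    """Seeded random-number source; identical seeds yield identical sequences."""

    def __init__(self, seed: int):
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)

    def spawn(self) -> "RandomSource":
        """Derive an independent child source (deterministic given the parent state)."""
        child = RandomSource(int(self.rng.integers(0, 2**31 - 1)))
        return child


# ---------------------------------------------------------------------------
# Counting and enumeration
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def bell_number(n: int) -> int:
    """The Bell number B_n: the number of partitions of an n-element set.

    Computed by the standard recurrence B_{n+1} = sum_k C(n, k) B_k with
    B_0 = B_1 = 1.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n <= 1:
        return 1
    # B_n = sum_{k=0}^{n-1} C(n-1, k) B_k
    return sum(math.comb(n - 1, k) * bell_number(k) for k in range(n))


def count_networks(n_reactions: int) -> int:
    """Number of distinct networks of N PTM reactions: the Bell number B_{3N}."""
    if n_reactions < 1:
        raise ValueError("n_reactions must be a positive integer")
    return bell_number(3 * n_reactions)


def enumerate_partitions(
    universe: SpeciesUniverse, max_size: int = 12
) -> Iterator[Partition]:
    """Yield every partition of the universe exactly once, in canonical order.

    Enumerates by assigning each label (in universe order) either to an
    existing block or to a new block; because labels are processed in sorted
    order this produces each partition once, with blocks ordered by smallest
    member.  Guarded against combinatorial blowup via ``max_size``.
    """
    n = universe.size
    if n > max_size:
        raise ValueError(
            f"universe of size {n} exceeds enumeration guard max_size={max_size}"
        )
    labels = universe.labels

    def rec(i: int, blocks: list[list[SpeciesLabel]]) -> Iterator[Partition]:
        if i == n:
            yield Partition(universe, [list(b) for b in blocks])
            return
        lab = labels[i]
        for b in blocks:
            b.append(lab)
            yield from rec(i + 1, blocks)
            b.pop()
        blocks.append([lab])
        yield from rec(i + 1, blocks)
        blocks.pop()

    yield from rec(0, [])


# ---------------------------------------------------------------------------
# Distance
# ---------------------------------------------------------------------------

def block_difference(a: Iterable[SpeciesLabel], b: Iterable[SpeciesLabel]) -> int:
    """Cardinality of the symmetric difference between two blocks."""
    return len(set(a) ^ set(b))


def _directional(A: Partition, block: Iterable[SpeciesLabel]) -> int:
    """d(A, b): distance from block b to its best-matching block of A."""
    return min(block_difference(a, block) for a in A.blocks)


def partition_distance(A: Partition, B: Partition) -> int:
    """Distance D(A, B) between two partitions of the same universe.

    D(A, B) = max( max_j d(A, b_j), max_i d(B, a_i) ), where d(A, b) is the
    minimum symmetric-difference size between b and any block of A.  Symmetric,
    zero iff A == B, and satisfies the triangle inequality.
    """
    if A.universe != B.universe:
        raise ValueError("partitions are over different universes")
    fwd = max(_directional(A, b) for b in B.blocks)
    bwd = max(_directional(B, a) for a in A.blocks)
    return max(fwd, bwd)


def distance_matrix(partitions: Sequence[Partition]) -> np.ndarray:
    """Symmetric integer matrix of pairwise partition distances."""
    m = len(partitions)
    out = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = partition_distance(partitions[i], partitions[j])
    return out


# ---------------------------------------------------------------------------
# Modifiers
# ---------------------------------------------------------------------------

def _violates_io(
    blocks: Sequence[Sequence[SpeciesLabel]],
    forbidden_pair: tuple[SpeciesLabel, SpeciesLabel] | None,
) -> bool:
    if forbidden_pair is None:
        return False
    x, y = forbidden_pair
    for b in blocks:
        if x in b and y in b:
            return True
    return False


def separate_modifier(
    P: Partition,
    rng: RandomSource,
    forbidden_pair: tuple[SpeciesLabel, SpeciesLabel] | None = None,
    max_retries: int = 32,
) -> Partition | None:
    """Split one randomly chosen block into two non-empty parts.

    The block is chosen uniformly among blocks of size >= 2, the split
    uniformly among the 2^(n-1) - 1 proper bipartitions of the block.  Returns
    None (no-op signal) when every block is a singleton.  Separation can never
    create a forbidden co-membership, so ``forbidden_pair`` is accepted only
    for interface symmetry with :func:`join_modifier`.
    """
    splittable = [i for i, b in enumerate(P.blocks) if len(b) >= 2]
    if not splittable:
        return None
    for _ in range(max_retries):
        i = splittable[int(rng.rng.integers(len(splittable)))]
        block = P.blocks[i]
        n = len(block)
        # uniform over proper bipartitions: random bitmask, reject trivial ones
        mask = int(rng.rng.integers(1, 2**n - 1))
        left = [lab for j, lab in enumerate(block) if (mask >> j) & 1]
        right = [lab for j, lab in enumerate(block) if not (mask >> j) & 1]
        new_blocks = [list(b) for j, b in enumerate(P.blocks) if j != i]
        new_blocks.extend([left, right])
        if _violates_io(new_blocks, forbidden_pair):
            continue  # unreachable for separate, kept for uniformity
        return Partition(P.universe, new_blocks)
    return None


def join_modifier(
    P: Partition,
    rng: RandomSource,
    forbidden_pair: tuple[SpeciesLabel, SpeciesLabel] | None = None,
    max_retries: int = 32,
) -> Partition | None:
    """Merge two randomly chosen blocks into one.

    The pair is chosen uniformly among admissible pairs; a pair is
    inadmissible if merging it would place ``forbidden_pair`` (by default the
    search's input and output species) in the same block.  Returns None
    (no-op signal) when the partition has a single block or no admissible pair
    is found within ``max_retries`` draws.
    """
    m = P.n_blocks
    if m < 2:
        return None
    for _ in range(max_retries):
        i, j = rng.rng.choice(m, size=2, replace=False)
        i, j = int(i), int(j)
        merged = list(P.blocks[i]) + list(P.blocks[j])
        new_blocks = [list(b) for k, b in enumerate(P.blocks) if k not in (i, j)]
        new_blocks.append(merged)
        if _violates_io(new_blocks, forbidden_pair):
            continue
        return Partition(P.universe, new_blocks)
    return None


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def partition_to_json(P: Partition) -> str:
    """Serialize a partition in canonical order to the JSON dialect."""
    obj = {
        "n_reactions": P.universe.n_reactions,
        "blocks": [[str(lab) for lab in b] for b in P.blocks],
    }
    return json.dumps(obj, indent=1)


def partition_from_json(text: str) -> Partition:
    """Parse a partition from JSON; rejects duplicates and omissions."""
    obj = json.loads(text)
    try:
        n = int(obj["n_reactions"])
        blocks = obj["blocks"]
    except (KeyError, TypeError) as exc:
        raise ValueError("partition JSON must have 'n_reactions' and 'blocks'") from exc
    return Partition.from_strings(n, blocks)
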