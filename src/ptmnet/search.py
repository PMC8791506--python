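"""Stochastic search over partition space for high-scoring topologies.

The main loop draws a uniformly random admissible partition and repeatedly
applies the recursive partition-search function psi, which explores a binary
tree of candidates produced by the join and separate modifiers (depth sigma),
accepting the first candidate whose score Phi beats the incumbent's.  The
loop stops when the score exceeds the convergence threshold rho or after
gamma iterations.

Phi is stochastic (random parameter draws), so within one psi invocation each
distinct candidate partition is evaluated once and cached; the incumbent's
score is the one recorded when it became the incumbent, which keeps accepted
scores non-decreasing along the trace.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable

from .bistability import phi_max
from .config import SearchConfig
from .partitions import (
    Partition,
    RandomSource,
    SpeciesLabel,
    SpeciesUniverse,
    bell_number,
    build_universe,
    join_modifier,
    separate_modifier,
)

__all__ = [
    "Evaluator",
    "SearchStep",
    "SearchTrace",
    "random_partition",
    "psi",
    "run_search",
    "make_phi_max_evaluator",
]

logger = logging.getLogger(__name__)

#: an evaluator maps (partition, rng) to (score, payload); the payload is the
#: best parameter point for the real evaluator, anything for stubs.
Evaluator = Callable[[Partition, RandomSource], tuple[float, object]]


@dataclass
class SearchStep:
    iteration: int
    partition: Partition
    score: float
    payload: object = None


@dataclass
class SearchTrace:
    """Accepted steps of one search run, plus the final result."""

    steps: list[SearchStep] = field(default_factory=list)
    reason: str = ""
    n_evaluations: int = 0

    @property
    def final(self) -> SearchStep:
        return self.steps[-1]

    def to_jsonl(self) -> str:
        lines = []
        for s in self.steps:
            lines.append(
                json.dumps(
                    {
                        "iteration": s.iteration,
                        "score": s.score,
                        "n_blocks": s.partition.n_blocks,
                        "blocks": [
                            [str(l) for l in b] for b in s.partition.blocks
                        ],
                    }
                )
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Uniform random partition
# ---------------------------------------------------------------------------

def _sample_uniform_partition(labels: list, rng: RandomSource) -> list[list]:
    """Exact uniform set partition via the Bell-number block-size recursion.

    The block containing the first element has size k with probability
    C(n-1, k-1) * B_{n-k} / B_n; its remaining members are uniform among the
    other elements; recurse on the rest.
    """
    n = len(labels)
    if n == 0:
        return []
    weights = [math.comb(n - 1, k - 1) * bell_number(n - k) for k in range(1, n + 1)]
    total = bell_number(n)
    u = rng.rng.random() * total
    acc, k = 0.0, n
    for i, w in enumerate(weights, start=1):
        acc += w
        if u < acc:
            k = i
            break
    rest = labels[1:]
    chosen = (
        list(rng.rng.choice(len(rest), size=k - 1, replace=False))
        if k > 1
        else []
    )
    block = [labels[0]] + [rest[i] for i in sorted(chosen)]
    remaining = [x for i, x in enumerate(rest) if i not in set(chosen)]
    return [block] + _sample_uniform_partition(remaining, rng)


def _forbidden_pair(
    universe: SpeciesUniverse, config: SearchConfig
) -> tuple[SpeciesLabel, SpeciesLabel] | None:
    try:
        a = SpeciesLabel.parse(config.input_species)
        b = SpeciesLabel.parse(config.output_species)
    except ValueError:
        return None
    if a in universe and b in universe:
        return (a, b)
    return None


def random_partition(
    universe: SpeciesUniverse,
    rng: RandomSource,
    forbidden_pair: tuple[SpeciesLabel, SpeciesLabel] | None = None,
    max_retries: int = 1000,
) -> Partition:
    """Uniformly random partition of the universe, re-drawn until admissible
    (the input and output species in distinct blocks)."""
    labels = list(universe.labels)
    for _ in range(max_retries):
        blocks = _sample_uniform_partition(labels, rng)
        P = Partition(universe, blocks)
        if forbidden_pair is None:
            return P
        x, y = forbidden_pair
        if P.block_index_of(x) != P.block_index_of(y):
            return P
    raise RuntimeError("could not draw an admissible partition")


# ---------------------------------------------------------------------------
# Recursive partition search
# ---------------------------------------------------------------------------

def psi(
    P0: Partition,
    P: Partition,
    sigma: int,
    evaluator: Evaluator,
    rng: RandomSource,
    cache: dict[Partition, tuple[float, object]] | None = None,
    forbidden_pair=None,
) -> Partition:
    """Recursive partition search: return a candidate scoring strictly above
    Phi(P0), or P0 itself if the depth-sigma binary tree yields none.

    At each node a join candidate P' and a separate candidate P'' are drawn
    from P; each is returned immediately if it beats the incumbent, otherwise
    both subtrees are explored at depth sigma - 1.  Candidate scores are
    cached for the duration of the call, so each distinct partition is
    evaluated at most once.  Modifier no-ops (e.g. a single-block partition
    cannot be joined) skip that branch.
    """
    cache = {} if cache is None else cache
    if P0 not in cache:
        cache[P0] = evaluator(P0, rng)
    incumbent = cache[P0][0]

    def score_of(Q: Partition) -> float:
        if Q not in cache:
            cache[Q] = evaluator(Q, rng)
        return cache[Q][0]

    def rec(P: Partition, sigma: int) -> Partition:
        if sigma == 0:
            return P0
        P_join = join_modifier(P, rng, forbidden_pair)
        if P_join is not None and score_of(P_join) > incumbent:
            return P_join
        P_sep = separate_modifier(P, rng, forbidden_pair)
        if P_sep is not None and score_of(P_sep) > incumbent:
            return P_sep
        for child in (P_join, P_sep):
            if child is None:
                continue
            R = rec(child, sigma - 1)
            if R is not P0 and score_of(R) > incumbent:
                return R
        return P0

    return rec(P, sigma)


def make_phi_max_evaluator(config: SearchConfig) -> Evaluator:
    """The real evaluator: Phi(P) = best-of-lambda random parameter draws."""

    def evaluate(P: Partition, rng: RandomSource):
        return phi_max(
            P,
            candidate_values=config.candidate_values,
            n_draws=config.n_parameter_draws,
            config=config,
            rng=rng,
        )

    return evaluate


def run_search(
    config: SearchConfig,
    rng: RandomSource | None = None,
    evaluator: Evaluator | None = None,
) -> SearchTrace:
    """Main search loop.

    Draws a uniform random admissible partition, then iterates
    P <- psi(P, P, sigma) until the incumbent score exceeds rho
    (reason "score") or gamma iterations elapse (reason "budget").
    Every accepted step is recorded; scores are non-decreasing.
    """
    rng = rng if rng is not None else RandomSource(config.seed)
    evaluator = evaluator if evaluator is not None else make_phi_max_evaluator(config)
    universe = build_universe(config.n_reactions)
    forbidden = _forbidden_pair(universe, config)

    n_evals = 0

    def counting_evaluator(P: Partition, r: RandomSource):
        nonlocal n_evals
        n_evals += 1
        return evaluator(P, r)

    P = random_partition(universe, rng, forbidden)
    score, payload = counting_evaluator(P, rng)
    trace = SearchTrace()
    trace.steps.append(SearchStep(0, P, score, payload))
    logger.info("iter=0 score=%.4f blocks=%d", score, P.n_blocks)

    it = 0
    while score <= config.score_threshold and it < config.max_iterations:
        it += 1
        cache = {P: (score, payload)}
        P_new = psi(
            P, P, config.depth, counting_evaluator, rng, cache, forbidden
        )
        if P_new != P:
            score, payload = cache[P_new]
            P = P_new
            trace.steps.append(SearchStep(it, P, score, payload))
        logger.info(
            "iter=%d score=%.4f blocks=%d evals=%d", it, score, P.n_blocks, n_evals
        )
    trace.reason = "score" if score > config.score_threshold else "budget"
    trace.n_evaluations = n_evals
    return trace
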