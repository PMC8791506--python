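# Methods

## The model

`ptmnet` studies networks built from N post-translational modification (PTM)
reactions, each a Michaelis–Menten unit

    S_i + E_i  ⇌(a_i, d_i)  C_i  →(k_i)  P_i + E_i,

modelled with the law of mass action only — no Michaelis–Menten or
quasi-steady-state approximation, because approximate kinetics are known to
misreport bistability. Rate constants are `a` (association, m³·mmol⁻¹·s⁻¹),
`d` (dissociation, s⁻¹) and `k` (catalysis, s⁻¹); concentrations are in
mmol/m³.

A network topology is specified entirely by a partition of the 3N-species
set {S_1, E_1, P_1, …, S_N, E_N, P_N}: species in the same block are
identified as one chemical species. Identifying P_i with E_j makes the
product of reaction i the enzyme of reaction j (activation); P_i with S_j
chains reactions; S_i with P_i within one reaction gives an
association–dissociation cycle; S_i, E_i, P_i all together gives dimer
formation/separation. Every partition yields a well-defined network and
vice versa, so the space of N-reaction topologies has exactly B_{3N}
(Bell number) elements — 4 213 597 at N = 4.

## ODE derivation

Starting from the 4N elementary rate equations (per reaction: S_i, E_i,
C_i, P_i), each block's merged species gets the sum of its members'
right-hand sides, with every member occurrence replaced by the merged
species. The substitution is purely mechanical, so self-referential merges
work out naturally: a block containing both the substrate and the enzyme of
one reaction produces a squared-concentration binding term (dimerization).
Rate expressions are stored as signed monomials (integer coefficient ×
rate-constant symbol × product of species), not opaque callables, so that
conservation can be checked as exact polynomial cancellation; a compiled
numeric right-hand side and analytic Jacobian are generated from the same
monomials for integration.

Conservation laws start from the 2N elementary lists {S_i, C_i, P_i}
(substrate) and {E_i, C_i} (enzyme). For each block, all current lists
sharing a member with the block are **concatenated** — not union-ed — the
block's members removed, and the merged species appended once. Repeats of a
complex in the concatenation are intrinsic overlap and become integer
multiplicities (e.g. merging {S_1, E_1} yields the law y + 2·C_1 + P_1).
The result is independent of block processing order, every merged species
lands in exactly one law, and the multiplicity-weighted derivative of every
law cancels identically as a polynomial — the master invariant the test
suite checks symbolically on hundreds of random partitions.

## Steady-state protocol

Initial states satisfy every conservation law exactly: complexes start at
zero and each law's total is spread over its merged members by a flat
Dirichlet draw (uniform on the simplex). Putting all mass in non-complex
species keeps the laws independently satisfiable, since complexes couple a
substrate law to an enzyme law.

Relaxation integrates in windows of τ = 10 s (LSODA, rtol 10⁻⁶,
atol 10⁻⁹, analytic Jacobian) and declares convergence when every species'
per-window change, scaled by the conserved total of the law containing it,
falls below ε = 10⁻³. A complex belonging to two laws is scaled by the
smaller of the two totals — the tighter, scale-free choice. At most κ = 360
windows are attempted (τ·κ = 3600 s, one hour, the reference response time
of cellular signalling); integrator failures surface as non-converged
results with a diagnostic, never exceptions. Values in [−10·atol, 0) are
clamped to zero. Note the criterion measures *rate of change*, not distance
to equilibrium: very slow kinetics can be flagged converged while still
drifting, which is accepted behaviour of the protocol (the closed-form
limit test therefore uses a longer horizon, τ = 10⁴ s, κ = 1000,
ε = 10⁻⁹, where that distinction is immaterial).

## Resettable-bistability score

The input species is E_1, the output P_2; partitions placing them in one
block are excluded from the search space (the output is normalized by its
law's total while the input law's total is being swept, which such
partitions would make circular). The input law's total sweeps the 21-point
half-octave grid Ω = 2⁻⁵ … 2⁵ mmol/m³ — the physiological protein
concentration range. At each grid point θ = 5 independent random initial
states are relaxed (Monte Carlo; no continuation between grid points, so
coexisting attractors are sampled rather than tracked) and the output's
normalized steady value, clamped to [0, 1], recorded. A replicate sweep is
discarded entirely if any of its 21 relaxations fails to converge; fewer
than two surviving replicates fail the evaluation with score 0 — the
conservative choice.

Per grid point, the bistability degree is 4 × the population
(divide-by-n) variance across replicates: 0 when monostable, 1 when the
outcomes split evenly between 0 and 1 (variance 1/4). The score of the
resulting vector V is the per-position average of

    wVL(v, l) = (v − |l − 11| / 10)²,

normalized by its maximum 0.6047619 (attained at the ideal vector of six
zeros, nine ones, six zeros), so the ideal signature — monostable at the
edges of the physiological range, bistable in the centre — scores exactly 1.
An everywhere-monostable system scores 7.7/12.7 ≈ 0.606. The aggregate is
implemented as the mean over the 21 positions (the plain sum is 21 × the
mean and peaks at 12.7); for non-default grid lengths the position weight
rescales to the same edge-to-centre ramp, with the 21-point case exactly
the formula above.

Φ(P) draws λ = 5 parameter points — every rate constant and every
non-input conserved total independently uniform from
Λ = {2⁻⁵, 2⁻⁴·⁵, …, 2⁵}, spanning reported MAPK-cascade kinase values —
and returns the best (score, ν) pair. Totals are fixed per ν; only initial
allocations vary across replicates.

## Search

The main loop starts from an exactly uniform random admissible partition
(sampled by the Bell-number block-size recursion: the block containing the
first element has size k with probability C(n−1, k−1)·B_{n−k}/B_n) and
iterates P ← ψ(P, P, σ) with σ = 4, stopping when the score exceeds
ρ = 0.8 or after γ = 150 iterations.

ψ(P₀, P, σ) explores a binary tree: at each node a join candidate
(two uniformly chosen blocks merged; pairs that would merge E_1 with P_2
are redrawn) and a separate candidate (a uniformly chosen block of size ≥ 2
split at a uniform proper bipartition) are scored, each returned
immediately if it strictly beats Φ(P₀); otherwise both subtrees are
explored at depth σ − 1, and P₀ is returned if nothing wins. Within one ψ
call each distinct canonical partition is scored at most once (cached,
fresh λ draws per candidate); at most 2^(σ+1) − 2 candidates are touched.
The incumbent's score is the one recorded when it became incumbent, not
re-evaluated each iteration — with a stochastic Φ this guarantees that
accepted scores are non-decreasing along the trace, and with deterministic
evaluators it coincides with re-evaluation. Join is tried before separate
on ties, following the step order.

## Design choices and limitations

- **Uniformity conventions** (uniform block choice, uniform proper
  bipartition, uniform admissible join pair, exact uniform initial
  partition) are the package's own; only "randomly" is inherent to the
  procedure. They make the samplers testable against enumeration oracles.
- **Canonical partition form** (labels ordered S < E < P then by reaction
  index; blocks by smallest label) exists to give equality, hashing and
  deterministic enumeration; it has no physical content.
- **Per-law convergence scaling** resolves an ambiguity (a single global
  total would weight small pools too loosely); the per-law choice is
  scale-free and reduces to the obvious reading for unmerged species.
- The test fixtures and the evaluation exercise small networks (N ≤ 4) and
  modest replicate counts; a full search at the default budget
  (γ = 150, σ = 4, λ = 5, θ = 5 → up to ~10⁵ relaxations of a 16-species
  stiff system) is hours of CPU and is exercised here only at reduced
  depth/budget. Passing tests demonstrate correctness of the machinery on
  the fixture topologies, not coverage of the 4.2-million-network space.
- Simultaneous binding of multiple enzymes to one substrate, complexes as
  partition elements, and eigenvalue-based stability classification are out
  of scope; bistability is operationalized purely through the
  variance-of-replicates score.
- SBML export is not provided; the derived-model JSON export lists species,
  monomials and conservation laws.
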