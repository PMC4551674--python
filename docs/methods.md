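# Methods

This note documents the model implemented by `rnagame`, the parameter
choices that matter, the synthetic data used for testing, and the known
limitations.

## Coarse-grained graph model

An RNA secondary structure (sequence plus non-crossing base pairs) is
decomposed into secondary structure elements. Helices are maximal runs
of stacked pairs; every loop region — its unpaired nucleotides together
with the closing pairs of the incident helices — is one junction element
whose kind is its helix degree (terminal loop, two-way, three-way,
four-way). Pseudoknots are rejected: the method's tree representation
requires nested structure.

Players are created per element: ⌈b/5⌉ players for a helix of b base
pairs (base pairs split as evenly as possible, at most five per player,
so long helices retain long-range flexibility), one player for one- and
two-way junctions, and two for a three-way junction — a STACK player at
the junction-facing base pairs of the two coaxially stacked helices and
a BRANCH player at the junction centre. Which two helices stack is an
input hint; the default heuristic stacks the two helices joined by the
shortest strand, a deterministic stand-in for experimentally known
stacking. A four-way junction is approximated by two stack/branch pairs
bridged by a linker player (five players), with the first two incident
helices in 5′ order assigned to one pseudo-three-way and the last two to
the other.

Edges follow covalent connectivity and form a tree. The edge between a
junction's own STACK and BRANCH players is 1 lattice unit; all other
edges — helix–junction and consecutive chunks of one long helix — are
2 units. The two-unit choice for intra-helix edges is a modelling
decision: the observed adjacent-node distance statistics distinguish
only same-junction (≈5.6 Å) from different-element (≈11.2 Å) pairs, and
a five-base-pair rise (≈11–14 Å) is far closer to the second mode.

Ordering: when the molecule contains a branching (degree ≥ 3) junction,
the depth-first search is rooted at the highest-degree junction nearest
the 5′ end and, at a three-way junction, explores the subtree through
the unstacked helix (behind the BRANCH player) first. Molecules without
branching junctions are walked from the 5′ end, which makes a hairpin's
order "helix, loop" and a chain's order the backbone order.

## Lattice geometry

Conformations live on the FCC lattice: integer triples reachable from
the origin by the 12 signed permutations of (1,1,0). One step (vector
norm √2) is calibrated to 5.6 Å. All geometry is exact integer
arithmetic:

* players occupy distinct sites;
* each length-2 edge occupies its midpoint site, so chains cannot thread
  through an edge;
* no two edges that lack a common player may share any point (segment
  intersection decided with integer cross products; collinear overlap
  beyond a shared endpoint also counts).

A player's action re-aims one outgoing tree edge: the child moves to
`parent + length · direction` and the child's entire subtree translates
rigidly with it (the alternative — re-randomising the subtree — would
make one action a global perturbation). Direction sets depend on the
acting player: helix players may continue straight or bend 60° (five
directions); frozen players of long helices (> 5 bp) must continue
straight; two-way junctions with one strand shorter than two nucleotides
behave like bendable helices; all other junction players, and the root,
use all 12 directions. A player whose legal set is empty skips its turn
without a bandit update.

Random embeddings place the root at the origin and walk the tree in DFS
order, drawing uniformly from each edge's legal directions with
backtracking, restarting up to 1000 times (an embedding failure raises).
The same self-avoidance predicates back both the public, pure-Python
API (`edges_intersect`, `Conformation.is_valid`) and numba-compiled
kernels used inside the sampling loop; the test suite cross-checks the
two against an independent rational-arithmetic oracle.

## Knowledge-based scoring

For every unordered pair of SSE-type classes (HELIX, ONE_WAY, TWO_WAY,
THREE_WAY — the three-way stack, branch and linker players all score as
THREE_WAY) a functional form of the inter-player distance d is fitted:

| form | expression | parameters |
| --- | --- | --- |
| LJ | −A((B/d)¹² − 2(B/d)⁶) | B = preferred distance (Å), A = 1 |
| Modified LJ | max(LJ, 0) | as LJ; repulsion clamped |
| Gauss | Σₖ Aₖ·N(d; μₖ, σₖ) | 1–5 components, EM-fitted, BIC-selected |
| 1/d² | d⁻² | none |

Fitting uses the distances between non-adjacent players pooled over a
reference ensemble of coarse-grained structures. The LJ preferred
distance B is the mode of a Gaussian kernel density estimate with twice
Scott's bandwidth: the LJ forms encode a single preferred distance, and
oversmoothing stabilises the argmax against sampling noise without
biasing a symmetric peak. The Gaussian mixture is a finite mixture with
BIC model selection over 1–5 components — a deterministic, desk-scale
replacement for nonparametric mixture machinery with the same functional
output. Class pairs never observed non-adjacently (possible on tiny
graphs) borrow the pooled distance sample.

Every fitted form is sup-normalised so its maximum over the observed
distance range is 1. For 1/d², whose supremum on (0, ∞) is unbounded,
the normaliser is the score at the smallest observed fitting distance,
so the normalised score is ≤ 1 wherever data existed.

A player's score is the sum of its normalised pair terms with **all**
other players (adjacent pairs included — their lattice-fixed distances
contribute a near-constant offset). The bandit reward is the score
divided by the number of partners and clipped to [0, 1]; bounded rewards
are what the UCB/EXP3 guarantees assume, and the clip only engages for
the plain LJ form, whose repulsive branch is negative.

Frozen helices cannot bend, so their own geometry carries little signal;
a frozen helix player's score is instead borrowed from the nearest
non-helix player along each incident tree branch, weighted by inverse
hop distance and averaged. (Walking to the *nearest* junction rather
than only to graph-adjacent neighbours is what gives the interior
players of a long helix a defined score; a frozen helix with no junction
in reach falls back to its own pair score with a warning.)

## The sampling game

Each tree edge owns a 12-armed bandit kept by the edge's parent:

* **UCB1**: pick the legal arm maximising mean + c·√(2 ln t / n_a),
  c = 1; unpulled legal arms are forced first in canonical direction
  order, ties broken canonically.
* **EXP3**: sample from (1−γ)·w/Σw + γ/K restricted to the legal set,
  γ = 0.1; the drawn arm's weight is multiplied by
  exp(γ·reward/(p·K)). Weights are rescaled when they approach overflow
  (the distribution is scale-free).

Gameplays (per turn):

* **AA** — every edge selects against the start-of-turn conformation;
  actions are applied in DFS order with legality re-checked on the
  evolving conformation (an action illegal at application is skipped);
  then all players score and all applied actions update.
* **OA** — one edge acts (round-robin in DFS edge order), then every
  edge updates with its player's new reward, non-acting edges updating
  their currently-held direction (for EXP3 the probability of that
  direction under the current policy over the allowed set is used).
* **OO** — one edge acts and only that edge updates.

One edge rather than one player acts per OA/OO turn so that a single
turn moves at most one subtree even at branching players. In OA and OO
the turn budget is the AA budget divided by the number of players,
keeping the number of bandit updates comparable across gameplays; the
default budget is 4000 turns, by which the regret diagnostics on the toy
fixtures have settled.

The default configuration is chosen from the molecule: without a
three-way junction, OA/UCB/Modified-LJ with frozen helices (a smooth
local optimisation); with one, AA/EXP3 with plain LJ when helix players
outnumber junction players by more than 1.5×, Modified-LJ otherwise
(the rugged, junction-dominated landscape favours Boltzmann-style
exploration, and abundant helices need the repulsive core to avoid
collapse). A sample set is the final conformations of n independent
games seeded seed, seed+1, …, which maximises diversity and makes runs
embarrassingly parallel; everything is bit-reproducible given the seed.

### Regret

A player's regret after T turns is the best fixed direction's cumulative
counterfactual reward minus the accumulated actual reward, with the
counterfactual recomputed geometrically against the recorded positions
of the other players. For players owning several edges the fixed
strategy is applied to the first (DFS) outgoing edge. Counterfactual
configurations are not legality-checked — a fixed strategy may stack
players — so pair distances are floored at 10⁻⁶ Å to keep scores finite.

The regret amplitude (per-turn increment of the regret series) settles
as games progress: its mean over the final quarter of a 4000-turn AA/EXP3
run is below the first quarter's in essentially every seeded run. The
*maximum* per-turn increment is a brittle statistic, however: with a
fixed exploration rate γ, rare exploration moves keep occurring late in
the game, and their severity grows as the rest of the system optimises
(the counterfactual best approaches the reward ceiling while the
exploring move wrecks the actual reward), so the late-game maximum often
exceeds the early-game one even though the typical amplitude shrinks.
The test suite asserts the mean-amplitude property and documents the
max-statistic behaviour.

## Evaluation

Native structures are coarse-grained by mapping chain residues in order
onto the secondary structure and averaging the heavy-atom (non-hydrogen)
coordinates of each player's nucleotides; the three-way STACK player
uses the first base pair of the two stacked helices, the BRANCH player
the whole junction. RMSD is computed after least-squares superposition
restricted to proper rotations (Kabsch with a reflection guard); fewer
than three points or collinear point sets are rejected as degenerate.
Sample sets are summarised by min/max RMSD, the count under a threshold,
and (energy, RMSD) pairs with energy = −total score.

## Synthetic fixtures

The fixture generator provides the toy topologies (hairpin, bulged
hairpin, three-way, four-way, long helix) with ground-truth player
counts, and reference ensembles whose non-adjacent inter-player
distances follow prescribed Gaussian or bimodal laws (default: Gaussian
with μ = 15 Å, σ = 2 Å, a typical inter-element distance scale for
small RNAs at this coarse-graining). Each ensemble member embeds a
random target distance matrix (adjacent pairs at their lattice lengths,
non-adjacent pairs drawn from their laws) into 3D by classical
multidimensional scaling, rescales to its own target mean, and a global
calibration loop then matches each law's empirical mean within 2%
(raising a generation error if it cannot).

What the ensemble does and does not emulate: the *location* (mean/modes)
of the target distance laws is reproduced faithfully, which is what the
score-fitting pipeline consumes; the *width* of the pooled distance
distribution is inflated by within-structure geometric spread, so tests
of σ-recovery draw distances directly from the law rather than from
ensembles. Real reference sets differ in further ways — correlated
distances along the backbone, sequence effects, junction-specific
anisotropy — so green tests demonstrate the machinery (fitting,
normalisation, sampling, evaluation) rather than biological accuracy of
any particular potential.

Synthetic native PDB files place one C1′ pseudo-atom per nucleotide at
the coordinate of the first player containing it; because closing base
pairs belong to both their helix and their junction, re-coarse-graining
such a file blurs junction centres by up to about one lattice step.
These files are labelled synthetic and exist for round-trip and pipeline
tests only.

## Numerical and engineering choices

* Exact integer geometry everywhere on the lattice; no floating-point
  tolerances in legality decisions.
* The validity/legality hot path is numba-compiled; first use in a fresh
  process pays a one-time JIT cost.
* Problem sizes in the test-suite and in `scripts/acceptance.py` are the
  toy fixtures (2–15 players), 4000-turn games, 50-sample runs and
  150–200-structure ensembles — sizes at which every quantity stabilises
  while the whole pipeline stays desk-scale.
* Ties everywhere (UCB argmax, KDE grid argmax, stacking heuristic,
  DFS child order) break deterministically in canonical order, which is
  what makes end-to-end byte-reproducibility possible.

## Limitations

* No all-atom reconstruction: outputs are player-level pseudo-atom
  models for downstream tools.
* Pseudoknots and junctions of degree > 4 are rejected.
* The lattice discretises orientation: a player's RMSD floor against an
  off-lattice native is on the order of half a lattice step even for a
  perfect topology.
* Scores fitted from the bundled synthetic ensembles are placeholders
  for potentials fitted on curated experimental structures; the `fit`
  command accepts any directory of coarse-grained structures for that
  purpose.
* With a fixed EXP3 exploration rate the sampler keeps exploring at
  equilibrium by design; single-run trajectories therefore never become
  strictly stationary, only their typical amplitude does.
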