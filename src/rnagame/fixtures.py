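"""Synthetic fixtures: toy secondary structures and reference ensembles.

Real pipelines derive scoring parameters from a curated set of solved
structures.  To keep the whole tool testable offline, this module
generates (a) dot-bracket strings for the standard toy topologies with
ground-truth SSE/player counts, and (b) synthetic ensembles of player
coordinates whose non-adjacent inter-player distances follow prescribed
Gaussian or bimodal-Gaussian laws, suitable inputs for score fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import FormatError, GenerationError
from .evaluation import NativeGraph
from .graph import RNAGraph, build_graph_from_dotbracket
from .lattice import STEP_ANGSTROM
from .scoring import PairScoreTable, ScoringForm, fit_pair_params

__all__ = [
    "FixtureTopology",
    "FixtureSpec",
    "SyntheticEnsembleSpec",
    "make_fixture",
    "make_reference_ensemble",
    "collect_pair_distances",
    "fit_table",
    "make_score_table",
]


class FixtureTopology(Enum):
    HAIRPIN = "HAIRPIN"
    BULGED_HAIRPIN = "BULGED_HAIRPIN"
    THREE_WAY = "THREE_WAY"
    FOUR_WAY = "FOUR_WAY"
    LONG_HELIX = "LONG_HELIX"


@dataclass(frozen=True)
class FixtureSpec:
    topology: FixtureTopology
    helix_lengths: tuple = ()
    loop_lengths: tuple = ()
    seed: int = 0

    def with_defaults(self) -> "FixtureSpec":
        defaults = {
            FixtureTopology.HAIRPIN: ((4,), (4,)),
            FixtureTopology.BULGED_HAIRPIN: ((4, 4), (3, 4)),
            FixtureTopology.THREE_WAY: ((4, 4, 4), (2, 2, 2, 3, 3)),
            FixtureTopology.FOUR_WAY: ((4, 4, 4, 4), (2, 2, 2, 2, 3, 3, 3)),
            FixtureTopology.LONG_HELIX: ((12,), (4,)),
        }
        h, l = defaults[self.topology]
        return FixtureSpec(
            self.topology,
            self.helix_lengths or h,
            self.loop_lengths or l,
            self.seed,
        )


def _hairpin(h, loop):
    return "(" * h + "." * loop + ")" * h, "G" * h + "A" * loop + "C" * h


def make_fixture(spec: FixtureSpec):
    """Deterministic dot-bracket text plus ground-truth counts.

    Returns ``(text, expected)`` with expected player/SSE counts computed
    from the coarse-graining rules (ceil(bp/5) players per helix, one per
    one-/two-way junction, two per three-way, five per four-way).
    """
    spec = spec.with_defaults()
    h, l = spec.helix_lengths, spec.loop_lengths
    t = spec.topology
    if t in (FixtureTopology.HAIRPIN, FixtureTopology.LONG_HELIX):
        if len(h) != 1 or len(l) != 1:
            raise FormatError("hairpin needs 1 helix length and 1 loop length")
        struct, seq = _hairpin(h[0], l[0])
        expected = {
            "n_helices": 1,
            "n_junctions": 1,
            "n_players": math.ceil(h[0] / 5) + 1,
        }
    elif t is FixtureTopology.BULGED_HAIRPIN:
        if len(h) != 2 or len(l) != 2:
            raise FormatError("bulged hairpin needs 2 helices and 2 loops "
                              "(bulge, terminal)")
        inner, inner_seq = _hairpin(h[1], l[1])
        struct = "(" * h[0] + "." * l[0] + inner + ")" * h[0]
        seq = "G" * h[0] + "A" * l[0] + inner_seq + "C" * h[0]
        expected = {
            "n_helices": 2,
            "n_junctions": 2,
            "n_players": math.ceil(h[0] / 5) + math.ceil(h[1] / 5) + 2,
        }
    elif t is FixtureTopology.THREE_WAY:
        if len(h) != 3 or len(l) != 5:
            raise FormatError("three-way needs 3 helices and 5 loops "
                              "(3 junction strands, 2 hairpin loops)")
        g0, g1, g2, l1, l2 = l
        arm1, arm1_seq = _hairpin(h[1], l1)
        arm2, arm2_seq = _hairpin(h[2], l2)
        struct = ("(" * h[0] + "." * g0 + arm1 + "." * g1 + arm2
                  + "." * g2 + ")" * h[0])
        seq = ("G" * h[0] + "A" * g0 + arm1_seq + "A" * g1 + arm2_seq
               + "A" * g2 + "C" * h[0])
        expected = {
            "n_helices": 3,
            "n_junctions": 3,  # the three-way plus two terminal loops
            "n_players": sum(math.ceil(b / 5) for b in h) + 2 + 2,
        }
    elif t is FixtureTopology.FOUR_WAY:
        if len(h) != 4 or len(l) != 7:
            raise FormatError("four-way needs 4 helices and 7 loops "
                              "(4 junction strands, 3 hairpin loops)")
        g0, g1, g2, g3, l1, l2, l3 = l
        arms = [_hairpin(h[k], (l1, l2, l3)[k - 1]) for k in (1, 2, 3)]
        struct = ("(" * h[0] + "." * g0 + arms[0][0] + "." * g1 + arms[1][0]
                  + "." * g2 + arms[2][0] + "." * g3 + ")" * h[0])
        seq = ("G" * h[0] + "A" * g0 + arms[0][1] + "A" * g1 + arms[1][1]
               + "A" * g2 + arms[2][1] + "A" * g3 + "C" * h[0])
        expected = {
            "n_helices": 4,
            "n_junctions": 4,
            "n_players": sum(math.ceil(b / 5) for b in h) + 5 + 3,
        }
    else:  # pragma: no cover
        raise FormatError(f"unknown topology {t}")
    text = f">{t.value.lower()}\n{seq}\n{struct}\n"
    return text, expected


# ---------------------------------------------------------------------------
# synthetic reference ensembles


@dataclass(frozen=True)
class SyntheticEnsembleSpec:
    """Distance laws for the synthetic reference ensemble.

    ``laws`` maps ``"CLASS_A|CLASS_B"`` (sorted) or the catch-all ``"*"``
    to either ``{"distribution": "gaussian", "mu": .., "sigma": ..}`` or
    ``{"distribution": "bimodal", "components": [[w, mu, sigma], ..]}``.
    """

    laws: dict = field(default_factory=lambda: {
        "*": {"distribution": "gaussian", "mu": 15.0, "sigma": 2.0}
    })
    n_structures: int = 200
    seed: int = 0

    def law_for(self, ci: str, cj: str) -> dict:
        key = "|".join(sorted((ci, cj)))
        law = self.laws.get(key, self.laws.get("*"))
        if law is None:
            raise GenerationError(f"no distance law for pair {key}")
        return law

    def components(self, ci: str, cj: str):
        law = self.law_for(ci, cj)
        if law["distribution"] == "gaussian":
            return [(1.0, float(law["mu"]), float(law["sigma"]))]
        comps = [(float(w), float(mu), float(s))
                 for w, mu, s in law["components"]]
        total = sum(w for w, _, _ in comps)
        if abs(total - 1.0) > 1e-9:
            raise GenerationError("mixture weights must sum to 1")
        return comps


def _nonadjacent_pairs(graph: RNAGraph):
    n = graph.n_players
    pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if frozenset((i, j)) not in graph.edges
    ]
    if not pairs:
        # tiny graphs (e.g. a hairpin) have only adjacent pairs; use them
        # so fitting and fixtures stay possible
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    return pairs


def _classical_mds(D: np.ndarray) -> np.ndarray:
    """Closest 3D configuration to a target distance matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:3]
    lam = np.clip(vals[idx], 0.0, None)
    X = vecs[:, idx] * np.sqrt(lam)
    if X.shape[1] < 3:  # fewer than 4 points span fewer than 3 axes
        X = np.hstack([X, np.zeros((n, 3 - X.shape[1]))])
    return X


def make_reference_ensemble(spec: SyntheticEnsembleSpec, graph: RNAGraph,
                            tolerance: float = 0.02, max_iter: int = 20):
    """Generate coordinate sets whose non-adjacent inter-player distances
    follow the spec's laws.

    Each structure embeds a random target distance matrix (adjacent pairs
    at their lattice lengths, non-adjacent pairs drawn from their laws)
    in 3D; a global per-law rescale loop then matches the empirical mean
    of each law group to its target mean within ``tolerance``.
    """
    rng = np.random.default_rng(spec.seed)
    n = graph.n_players
    pairs = _nonadjacent_pairs(graph)
    classes = [p.scoring_class for p in graph.players]
    if not pairs:
        raise GenerationError("graph has no non-adjacent player pairs")

    coord_sets = []
    for _ in range(spec.n_structures):
        D = np.zeros((n, n))
        for e, length in graph.edges.items():
            i, j = sorted(e)
            D[i, j] = D[j, i] = length * STEP_ANGSTROM
        targets = []
        for i, j in pairs:
            comps = spec.components(classes[i], classes[j])
            ws = np.array([w for w, _, _ in comps])
            k = rng.choice(len(comps), p=ws / ws.sum())
            d = -1.0
            while d <= 0:
                d = rng.normal(comps[k][1], comps[k][2])
            D[i, j] = D[j, i] = d
            targets.append(d)
        X = _classical_mds(D)
        # the 3D embedding shrinks infeasible target matrices; restore the
        # structure's own mean non-adjacent distance
        realized = np.array([np.linalg.norm(X[i] - X[j]) for i, j in pairs])
        X = X * (np.mean(targets) / realized.mean())
        coord_sets.append(X)

    # global calibration, one group per distinct target mean
    groups = {}
    for i, j in pairs:
        mean_d = sum(
            w * mu for w, mu, _ in spec.components(classes[i], classes[j])
        )
        groups.setdefault(round(mean_d, 9), []).append((i, j))
    for _ in range(max_iter):
        worst = 0.0
        factors = []
        for target, idx in groups.items():
            ds = np.array([
                np.linalg.norm(X[i] - X[j]) for X in coord_sets
                for i, j in idx
            ])
            ratio = target / ds.mean()
            factors.append(ratio)
            worst = max(worst, abs(ratio - 1.0))
        if worst <= tolerance:
            return [NativeGraph(graph=graph, coords=X) for X in coord_sets]
        scale = float(np.mean(factors))
        coord_sets = [X * scale for X in coord_sets]
    raise GenerationError(
        f"ensemble means not within {tolerance:.0%} after {max_iter} rescales"
    )


# ---------------------------------------------------------------------------
# fitting pipeline helpers


def collect_pair_distances(graph: RNAGraph, coord_sets) -> dict:
    """Pool non-adjacent inter-player distances per SSE-class pair."""
    classes = [p.scoring_class for p in graph.players]
    out = {}
    for X in coord_sets:
        X = getattr(X, "coords", X)
        for i, j in _nonadjacent_pairs(graph):
            key = tuple(sorted((classes[i], classes[j])))
            out.setdefault(key, []).append(float(np.linalg.norm(X[i] - X[j])))
    return out


def fit_table(graph: RNAGraph, coord_sets, form: ScoringForm,
              min_samples: int = 30, seed: int = 0) -> PairScoreTable:
    """Fit a full score table (all class pairs present in the graph) from
    an ensemble of coordinate sets."""
    dists = collect_pair_distances(graph, coord_sets)
    classes = sorted({p.scoring_class for p in graph.players})
    pooled = [d for v in dists.values() for d in v]
    table = PairScoreTable()
    for a in range(len(classes)):
        for b in range(a, len(classes)):
            key = (classes[a], classes[b])
            # pairs never observed non-adjacently borrow the pooled law
            samples = dists.get(tuple(sorted(key)), pooled)
            table.set(*key, fit_pair_params(samples, form,
                                            min_samples=min_samples,
                                            seed=seed))
    return table


def make_score_table(graph_or_dbn, form: ScoringForm = ScoringForm.MODIFIED_LJ,
                     spec: SyntheticEnsembleSpec | None = None,
                     seed: int = 0) -> PairScoreTable:
    """End-to-end convenience: synthetic ensemble -> fitted score table."""
    graph = (
        graph_or_dbn
        if isinstance(graph_or_dbn, RNAGraph)
        else build_graph_from_dotbracket(graph_or_dbn)
    )
    spec = spec or SyntheticEnsembleSpec(seed=seed)
    ensemble = make_reference_ensemble(spec, graph)
    return fit_table(graph, [ng.coords for ng in ensemble], form, seed=seed)
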