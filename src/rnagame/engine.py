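"""Regret-minimisation sampling games on the player graph.

Every tree edge of the player graph carries a 12-armed bandit owned by
the edge's parent player: an arm is a lattice direction for the child.
Two bandit policies are implemented:

* **UCB1** — deterministic optimism: pick the arm maximising
  ``mean + c * sqrt(2 ln t / n_a)``; unpulled arms first.
* **EXP3** — exponential weights with importance-weighted updates and a
  ``gamma``-uniform exploration mixture (a Boltzmann-like sampler over
  accumulated scores).

Three gameplays schedule who acts and who updates each turn: AA (all
play, all update), OA (one plays round-robin, all update) and OO (one
plays, only that one updates).  In OA/OO the turn budget is the AA
budget divided by the number of players, so all gameplays perform a
comparable number of bandit updates.

The per-player regret (gap to the best fixed direction in hindsight,
evaluated against the recorded trajectory of the other players) is the
convergence diagnostic: its per-turn amplitude flattening out signals
that the game has settled near an equilibrium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import RNAGameError
from .graph import PlayerType, RNAGraph, helix_junction_ratio
from .lattice import (
    DIRECTIONS,
    N_DIRECTIONS,
    Conformation,
    StrategySet,
    _allowed_for_edge,
    _arrays,
    legal_actions,
    random_embedding,
)
from .scoring import PairScoreTable, ScoringForm, player_rewards, total_score

__all__ = [
    "Gameplay",
    "Algorithm",
    "GameConfig",
    "BanditState",
    "RegretTrace",
    "SampleSet",
    "ucb_select",
    "exp3_probs",
    "exp3_select",
    "update_ucb",
    "update_exp3",
    "play_turn",
    "run_game",
    "sample",
    "regret",
    "regret_series",
    "default_gameplay",
]


class Gameplay(Enum):
    AA = "AA"
    OA = "OA"
    OO = "OO"


class Algorithm(Enum):
    UCB = "UCB"
    EXP3 = "EXP3"


DEFAULT_TURNS = 4000  # regret amplitude is stationary by then on toy graphs


@dataclass
class GameConfig:
    gameplay: Gameplay = Gameplay.OA
    algorithm: Algorithm = Algorithm.UCB
    form: ScoringForm = ScoringForm.MODIFIED_LJ
    frozen: bool = True
    turns: int = DEFAULT_TURNS
    n_samples: int = 50
    seed: int = 0
    ucb_c: float = 1.0
    exp3_gamma: float = 0.1

    def __post_init__(self):
        if self.turns < 0:
            raise RNAGameError("turns must be >= 0")
        if self.n_samples < 1:
            raise RNAGameError("n_samples must be >= 1")
        if not (0 < self.exp3_gamma <= 1):
            raise RNAGameError("exp3_gamma must be in (0, 1]")

    def to_dict(self):
        return {
            "gameplay": self.gameplay.value,
            "algorithm": self.algorithm.value,
            "form": self.form.value,
            "frozen": self.frozen,
            "turns": self.turns,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "ucb_c": self.ucb_c,
            "exp3_gamma": self.exp3_gamma,
        }

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        for key, enum in (("gameplay", Gameplay), ("algorithm", Algorithm),
                          ("form", ScoringForm)):
            if key in d:
                d[key] = enum(d[key])
        return cls(**d)


@dataclass
class BanditState:
    """Arm statistics for one player-edge (12 lattice directions)."""

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros(N_DIRECTIONS, dtype=np.int64)
    )
    means: np.ndarray = field(
        default_factory=lambda: np.zeros(N_DIRECTIONS)
    )
    weights: np.ndarray = field(
        default_factory=lambda: np.ones(N_DIRECTIONS)
    )
    t: int = 0


@dataclass
class RegretTrace:
    """Recorded trajectory: per-turn positions and per-player rewards."""

    graph: RNAGraph
    positions: np.ndarray  # (T, n, 3) int64, post-turn lattice positions
    scores: np.ndarray     # (T, n) normalised per-player rewards
    step_angstrom: float

    @property
    def n_turns(self) -> int:
        return self.positions.shape[0]


@dataclass
class SampleSet:
    """Conformations from independent seeded games."""

    samples: list          # Conformation per game
    total_scores: list     # total score of each sample
    config: GameConfig
    seeds: list
    rmsds: list | None = None

    def __len__(self):
        return len(self.samples)


# ---------------------------------------------------------------------------
# bandit policies


def ucb_select(state: BanditState, legal, ucb_c: float = 1.0):
    """UCB1 arm choice over the legal set; unpulled legal arms are forced
    first, ties resolved in canonical direction order.  Returns None on an
    empty legal set (skip-turn)."""
    acts = tuple(legal)
    if not acts:
        return None
    for a in acts:  # canonical order is preserved by StrategySet
        if state.counts[a] == 0:
            return a
    t = max(state.t, 1)
    scores = [
        state.means[a] + ucb_c * np.sqrt(2.0 * np.log(t) / state.counts[a])
        for a in acts
    ]
    return acts[int(np.argmax(scores))]


def exp3_probs(state: BanditState, actions, gamma: float) -> np.ndarray:
    """EXP3 distribution over ``actions``: exponential weights restricted
    to the set and renormalised, mixed with gamma-uniform exploration."""
    acts = np.asarray(tuple(actions), dtype=np.int64)
    w = state.weights[acts]
    return (1.0 - gamma) * w / w.sum() + gamma / len(acts)


def exp3_select(state: BanditState, legal, rng, gamma: float = 0.1):
    """Sample an arm from the EXP3 distribution over the legal set;
    None on an empty set."""
    acts = tuple(legal)
    if not acts:
        return None
    p = exp3_probs(state, acts, gamma)
    return int(rng.choice(np.asarray(acts), p=p / p.sum()))


def _clip_reward(reward: float) -> float:
    if reward < 0.0 or reward > 1.0:
        warnings.warn(f"reward {reward} outside [0, 1]; clipped")
        return min(max(reward, 0.0), 1.0)
    return float(reward)


def update_ucb(state: BanditState, action: int, reward: float) -> BanditState:
    """Running-mean update of the pulled arm."""
    reward = _clip_reward(reward)
    state.counts[action] += 1
    state.means[action] += (reward - state.means[action]) / state.counts[action]
    state.t += 1
    return state


def update_exp3(state: BanditState, action: int, reward: float, gamma: float,
                p_action: float, n_legal: int) -> BanditState:
    """Importance-weighted exponential update of the drawn arm."""
    if p_action <= 0:
        raise RNAGameError("EXP3 update requires the drawn probability > 0")
    reward = _clip_reward(reward)
    state.weights[action] *= np.exp(gamma * reward / (p_action * n_legal))
    # guard against overflow on long runs; the distribution is scale-free
    top = state.weights.max()
    if top > 1e100:
        state.weights /= top
    state.counts[action] += 1
    state.t += 1
    return state


# ---------------------------------------------------------------------------
# gameplays


def _acting_edges(graph: RNAGraph):
    """(parent, child) edges in DFS order, grouped by acting player."""
    return [
        (pid, c)
        for pid in graph.ordering
        for c in graph.children.get(pid, [])
    ]


def _select(state, legal, config: GameConfig, rng):
    """Policy dispatch; returns (action, p_action, n_legal) or None."""
    acts = tuple(legal)
    if not acts:
        return None
    if config.algorithm is Algorithm.UCB:
        a = ucb_select(state, acts, config.ucb_c)
        return a, 1.0, len(acts)
    p = exp3_probs(state, acts, config.exp3_gamma)
    p = p / p.sum()
    a = int(rng.choice(np.asarray(acts), p=p))
    return a, float(p[acts.index(a)]), len(acts)


def _update(state, action, reward, p_action, n_legal, config: GameConfig):
    if config.algorithm is Algorithm.UCB:
        update_ucb(state, action, reward)
    else:
        update_exp3(state, action, reward, config.exp3_gamma, p_action, n_legal)


def _apply_checked(conf, parent, child, action):
    """Apply if still legal on the evolving conformation; None if not."""
    la = legal_actions(conf, parent, child)
    if action not in la.directions:
        return None
    arr = _arrays(conf.graph)
    e = arr.edge_of_child[child]
    target = conf.positions[parent] + arr.lengths[e] * DIRECTIONS[action]
    delta = target - conf.positions[child]
    conf.positions[arr.subtree[e]] += delta
    return conf


def play_turn(conf: Conformation, states: dict, config: GameConfig,
              table: PairScoreTable, rng, turn_index: int = 0):
    """Advance the game by one turn under the configured gameplay.

    ``states`` maps each edge's child id to its BanditState.  The
    conformation is modified in place; blocked edges (empty legal set)
    skip without an update.
    """
    graph = conf.graph
    edges = _acting_edges(graph)

    if config.gameplay is Gameplay.AA:
        # phase 1: everyone selects against the start-of-turn conformation
        start = conf.copy()
        picks = []
        for parent, child in edges:
            sel = _select(
                states[child], legal_actions(start, parent, child),
                config, rng,
            )
            if sel is not None:
                picks.append((parent, child, *sel))
        # phase 2: apply in DFS order, re-checking legality as the
        # conformation evolves; then everyone scores and updates
        applied = []
        for parent, child, action, p_a, n_legal in picks:
            if _apply_checked(conf, parent, child, action) is not None:
                applied.append((parent, child, action, p_a, n_legal))
        rewards = player_rewards(conf, table)
        for parent, child, action, p_a, n_legal in applied:
            _update(states[child], action, rewards[parent], p_a, n_legal,
                    config)
        return conf, states

    # OA/OO: a single edge acts per turn, round-robin in DFS edge order
    if not edges:
        return conf, states
    actor, acting_child = edges[turn_index % len(edges)]

    drawn = {}
    sel = _select(
        states[acting_child], legal_actions(conf, actor, acting_child),
        config, rng,
    )
    if sel is not None:
        action, p_a, n_legal = sel
        if _apply_checked(conf, actor, acting_child, action) is not None:
            drawn[acting_child] = (action, p_a, n_legal)

    rewards = player_rewards(conf, table)

    if config.gameplay is Gameplay.OO:
        for child, (action, p_a, n_legal) in drawn.items():
            _update(states[child], action, rewards[actor], p_a, n_legal,
                    config)
        return conf, states

    # OA: every player folds the new scores into its current strategy
    for parent, child in edges:
        if child in drawn:
            action, p_a, n_legal = drawn[child]
        else:
            action = _current_action(conf, parent, child)
            allowed = _allowed_for_edge(conf, parent)
            if action not in allowed:
                continue
            if config.algorithm is Algorithm.EXP3:
                p = exp3_probs(states[child], allowed, config.exp3_gamma)
                p_a = float(p[allowed.index(action)] / p.sum())
            else:
                p_a = 1.0
            n_legal = len(allowed)
        _update(states[child], action, rewards[parent], p_a, n_legal, config)
    return conf, states


def _current_action(conf: Conformation, parent: int, child: int) -> int:
    from .lattice import direction_index

    return direction_index(conf.edge_direction(parent, child))


def _turn_budget(config: GameConfig, graph: RNAGraph) -> int:
    if config.turns == 0 or config.gameplay is Gameplay.AA:
        return config.turns
    return max(1, config.turns // max(graph.n_players, 1))


def run_game(graph: RNAGraph, config: GameConfig, table: PairScoreTable,
             seed=None):
    """One full game: random start, ``turns`` turns, returns the final
    conformation and the recorded trace."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    for p in graph.players:
        p.frozen = bool(config.frozen) and p.ptype is PlayerType.HELIX
    conf = random_embedding(graph, rng)
    n = graph.n_players
    T = _turn_budget(config, graph)
    states = {child: BanditState() for _, child in _acting_edges(graph)}
    positions = np.zeros((T, n, 3), dtype=np.int64)
    scores = np.zeros((T, n))
    for t in range(T):
        play_turn(conf, states, config, table, rng, turn_index=t)
        positions[t] = conf.positions
        scores[t] = player_rewards(conf, table)
    trace = RegretTrace(
        graph=graph, positions=positions, scores=scores,
        step_angstrom=conf.step_angstrom,
    )
    return conf, trace


def sample(graph: RNAGraph, config: GameConfig,
           table: PairScoreTable) -> SampleSet:
    """``n_samples`` independent games seeded ``seed, seed+1, ...``; each
    contributes its final conformation."""
    confs, totals, seeds = [], [], []
    for k in range(config.n_samples):
        s = config.seed + k
        conf, _ = run_game(graph, config, table, seed=s)
        confs.append(conf)
        totals.append(total_score(conf, table))
        seeds.append(s)
    return SampleSet(samples=confs, total_scores=totals, config=config,
                     seeds=seeds)


# ---------------------------------------------------------------------------
# regret


def _counterfactual_rewards(trace: RegretTrace, table: PairScoreTable,
                            player: int, direction: int) -> np.ndarray:
    """Reward player would have received at each recorded turn had its
    primary edge always aimed at ``direction`` (others as recorded)."""
    graph = trace.graph
    child = (graph.children.get(player) or [None])[0]
    T, n = trace.scores.shape
    if child is None:
        return trace.scores[:, player].copy()
    arr = _arrays(graph)
    e = arr.edge_of_child[child]
    sub = arr.subtree[e]
    pos = trace.positions.astype(float).copy()  # (T, n, 3)
    target = pos[:, player, :] + arr.lengths[e] * DIRECTIONS[direction]
    delta = target - pos[:, child, :]
    pos[:, sub, :] += delta[:, None, :]
    xyz = pos * (trace.step_angstrom / np.sqrt(2.0))
    diff = xyz[:, :, None, :] - xyz[:, None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))  # (T, n, n)
    # a fixed strategy may stack players on one site (counterfactuals are
    # not legality-checked); keep the pair scores finite
    dist = np.maximum(dist, 1e-6)
    classes = [p.scoring_class for p in graph.players]
    S = np.zeros((T, n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals = table.get(classes[i], classes[j]).score(dist[:, i, j])
            S[:, i, j] = vals
            S[:, j, i] = vals
    row_sums = S.sum(axis=2)  # (T, n)
    pl = graph.players[player]
    if pl.frozen and pl.ptype is PlayerType.HELIX:
        from .scoring import _frozen_neighbors

        neigh = _frozen_neighbors(graph, player)
        if neigh:
            score = sum(row_sums[:, q] / d for q, d in neigh) / len(neigh)
        else:
            score = row_sums[:, player]
    else:
        score = row_sums[:, player]
    return np.clip(score / max(n - 1, 1), 0.0, 1.0)


def regret_series(trace: RegretTrace, table: PairScoreTable,
                  player: int) -> np.ndarray:
    """Regret_i(t) for t = 1..T: best fixed direction in hindsight minus
    the accumulated reward."""
    T = trace.n_turns
    actual = np.cumsum(trace.scores[:, player])
    cf = np.stack([
        np.cumsum(_counterfactual_rewards(trace, table, player, d))
        for d in range(N_DIRECTIONS)
    ])
    return cf.max(axis=0) - actual


def regret(trace: RegretTrace, table: PairScoreTable, player: int,
           T: int | None = None) -> float:
    """Regret of ``player`` after ``T`` turns (default: the whole trace)."""
    if T == 0:
        return 0.0
    series = regret_series(trace, table, player)
    T = trace.n_turns if T is None else T
    return float(series[T - 1])


# ---------------------------------------------------------------------------
# default gameplay


def default_gameplay(graph: RNAGraph, **overrides) -> GameConfig:
    """Settings chosen from the molecule's junction content: without a
    three-way junction OA/UCB/Modified-LJ with frozen helices; with one,
    AA/EXP3 and plain LJ when helix players outnumber junction players by
    more than 1.5x (Modified-LJ otherwise)."""
    has_three_way = any(
        p.ptype in (PlayerType.THREE_WAY_STACK, PlayerType.THREE_WAY_BRANCH)
        for p in graph.players
    )
    if not has_three_way:
        cfg = dict(gameplay=Gameplay.OA, algorithm=Algorithm.UCB,
                   form=ScoringForm.MODIFIED_LJ, frozen=True)
    else:
        ratio = helix_junction_ratio(graph)
        form = ScoringForm.LJ if ratio > 1.5 else ScoringForm.MODIFIED_LJ
        cfg = dict(gameplay=Gameplay.AA, algorithm=Algorithm.EXP3,
                   form=form, frozen=False)
    cfg.update(overrides)
    return GameConfig(**cfg)
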