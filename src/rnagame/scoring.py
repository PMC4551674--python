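"""Knowledge-based pairwise scoring of coarse-grained conformations.

Scores mimic a knowledge-based energy: the distance ``d`` between two
players is fed through a functional form whose parameters are fitted, per
pair of SSE-type classes (HELIX, ONE_WAY, TWO_WAY, THREE_WAY), to observed
inter-player distance distributions.  Four forms are supported:

``LJ``            -A * ((B/d)^12 - 2 (B/d)^6)   — one preferred distance B,
                  hard repulsive core.
``MODIFIED_LJ``   max(LJ, 0) — the repulsive branch flattened to zero, so
                  close packing is not penalised.
``GAUSS``         sum_k A_k N(d; mu_k, sigma_k) — a Gaussian mixture with
                  as many preferred distances as mixture modes.
``INV_SQ``        1/d^2 — a parameter-free contact score.

Fitted scores are sup-normalised so that each pair term lies in [0, 1]
over the observed distance range (except the LJ repulsive branch, which
is negative by design); a player's score is the sum of its pair terms
with every other player, and the bandit reward is that score normalised
by the number of partners, clipped to [0, 1].

A frozen helix cannot bend, so its own position carries little signal:
its score is instead borrowed from the nearest junction players along the
tree, each weighted by the inverse hop distance, and averaged.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.mixture import GaussianMixture

from .errors import (
    DomainError,
    InsufficientDataError,
    MissingParameterError,
)
from .graph import PlayerType, RNAGraph
from .lattice import Conformation, to_cartesian

__all__ = [
    "ScoringForm",
    "PairParams",
    "PairScoreTable",
    "lj_score",
    "mod_lj_score",
    "gauss_score",
    "invsq_score",
    "fit_pair_params",
    "player_score",
    "frozen_helix_score",
    "total_score",
    "all_player_scores",
    "player_rewards",
]

SQRT_2PI = math.sqrt(2.0 * math.pi)


class ScoringForm(Enum):
    LJ = "LJ"
    MODIFIED_LJ = "MODIFIED_LJ"
    GAUSS = "GAUSS"
    INV_SQ = "INV_SQ"


# ---------------------------------------------------------------------------
# raw functional forms (vectorised over d)


def _check_positive(d):
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise DomainError("distance must be positive")
    return d


def lj_score(d, A: float, B: float):
    """Lennard-Jones-shaped score: maximum value ``A`` at ``d == B``,
    negative repulsive branch below ``B / 2^(1/6)``, -> 0 as d -> inf."""
    d = _check_positive(d)
    if B <= 0:
        raise DomainError("B must be positive")
    q6 = (B / d) ** 6
    out = -A * (q6 * q6 - 2.0 * q6)
    return out if out.shape else float(out)


def mod_lj_score(d, A: float, B: float):
    """Lennard-Jones with the repulsive branch clamped to zero."""
    out = np.maximum(lj_score(d, A, B), 0.0)
    return out if np.shape(out) else float(out)


def gauss_score(d, components):
    """Gaussian-mixture score: sum_k A_k * pdf(d; mu_k, sigma_k)."""
    d = np.asarray(d, dtype=float)
    if len(components) == 0:
        raise DomainError("need at least one mixture component")
    out = np.zeros_like(d)
    for A_k, mu_k, sigma_k in components:
        if sigma_k <= 0:
            raise DomainError("sigma must be positive")
        out = out + A_k / (sigma_k * SQRT_2PI) * np.exp(
            -((d - mu_k) ** 2) / (2.0 * sigma_k**2)
        )
    return out if out.shape else float(out)


def invsq_score(d):
    """Inverse-square contact score 1/d^2."""
    d = _check_positive(d)
    out = 1.0 / d**2
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# fitted parameters


@dataclass
class PairParams:
    """Fitted scoring parameters for one (SSE type, SSE type) pair."""

    form: ScoringForm
    A: float = 1.0
    B: float | None = None          # preferred distance (LJ forms), Angstrom
    components: tuple = ()          # GAUSS: (weight, mu, sigma) per component
    norm: float = 1.0               # multiplier making sup(score) == 1
    d_min: float = 1.0              # smallest observed fitting distance
    d_max: float = 100.0            # largest observed fitting distance

    def raw(self, d):
        if self.form is ScoringForm.LJ:
            return lj_score(d, self.A, self.B)
        if self.form is ScoringForm.MODIFIED_LJ:
            return mod_lj_score(d, self.A, self.B)
        if self.form is ScoringForm.GAUSS:
            return gauss_score(d, self.components)
        return invsq_score(d)

    def score(self, d):
        """Normalised score; sup over the fitted range is 1."""
        out = np.asarray(self.raw(d)) * self.norm
        return out if out.shape else float(out)

    def to_dict(self):
        return {
            "form": self.form.value,
            "A": self.A,
            "B": self.B,
            "components": [list(c) for c in self.components],
            "norm": self.norm,
            "d_min": self.d_min,
            "d_max": self.d_max,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            form=ScoringForm(d["form"]),
            A=d.get("A", 1.0),
            B=d.get("B"),
            components=tuple(tuple(c) for c in d.get("components", [])),
            norm=d.get("norm", 1.0),
            d_min=d.get("d_min", 1.0),
            d_max=d.get("d_max", 100.0),
        )


def fit_pair_params(distances, form: ScoringForm, min_samples: int = 30,
                    max_components: int = 5, seed: int = 0) -> PairParams:
    """Fit one pair's parameters from observed inter-player distances.

    LJ forms place their preferred distance ``B`` at the mode of a kernel
    density estimate; the GAUSS form fits finite Gaussian mixtures of 1 to
    ``max_components`` components by EM and keeps the BIC-best model;
    INV_SQ has no free parameters.  All forms are then sup-normalised over
    the observed distance range.
    """
    d = np.asarray(distances, dtype=float)
    d = d[np.isfinite(d) & (d > 0)]
    if d.size < min_samples:
        raise InsufficientDataError(
            f"{d.size} distance samples < required minimum {min_samples}"
        )
    d_min, d_max = float(d.min()), float(d.max())
    params = PairParams(form=form, d_min=d_min, d_max=d_max)

    if form in (ScoringForm.LJ, ScoringForm.MODIFIED_LJ):
        params.B = _kde_mode(d)
        params.A = 1.0
        params.norm = 1.0  # sup of the raw form is A at d == B
    elif form is ScoringForm.GAUSS:
        params.components = _fit_gaussian_mixture(d, max_components, seed)
        params.norm = 1.0 / _mixture_sup(params.components, d_min, d_max)
    elif form is ScoringForm.INV_SQ:
        params.norm = d_min**2  # sup over d >= d_min is 1/d_min^2
    return params


def _mixture_sup(components, d_min: float, d_max: float) -> float:
    """Supremum of the mixture score: dense grid seeded with the component
    means, then local refinement around the best point."""
    from scipy.optimize import minimize_scalar

    lo, hi = max(min(d_min * 0.5, min(m for _, m, _ in components)), 1e-6), \
        max(d_max, max(m for _, m, _ in components))
    grid = np.unique(np.concatenate([
        np.linspace(lo, hi, 4096),
        [mu for _, mu, _ in components],
    ]))
    vals = gauss_score(grid, components)
    x0 = float(grid[np.argmax(vals)])
    span = (hi - lo) / 4096
    res = minimize_scalar(
        lambda x: -gauss_score(x, components),
        bounds=(max(lo, x0 - 2 * span), min(hi, x0 + 2 * span)),
        method="bounded",
    )
    return max(float(np.max(vals)), float(-res.fun))


def _kde_mode(d: np.ndarray) -> float:
    """Dominant mode of the distance distribution.

    The bandwidth is twice Scott's rule: the LJ forms keep a single
    preferred distance, and oversmoothing stabilises the argmax against
    sampling noise without biasing a symmetric peak."""
    if np.ptp(d) < 1e-12:
        return float(d[0])
    kde = gaussian_kde(d, bw_method=lambda k: k.n ** (-1 / 5) * 2.0)
    grid = np.linspace(d.min(), d.max(), 2048)
    return float(grid[np.argmax(kde(grid))])


def _fit_gaussian_mixture(d: np.ndarray, max_components: int, seed: int):
    X = d.reshape(-1, 1)
    best, best_bic = None, np.inf
    for k in range(1, max_components + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="full",
            random_state=seed, n_init=2, max_iter=500,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(X)
        bic = gm.bic(X)
        if bic < best_bic:
            best, best_bic = gm, bic
    comps = sorted(
        zip(
            best.weights_.ravel(),
            best.means_.ravel(),
            np.sqrt(best.covariances_.ravel()),
        ),
        key=lambda c: c[1],
    )
    return tuple((float(w), float(mu), float(s)) for w, mu, s in comps)


# ---------------------------------------------------------------------------
# score table


@dataclass
class PairScoreTable:
    """Symmetric map (SSE class, SSE class) -> PairParams."""

    entries: dict = field(default_factory=dict)

    @staticmethod
    def _key(ci: str, cj: str):
        return tuple(sorted((ci, cj)))

    def set(self, ci: str, cj: str, params: PairParams):
        self.entries[self._key(ci, cj)] = params

    def get(self, ci: str, cj: str) -> PairParams:
        key = self._key(ci, cj)
        if key not in self.entries:
            raise MissingParameterError(f"no parameters for pair {key}")
        return self.entries[key]

    def covers(self, graph: RNAGraph) -> bool:
        classes = {p.scoring_class for p in graph.players}
        return all(
            self._key(a, b) in self.entries
            for a in classes
            for b in classes
        )

    def to_json(self) -> str:
        return json.dumps(
            {"|".join(k): v.to_dict() for k, v in sorted(self.entries.items())},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PairScoreTable":
        table = cls()
        for key, d in json.loads(text).items():
            a, b = key.split("|")
            table.set(a, b, PairParams.from_dict(d))
        return table


# ---------------------------------------------------------------------------
# player scores


def _pair_matrix(conf: Conformation, table: PairScoreTable) -> np.ndarray:
    """Symmetric matrix S[i, j] = pair score of players i and j (0 on the
    diagonal)."""
    xyz = to_cartesian(conf)
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    n = conf.graph.n_players
    classes = [p.scoring_class for p in conf.graph.players]
    S = np.zeros((n, n))
    uniq = sorted(set(classes))
    cls_arr = np.array([uniq.index(c) for c in classes])
    iu, ju = np.triu_indices(n, k=1)
    for a in range(len(uniq)):
        for b in range(a, len(uniq)):
            mask = (
                ((cls_arr[iu] == a) & (cls_arr[ju] == b))
                | ((cls_arr[iu] == b) & (cls_arr[ju] == a))
            )
            if not mask.any():
                continue
            params = table.get(uniq[a], uniq[b])
            vals = params.score(dist[iu[mask], ju[mask]])
            S[iu[mask], ju[mask]] = vals
            S[ju[mask], iu[mask]] = vals
    return S


def player_score(j: int, conf: Conformation, table: PairScoreTable) -> float:
    """Sum of the pair scores between player ``j`` and every other player
    (the frozen-helix rule is applied by :func:`all_player_scores`)."""
    return float(_pair_matrix(conf, table)[j].sum())


def _frozen_neighbors(graph: RNAGraph, j: int):
    """Nearest non-helix player along each tree branch incident to ``j``,
    with its hop distance."""
    out = []
    for first in graph.neighbors(j):
        prev, cur, dist = j, first, 1
        while graph.players[cur].ptype is PlayerType.HELIX:
            nxt = [q for q in graph.neighbors(cur) if q != prev]
            if not nxt:
                cur = None
                break
            prev, cur = cur, nxt[0]
            dist += 1
        if cur is not None:
            out.append((cur, dist))
    return out


def frozen_helix_score(j: int, conf: Conformation,
                       table: PairScoreTable) -> float:
    """Score of a frozen helix player: the scores of its nearest junction
    players along the tree, weighted by inverse hop distance, averaged."""
    neighbors = _frozen_neighbors(conf.graph, j)
    if not neighbors:
        warnings.warn(
            f"frozen helix player {j} has no junction neighbor; "
            "falling back to its own pair score"
        )
        return player_score(j, conf, table)
    S = _pair_matrix(conf, table)
    total = sum(S[q].sum() / dist for q, dist in neighbors)
    return float(total / len(neighbors))


def all_player_scores(conf: Conformation, table: PairScoreTable) -> np.ndarray:
    """Per-player scores with the frozen-helix substitution applied."""
    S = _pair_matrix(conf, table)
    scores = S.sum(axis=1)
    for p in conf.graph.players:
        if p.frozen and p.ptype is PlayerType.HELIX:
            neighbors = _frozen_neighbors(conf.graph, p.id)
            if neighbors:
                scores[p.id] = sum(
                    S[q].sum() / dist for q, dist in neighbors
                ) / len(neighbors)
    return scores


def total_score(conf: Conformation, table: PairScoreTable) -> float:
    """Sum of all player scores; ``Energy = -total_score`` in
    energy-vs-RMSD diagnostics."""
    return float(all_player_scores(conf, table).sum())


def player_rewards(conf: Conformation, table: PairScoreTable) -> np.ndarray:
    """Bandit rewards in [0, 1]: each player's score divided by its number
    of scoring partners, clipped (bounded rewards are required by the
    UCB/EXP3 guarantees)."""
    n = conf.graph.n_players
    if n < 2:
        return np.zeros(n)
    return np.clip(all_player_scores(conf, table) / (n - 1), 0.0, 1.0)
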