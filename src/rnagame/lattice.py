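"""FCC lattice geometry, move legality and lattice embeddings.

The conformational space is the face-centred cubic ("3D triangular")
lattice: integer triples with even coordinate sum, whose 12 nearest
neighbours are the signed permutations of (1, 1, 0).  One lattice step
(vector norm sqrt(2)) is calibrated to 5.6 Angstrom, the short mode of
the distance distribution between adjacent coarse-grained nodes; edges of
two lattice units then reproduce the 11.2 Angstrom mode between adjacent
players of different SSEs.

A conformation assigns every player a lattice point such that tree edges
are straight lattice segments of their prescribed length, no two players
coincide, length-2 edges do not thread through occupied sites, and no two
non-adjacent edges cross.  Geometry is exact integer arithmetic; the hot
path (validity and per-direction legality masks) is compiled with numba,
and a pure-Python mirror of the same predicates serves as the reference
implementation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .errors import EmbeddingError, RejectedActionError
from .graph import PlayerType, RNAGraph

__all__ = [
    "DIRECTIONS",
    "N_DIRECTIONS",
    "STEP_ANGSTROM",
    "LatticePoint",
    "StrategySet",
    "Conformation",
    "neighbor_directions",
    "angle_between",
    "direction_index",
    "allowed_directions",
    "legal_actions",
    "apply_action",
    "edges_intersect",
    "random_embedding",
    "to_cartesian",
]

#: default lattice step in Angstrom (short adjacent-player distance mode)
STEP_ANGSTROM = 5.6

#: the 12 FCC nearest-neighbour vectors (signed permutations of (1,1,0)),
#: canonical lexicographic order
DIRECTIONS = np.array(
    sorted(
        v
        for v in itertools.product((-1, 0, 1), repeat=3)
        if v.count(0) == 1
    ),
    dtype=np.int64,
)
N_DIRECTIONS = len(DIRECTIONS)

_DIR_INDEX = {tuple(int(x) for x in d): i for i, d in enumerate(DIRECTIONS)}

LatticePoint = tuple  # integer triple with even coordinate sum


def neighbor_directions():
    """The 12 FCC nearest-neighbour direction vectors (lexicographic)."""
    return [tuple(int(x) for x in d) for d in DIRECTIONS]


def direction_index(vector) -> int:
    """Canonical index of a direction vector."""
    return _DIR_INDEX[tuple(int(x) for x in vector)]


def angle_between(d1, d2) -> float:
    """Angle in degrees between two lattice directions (exact: the integer
    dot product of two FCC neighbour vectors is in {-2, -1, 0, 1, 2})."""
    dot = int(np.dot(np.asarray(d1), np.asarray(d2)))
    return {2: 0.0, 1: 60.0, 0: 90.0, -1: 120.0, -2: 180.0}[dot]


@dataclass(frozen=True)
class StrategySet:
    """Direction indices (into ``DIRECTIONS``) available to one player."""

    player_id: int
    directions: tuple

    def __len__(self):
        return len(self.directions)

    def __iter__(self):
        return iter(self.directions)


@dataclass
class Conformation:
    """Assignment of players to lattice points (row = player id)."""

    graph: RNAGraph
    positions: np.ndarray  # (n_players, 3) int64
    step_angstrom: float = STEP_ANGSTROM

    def copy(self) -> "Conformation":
        return replace(self, positions=self.positions.copy())

    def edge_direction(self, parent: int, child: int):
        """Unit lattice direction of the tree edge parent -> child."""
        delta = self.positions[child] - self.positions[parent]
        return tuple(int(x) for x in delta // self.graph.edge_length(parent, child))

    def incoming_direction(self, pid: int):
        """Direction of the edge entering ``pid`` from its parent
        (None for the root)."""
        par = self.graph.parent.get(pid)
        if par is None:
            return None
        return self.edge_direction(par, pid)

    def cartesian(self) -> np.ndarray:
        return to_cartesian(self)

    def is_valid(self) -> bool:
        arr = _arrays(self.graph)
        return bool(
            _conf_valid(self.positions, arr.edges, arr.lengths, arr.pairs)
        )


# ---------------------------------------------------------------------------
# per-graph static geometry arrays (cached on the graph object)


@dataclass
class _GraphArrays:
    edges: np.ndarray        # (E, 2) int64, (parent, child) in DFS edge order
    lengths: np.ndarray      # (E,) int64
    pairs: np.ndarray        # (M, 2) int64 indices of non-adjacent edge pairs
    subtree: np.ndarray      # (E, n) bool: players moved when edge e re-aims
    pair_prefix: np.ndarray  # (E,) int64: #pairs valid once edges 0..e placed
    edge_of_child: dict      # child id -> edge index


def _arrays(graph: RNAGraph) -> _GraphArrays:
    cached = getattr(graph, "_lattice_arrays", None)
    if cached is not None:
        return cached
    n = graph.n_players
    edges = []
    for pid in graph.ordering:
        for c in graph.children.get(pid, []):
            edges.append((pid, c))
    # DFS edge order: child of edge k is ordering[k + 1]
    edges.sort(key=lambda e: graph.ordering.index(e[1]))
    E = len(edges)
    edges_arr = np.array(edges, dtype=np.int64).reshape(E, 2)
    lengths = np.array(
        [graph.edge_length(a, b) for a, b in edges], dtype=np.int64
    )
    endpoint_sets = [set(e) for e in edges]
    pairs = [
        (i, j)
        for i in range(E)
        for j in range(i + 1, E)
        if not (endpoint_sets[i] & endpoint_sets[j])
    ]
    # sort so that pairs usable with only the first k edges form a prefix
    pairs.sort(key=lambda ij: max(ij))
    pairs_arr = np.array(pairs, dtype=np.int64).reshape(len(pairs), 2)
    pair_prefix = np.zeros(max(E, 1), dtype=np.int64)
    for e in range(E):
        pair_prefix[e] = sum(1 for i, j in pairs if max(i, j) <= e)
    subtree = np.zeros((max(E, 1), n), dtype=np.bool_)
    for k, (a, b) in enumerate(edges):
        for pid in graph.subtree(b):
            subtree[k, pid] = True
    arr = _GraphArrays(
        edges=edges_arr,
        lengths=lengths,
        pairs=pairs_arr,
        subtree=subtree,
        pair_prefix=pair_prefix,
        edge_of_child={b: k for k, (a, b) in enumerate(edges)},
    )
    graph._lattice_arrays = arr
    return arr


# ---------------------------------------------------------------------------
# exact integer geometry — numba kernels


@njit(cache=True)
def _segs_share_point(ax, ay, az, bx, by, bz, cx, cy, cz, dx, dy, dz):
    """True iff closed segments [a,b] and [c,d] share at least one point.
    All-integer; exact."""
    rx, ry, rz = bx - ax, by - ay, bz - az
    sx, sy, sz = dx - cx, dy - cy, dz - cz
    wx, wy, wz = cx - ax, cy - ay, cz - az
    nx = ry * sz - rz * sy
    ny = rz * sx - rx * sz
    nz = rx * sy - ry * sx
    if nx != 0 or ny != 0 or nz != 0:
        # non-parallel: must be coplanar and parameters within [0, 1]
        if wx * nx + wy * ny + wz * nz != 0:
            return False
        denom = nx * nx + ny * ny + nz * nz
        # t = ((w x s) . n) / |n|^2 along r; u = ((w x r) . n) / |n|^2 along s
        t_num = (
            (wy * sz - wz * sy) * nx
            + (wz * sx - wx * sz) * ny
            + (wx * sy - wy * sx) * nz
        )
        u_num = (
            (wy * rz - wz * ry) * nx
            + (wz * rx - wx * rz) * ny
            + (wx * ry - wy * rx) * nz
        )
        return 0 <= t_num <= denom and 0 <= u_num <= denom
    # parallel: intersect iff collinear and 1D intervals overlap
    cxr = wy * rz - wz * ry
    cyr = wz * rx - wx * rz
    czr = wx * ry - wy * rx
    if cxr != 0 or cyr != 0 or czr != 0:
        return False
    rr = rx * rx + ry * ry + rz * rz
    t0 = wx * rx + wy * ry + wz * rz
    t1 = t0 + sx * rx + sy * ry + sz * rz
    lo = min(t0, t1)
    hi = max(t0, t1)
    return not (hi < 0 or lo > rr)


@njit(cache=True)
def _conf_valid(pos, edges, lengths, pairs):
    """Occupancy (distinct players, free length-2 midpoints) plus
    non-adjacent edge-pair intersection checks."""
    n = pos.shape[0]
    E = edges.shape[0]
    npts = n
    for e in range(E):
        if lengths[e] == 2:
            npts += 1
    pts = np.empty((npts, 3), np.int64)
    for i in range(n):
        pts[i, 0] = pos[i, 0]
        pts[i, 1] = pos[i, 1]
        pts[i, 2] = pos[i, 2]
    k = n
    for e in range(E):
        if lengths[e] == 2:
            a = edges[e, 0]
            b = edges[e, 1]
            pts[k, 0] = (pos[a, 0] + pos[b, 0]) // 2
            pts[k, 1] = (pos[a, 1] + pos[b, 1]) // 2
            pts[k, 2] = (pos[a, 2] + pos[b, 2]) // 2
            k += 1
    for i in range(npts):
        for j in range(i + 1, npts):
            if (
                pts[i, 0] == pts[j, 0]
                and pts[i, 1] == pts[j, 1]
                and pts[i, 2] == pts[j, 2]
            ):
                return False
    for m in range(pairs.shape[0]):
        e1 = pairs[m, 0]
        e2 = pairs[m, 1]
        a = edges[e1, 0]
        b = edges[e1, 1]
        c = edges[e2, 0]
        d = edges[e2, 1]
        if _segs_share_point(
            pos[a, 0], pos[a, 1], pos[a, 2],
            pos[b, 0], pos[b, 1], pos[b, 2],
            pos[c, 0], pos[c, 1], pos[c, 2],
            pos[d, 0], pos[d, 1], pos[d, 2],
        ):
            return False
    return True


@njit(cache=True)
def _legal_mask(pos, edges, lengths, pairs, subtree_row, parent, child,
                elen, allowed, dirs):
    """For each allowed direction, re-aim edge parent->child (rigidly
    translating the child's subtree) and test full validity."""
    out = np.zeros(dirs.shape[0], np.bool_)
    tmp = np.empty_like(pos)
    for d in range(dirs.shape[0]):
        if not allowed[d]:
            continue
        ncx = pos[parent, 0] + elen * dirs[d, 0]
        ncy = pos[parent, 1] + elen * dirs[d, 1]
        ncz = pos[parent, 2] + elen * dirs[d, 2]
        dx = ncx - pos[child, 0]
        dy = ncy - pos[child, 1]
        dz = ncz - pos[child, 2]
        for i in range(pos.shape[0]):
            if subtree_row[i]:
                tmp[i, 0] = pos[i, 0] + dx
                tmp[i, 1] = pos[i, 1] + dy
                tmp[i, 2] = pos[i, 2] + dz
            else:
                tmp[i, 0] = pos[i, 0]
                tmp[i, 1] = pos[i, 1]
                tmp[i, 2] = pos[i, 2]
        if _conf_valid(tmp, edges, lengths, pairs):
            out[d] = True
    return out


# ---------------------------------------------------------------------------
# public geometric predicates


def edges_intersect(p1, p2, p3, p4) -> bool:
    """Exact intersection test for two straight lattice segments.

    Segments that share an endpoint *and touch only at that point* are not
    counted as intersecting (tree edges meet at their common player);
    collinear overlap beyond a shared endpoint still counts.
    """
    p1, p2, p3, p4 = (tuple(int(x) for x in p) for p in (p1, p2, p3, p4))
    shared = {p1, p2} & {p3, p4}
    if not _segs_share_point(*p1, *p2, *p3, *p4):
        return False
    if not shared:
        return True
    # they intersect and share an endpoint: intersecting beyond the shared
    # point is only possible for collinear overlapping segments
    r = np.array(p2) - np.array(p1)
    s = np.array(p4) - np.array(p3)
    if np.any(np.cross(r, s)):
        return False  # single intersection point == the shared endpoint
    # collinear: overlap longer than a point?
    rr = int(r @ r)
    t = sorted((int((np.array(p3) - np.array(p1)) @ r),
                int((np.array(p4) - np.array(p1)) @ r)))
    return min(rr, t[1]) - max(0, t[0]) > 0


# ---------------------------------------------------------------------------
# strategy sets


_FIVE_DIR_CACHE = {}


def _five_direction_set(incoming) -> tuple:
    """The 0-degree continuation plus the four 60-degree neighbours."""
    key = tuple(int(x) for x in incoming)
    if key not in _FIVE_DIR_CACHE:
        inc = np.array(key)
        dots = DIRECTIONS @ inc
        _FIVE_DIR_CACHE[key] = tuple(int(i) for i in np.flatnonzero(dots >= 1))
    return _FIVE_DIR_CACHE[key]


def allowed_directions(ptype, frozen: bool = False, incoming=None, *,
                       large_helix: bool = False,
                       small_two_way: bool = False) -> tuple:
    """Direction indices a player of this type may aim its outgoing edge at.

    Helix players keep within 60 degrees of their incoming direction (a
    frozen large helix must continue perfectly straight); two-way junctions
    with one strand shorter than two nucleotides behave like bendable
    helices; every other junction player — and the root, which has no
    incoming direction — may use all 12 lattice directions.
    """
    if incoming is None:
        return tuple(range(N_DIRECTIONS))
    if ptype is PlayerType.HELIX:
        if large_helix and frozen:
            return (direction_index(incoming),)
        return _five_direction_set(incoming)
    if ptype is PlayerType.TWO_WAY and small_two_way:
        return _five_direction_set(incoming)
    return tuple(range(N_DIRECTIONS))


def _allowed_for_edge(conf: Conformation, parent: int) -> tuple:
    p = conf.graph.players[parent]
    return allowed_directions(
        p.ptype,
        frozen=p.frozen,
        incoming=conf.incoming_direction(parent),
        large_helix=p.large_helix,
        small_two_way=p.small_two_way,
    )


def legal_actions(conf: Conformation, player_id: int,
                  child: int | None = None) -> StrategySet:
    """Collision- and crossing-free subset of the player's allowed
    directions for the edge towards ``child`` (default: first child)."""
    children = conf.graph.children.get(player_id, [])
    if not children:
        return StrategySet(player_id, ())
    if child is None:
        child = children[0]
    arr = _arrays(conf.graph)
    e = arr.edge_of_child[child]
    allowed = np.zeros(N_DIRECTIONS, dtype=np.bool_)
    for d in _allowed_for_edge(conf, player_id):
        allowed[d] = True
    mask = _legal_mask(
        conf.positions, arr.edges, arr.lengths, arr.pairs,
        arr.subtree[e], player_id, child, arr.lengths[e], allowed, DIRECTIONS,
    )
    return StrategySet(player_id, tuple(int(i) for i in np.flatnonzero(mask)))


def apply_action(conf: Conformation, player_id: int, direction,
                 child: int | None = None,
                 check: bool = True) -> Conformation:
    """Re-aim the edge from ``player_id`` to its child along ``direction``
    and rigidly translate the child's whole subtree."""
    d_idx = direction if isinstance(direction, (int, np.integer)) \
        else direction_index(direction)
    children = conf.graph.children.get(player_id, [])
    if not children:
        raise RejectedActionError(f"player {player_id} has no outgoing edge")
    if child is None:
        child = children[0]
    if check and d_idx not in legal_actions(conf, player_id, child).directions:
        raise RejectedActionError(
            f"direction {tuple(DIRECTIONS[d_idx])} is not legal for "
            f"edge {player_id}->{child}"
        )
    arr = _arrays(conf.graph)
    e = arr.edge_of_child[child]
    new = conf.copy()
    target = new.positions[player_id] + arr.lengths[e] * DIRECTIONS[d_idx]
    delta = target - new.positions[child]
    new.positions[arr.subtree[e]] += delta
    return new


# ---------------------------------------------------------------------------
# embeddings


def random_embedding(graph: RNAGraph, seed, max_restarts: int = 1000,
                     step_angstrom: float = STEP_ANGSTROM) -> Conformation:
    """Self-avoiding random embedding: root at the origin, then DFS
    placement drawing uniformly among legal directions, with backtracking
    and bounded restarts."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    arr = _arrays(graph)
    n = graph.n_players
    E = arr.edges.shape[0]
    root = graph.ordering[0]
    order_pos = {pid: k for k, pid in enumerate(graph.ordering)}
    # edge k places player ordering[k+1]; prefix arrays allow partial checks
    for _ in range(max_restarts):
        pos = np.zeros((n, 3), dtype=np.int64)
        if E == 0:
            return Conformation(graph, pos, step_angstrom)
        if _try_place(graph, arr, pos, 0, rng, order_pos):
            conf = Conformation(graph, pos, step_angstrom)
            return conf
    raise EmbeddingError(
        f"no self-avoiding embedding found in {max_restarts} restarts"
    )


def _try_place(graph, arr, pos, e, rng, order_pos, depth_budget=None):
    """Place the child of DFS edge ``e``; recurse over remaining edges."""
    E = arr.edges.shape[0]
    if e == E:
        return True
    parent, child = int(arr.edges[e, 0]), int(arr.edges[e, 1])
    par_of_parent = graph.parent.get(parent)
    if par_of_parent is None:
        incoming = None
    else:
        delta = pos[parent] - pos[par_of_parent]
        incoming = tuple(
            int(x) for x in delta // graph.edge_length(par_of_parent, parent)
        )
    p = graph.players[parent]
    cand = list(
        allowed_directions(
            p.ptype, frozen=p.frozen, incoming=incoming,
            large_helix=p.large_helix, small_two_way=p.small_two_way,
        )
    )
    rng.shuffle(cand)
    n_placed = e + 2  # players ordering[0..e+1] are placed after this edge
    placed_players = [graph.ordering[i] for i in range(n_placed)]
    sub_pos_idx = np.array(placed_players, dtype=np.int64)
    remap = {pid: i for i, pid in enumerate(placed_players)}
    edges_sub = np.array(
        [[remap[int(arr.edges[k, 0])], remap[int(arr.edges[k, 1])]]
         for k in range(e + 1)],
        dtype=np.int64,
    )
    lengths_sub = arr.lengths[: e + 1]
    pairs_sub = arr.pairs[: arr.pair_prefix[e]]
    for d in cand:
        pos[child] = pos[parent] + arr.lengths[e] * DIRECTIONS[d]
        if _conf_valid(pos[sub_pos_idx], edges_sub, lengths_sub, pairs_sub):
            if _try_place(graph, arr, pos, e + 1, rng, order_pos):
                return True
    return False


def to_cartesian(conf: Conformation) -> np.ndarray:
    """Scale integer lattice coordinates to Angstrom: one lattice step
    (vector norm sqrt 2) maps to ``step_angstrom``."""
    return conf.positions * (conf.step_angstrom / math.sqrt(2.0))
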