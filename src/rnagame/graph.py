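"""Secondary-structure parsing and the coarse-grained player graph.

An RNA secondary structure (dot-bracket) is decomposed into secondary
structure elements (SSEs): helices, terminal loops (one-way junctions),
bulges/internal loops (two-way junctions) and multibranch junctions.
Each SSE becomes one or more *players* — the nodes of a tree whose edges
follow the covalent connectivity of the molecule:

* a helix of ``b`` base pairs becomes ``ceil(b/5)`` players (at most five
  base pairs each, so long helices keep some long-range flexibility);
* one- and two-way junctions become a single player;
* a three-way junction becomes two players: a STACK player sitting at the
  first base pair of the two coaxially stacked helices, and a BRANCH
  player at the centre of the junction nucleotides;
* a four-way junction is approximated by two three-way junctions plus a
  LINKER player (five players in total).

Players are ordered by a depth-first search rooted at the highest-degree
junction nearest the 5' end; at a three-way junction the subtree through
the unstacked helix is visited first.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum

from .errors import (
    FormatError,
    ParseError,
    UndefinedRatioError,
    UnsupportedStructureError,
)

__all__ = [
    "SSEKind",
    "PlayerType",
    "SecondaryStructure",
    "SSE",
    "Player",
    "RNAGraph",
    "parse_dotbracket",
    "decompose_sses",
    "build_players",
    "build_graph",
    "order_players",
    "helix_junction_ratio",
    "build_graph_from_dotbracket",
]

MAX_BASEPAIRS_PER_PLAYER = 5


class SSEKind(Enum):
    HELIX = "HELIX"
    ONE_WAY = "ONE_WAY"
    TWO_WAY = "TWO_WAY"
    THREE_WAY = "THREE_WAY"
    FOUR_WAY = "FOUR_WAY"


class PlayerType(Enum):
    HELIX = "HELIX"
    ONE_WAY = "ONE_WAY"
    TWO_WAY = "TWO_WAY"
    THREE_WAY_STACK = "THREE_WAY_STACK"
    THREE_WAY_BRANCH = "THREE_WAY_BRANCH"
    LINKER = "LINKER"


#: player type -> SSE-type class used to key the pairwise score table
SCORING_CLASS = {
    PlayerType.HELIX: "HELIX",
    PlayerType.ONE_WAY: "ONE_WAY",
    PlayerType.TWO_WAY: "TWO_WAY",
    PlayerType.THREE_WAY_STACK: "THREE_WAY",
    PlayerType.THREE_WAY_BRANCH: "THREE_WAY",
    PlayerType.LINKER: "THREE_WAY",
}


@dataclass(frozen=True)
class SecondaryStructure:
    """A sequence plus a set of non-crossing base pairs (0-based, i < j)."""

    sequence: str
    pairs: frozenset

    def __post_init__(self):
        n = len(self.sequence)
        if n < 1:
            raise FormatError("empty sequence")
        seen = set()
        for i, j in self.pairs:
            if not (0 <= i < j < n):
                raise FormatError(f"pair ({i},{j}) out of range")
            if i in seen or j in seen:
                raise FormatError("an index occurs in more than one pair")
            seen.update((i, j))

    @property
    def partner(self):
        """Array-like map index -> paired index or -1."""
        p = [-1] * len(self.sequence)
        for i, j in self.pairs:
            p[i], p[j] = j, i
        return p

    def is_nested(self) -> bool:
        sp = sorted(self.pairs)
        for a in range(len(sp)):
            i, j = sp[a]
            for k, l in sp[a + 1:]:
                if i < k < j < l:
                    return False
        return True


@dataclass(frozen=True)
class SSE:
    """One secondary structure element.

    For helices ``pairs`` holds the stacked base pairs from the outermost
    inward.  For junctions ``helices`` lists the incident helix SSE indices
    (enclosing helix first, then children 5'→3') and ``gaps`` the unpaired
    strand lengths between consecutive incident helices in that cyclic
    order.
    """

    kind: SSEKind
    nucleotides: frozenset
    pairs: tuple = ()
    helices: tuple = ()
    gaps: tuple = ()
    #: junctions only: True if helices[0] is the enclosing helix (False for
    #: the exterior loop, whose incident helices are all children)
    has_parent: bool = False

    @property
    def n_basepairs(self) -> int:
        return len(self.pairs)

    @property
    def degree(self) -> int:
        return len(self.helices)


@dataclass
class Player:
    """A node of the coarse-grained graph / an agent of the sampling game."""

    id: int
    ptype: PlayerType
    sse_index: int
    nucleotides: frozenset
    n_basepairs_covered: int = 0
    frozen: bool = False
    #: position of a helix chunk within its helix (0 = outermost)
    chunk_index: int = 0
    #: helices longer than five base pairs may be frozen straight
    large_helix: bool = False
    #: two-way junctions with one strand shorter than two nucleotides are
    #: direction-restricted like helices
    small_two_way: bool = False

    @property
    def scoring_class(self) -> str:
        return SCORING_CLASS[self.ptype]


@dataclass
class RNAGraph:
    """Tree of players with lattice edge lengths and a DFS ordering."""

    players: list
    edges: dict  # frozenset({i, j}) -> edge length in lattice units (1 or 2)
    ordering: list = field(default_factory=list)
    parent: dict = field(default_factory=dict)  # child id -> parent id
    children: dict = field(default_factory=dict)  # id -> ordered child ids
    sses: list = field(default_factory=list)
    ss: SecondaryStructure | None = None

    @property
    def n_players(self) -> int:
        return len(self.players)

    def neighbors(self, pid: int):
        out = []
        for e in self.edges:
            if pid in e:
                (other,) = e - {pid}
                out.append(other)
        return sorted(out)

    def edge_length(self, i: int, j: int) -> int:
        return self.edges[frozenset((i, j))]

    def subtree(self, pid: int):
        """All player ids in the subtree rooted at ``pid`` (inclusive)."""
        out, stack = [], [pid]
        while stack:
            p = stack.pop()
            out.append(p)
            stack.extend(self.children.get(p, []))
        return sorted(out)

    def to_json(self) -> str:
        data = {
            "players": [
                {
                    "id": p.id,
                    "ptype": p.ptype.value,
                    "sse_index": p.sse_index,
                    "nucleotides": sorted(p.nucleotides),
                    "n_basepairs_covered": p.n_basepairs_covered,
                    "frozen": p.frozen,
                }
                for p in self.players
            ],
            "edges": [[min(e), max(e), l] for e, l in sorted(self.edges.items(), key=lambda kv: sorted(kv[0]))],
            "ordering": list(self.ordering),
        }
        return json.dumps(data, indent=1)


# ---------------------------------------------------------------------------
# parsing


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse dot-bracket content: optional ``>`` header, sequence line,
    structure line."""
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise FormatError("need a sequence line and a structure line")
    seq, struct = lines[0].upper().replace("T", "U"), lines[1]
    if len(seq) != len(struct):
        raise FormatError(
            f"sequence length {len(seq)} != structure length {len(struct)}"
        )
    if set(seq) - set("ACGUN"):
        raise ParseError(f"bad sequence characters: {set(seq) - set('ACGUN')}")
    if set(struct) - set(".()"):
        raise ParseError(f"bad structure characters: {set(struct) - set('.()')}")
    stack, pairs = [], set()
    for k, c in enumerate(struct):
        if c == "(":
            stack.append(k)
        elif c == ")":
            if not stack:
                raise ParseError(f"unbalanced ')' at column {k}")
            pairs.add((stack.pop(), k))
    if stack:
        raise ParseError(f"unbalanced '(' at column {stack[-1]}")
    return SecondaryStructure(seq, frozenset(pairs))


# ---------------------------------------------------------------------------
# SSE decomposition


def decompose_sses(ss: SecondaryStructure):
    """Split a secondary structure into helices and junction SSEs.

    Helices are maximal runs of stacked pairs; every loop region (its
    unpaired nucleotides plus the closing pairs of the incident helices)
    becomes one junction SSE whose kind is its helix degree.
    """
    if not ss.is_nested():
        raise UnsupportedStructureError("pseudoknotted structures are not supported")
    partner = ss.partner
    n = len(ss.sequence)

    # helices: maximal stacks of consecutive pairs
    helices = []
    sp = sorted(ss.pairs)
    used = set()
    for i, j in sp:
        if (i, j) in used:
            continue
        run = [(i, j)]
        used.add((i, j))
        a, b = i, j
        while (a + 1, b - 1) in ss.pairs:
            a, b = a + 1, b - 1
            run.append((a, b))
            used.add((a, b))
        nts = frozenset(x for pr in run for x in pr)
        helices.append(SSE(SSEKind.HELIX, nts, pairs=tuple(run)))

    outer_of = {h.pairs[0]: idx for idx, h in enumerate(helices)}

    def top_level(lo, hi):
        """Unpaired positions and helix outer pairs at top level in [lo, hi)."""
        unpaired, children = [], []
        k = lo
        while k < hi:
            if partner[k] > k:
                children.append(outer_of[(k, partner[k])])
                k = partner[k] + 1
            elif partner[k] == -1:
                unpaired.append(k)
                k += 1
            else:  # partner[k] < k: closing bracket at top level — impossible here
                k += 1
        return unpaired, children

    junctions = []

    # exterior loop
    ext_unpaired, ext_children = top_level(0, n)
    if ext_children and (ext_unpaired or len(ext_children) >= 2):
        closing = [helices[c].pairs[0] for c in ext_children]
        nts = frozenset(ext_unpaired) | frozenset(x for pr in closing for x in pr)
        gaps = _gap_sizes(None, [helices[c] for c in ext_children], n)
        junctions.append(
            SSE(_junction_kind(len(ext_children)), nts,
                helices=tuple(ext_children), gaps=gaps, has_parent=False)
        )
    elif not ext_children:
        # no pairs at all: the whole strand is one degenerate terminal loop
        junctions.append(SSE(SSEKind.ONE_WAY, frozenset(range(n))))

    # loop enclosed by each helix's innermost pair
    for h_idx, h in enumerate(helices):
        a, b = h.pairs[-1]
        unpaired, children = top_level(a + 1, b)
        closing = [(a, b)] + [helices[c].pairs[0] for c in children]
        nts = frozenset(unpaired) | frozenset(x for pr in closing for x in pr)
        gaps = _gap_sizes(h, [helices[c] for c in children], n)
        junctions.append(
            SSE(_junction_kind(1 + len(children)), nts,
                helices=tuple([h_idx] + children), gaps=gaps, has_parent=True)
        )

    return helices + junctions


def _junction_kind(degree: int) -> SSEKind:
    kinds = {1: SSEKind.ONE_WAY, 2: SSEKind.TWO_WAY,
             3: SSEKind.THREE_WAY, 4: SSEKind.FOUR_WAY}
    if degree not in kinds:
        raise UnsupportedStructureError(
            f"junctions of degree {degree} are not supported"
        )
    return kinds[degree]


def _gap_sizes(parent: SSE | None, children, n: int):
    """Unpaired strand lengths between consecutive incident helices
    (cyclic order parent, child1, ..., childK, back to parent)."""
    bounds = []
    if parent is not None:
        a, b = parent.pairs[-1]
        lo, hi = a, b
    else:
        lo, hi = -1, n
    prev = lo
    for c in children:
        i, j = c.pairs[0]
        bounds.append(i - prev - 1)
        prev = j
    bounds.append(hi - prev - 1)
    return tuple(bounds)


# ---------------------------------------------------------------------------
# players


def stacked_pair_default(sse: SSE):
    """Default coaxial-stacking choice at a three-way junction: the two
    helices flanking the shortest connecting strand are stacked."""
    hs = list(sse.helices)
    if sse.has_parent:
        # cyclic: gaps[k] lies between hs[k] and hs[(k+1) % deg]
        k = min(range(len(sse.gaps)), key=lambda g: (sse.gaps[g], g))
        return (hs[k], hs[(k + 1) % len(hs)])
    # exterior junction: gaps[0]/gaps[-1] are dangling ends, not connectors
    k = min(range(1, len(sse.gaps) - 1), key=lambda g: (sse.gaps[g], g))
    return (hs[k - 1], hs[k])


def build_players(sses, stacking_hint=None):
    """Expand SSEs into players.

    ``stacking_hint`` optionally maps a three-way junction's SSE index to
    the pair of helix SSE indices that stack coaxially; by default the two
    helices joined by the shortest strand are taken as stacked.
    """
    stacking_hint = stacking_hint or {}
    players = []

    def add(ptype, sse_index, nts, n_bp=0, chunk=0, **kw):
        players.append(
            Player(len(players), ptype, sse_index, frozenset(nts),
                   n_basepairs_covered=n_bp, chunk_index=chunk, **kw)
        )
        return players[-1]

    for s_idx, sse in enumerate(sses):
        if sse.kind is SSEKind.HELIX:
            b = sse.n_basepairs
            n_chunks = max(1, math.ceil(b / MAX_BASEPAIRS_PER_PLAYER))
            large = b > MAX_BASEPAIRS_PER_PLAYER
            # balanced split keeps every player at <= 5 base pairs
            base, extra = divmod(b, n_chunks)
            pos = 0
            for c in range(n_chunks):
                size = base + (1 if c < extra else 0)
                chunk_pairs = sse.pairs[pos:pos + size]
                pos += size
                nts = [x for pr in chunk_pairs for x in pr]
                add(PlayerType.HELIX, s_idx, nts, n_bp=size, chunk=c,
                    large_helix=large)
        elif sse.kind is SSEKind.ONE_WAY:
            add(PlayerType.ONE_WAY, s_idx, sse.nucleotides)
        elif sse.kind is SSEKind.TWO_WAY:
            small = min(sse.gaps) < 2
            add(PlayerType.TWO_WAY, s_idx, sse.nucleotides, small_two_way=small)
        elif sse.kind is SSEKind.THREE_WAY:
            stacked = stacking_hint.get(s_idx) or stacked_pair_default(sse)
            nts_stack = _closing_pair_nts(sses, sse, stacked)
            add(PlayerType.THREE_WAY_STACK, s_idx, nts_stack)
            add(PlayerType.THREE_WAY_BRANCH, s_idx, sse.nucleotides)
        elif sse.kind is SSEKind.FOUR_WAY:
            hs = list(sse.helices)
            pair_a, pair_b = (hs[0], hs[1]), (hs[2], hs[3])
            add(PlayerType.THREE_WAY_STACK, s_idx, _closing_pair_nts(sses, sse, pair_a))
            add(PlayerType.THREE_WAY_BRANCH, s_idx, sse.nucleotides)
            add(PlayerType.LINKER, s_idx, sse.nucleotides)
            add(PlayerType.THREE_WAY_STACK, s_idx, _closing_pair_nts(sses, sse, pair_b))
            add(PlayerType.THREE_WAY_BRANCH, s_idx, sse.nucleotides)
        else:  # pragma: no cover
            raise UnsupportedStructureError(f"unknown SSE kind {sse.kind}")
    return players


def _closing_pair_nts(sses, junction: SSE, helix_pair):
    """Nucleotides of the junction-facing (first) base pair of two helices."""
    nts = []
    for h_idx in helix_pair:
        h = sses[h_idx]
        # the pair of the helix that faces this junction
        if junction.has_parent and h_idx == junction.helices[0]:
            nts.extend(h.pairs[-1])  # enclosing helix: innermost pair
        else:
            nts.extend(h.pairs[0])   # child helix: outermost pair
    return nts


# ---------------------------------------------------------------------------
# graph


def build_graph(players, sses, ss: SecondaryStructure | None = None,
                stacking_hint=None) -> RNAGraph:
    """Connect players along the covalent SSE connectivity.

    Edge lengths are 2 lattice units everywhere except between the STACK
    and BRANCH players of one multibranch junction, which sit one unit
    apart (the two distance modes observed between adjacent coarse-grained
    nodes: same junction vs. different SSEs).
    """
    stacking_hint = stacking_hint or {}
    by_sse = {}
    for p in players:
        by_sse.setdefault(p.sse_index, []).append(p)

    edges = {}

    def connect(i, j, length=2):
        if i == j:
            raise UnsupportedStructureError("self edge")
        edges[frozenset((i, j))] = length

    def helix_end(h_idx: int, facing: str) -> int:
        chunks = by_sse[h_idx]
        return (min(chunks, key=lambda p: p.chunk_index) if facing == "outer"
                else max(chunks, key=lambda p: p.chunk_index)).id

    for s_idx, sse in enumerate(sses):
        plist = by_sse.get(s_idx, [])
        if sse.kind is SSEKind.HELIX:
            chunks = sorted(plist, key=lambda p: p.chunk_index)
            for a, b in zip(chunks, chunks[1:]):
                connect(a.id, b.id, 2)
            continue
        # junction SSE: attach incident helices
        incident = []
        for k, h_idx in enumerate(sse.helices):
            facing = "inner" if (k == 0 and sse.has_parent) else "outer"
            incident.append((h_idx, helix_end(h_idx, facing)))
        if sse.kind in (SSEKind.ONE_WAY, SSEKind.TWO_WAY):
            for _, end in incident:
                connect(plist[0].id, end, 2)
        elif sse.kind is SSEKind.THREE_WAY:
            stack, branch = plist[0], plist[1]
            connect(stack.id, branch.id, 1)
            stacked = set(stacking_hint.get(s_idx) or stacked_pair_default(sse))
            for h_idx, end in incident:
                connect((stack if h_idx in stacked else branch).id, end, 2)
        elif sse.kind is SSEKind.FOUR_WAY:
            stack_a, branch_a, linker, stack_b, branch_b = plist
            connect(stack_a.id, branch_a.id, 1)
            connect(branch_a.id, linker.id, 2)
            connect(linker.id, branch_b.id, 2)
            connect(stack_b.id, branch_b.id, 1)
            hs = [h for h, _ in incident]
            for (h_idx, end) in incident:
                owner = stack_a if h_idx in hs[:2] else stack_b
                connect(owner.id, end, 2)

    graph = RNAGraph(players=list(players), edges=edges, sses=list(sses), ss=ss)
    if len(edges) != len(players) - 1 or not _connected(graph):
        raise UnsupportedStructureError("player graph is not a tree")
    order_players(graph)
    return graph


def _connected(graph: RNAGraph) -> bool:
    if not graph.players:
        return False
    seen, stack = set(), [graph.players[0].id]
    while stack:
        p = stack.pop()
        if p in seen:
            continue
        seen.add(p)
        stack.extend(q for q in graph.neighbors(p) if q not in seen)
    return len(seen) == len(graph.players)


def order_players(graph: RNAGraph):
    """Root the tree and number players by depth-first search.

    The root is the first player of the highest-degree junction closest to
    the 5' end.  Children are visited junction-internal players first (so
    at a three-way junction the subtree through the unstacked helix, which
    hangs off the BRANCH player, is explored before the stacked helices).
    """
    branching = [
        (i, s) for i, s in enumerate(graph.sses)
        if s.kind is not SSEKind.HELIX and s.degree >= 3
    ]
    if branching:
        root_sse = max(
            branching,
            key=lambda t: (t[1].degree, -min(t[1].nucleotides or {0})),
        )[0]
        root = min(
            (p for p in graph.players if p.sse_index == root_sse),
            key=lambda p: p.id,
        ).id
    else:
        # no branching junction: walk the chain from the 5' end
        root = min(
            graph.players,
            key=lambda p: (min(p.nucleotides or {10**9}), p.id),
        ).id

    order, parent, children = [], {}, {p.id: [] for p in graph.players}
    seen = {root}
    stack = [root]
    while stack:
        pid = stack.pop()
        order.append(pid)
        me = graph.players[pid]
        nbrs = [q for q in graph.neighbors(pid) if q not in seen]
        # same-junction players first, then by id
        nbrs.sort(key=lambda q: (graph.players[q].sse_index != me.sse_index, q))
        for q in nbrs:
            seen.add(q)
            parent[q] = pid
        children[pid] = list(nbrs)
        stack.extend(reversed(nbrs))

    graph.ordering = order
    graph.parent = parent
    graph.children = children
    return order


def helix_junction_ratio(graph: RNAGraph) -> float:
    """(# helix players) / (# junction players) — drives the default
    choice of scoring form."""
    n_helix = sum(1 for p in graph.players if p.ptype is PlayerType.HELIX)
    n_junction = graph.n_players - n_helix
    if n_junction == 0:
        raise UndefinedRatioError("graph has no junction players")
    return n_helix / n_junction


def build_graph_from_dotbracket(text: str, stacking_hint=None) -> RNAGraph:
    """Convenience: dot-bracket text straight to an ordered player graph."""
    ss = parse_dotbracket(text)
    sses = decompose_sses(ss)
    players = build_players(sses, stacking_hint=stacking_hint)
    return build_graph(players, sses, ss=ss, stacking_hint=stacking_hint)
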