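"""Shared fixtures and independent geometric oracles for the test suite."""

from fractions import Fraction

import pytest

from rnagame.fixtures import (
    FixtureSpec,
    FixtureTopology,
    SyntheticEnsembleSpec,
    fit_table,
    make_fixture,
    make_reference_ensemble,
)
from rnagame.graph import build_graph_from_dotbracket
from rnagame.scoring import ScoringForm

THREE_WAY_DBN, THREE_WAY_EXPECTED = make_fixture(
    FixtureSpec(FixtureTopology.THREE_WAY)
)
HAIRPIN_DBN, HAIRPIN_EXPECTED = make_fixture(
    FixtureSpec(FixtureTopology.HAIRPIN)
)


@pytest.fixture
def hairpin_graph():
    return build_graph_from_dotbracket(HAIRPIN_DBN)


@pytest.fixture
def three_way_graph():
    return build_graph_from_dotbracket(THREE_WAY_DBN)


@pytest.fixture(scope="session")
def three_way_ensemble():
    graph = build_graph_from_dotbracket(THREE_WAY_DBN)
    spec = SyntheticEnsembleSpec(n_structures=150, seed=11)
    return graph, [ng.coords for ng in make_reference_ensemble(spec, graph)]


@pytest.fixture(scope="session")
def modlj_table(three_way_ensemble):
    graph, coords = three_way_ensemble
    return fit_table(graph, coords, ScoringForm.MODIFIED_LJ, seed=0)


@pytest.fixture(scope="session")
def hairpin_table():
    graph = build_graph_from_dotbracket(HAIRPIN_DBN)
    spec = SyntheticEnsembleSpec(n_structures=120, seed=5)
    coords = [ng.coords for ng in make_reference_ensemble(spec, graph)]
    return fit_table(graph, coords, ScoringForm.MODIFIED_LJ, seed=0)


# ---------------------------------------------------------------------------
# independent exact-geometry oracles (pure Python rationals; no package code)


def seg_point_oracle(a, b, t: Fraction):
    return tuple(Fraction(ai) + t * (Fraction(bi) - Fraction(ai))
                 for ai, bi in zip(a, b))


def segments_share_point_oracle(a, b, c, d) -> bool:
    """Brute-force exact test: do closed segments [a,b], [c,d] intersect?

    Solves the 2x2 linear system per coordinate pair with Fractions and
    falls back to 1D interval overlap for parallel segments.
    """
    a, b, c, d = (tuple(Fraction(x) for x in p) for p in (a, b, c, d))
    r = tuple(bi - ai for ai, bi in zip(a, b))
    s = tuple(di - ci for ci, di in zip(c, d))
    w = tuple(ci - ai for ai, ci in zip(a, c))
    cross = (
        r[1] * s[2] - r[2] * s[1],
        r[2] * s[0] - r[0] * s[2],
        r[0] * s[1] - r[1] * s[0],
    )
    if any(cross):
        if sum(wi * ni for wi, ni in zip(w, cross)) != 0:
            return False  # skew
        denom = sum(ni * ni for ni in cross)
        w_x_s = (
            w[1] * s[2] - w[2] * s[1],
            w[2] * s[0] - w[0] * s[2],
            w[0] * s[1] - w[1] * s[0],
        )
        w_x_r = (
            w[1] * r[2] - w[2] * r[1],
            w[2] * r[0] - w[0] * r[2],
            w[0] * r[1] - w[1] * r[0],
        )
        t = Fraction(sum(wxsi * ni for wxsi, ni in zip(w_x_s, cross)), denom)
        u = Fraction(sum(wxri * ni for wxri, ni in zip(w_x_r, cross)), denom)
        return 0 <= t <= 1 and 0 <= u <= 1
    # parallel
    w_x_r = (
        w[1] * r[2] - w[2] * r[1],
        w[2] * r[0] - w[0] * r[2],
        w[0] * r[1] - w[1] * r[0],
    )
    if any(w_x_r):
        return False
    rr = sum(ri * ri for ri in r)
    if rr == 0:
        return a == c
    t0 = Fraction(sum(wi * ri for wi, ri in zip(w, r)), rr)
    t1 = t0 + Fraction(sum(si * ri for si, ri in zip(s, r)), rr)
    lo, hi = min(t0, t1), max(t0, t1)
    return not (hi < 0 or lo > 1)


def conformation_violations_oracle(conf) -> list:
    """Exhaustive O(E^2) conformation check, independent of the package's
    validity kernels: position collisions, occupied length-2 midpoints,
    and crossings between edges that do not share a player."""
    graph = conf.graph
    pos = {p.id: tuple(int(x) for x in conf.positions[p.id])
           for p in graph.players}
    problems = []
    ids = sorted(pos)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if pos[ids[i]] == pos[ids[j]]:
                problems.append(("collision", ids[i], ids[j]))
    edges = [(min(e), max(e), l) for e, l in graph.edges.items()]
    occupied = set(pos.values())
    midpoints = {}
    for a, b, l in edges:
        if l == 2:
            mid = tuple((pa + pb) // 2 for pa, pb in zip(pos[a], pos[b]))
            if mid in occupied or mid in midpoints:
                problems.append(("midpoint", a, b))
            midpoints[mid] = (a, b)
    for x in range(len(edges)):
        for y in range(x + 1, len(edges)):
            a1, b1, _ = edges[x]
            a2, b2, _ = edges[y]
            if {a1, b1} & {a2, b2}:
                continue
            if segments_share_point_oracle(pos[a1], pos[b1],
                                           pos[a2], pos[b2]):
                problems.append(("crossing", (a1, b1), (a2, b2)))
    return problems
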