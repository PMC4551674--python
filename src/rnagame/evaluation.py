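"""Evaluation against native structures.

A native 3D structure is coarse-grained to one coordinate per player (the
unweighted centre of the heavy atoms of the player's nucleotides; at a
three-way junction the STACK player uses the first base pair of the two
stacked helices and the BRANCH player the whole junction).  Sampled
conformations are compared with the native coordinates by least-squares
rigid superposition (proper rotations only) followed by

    RMSD(m, n) = sqrt( (1/p) * sum_i ||m_i - n_i||^2 )

and a sample set is summarised the way sampling benchmarks are reported:
minimum and maximum RMSD plus the number of samples below a threshold.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
from Bio.PDB import PDBParser

from .errors import (
    ComparisonError,
    DegenerateSuperpositionError,
    MappingError,
)
from .graph import RNAGraph, SecondaryStructure
from .lattice import to_cartesian
from .scoring import PairScoreTable, total_score

__all__ = [
    "NativeGraph",
    "SampleSummary",
    "coarse_grain_native",
    "superpose",
    "rmsd",
    "summarize",
]


@dataclass
class NativeGraph:
    """Player graph plus native Cartesian coordinates (Angstrom)."""

    graph: RNAGraph
    coords: np.ndarray  # (n_players, 3)


@dataclass
class SampleSummary:
    rmsd_min: float
    rmsd_max: float
    n_below_threshold: int
    threshold: float
    energy_rmsd_pairs: list  # (energy = -total score, rmsd) per sample

    def to_tsv_row(self, label: str, n_players: int) -> str:
        return "\t".join(
            str(x)
            for x in (
                label, n_players, f"{self.rmsd_min:.2f}",
                f"{self.rmsd_max:.2f}", self.n_below_threshold,
                self.threshold,
            )
        )


# ---------------------------------------------------------------------------
# native coarse-graining


def coarse_grain_native(pdb_text: str, ss: SecondaryStructure,
                        graph: RNAGraph, chain: str | None = None) -> NativeGraph:
    """Coarse-grain a PDB structure onto the player graph.

    Residues of the selected chain (first chain by default, first model
    only) are mapped in order onto the sequence positions of ``ss``; each
    player's coordinate is the geometric centre of the heavy atoms of its
    nucleotides.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("native", _io.StringIO(pdb_text))
    model = next(structure.get_models())
    chains = {c.id: c for c in model.get_chains()}
    if chain is None:
        chain_obj = next(iter(chains.values()))
    elif chain in chains:
        chain_obj = chains[chain]
    else:
        raise MappingError(f"chain {chain!r} not in PDB (has {sorted(chains)})")
    residues = [r for r in chain_obj.get_residues()]
    if len(residues) < len(ss.sequence):
        raise MappingError(
            f"chain has {len(residues)} residues but the secondary "
            f"structure covers {len(ss.sequence)} nucleotides"
        )
    residues = residues[: len(ss.sequence)]

    centers = {}
    missing = []
    for idx, res in enumerate(residues):
        atoms = [
            a for a in res.get_atoms()
            if (a.element or a.get_name()[:1]).upper() != "H"
        ]
        if not atoms:
            missing.append(idx)
            continue
        centers[idx] = np.mean([a.get_coord() for a in atoms], axis=0)
    if missing:
        raise MappingError(f"residues with no heavy atoms: {missing}")

    coords = np.zeros((graph.n_players, 3))
    for p in graph.players:
        pts = [centers[i] for i in sorted(p.nucleotides)]
        if not pts:
            raise MappingError(f"player {p.id} has no mapped nucleotides")
        coords[p.id] = np.mean(pts, axis=0)
    return NativeGraph(graph=graph, coords=coords)


# ---------------------------------------------------------------------------
# superposition and RMSD


def superpose(m, n):
    """Least-squares rigid superposition of ``m`` onto ``n`` (Kabsch).

    Returns ``(rotation, translation)`` with ``rotation`` a proper
    rotation matrix (det +1; reflections excluded) such that
    ``m @ rotation.T + translation`` best fits ``n``.
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    if m.shape != n.shape or m.ndim != 2 or m.shape[1] != 3:
        raise DegenerateSuperpositionError("coordinate shapes must match (p, 3)")
    p = m.shape[0]
    if p < 3:
        raise DegenerateSuperpositionError("need at least 3 points")
    mc, nc = m.mean(axis=0), n.mean(axis=0)
    A, B = m - mc, n - nc
    if np.linalg.matrix_rank(A, tol=1e-9) < 2 or \
            np.linalg.matrix_rank(B, tol=1e-9) < 2:
        raise DegenerateSuperpositionError("collinear point set")
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = nc - R @ mc
    return R, t


def rmsd(m, n, superpose_first: bool = True) -> float:
    """Root-mean-square deviation between matched point sets, optionally
    after optimal rigid superposition."""
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    if m.shape != n.shape:
        raise ComparisonError(f"point counts differ: {m.shape} vs {n.shape}")
    if superpose_first:
        R, t = superpose(m, n)
        m = m @ R.T + t
    return float(np.sqrt(((m - n) ** 2).sum(axis=1).mean()))


# ---------------------------------------------------------------------------
# sample-set summaries


def summarize(samples, native: NativeGraph, threshold: float,
              table: PairScoreTable | None = None) -> SampleSummary:
    """RMSD statistics of a sample set against a native structure."""
    rmsds, pairs = [], []
    for k, conf in enumerate(samples.samples):
        if conf.graph.n_players != native.graph.n_players:
            raise ComparisonError(
                "sample and native graphs have different player counts"
            )
        value = rmsd(to_cartesian(conf), native.coords, superpose_first=True)
        rmsds.append(value)
        if table is not None:
            energy = -samples.total_scores[k] if samples.total_scores else \
                -total_score(conf, table)
            pairs.append((energy, value))
    samples.rmsds = rmsds
    return SampleSummary(
        rmsd_min=float(min(rmsds)),
        rmsd_max=float(max(rmsds)),
        n_below_threshold=int(sum(1 for r in rmsds if r < threshold)),
        threshold=threshold,
        energy_rmsd_pairs=pairs,
    )
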