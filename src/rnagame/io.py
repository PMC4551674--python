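"""File formats: dot-bracket, multi-model pseudo-atom PDB, JSON, TSV.

Sampled conformations are written as multi-model PDB with one pseudo-atom
per player (atom name ``P``, residue ``PLR``, residue number = player id
+ 1), which any molecular viewer will display as a bead chain.  Native
structures are read with Biopython's PDB parser.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

from .errors import FormatError
from .graph import SecondaryStructure, parse_dotbracket
from .lattice import to_cartesian
from .scoring import PairScoreTable

__all__ = [
    "read_dotbracket",
    "write_pdb_models",
    "read_pdb_models",
    "read_params",
    "write_params",
    "write_native_pdb",
    "write_summary_tsv",
]


def read_dotbracket(path) -> SecondaryStructure:
    return parse_dotbracket(Path(path).read_text())


_ATOM_FMT = (
    "ATOM  {serial:5d}  P   PLR {chain}{resseq:4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           P"
)


def write_pdb_models(coord_sets, path=None) -> str:
    """Write coordinate sets (one (p, 3) Angstrom array per sample, or
    Conformations) as a multi-model pseudo-atom PDB."""
    lines = []
    for k, coords in enumerate(coord_sets, start=1):
        if hasattr(coords, "positions"):
            coords = to_cartesian(coords)
        coords = np.asarray(coords, dtype=float)
        lines.append(f"MODEL     {k:4d}")
        for i, (x, y, z) in enumerate(coords):
            lines.append(
                _ATOM_FMT.format(serial=i + 1, chain="A", resseq=i + 1,
                                 x=x, y=y, z=z)
            )
        lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_pdb_models(source) -> list:
    """Read a (multi-model) PDB into a list of (p, 3) coordinate arrays,
    atoms in record order per model."""
    text = source
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("models", _io.StringIO(text))
    out = []
    for model in structure.get_models():
        coords = [a.get_coord() for a in model.get_atoms()]
        if not coords:
            raise FormatError("PDB model with no atoms")
        out.append(np.asarray(coords, dtype=float))
    if not out:
        raise FormatError("no models in PDB input")
    return out


def write_native_pdb(ss: SecondaryStructure, graph, coords,
                     path=None) -> str:
    """Write a synthetic full-length native PDB: one C1' pseudo-atom per
    nucleotide, placed at the coordinate of the first player containing
    that nucleotide.  Intended for fixtures and round-trip tests."""
    owner = {}
    for p in graph.players:
        for nt in p.nucleotides:
            owner.setdefault(nt, p.id)
    coords = np.asarray(coords, dtype=float)
    lines = []
    for i in range(len(ss.sequence)):
        pid = owner.get(i, 0)
        x, y, z = coords[pid]
        lines.append(
            "ATOM  {serial:5d}  C1' {res:>3} A{resseq:4d}    "
            "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C".format(
                serial=i + 1, res=ss.sequence[i], resseq=i + 1,
                x=x, y=y, z=z,
            )
        )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_params(path) -> PairScoreTable:
    return PairScoreTable.from_json(Path(path).read_text())


def write_params(table: PairScoreTable, path) -> None:
    Path(path).write_text(table.to_json() + "\n")


def write_summary_tsv(rows, path=None) -> str:
    """Summary rows mirroring the benchmark-table layout."""
    header = "\t".join(
        ("pdb_id", "n_players", "rmsd_min", "rmsd_max", "n_below", "threshold")
    )
    text = "\n".join([header] + list(rows)) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
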