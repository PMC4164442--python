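"""Reading and writing protein models in PDB format.

A :class:`ProteinModel` is an ordered list of residues, each holding its
heavy-atom coordinates keyed by atom name.  Internal residue indexing is
0-based and contiguous; the author numbering of the source file is kept as
metadata only, because decoy sets frequently carry irregular or gapped
author numbering.

Parsing rules:

* only the first ``MODEL`` block of a multi-model file is used;
* alternate locations other than blank or ``'A'`` are discarded;
* ``HETATM`` records are dropped;
* residues without a CA atom are dropped with a warning (they cannot take
  part in any downstream feature computation);
* all chains are concatenated in file order into a single residue list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

from .errors import FormatError

__all__ = [
    "Residue",
    "ProteinModel",
    "read_pdb",
    "write_pdb",
    "sequence_of",
]

#: Standard 3-letter -> 1-letter amino-acid code table.
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class Residue:
    """One residue: name, author numbering and heavy-atom coordinates."""

    name: str
    chain_id: str
    resseq: int
    icode: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    elements: dict[str, str] = field(default_factory=dict)

    @property
    def is_standard(self) -> bool:
        return self.name in AA3_TO_1

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.name, "X")

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]


@dataclass
class ProteinModel:
    """A single decoy (or reference) structure.

    ``residues`` is ordered by (chain file order, residue_seq,
    insertion_code) and re-indexed contiguously from 0.
    """

    model_id: str
    residues: list[Residue]
    target_id: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """(N, 3) array of CA positions in file order."""
        return np.array([r.ca for r in self.residues], dtype=float)

    def heavy_atoms(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """All heavy atoms as (coords, residue_index, element) triples."""
        coords, res_idx, elements = [], [], []
        for i, res in enumerate(self.residues):
            for name, pos in res.atoms.items():
                elem = res.elements.get(name, name.strip()[:1])
                if elem == "H":
                    continue
                coords.append(pos)
                res_idx.append(i)
                elements.append(elem)
        return np.array(coords, float), np.array(res_idx, int), elements


def _guess_element(atom_name: str, element: str) -> str:
    elem = (element or "").strip().upper()
    if elem:
        return elem.capitalize() if len(elem) > 1 else elem
    name = atom_name.strip()
    # PDB convention: columns 13-14 carry the element for standard residues
    return name.lstrip("0123456789")[:1].upper()


def read_pdb(path: str | Path, model_id: str | None = None,
             target_id: str = "") -> ProteinModel:
    """Parse a PDB file into a :class:`ProteinModel`.

    Parameters
    ----------
    path:
        PDB file with at least one ATOM record.
    model_id:
        Identifier for the parsed model; defaults to the file stem.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    FormatError
        If no residue with a CA atom survives parsing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    if model_id is None:
        model_id = path.stem

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(model_id, str(path))
    models = list(structure)
    if not models:
        raise FormatError(f"{path}: no parsable ATOM records")
    first = models[0]

    residues: list[Residue] = []
    n_dropped = 0
    for chain in first:
        chain_residues: list[Residue] = []
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag.strip():  # HETATM / water
                continue
            out = Residue(name=res.get_resname().strip(),
                          chain_id=chain.id, resseq=resseq,
                          icode=icode.strip())
            for atom in res:
                altloc = atom.get_altloc()
                if atom.is_disordered():
                    # keep blank/'A' conformer only
                    picked = None
                    for alt_id in ("", " ", "A"):
                        if atom.disordered_has_id(alt_id):
                            picked = atom.disordered_get(alt_id)
                            break
                    if picked is None:
                        continue
                    atom = picked
                elif altloc not in ("", " ", "A"):
                    continue
                name = atom.get_name().strip()
                out.atoms[name] = np.asarray(atom.get_coord(), dtype=float)
                out.elements[name] = _guess_element(name, atom.element)
            if "CA" not in out.atoms:
                n_dropped += 1
                continue
            chain_residues.append(out)
        chain_residues.sort(key=lambda r: (r.resseq, r.icode))
        residues.extend(chain_residues)

    if n_dropped:
        warnings.warn(
            f"{path.name}: dropped {n_dropped} residue(s) lacking a CA atom",
            stacklevel=2,
        )
    if not residues:
        raise FormatError(f"{path}: no residues with CA atoms after filtering")
    chains = {r.chain_id for r in residues}
    if len(chains) > 1:
        warnings.warn(
            f"{path.name}: {len(chains)} chains concatenated in file order",
            stacklevel=2,
        )
    return ProteinModel(model_id=model_id, residues=residues,
                        target_id=target_id)


def sequence_of(model: ProteinModel) -> str:
    """One-letter sequence; nonstandard residues map to ``'X'``."""
    if model.length < 1:
        raise FormatError("empty model has no sequence")
    return "".join(res.one_letter for res in model.residues)


_ATOM_FMT = ("ATOM  {serial:5d} {name:^4s}{altloc:1s}{resname:>3s} "
             "{chain:1s}{resseq:4d}{icode:1s}   "
             "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
             "          {element:>2s}\n")


def _format_atom_name(name: str, element: str) -> str:
    # single-letter elements are indented one column per wwPDB layout
    if len(element) == 1 and len(name) < 4:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(model: ProteinModel, path: str | Path) -> None:
    """Write the model as fixed-width ATOM records (wwPDB v3.3 layout)."""
    path = Path(path)
    serial = 1
    with path.open("w") as fh:
        for res in model.residues:
            for name, pos in res.atoms.items():
                elem = res.elements.get(name, name[:1])
                fh.write(_ATOM_FMT.format(
                    serial=serial,
                    name=_format_atom_name(name, elem),
                    altloc=" ",
                    resname=res.name,
                    chain=res.chain_id or "A",
                    resseq=res.resseq,
                    icode=res.icode or " ",
                    x=pos[0], y=pos[1], z=pos[2],
                    occ=1.0, b=0.0,
                    element=elem.upper(),
                ))
                serial += 1
        fh.write("TER\nEND\n")
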