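"""Shared fixtures: tiny hand-written PDB texts and synthetic structures."""

import numpy as np
import pytest

from rfmqa.structure_io import ProteinModel, Residue
from rfmqa.synthetic import DecoyGeneratorParams, make_reference


def _atom_line(serial, name, resname, chain, resseq, x, y, z, element,
               record="ATOM  ", altloc=" "):
    pad_name = f" {name:<3s}" if len(element) == 1 and len(name) < 4 \
        else f"{name:<4s}"
    return (f"{record}{serial:5d} {pad_name}{altloc}{resname:>3s} {chain}"
            f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            f"          {element:>2s}")


@pytest.fixture
def three_residue_pdb(tmp_path):
    """ALA-GLY-ALA backbone, hand-written fixed-width PDB text."""
    lines = []
    serial = 1
    coords = {
        1: {"N": (0.0, 0.0, 0.0), "CA": (1.458, 0.0, 0.0),
            "C": (2.0, 1.4, 0.0), "O": (1.4, 2.4, 0.0)},
        2: {"N": (3.3, 1.5, 0.0), "CA": (4.0, 2.8, 0.0),
            "C": (5.5, 2.6, 0.0), "O": (6.2, 3.6, 0.0)},
        3: {"N": (6.0, 1.4, 0.0), "CA": (7.4, 1.1, 0.0),
            "C": (8.2, 2.4, 0.0), "O": (9.4, 2.3, 0.0)},
    }
    resnames = {1: "ALA", 2: "GLY", 3: "ALA"}
    for resseq, atoms in coords.items():
        for name, (x, y, z) in atoms.items():
            lines.append(_atom_line(serial, name, resnames[resseq], "A",
                                    resseq, x, y, z, name[0]))
            serial += 1
    lines += ["TER", "END"]
    path = tmp_path / "aga.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def atom_line_factory():
    return _atom_line


@pytest.fixture(scope="session")
def helix12():
    """Ideal 12-residue poly-backbone α-helix."""
    return make_reference(DecoyGeneratorParams(n_residues=12, seed=42))


@pytest.fixture(scope="session")
def helix30():
    """Ideal 30-residue α-helix reference."""
    return make_reference(DecoyGeneratorParams(n_residues=30, seed=42))


@pytest.fixture(scope="session")
def mixed20():
    """20-residue helix-loop-helix reference (mixed SS, varied ASA)."""
    return make_reference(DecoyGeneratorParams(
        n_residues=20, topology="helix-loop-helix", seed=7))


def rigid_transform(model: ProteinModel, rotation: np.ndarray,
                    translation: np.ndarray) -> ProteinModel:
    """Apply a rigid motion to every atom of a model (new object)."""
    residues = []
    for res in model.residues:
        residues.append(Residue(
            name=res.name, chain_id=res.chain_id, resseq=res.resseq,
            icode=res.icode,
            atoms={k: rotation @ v + translation for k, v in res.atoms.items()},
            elements=dict(res.elements),
        ))
    return ProteinModel(model_id=model.model_id + "_moved",
                        residues=residues, target_id=model.target_id)


@pytest.fixture
def rigid():
    return rigid_transform
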