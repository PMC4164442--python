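"""Observed structural features and predictor-file parsers.

Two quantities are derived from a 3D model and later compared with
sequence-based predictions:

* the 3-state secondary structure (H/E/C), assigned with the
  Kabsch–Sander hydrogen-bond criterion (backbone electrostatic H-bond
  energy below -0.5 kcal/mol; helices from runs of i->i+3/4/5 turns,
  strands from bridge patterns) and reduced 8->3 states by the common
  convention {H,G,I}->H, {E,B}->E, rest->C;
* the per-residue absolute solvent accessibility (ASA, in Å²), computed
  with the Shrake–Rupley rolling-probe method (probe 1.4 Å, deterministic
  spiral point set, >= 960 points per atom).

Both are built in so the pipeline runs with no external binaries; when
DSSP output or prediction files from external tools are supplied they
take precedence.  Parsers accept classic DSSP text, PSIPRED vertical
(.ss2) format, and plain TSV tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import AlignmentError, FormatError
from .structure_io import ProteinModel

__all__ = [
    "SecondaryStructureString",
    "ConfidenceTrack",
    "AccessibilityTrack",
    "assign_secondary_structure",
    "compute_asa",
    "parse_dssp_file",
    "parse_ss_prediction",
    "parse_asa_prediction",
    "MAX_ASA",
    "VDW_RADII",
]

#: van der Waals radii (Å) used by the accessibility calculation.
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
DEFAULT_VDW = 1.7
PROBE_RADIUS = 1.4

#: Theoretical maximum ASA per residue (Å², Tien et al. 2013), used to
#: convert relative accessibility predictions to absolute values.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: 8-state -> 3-state reduction.
SS8_TO_3 = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def reduce_ss8(state: str) -> str:
    return SS8_TO_3.get(state, "C")


@dataclass
class SecondaryStructureString:
    """3-state secondary structure over {H, E, C}."""

    states: str
    source: str = "computed"  # computed | dssp_file | predicted

    def __post_init__(self) -> None:
        bad = set(self.states) - set("HEC")
        if bad:
            raise FormatError(f"invalid 3-state letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class ConfidenceTrack:
    """Per-residue prediction confidence in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise FormatError("confidence values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class AccessibilityTrack:
    """Per-residue absolute solvent accessibility in Å²."""

    values: np.ndarray
    source: str = "computed"  # computed | dssp_file | predicted

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and self.values.min() < 0:
            raise FormatError("ASA values must be nonnegative")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Secondary structure assignment (Kabsch–Sander hydrogen bonds)
# ---------------------------------------------------------------------------

_HBOND_CUTOFF = -0.5       # kcal/mol
_HBOND_CONST = 0.084 * 332  # q1*q2*f in the Kabsch–Sander energy formula
_PEPTIDE_BOND_MAX = 2.5     # Å; larger C(i-1)-N(i) distance = chain break


def _backbone_arrays(model: ProteinModel):
    """Backbone coordinate arrays plus a completeness mask."""
    n = model.length
    coords = {name: np.full((n, 3), np.nan) for name in ("N", "CA", "C", "O")}
    complete = np.zeros(n, dtype=bool)
    for i, res in enumerate(model.residues):
        ok = True
        for name in ("N", "CA", "C", "O"):
            if name in res.atoms:
                coords[name][i] = res.atoms[name]
            else:
                ok = False
        complete[i] = ok
    return coords, complete


def _amide_hydrogens(coords, complete, is_proline) -> np.ndarray:
    """Reconstruct amide H geometrically: N-H parallel to the previous C=O."""
    n = len(complete)
    h = np.full((n, 3), np.nan)
    for i in range(1, n):
        if is_proline[i] or not complete[i] or not complete[i - 1]:
            continue
        # chain-break check on the peptide bond
        if np.linalg.norm(coords["N"][i] - coords["C"][i - 1]) > _PEPTIDE_BOND_MAX:
            continue
        co = coords["C"][i - 1] - coords["O"][i - 1]
        norm = np.linalg.norm(co)
        if norm < 1e-9:
            continue
        h[i] = coords["N"][i] + co / norm
    return h


def _hbond_matrix(model: ProteinModel) -> np.ndarray:
    """hb[a, d] is True when the CO of residue *a* accepts the NH of *d*."""
    n = model.length
    coords, complete = _backbone_arrays(model)
    is_pro = np.array([r.name == "PRO" for r in model.residues])
    h = _amide_hydrogens(coords, complete, is_pro)
    has_h = np.isfinite(h[:, 0])

    hb = np.zeros((n, n), dtype=bool)
    ca = coords["CA"]
    for a in range(n):
        if not complete[a]:
            continue
        for d in range(n):
            if d == a or abs(d - a) < 2 or not has_h[d] or not complete[d]:
                continue
            if np.linalg.norm(ca[a] - ca[d]) > 9.0:
                continue
            r_on = np.linalg.norm(coords["O"][a] - coords["N"][d])
            r_ch = np.linalg.norm(coords["C"][a] - h[d])
            r_oh = np.linalg.norm(coords["O"][a] - h[d])
            r_cn = np.linalg.norm(coords["C"][a] - coords["N"][d])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # clashing geometry, treat as no bond
            energy = _HBOND_CONST * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < _HBOND_CUTOFF:
                hb[a, d] = True
    return hb


def assign_secondary_structure(model: ProteinModel) -> SecondaryStructureString:
    """Assign H/E/C states from backbone hydrogen bonding.

    Helix states come from runs of two consecutive i->i+n turns
    (n = 4 for α, 3 for 3-10, 5 for π); strand states from parallel or
    antiparallel bridge patterns.  α-helix takes priority over strand,
    strand over the short helix types.  Models with fewer than 5
    complete-backbone residues are returned as all-coil with a warning.
    """
    n = model.length
    _, complete = _backbone_arrays(model)
    if int(complete.sum()) < 5:
        warnings.warn("fewer than 5 residues with complete backbone; "
                      "returning all-coil assignment", stacklevel=2)
        return SecondaryStructureString("C" * n, source="computed")

    hb = _hbond_matrix(model)

    def turn(i: int, step: int) -> bool:
        return 0 <= i and i + step < n and hb[i, i + step]

    helix4 = np.zeros(n, dtype=bool)
    helix35 = np.zeros(n, dtype=bool)
    for step, mask in ((4, helix4), (3, helix35), (5, helix35)):
        for i in range(1, n - step):
            if turn(i - 1, step) and turn(i, step):
                mask[i:i + step] = True

    bridge = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[i - 1, j] and hb[j, i + 1]) or \
                   (hb[j - 1, i] and hb[i, j + 1])
            anti = (hb[i, j] and hb[j, i]) or \
                   (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if para or anti:
                bridge[i] = bridge[j] = True

    states = []
    for i in range(n):
        if helix4[i]:
            states.append("H")
        elif bridge[i]:
            states.append("E")
        elif helix35[i]:
            states.append("H")  # G/I reduce to H
        else:
            states.append("C")
    return SecondaryStructureString("".join(states), source="computed")


# ---------------------------------------------------------------------------
# Solvent accessibility (Shrake–Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def compute_asa(model: ProteinModel, probe: float = PROBE_RADIUS,
                n_points: int = 960) -> AccessibilityTrack:
    """Per-residue absolute solvent accessibility in Å².

    Heavy atoms only; each atom's accessible area is the fraction of a
    fixed spiral point set on its solvent-expanded sphere not occluded by
    any neighbour, times the sphere area.  Deterministic for a fixed
    point count.
    """
    coords, res_idx, elements = model.heavy_atoms()
    n_atoms = len(coords)
    radii = np.array([VDW_RADII.get(e.upper()[:1], DEFAULT_VDW)
                      for e in elements])
    expanded = radii + probe
    unit = _sphere_points(n_points)

    per_res = np.zeros(model.length)
    for i in range(n_atoms):
        # neighbour prefilter: spheres that can occlude atom i
        d = np.linalg.norm(coords - coords[i], axis=1)
        nb = (d < expanded[i] + expanded) & (np.arange(n_atoms) != i)
        pts = coords[i] + expanded[i] * unit
        if nb.any():
            nb_coords = coords[nb]
            nb_r2 = expanded[nb] ** 2
            d2 = ((pts[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            accessible = ~(d2 < nb_r2[None, :]).any(axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        per_res[res_idx[i]] += frac * 4.0 * np.pi * expanded[i] ** 2
    return AccessibilityTrack(per_res, source="computed")


# ---------------------------------------------------------------------------
# Parsers for external tool output
# ---------------------------------------------------------------------------

def parse_dssp_file(path: str | Path, expected_sequence: str | None = None
                    ) -> tuple[SecondaryStructureString, AccessibilityTrack]:
    """Parse classic DSSP text output into reduced SS states and ASA.

    ``expected_sequence`` (one-letter) enables an alignment check against
    the model the file is meant to describe.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    start = None
    for k, line in enumerate(lines):
        if line.startswith("  #  RESIDUE"):
            start = k + 1
            break
    if start is None:
        raise FormatError(f"{path}: DSSP data header not found")

    states, accs, seq = [], [], []
    for line in lines[start:]:
        if len(line) < 38:
            raise FormatError(f"{path}: truncated DSSP data line")
        aa = line[13]
        if aa == "!":  # chain break marker
            continue
        states.append(reduce_ss8(line[16]))
        seq.append(aa.upper())
        try:
            accs.append(float(line[34:38]))
        except ValueError as exc:
            raise FormatError(f"{path}: bad ACC field: {line[34:38]!r}") from exc
    if not states:
        raise FormatError(f"{path}: no residue rows")

    if expected_sequence is not None:
        got = "".join(seq)
        if len(got) != len(expected_sequence) or any(
                g != e and "X" not in (g, e)
                for g, e in zip(got, expected_sequence)):
            mismatches = [i for i, (g, e) in
                          enumerate(zip(got, expected_sequence)) if g != e]
            raise AlignmentError(
                f"{path}: sequence mismatch vs model at positions "
                f"{mismatches[:10]} (lengths {len(got)} vs "
                f"{len(expected_sequence)})")
    return (SecondaryStructureString("".join(states), source="dssp_file"),
            AccessibilityTrack(np.array(accs), source="dssp_file"))


def parse_ss_prediction(path: str | Path
                        ) -> tuple[SecondaryStructureString, ConfidenceTrack]:
    """Parse a secondary-structure prediction file.

    Two layouts are accepted:

    * PSIPRED vertical format: ``index residue state pC pH pE``;
      confidence is the maximum class probability;
    * generic 3-column table: ``residue state confidence``; integer
      confidences 0-9 are scaled to [0, 1] by dividing by 9.
    """
    path = Path(path)
    states, confs = [], []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) >= 6:
            state = tokens[2]
            probs = [float(t) for t in tokens[3:6]]
            conf = min(max(probs), 1.0)
        elif len(tokens) == 3:
            state = tokens[1]
            value = float(tokens[2])
            if tokens[2].isdigit() and 0 <= int(tokens[2]) <= 9:
                conf = int(tokens[2]) / 9.0
            else:
                conf = min(max(value, 0.0), 1.0)
        else:
            raise FormatError(f"{path}: unrecognised row: {raw!r}")
        if state not in "HEC":
            raise FormatError(f"{path}: unknown state letter {state!r}")
        states.append(state)
        confs.append(conf)
    if not states:
        raise FormatError(f"{path}: no prediction rows")
    return (SecondaryStructureString("".join(states), source="predicted"),
            ConfidenceTrack(np.array(confs)))


def parse_asa_prediction(path: str | Path, relative: bool = False,
                         sequence: str | None = None) -> AccessibilityTrack:
    """Parse a predicted-ASA table into absolute Å² values.

    Rows are ``index value`` or ``index residue value``.  With
    ``relative=True`` values are fractions of the residue's theoretical
    maximum ASA and are converted using the shipped table; the residue
    identity comes from the file's residue column or from *sequence*.
    Negative values are clamped to zero with a warning.
    """
    path = Path(path)
    rows: list[tuple[str | None, float]] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) == 2:
            rows.append((None, float(tokens[1])))
        elif len(tokens) >= 3:
            rows.append((tokens[1], float(tokens[2])))
        else:
            raise FormatError(f"{path}: unrecognised row: {raw!r}")
    if not rows:
        raise FormatError(f"{path}: no data rows")

    values = []
    for i, (aa, value) in enumerate(rows):
        if relative:
            letter = aa if aa else (sequence[i] if sequence else None)
            if letter is None:
                raise FormatError(
                    f"{path}: relative ASA needs a residue column or an "
                    f"explicit sequence")
            values.append(value * MAX_ASA.get(letter.upper(), 150.0))
        else:
            values.append(value)
    values = np.array(values)
    if (values < 0).any():
        warnings.warn(f"{path.name}: negative ASA values clamped to 0",
                      stacklevel=2)
        values = np.maximum(values, 0.0)
    return AccessibilityTrack(values, source="predicted")
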