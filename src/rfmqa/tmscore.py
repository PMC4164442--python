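"""TM-score between a decoy and a reference structure.

TM-score is a length-normalised structural similarity in (0, 1]:

    TM = max over superpositions of (1/L) * sum_i 1 / (1 + (d_i/d0)^2)

with L the reference length, d_i the CA-CA distance of residue pair i
after superposition and d0(L) = 1.24 * (L - 15)^(1/3) - 1.8 Å (floored
at 0.5 Å for short chains).  The maximisation uses the standard
heuristic: rigid fits seeded on contiguous fragments of lengths L, L/2
and L/4 at several offsets, each refined by alternating between a
least-squares fit on the currently included residue pairs and
re-inclusion of pairs closer than a distance cutoff.

Residue correspondence is positional: decoys of the same target share
the reference numbering, so no sequence alignment is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .structure_io import ProteinModel

__all__ = ["Superposition", "kabsch_superpose", "tm_score", "d0"]


@dataclass
class Superposition:
    """Least-squares rigid-body fit of one coordinate set onto another."""

    rotation: np.ndarray      # 3x3, det +1
    translation: np.ndarray   # 3-vector, Å
    rmsd: float               # over the fitted subset, Å
    aligned_pairs: np.ndarray  # indices used for the fit
    degenerate: bool = False   # collinear/rank-deficient input

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray,
                     pairs: np.ndarray | None = None) -> Superposition:
    """Optimal rigid superposition of ``coords_a`` onto ``coords_b``.

    Minimises RMSD over rotations (determinant +1, so reflections are
    excluded) and translations.  ``pairs`` restricts the fit to a subset
    of rows; the returned transform still applies to full arrays.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ParameterError("coordinate sets must be matching (n, 3) arrays")
    if pairs is None:
        pairs = np.arange(len(a))
    pairs = np.asarray(pairs, dtype=int)
    if len(pairs) < 3:
        raise ParameterError("superposition needs at least 3 point pairs")

    sub_a, sub_b = a[pairs], b[pairs]
    cen_a, cen_b = sub_a.mean(axis=0), sub_b.mean(axis=0)
    h = (sub_a - cen_a).T @ (sub_b - cen_b)
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rotation = vt.T @ d @ u.T
    translation = cen_b - rotation @ cen_a
    fitted = sub_a @ rotation.T + translation
    rmsd = float(np.sqrt(((fitted - sub_b) ** 2).sum(axis=1).mean()))
    # rank-deficient (collinear) sets leave a rotational degree of freedom
    degenerate = bool(s[1] < 1e-8 * max(s[0], 1.0))
    return Superposition(rotation=rotation, translation=translation,
                         rmsd=rmsd, aligned_pairs=pairs,
                         degenerate=degenerate)


def d0(length: int) -> float:
    """TM-score distance scale for a reference of *length* residues."""
    if length > 15:
        value = 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8
    else:
        value = 0.5
    return max(value, 0.5)


def _score(decoy: np.ndarray, ref: np.ndarray, sp: Superposition,
           d0_val: float, norm_len: int) -> tuple[float, np.ndarray]:
    moved = sp.apply(decoy)
    dist = np.linalg.norm(moved - ref, axis=1)
    return float((1.0 / (1.0 + (dist / d0_val) ** 2)).sum() / norm_len), dist


def _refine(decoy: np.ndarray, ref: np.ndarray, seed_pairs: np.ndarray,
            d0_val: float, norm_len: int, max_iter: int = 30
            ) -> float:
    """Alternating fit/include refinement from one seed fragment."""
    best = 0.0
    try:
        sp = kabsch_superpose(decoy, ref, seed_pairs)
    except ParameterError:
        return best
    prev_sel: frozenset[int] | None = None
    for _ in range(max_iter):
        score, dist = _score(decoy, ref, sp, d0_val, norm_len)
        best = max(best, score)
        cutoff = max(d0_val, 3.0)
        sel = np.where(dist < cutoff)[0]
        while len(sel) < 3:
            cutoff += 0.5
            sel = np.where(dist < cutoff)[0]
        key = frozenset(sel.tolist())
        if key == prev_sel:
            break
        prev_sel = key
        sp = kabsch_superpose(decoy, ref, sel)
    return best


def tm_score(decoy: ProteinModel | np.ndarray,
             reference: ProteinModel | np.ndarray) -> float:
    """TM-score of *decoy* against *reference*, normalised by reference length.

    Accepts models (CA coordinates are extracted positionally) or raw
    (n, 3) CA coordinate arrays of equal length.  Deterministic; 1.0 for
    a decoy identical to the reference.
    """
    ca_d = decoy.ca_coords() if isinstance(decoy, ProteinModel) else \
        np.asarray(decoy, dtype=float)
    ca_r = reference.ca_coords() if isinstance(reference, ProteinModel) else \
        np.asarray(reference, dtype=float)
    if len(ca_d) != len(ca_r):
        raise ParameterError(
            f"decoy and reference must share residue correspondence "
            f"({len(ca_d)} vs {len(ca_r)} residues)")
    n = len(ca_r)
    if n < 3:
        raise ParameterError("TM-score needs at least 3 common residues")

    d0_val = d0(n)
    best = 0.0
    for frag_len in sorted({n, max(n // 2, 4), max(n // 4, 4),
                            max(n // 8, 4)}, reverse=True):
        step = max(frag_len // 4, 1)
        starts = list(range(0, n - frag_len + 1, step))
        if starts and starts[-1] != n - frag_len:
            starts.append(n - frag_len)
        for start in starts:
            seed = np.arange(start, start + frag_len)
            best = max(best, _refine(ca_d, ca_r, seed, d0_val, n))
    return min(best, 1.0)
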