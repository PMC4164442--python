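"""Statistical-potential energy features.

The three energy features are normally produced by external scoring
programs (dDFIRE, RWplus, GOAP) and imported as two-column score tables.
Because the downstream pipeline only ever uses energies through a
per-pool min-max normalisation, their units and absolute scale are
irrelevant; the only convention enforced is *lower = better*, with a
``negate`` switch for tables of the opposite sign.

A built-in residue-contact pseudo-energy is provided so the pipeline is
fully runnable and testable without any external binary.  It is a
deterministic distance-binned CA contact potential with a small shipped
weight table derived from a hydrophobicity scale — favourable mid-range
contacts between hydrophobic residues, a clash penalty below 4 Å — and
makes no claim to the accuracy of the published potentials it slots in
for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError
from .structure_io import ProteinModel

__all__ = [
    "EnergyTable",
    "read_energy_table",
    "contact_potential",
    "PotentialParams",
    "DEFAULT_METHOD_NAMES",
]

#: Default names of the three energy feature slots (F1-F3).
DEFAULT_METHOD_NAMES = ("dDFIRE", "RWplus", "GOAP")


@dataclass
class EnergyTable:
    """Per-model energies of one scoring method; lower is better."""

    method_name: str
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mid, value in self.scores.items():
            if not np.isfinite(value):
                raise FormatError(
                    f"{self.method_name}: non-finite energy for {mid}")

    def energy_of(self, model_id: str) -> float:
        try:
            return self.scores[model_id]
        except KeyError:
            raise KeyError(
                f"{self.method_name}: model {model_id} absent") from None

    def __len__(self) -> int:
        return len(self.scores)


def read_energy_table(path: str | Path, method_name: str,
                      negate: bool = False) -> EnergyTable:
    """Read a 2-column (model_id, energy) TSV/CSV score table.

    ``negate`` flips the sign for programs that report higher-is-better
    scores.  Duplicate model ids and non-numeric energies are errors.
    """
    path = Path(path)
    scores: dict[str, float] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.replace(",", "\t").split()
        if len(tokens) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'model_id energy'")
        mid = tokens[0]
        try:
            value = float(tokens[1])
        except ValueError as exc:
            raise FormatError(
                f"{path}:{lineno}: non-numeric energy {tokens[1]!r}") from exc
        if not np.isfinite(value):
            raise FormatError(f"{path}:{lineno}: non-finite energy")
        if mid in scores:
            raise FormatError(f"{path}:{lineno}: duplicate model id {mid!r}")
        scores[mid] = -value if negate else value
    return EnergyTable(method_name=method_name, scores=scores)


# Kyte–Doolittle hydropathy, used to build the shipped contact weights.
_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass
class PotentialParams:
    """Parameters of the built-in CA contact pseudo-energy."""

    clash_distance: float = 4.0    # Å; CA pairs closer than this are penalised
    contact_distance: float = 8.0  # Å; upper edge of the favourable band
    clash_penalty: float = 1.0
    contact_base: float = -0.2
    hydropathy_scale: float = 0.05
    min_separation: int = 3        # |i - j| >= this along the chain


def contact_potential(model: ProteinModel,
                      params: PotentialParams | None = None) -> float:
    """Deterministic CA contact pseudo-energy (lower = better).

    E = sum over pairs with |i-j| >= 3 of w(aa_i, aa_j, bin(d_ij)) where
    mid-range contacts (clash_distance..contact_distance) score
    ``contact_base - scale * (h_i + h_j)`` and closer pairs pay the clash
    penalty.  Rigid motions leave the energy unchanged.
    """
    if params is None:
        params = PotentialParams()
    n = model.length
    if n < params.min_separation + 1:
        return 0.0
    ca = model.ca_coords()
    h = np.array([_HYDROPATHY.get(r.one_letter, 0.0) for r in model.residues])
    ii, jj = np.triu_indices(n, k=params.min_separation)
    d = np.linalg.norm(ca[ii] - ca[jj], axis=1)
    clash = d < params.clash_distance
    contact = (~clash) & (d < params.contact_distance)
    energy = params.clash_penalty * clash.sum()
    energy += (params.contact_base
               - params.hydropathy_scale * (h[ii] + h[jj]))[contact].sum()
    return float(energy)


def energy_table_from_models(models: list[ProteinModel],
                             method_name: str = "builtin_contact",
                             params: PotentialParams | None = None
                             ) -> EnergyTable:
    """Score a list of models with the built-in potential."""
    return EnergyTable(
        method_name=method_name,
        scores={m.model_id: contact_potential(m, params) for m in models})
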