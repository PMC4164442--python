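"""Self-contained synthetic decoy pools for testing and simulation.

The generator emulates the inputs of a decoy-ranking experiment with no
external data:

* a *reference* backbone (N, CA, C, O) built from ideal internal
  coordinates — α-helix (φ = -57°, ψ = -47°), a helix-loop-helix, or a
  β-hairpin-like strand pair;
* a *decoy pool*: copies of the reference perturbed by per-residue rigid
  Gaussian jitter of increasing scale, so pool quality spans a smooth
  gradient; each decoy's true TM-score against the reference is its
  label.  Jitter is applied per residue (the whole residue moves
  together) so the hydrogen-bond pattern — and with it the assigned
  secondary structure — degrades gradually rather than collapsing;
* *predictor stand-ins*: a simulated secondary-structure prediction that
  agrees with the reference assignment at a tunable rate, with higher
  confidence on correct positions; a simulated ASA prediction equal to
  the reference ASA plus Gaussian noise; and three simulated energies
  drawn to correlate with (1 - TM) at a tunable level.

Default parameter values are chosen to resemble a realistic server-model
pool: predicted secondary structure correct at ~80% of positions (a
typical three-state prediction accuracy), ASA noise of 15 Å², and
energies correlating with quality at 0.7 within a pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .features import TargetPool, build_feature_vector
from .potentials import DEFAULT_METHOD_NAMES, EnergyTable
from .struct_features import (AccessibilityTrack, ConfidenceTrack,
                              SecondaryStructureString,
                              assign_secondary_structure, compute_asa)
from .structure_io import ProteinModel, Residue
from .tmscore import tm_score

__all__ = [
    "DecoyGeneratorParams",
    "make_reference",
    "make_decoys",
    "make_decoy_pool",
    "simulate_predictions",
    "simulate_energies",
    "PoolBundle",
]

# ideal backbone internal coordinates (Å, degrees)
_BOND = {"N_CA": 1.458, "CA_C": 1.525, "C_N": 1.329, "C_O": 1.231}
_ANGLE = {"N_CA_C": 111.2, "CA_C_N": 116.2, "C_N_CA": 121.7, "CA_C_O": 120.8}
_OMEGA = 180.0

_PHI_PSI = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 120.0),
    "loop": (-75.0, 145.0),
}

# default jitter ladder 0.4..1.6 Å: on a 30-residue target this spreads
# labels over roughly TM 0.3-0.8 (pool mean ~0.5, comparable to a real
# server-model pool) without including the native itself
_DEFAULT_MIN_SIGMA = 0.4
_DEFAULT_MAX_SIGMA = 1.6


@dataclass
class DecoyGeneratorParams:
    """Study conditions of one synthetic target."""

    n_residues: int = 30
    topology: str = "helix"  # helix | helix-loop-helix | strand-pair
    n_decoys: int = 10
    noise_sigmas: tuple[float, ...] | None = None  # Å, one per decoy
    ss_pred_accuracy: float = 0.8
    asa_pred_noise_sd: float = 15.0  # Å²
    energy_quality_corr: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 8:
            raise ParameterError("n_residues must be >= 8")
        if self.n_decoys < 2:
            raise ParameterError("n_decoys must be >= 2")
        if not 0 <= self.ss_pred_accuracy <= 1:
            raise ParameterError("ss_pred_accuracy must be in [0, 1]")
        if not -1 <= self.energy_quality_corr <= 1:
            raise ParameterError("energy_quality_corr must be in [-1, 1]")
        if self.topology not in ("helix", "helix-loop-helix", "strand-pair"):
            raise ParameterError(f"unsupported topology {self.topology!r}")
        if self.noise_sigmas is None:
            self.noise_sigmas = tuple(
                np.linspace(_DEFAULT_MIN_SIGMA, _DEFAULT_MAX_SIGMA,
                            self.n_decoys))
        if len(self.noise_sigmas) != self.n_decoys:
            raise ParameterError("noise_sigmas must have one entry per decoy")
        if any(s < 0 for s in self.noise_sigmas):
            raise ParameterError("noise sigmas must be nonnegative")


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float
                ) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D from A-B-C."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _torsion_profile(params: DecoyGeneratorParams) -> list[tuple[float, float]]:
    n = params.n_residues
    if params.topology == "helix":
        return [_PHI_PSI["helix"]] * n
    if params.topology == "helix-loop-helix":
        third = n // 3
        return ([_PHI_PSI["helix"]] * third
                + [_PHI_PSI["loop"]] * (n - 2 * third)
                + [_PHI_PSI["helix"]] * third)
    # strand-pair: two extended strands joined by a tight two-residue turn
    half = (n - 2) // 2
    turn = [(60.0, 60.0), (90.0, 0.0)]
    profile = [_PHI_PSI["strand"]] * half + turn + \
        [_PHI_PSI["strand"]] * (n - half - 2)
    return profile[:n]


_SEQUENCE_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def make_reference(params: DecoyGeneratorParams) -> ProteinModel:
    """Build an ideal-geometry backbone reference; deterministic per seed.

    The sequence is drawn uniformly from the standard residues minus
    proline, whose ring would be inconsistent with the imposed backbone
    torsions.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(0,)))
    profile = _torsion_profile(params)
    n = params.n_residues
    seq = rng.choice(list(_SEQUENCE_ALPHABET.replace("P", "")), size=n)

    one_to_three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
        "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
        "M": "MET", "N": "ASN", "Q": "GLN", "R": "ARG", "S": "SER",
        "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    }

    coords_n = np.zeros((n, 3))
    coords_ca = np.zeros((n, 3))
    coords_c = np.zeros((n, 3))
    coords_o = np.zeros((n, 3))

    coords_n[0] = (0.0, 0.0, 0.0)
    coords_ca[0] = (_BOND["N_CA"], 0.0, 0.0)
    ang = np.deg2rad(_ANGLE["N_CA_C"])
    coords_c[0] = coords_ca[0] + _BOND["CA_C"] * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, n):
        psi_prev = profile[i - 1][1]
        coords_n[i] = _place_atom(coords_n[i - 1], coords_ca[i - 1],
                                  coords_c[i - 1], _BOND["C_N"],
                                  _ANGLE["CA_C_N"], psi_prev)
        coords_ca[i] = _place_atom(coords_ca[i - 1], coords_c[i - 1],
                                   coords_n[i], _BOND["N_CA"],
                                   _ANGLE["C_N_CA"], _OMEGA)
        coords_c[i] = _place_atom(coords_c[i - 1], coords_n[i],
                                  coords_ca[i], _BOND["CA_C"],
                                  _ANGLE["N_CA_C"], profile[i][0])
        # carbonyl O of the previous residue, anti to the new amide N
        coords_o[i - 1] = _place_atom(coords_n[i - 1], coords_ca[i - 1],
                                      coords_c[i - 1], _BOND["C_O"],
                                      _ANGLE["CA_C_O"], psi_prev + 180.0)
    coords_o[n - 1] = _place_atom(coords_n[n - 1], coords_ca[n - 1],
                                  coords_c[n - 1], _BOND["C_O"],
                                  _ANGLE["CA_C_O"], profile[n - 1][1] + 180.0)

    residues = []
    for i in range(n):
        name3 = one_to_three[str(seq[i])]
        residues.append(Residue(
            name=name3, chain_id="A", resseq=i + 1, icode="",
            atoms={"N": coords_n[i], "CA": coords_ca[i],
                   "C": coords_c[i], "O": coords_o[i]},
            elements={"N": "N", "CA": "C", "C": "C", "O": "O"},
        ))
    return ProteinModel(model_id="reference", residues=residues,
                        target_id=f"synth{params.seed}")


def make_decoys(reference: ProteinModel, params: DecoyGeneratorParams
                ) -> list[ProteinModel]:
    """Perturbed copies of the reference, one per noise sigma.

    Jitter is rigid per residue: one Gaussian offset is drawn per
    residue and applied to all of its atoms.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(1,)))
    decoys = []
    for d, sigma in enumerate(params.noise_sigmas):
        offsets = rng.normal(0.0, max(sigma, 1e-12),
                             size=(reference.length, 3))
        if sigma == 0:
            offsets[:] = 0.0
        residues = []
        for i, res in enumerate(reference.residues):
            residues.append(Residue(
                name=res.name, chain_id=res.chain_id, resseq=res.resseq,
                icode=res.icode,
                atoms={k: v + offsets[i] for k, v in res.atoms.items()},
                elements=dict(res.elements),
            ))
        decoys.append(ProteinModel(
            model_id=f"decoy_{d:03d}", residues=residues,
            target_id=reference.target_id))
    return decoys


def simulate_predictions(reference: ProteinModel,
                         params: DecoyGeneratorParams
                         ) -> tuple[SecondaryStructureString, ConfidenceTrack,
                                    AccessibilityTrack]:
    """Sequence-based predictor stand-ins derived from the reference.

    The SS prediction matches the reference assignment at rate
    ``ss_pred_accuracy``; confidences are drawn higher on correct
    positions (0.7-1.0) than on wrong ones (0.3-0.7), as real predictors
    tend to be better calibrated where they are right.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(2,)))
    true_ss = assign_secondary_structure(reference).states
    states, confs = [], []
    for s in true_ss:
        if rng.random() < params.ss_pred_accuracy:
            states.append(s)
            confs.append(rng.uniform(0.7, 1.0))
        else:
            others = [c for c in "HEC" if c != s]
            states.append(others[rng.integers(0, 2)])
            confs.append(rng.uniform(0.3, 0.7))
    asa_ref = compute_asa(reference).values
    asa_noise = rng.normal(0.0, params.asa_pred_noise_sd, size=len(asa_ref))
    asa_pred = np.maximum(asa_ref + asa_noise, 0.0)
    return (SecondaryStructureString("".join(states), source="predicted"),
            ConfidenceTrack(np.array(confs)),
            AccessibilityTrack(asa_pred, source="predicted"))


def simulate_energies(model_ids: list[str], labels: np.ndarray,
                      params: DecoyGeneratorParams
                      ) -> tuple[EnergyTable, EnergyTable, EnergyTable]:
    """Three pseudo-energy tables correlating with (1 - TM).

    Each table's energies are rho * z + sqrt(1 - rho^2) * eps on the
    standardised badness z = standardise(1 - TM), then affinely mapped
    to an energy-like scale.  Lower = better holds on average whenever
    rho > 0.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(3,)))
    badness = 1.0 - np.asarray(labels, dtype=float)
    sd = badness.std()
    z = (badness - badness.mean()) / sd if sd > 0 else np.zeros_like(badness)
    rho = params.energy_quality_corr
    tables = []
    for k, name in enumerate(DEFAULT_METHOD_NAMES):
        eps = rng.normal(size=len(labels))
        signal = rho * z + np.sqrt(max(0.0, 1.0 - rho * rho)) * eps
        energies = -5000.0 + 150.0 * signal + 25.0 * k
        tables.append(EnergyTable(
            method_name=name,
            scores=dict(zip(model_ids, energies.tolist()))))
    return tuple(tables)


@dataclass
class PoolBundle:
    """Everything one synthetic target produces, pre- and post-features."""

    reference: ProteinModel
    decoys: list[ProteinModel]
    labels: np.ndarray
    predicted_ss: SecondaryStructureString
    confidence: ConfidenceTrack
    asa_pred: AccessibilityTrack
    energies: tuple[EnergyTable, EnergyTable, EnergyTable]
    pool: TargetPool


def make_decoy_pool(reference: ProteinModel, params: DecoyGeneratorParams,
                    asa_points: int = 240) -> TargetPool:
    """Generate decoys, labels, predictor stand-ins and assemble features.

    ``asa_points`` controls the sphere-point count of the accessibility
    computation for the observed tracks (the default trades a fraction
    of a percent of area accuracy for speed across large pool sets).
    """
    return make_pool_bundle(reference, params, asa_points=asa_points).pool


def make_pool_bundle(reference: ProteinModel, params: DecoyGeneratorParams,
                     asa_points: int = 240) -> PoolBundle:
    """Like :func:`make_decoy_pool` but keeps all intermediate artifacts."""
    decoys = make_decoys(reference, params)
    labels = np.array([tm_score(d, reference) for d in decoys])
    pred_ss, conf, asa_pred = simulate_predictions(reference, params)
    energies = simulate_energies([d.model_id for d in decoys], labels, params)
    rows = []
    for decoy in decoys:
        observed = assign_secondary_structure(decoy)
        asa_obs = compute_asa(decoy, n_points=asa_points)
        fv = build_feature_vector(decoy, observed, pred_ss, conf,
                                  asa_obs, asa_pred, energies)
        rows.append(fv.as_array())
    pool = TargetPool(
        target_id=reference.target_id,
        model_ids=[d.model_id for d in decoys],
        features=np.array(rows),
        labels=labels,
    )
    return PoolBundle(reference=reference, decoys=decoys, labels=labels,
                      predicted_ss=pred_ss, confidence=conf,
                      asa_pred=asa_pred, energies=energies, pool=pool)


def make_pools(n_pools: int, base_seed: int = 0,
               template: DecoyGeneratorParams | None = None,
               asa_points: int = 240) -> list[TargetPool]:
    """A list of independent synthetic pools with distinct seeds/targets."""
    if template is None:
        template = DecoyGeneratorParams()
    pools = []
    for k in range(n_pools):
        params = DecoyGeneratorParams(
            n_residues=template.n_residues,
            topology=template.topology,
            n_decoys=template.n_decoys,
            noise_sigmas=template.noise_sigmas,
            ss_pred_accuracy=template.ss_pred_accuracy,
            asa_pred_noise_sd=template.asa_pred_noise_sd,
            energy_quality_corr=template.energy_quality_corr,
            seed=base_seed * 100003 + k,
        )
        ref = make_reference(params)
        ref.target_id = f"synth{params.seed}"
        pools.append(make_decoy_pool(ref, params, asa_points=asa_points))
    return pools
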