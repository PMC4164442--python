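"""Assembly of the 9-dimensional feature vector and per-pool normalisation.

Each decoy is described by nine features, in fixed order:

====  ======================  =========================================
F1    dDFIRE energy           statistical potential (imported or built-in)
F2    RWplus energy           statistical potential
F3    GOAP energy             statistical potential
F4    helix match fraction    positions where model and prediction agree on H
F5    sheet match fraction    positions where both say E
F6    coil match fraction     positions where both say C
F7    SS consistency score    confidence-weighted agreement, in [0, 1]
F8    ASA correlation         Pearson r of model vs predicted ASA
F9    ASA cosine              cosine of the two nonnegative ASA vectors
====  ======================  =========================================

Before training, every feature column *and* the TM-score label are
min-max normalised to [0, 1] within each target's decoy pool, so the
learned response is a relative quality score and the units of the
imported energies never matter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .potentials import EnergyTable
from .struct_features import (AccessibilityTrack, ConfidenceTrack,
                              SecondaryStructureString)
from .structure_io import ProteinModel

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "TargetPool",
    "ss_match_fractions",
    "ss_consistency_score",
    "asa_consistency",
    "build_feature_vector",
    "normalize_pool",
    "pool_to_dataframe",
    "pool_from_dataframe",
]

FEATURE_NAMES = (
    "F1_dDFIRE", "F2_RWplus", "F3_GOAP",
    "F4_helix_match", "F5_sheet_match", "F6_coil_match",
    "F7_ss_consistency", "F8_asa_corr", "F9_asa_cos",
)


@dataclass(frozen=True)
class FeatureVector:
    """Raw feature values of one model, in fixed F1..F9 order."""

    f1_dDFIRE: float
    f2_RWplus: float
    f3_GOAP: float
    f4_helix_match: float
    f5_sheet_match: float
    f6_coil_match: float
    f7_ss_consistency: float
    f8_asa_corr: float
    f9_asa_cos: float

    def as_array(self) -> np.ndarray:
        return np.array([
            self.f1_dDFIRE, self.f2_RWplus, self.f3_GOAP,
            self.f4_helix_match, self.f5_sheet_match, self.f6_coil_match,
            self.f7_ss_consistency, self.f8_asa_corr, self.f9_asa_cos,
        ])


@dataclass
class TargetPool:
    """One target's decoy set: ids, feature matrix, optional TM labels."""

    target_id: str
    model_ids: list[str]
    features: np.ndarray                      # (n, 9) raw values
    labels: np.ndarray | None = None          # raw TM-scores
    normalized: np.ndarray | None = None      # (n, 9) in [0, 1]
    labels_normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] != len(FEATURE_NAMES):
            raise ValueError("feature matrix must be (n_models, 9)")
        if len(self.model_ids) != len(self.features):
            raise ValueError("model_ids and feature rows disagree")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=float)
            if len(self.labels) != len(self.model_ids):
                raise ValueError("labels and model_ids disagree")

    @property
    def n_models(self) -> int:
        return len(self.model_ids)

    @property
    def is_labeled(self) -> bool:
        return self.labels is not None


def ss_match_fractions(observed: SecondaryStructureString,
                       predicted: SecondaryStructureString
                       ) -> tuple[float, float, float]:
    """Fractions of positions where model and prediction agree per state.

    Returns (helix, sheet, coil) fractions, each the count of positions
    where both strings carry that state divided by the chain length.
    """
    if len(observed) != len(predicted):
        raise AlignmentError(
            f"SS strings differ in length ({len(observed)} vs {len(predicted)})")
    n = len(observed)
    if n < 1:
        raise AlignmentError("empty secondary-structure strings")
    counts = {"H": 0, "E": 0, "C": 0}
    for o, p in zip(observed.states, predicted.states):
        if o == p:
            counts[o] += 1
    return counts["H"] / n, counts["E"] / n, counts["C"] / n


def ss_consistency_score(observed: SecondaryStructureString,
                         predicted: SecondaryStructureString,
                         conf: ConfidenceTrack,
                         normalize_by: str = "length") -> float:
    """Confidence-weighted secondary-structure agreement in [0, 1].

    score = (1/N) * sum_i delta(s_i^obs, s_i^pred) * c_i, with N the
    chain length by default.  ``normalize_by='confidence'`` divides by
    sum(c_i) instead, which rescales the score to pure agreement among
    confidently predicted positions.
    """
    if not (len(observed) == len(predicted) == len(conf)):
        raise AlignmentError("SS strings and confidence track must align")
    match = np.fromiter(
        (o == p for o, p in zip(observed.states, predicted.states)),
        dtype=float, count=len(observed))
    weighted = float((match * conf.values).sum())
    if normalize_by == "confidence":
        total = float(conf.values.sum())
        return weighted / total if total > 0 else 0.0
    return weighted / len(observed)


def asa_consistency(a_model: AccessibilityTrack,
                    a_pred: AccessibilityTrack) -> tuple[float, float]:
    """(Pearson r, cosine) between model and predicted ASA vectors."""
    if len(a_model) != len(a_pred):
        raise AlignmentError("ASA tracks differ in length")
    x, y = a_model.values, a_pred.values
    if len(x) < 2:
        raise AlignmentError("ASA comparison needs at least 2 residues")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance ASA vector; correlation set to 0",
                      stacklevel=2)
        r = 0.0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        warnings.warn("zero-norm ASA vector; cosine set to 0", stacklevel=2)
        cos = 0.0
    else:
        cos = float(np.dot(x, y) / (nx * ny))
    return r, cos


def build_feature_vector(model: ProteinModel,
                         observed_ss: SecondaryStructureString,
                         predicted_ss: SecondaryStructureString,
                         conf: ConfidenceTrack,
                         asa_model: AccessibilityTrack,
                         asa_pred: AccessibilityTrack,
                         energies: tuple[EnergyTable, EnergyTable, EnergyTable],
                         consistency_norm: str = "length") -> FeatureVector:
    """Assemble one model's raw feature vector in F1..F9 order."""
    if len(observed_ss) != model.length:
        raise AlignmentError("observed SS does not match model length")
    e1, e2, e3 = (table.energy_of(model.model_id) for table in energies)
    f4, f5, f6 = ss_match_fractions(observed_ss, predicted_ss)
    f7 = ss_consistency_score(observed_ss, predicted_ss, conf,
                              normalize_by=consistency_norm)
    f8, f9 = asa_consistency(asa_model, asa_pred)
    return FeatureVector(e1, e2, e3, f4, f5, f6, f7, f8, f9)


def minmax_normalize(column: np.ndarray) -> np.ndarray:
    """Min-max map to [0, 1]; constant columns become all-zero with a warning."""
    column = np.asarray(column, dtype=float)
    lo, hi = column.min(), column.max()
    if hi == lo:
        warnings.warn("constant column in pool normalisation; set to 0",
                      stacklevel=2)
        return np.zeros_like(column)
    return (column - lo) / (hi - lo)


def normalize_pool(pool: TargetPool) -> TargetPool:
    """Min-max normalise every feature column (and the label) within the pool."""
    if pool.n_models < 1:
        raise ValueError(f"pool {pool.target_id}: empty pool")
    if pool.n_models == 1:
        warnings.warn(
            f"pool {pool.target_id}: single model, all columns constant",
            stacklevel=2)
        labels_norm = np.zeros(1) if pool.is_labeled else None
        return replace(pool, normalized=np.zeros_like(pool.features),
                       labels_normalized=labels_norm)
    normalized = np.column_stack([
        minmax_normalize(pool.features[:, j])
        for j in range(pool.features.shape[1])
    ])
    labels_norm = minmax_normalize(pool.labels) if pool.is_labeled else None
    return replace(pool, normalized=normalized, labels_normalized=labels_norm)


def pool_to_dataframe(pool: TargetPool) -> pd.DataFrame:
    """Serialise a pool to a flat table (one row per model)."""
    df = pd.DataFrame(pool.features, columns=list(FEATURE_NAMES))
    df.insert(0, "model_id", pool.model_ids)
    df.insert(0, "target_id", pool.target_id)
    if pool.is_labeled:
        df["label"] = pool.labels
    return df


def pool_from_dataframe(df: pd.DataFrame, target_id: str | None = None
                        ) -> TargetPool:
    """Rebuild a pool from a table produced by :func:`pool_to_dataframe`."""
    if target_id is not None:
        df = df[df["target_id"] == target_id]
    else:
        targets = df["target_id"].unique()
        if len(targets) != 1:
            raise ValueError("table holds multiple targets; pass target_id")
        target_id = targets[0]
    labels = df["label"].to_numpy() if "label" in df.columns else None
    if labels is not None and np.isnan(labels).all():
        labels = None
    return TargetPool(
        target_id=str(target_id),
        model_ids=[str(m) for m in df["model_id"]],
        features=df[list(FEATURE_NAMES)].to_numpy(),
        labels=labels,
    )


def pools_from_dataframe(df: pd.DataFrame) -> list[TargetPool]:
    """Split a multi-target feature table into per-target pools."""
    return [pool_from_dataframe(g, target_id=t)
            for t, g in df.groupby("target_id", sort=True)]


def pools_to_dataframe(pools: list[TargetPool]) -> pd.DataFrame:
    return pd.concat([pool_to_dataframe(p) for p in pools], ignore_index=True)
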