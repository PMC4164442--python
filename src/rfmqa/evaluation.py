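"""Assessment metrics for comparing quality-assessment methods.

All metrics operate on labelled decoy pools (true TM-scores known) and
the per-pool selections or score vectors a method produced:

* ``CC_TM`` — Pearson correlation, over targets, between the TM-score of
  the selected model and the best model in the pool;
* Spearman rank correlation of the same two vectors, using the classic
  1 - 6*sum(d^2)/(n(n^2-1)) formula (mean ranks and Pearson-on-ranks
  when ties occur);
* ``TM_loss`` — TM_best minus TM_selected, averaged over targets;
* selection Z-score — (TM_selected - pool mean)/pool sd; a random pick
  has expectation zero, so Z directly measures added value;
* ``CC_rank`` — per-pool Spearman between predicted and true rankings,
  averaged over pools;
* pairwise gain/loss/equal counts between two methods' selections;
* the Z-score histogram over bins Z<0, [0,1), [1,2), [2,3), Z>=3.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import ParameterError
from .features import TargetPool

__all__ = [
    "pearson", "spearman", "tm_loss", "z_score", "pairwise_compare",
    "cc_rank", "z_bin_distribution", "EvaluationReport", "evaluate_selections",
    "Z_BIN_LABELS",
]

Z_BIN_LABELS = ("Z<0", "0<=Z<1", "1<=Z<2", "2<=Z<3", "Z>=3")


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN with a warning on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ParameterError("pearson needs two equal-length vectors, n >= 2")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance input; correlation undefined",
                      stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Rank correlation.

    Without ties this is exactly 1 - 6*sum(d^2) / (n*(n^2-1)) with d the
    rank differences; with ties, mean ranks are assigned and the
    Pearson-on-ranks equivalent is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ParameterError("spearman needs two equal-length vectors, n >= 2")
    rx, ry = rankdata(x), rankdata(y)
    has_ties = len(np.unique(rx)) < len(rx) or len(np.unique(ry)) < len(ry)
    if has_ties:
        if rx.std() == 0 or ry.std() == 0:
            warnings.warn("all-tied vector; rank correlation undefined",
                          stacklevel=2)
            return float("nan")
        return float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    d2 = float(((rx - ry) ** 2).sum())
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def _selected_label(pool: TargetPool, selected_model: str) -> float:
    try:
        i = pool.model_ids.index(selected_model)
    except ValueError:
        raise ParameterError(
            f"model {selected_model!r} not in pool {pool.target_id}") from None
    if not pool.is_labeled:
        raise ParameterError(f"pool {pool.target_id} has no labels")
    return float(pool.labels[i])


def tm_loss(pool: TargetPool, selected_model: str) -> float:
    """TM_best - TM_selected for one pool; zero iff a best model was picked."""
    return float(pool.labels.max()) - _selected_label(pool, selected_model)


def z_score(pool: TargetPool, selected_model: str, ddof: int = 1) -> float:
    """Selection Z-score: (TM_selected - pool mean) / pool sd.

    ``ddof=1`` (sample sd) by default; pass ``ddof=0`` for the population
    variant.
    """
    value = _selected_label(pool, selected_model)
    sd = float(pool.labels.std(ddof=ddof))
    if sd == 0:
        warnings.warn(f"pool {pool.target_id}: zero label sd; Z undefined",
                      stacklevel=2)
        return float("nan")
    return (value - float(pool.labels.mean())) / sd


def pairwise_compare(selections_a: dict[str, str],
                     selections_b: dict[str, str],
                     pools: list[TargetPool]) -> tuple[int, int, int]:
    """(gain, loss, equal) counts of method A vs method B over pools.

    Gain counts pools where A's selected model has strictly higher true
    TM than B's; pools missing a selection from either method are
    skipped with a warning.
    """
    gain = loss = equal = 0
    for pool in pools:
        if pool.target_id not in selections_a or \
                pool.target_id not in selections_b:
            warnings.warn(f"pool {pool.target_id}: missing selection; skipped",
                          stacklevel=2)
            continue
        tm_a = _selected_label(pool, selections_a[pool.target_id])
        tm_b = _selected_label(pool, selections_b[pool.target_id])
        if tm_a > tm_b:
            gain += 1
        elif tm_a < tm_b:
            loss += 1
        else:
            equal += 1
    return gain, loss, equal


def cc_rank(pools: list[TargetPool],
            predicted_scores: dict[str, np.ndarray]) -> float:
    """Mean per-pool rank correlation of predicted scores vs true labels."""
    rhos = []
    for pool in pools:
        scores = np.asarray(predicted_scores[pool.target_id], dtype=float)
        if pool.n_models < 2:
            warnings.warn(f"pool {pool.target_id}: single model; excluded "
                          "from CC_rank", stacklevel=2)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = spearman(scores, pool.labels)
        if np.isfinite(rho):
            rhos.append(rho)
    if not rhos:
        raise ParameterError("no pool eligible for CC_rank")
    return float(np.mean(rhos))


def z_bin_distribution(z_scores: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of selection Z-scores over the standard five bins.

    Returns (counts, fractions) for Z<0, [0,1), [1,2), [2,3), Z>=3.
    """
    z = np.asarray(z_scores, dtype=float)
    z = z[np.isfinite(z)]
    edges = [-np.inf, 0.0, 1.0, 2.0, 3.0, np.inf]
    counts = np.histogram(z, bins=edges)[0]
    fractions = counts / counts.sum() if counts.sum() else counts.astype(float)
    return counts, fractions


@dataclass
class EvaluationReport:
    """Aggregate metrics of one method over a set of labelled pools."""

    method: str
    n_targets: int
    cc_tm: float
    spearman: float
    mean_tm_loss: float
    tm_sum: float
    z_sum: float
    z_scores: dict[str, float] = field(default_factory=dict)
    z_bins: tuple[int, ...] = (0, 0, 0, 0, 0)
    cc_rank: float | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_targets": self.n_targets,
            "cc_tm": self.cc_tm,
            "spearman": self.spearman,
            "mean_tm_loss": self.mean_tm_loss,
            "tm_sum": self.tm_sum,
            "z_sum": self.z_sum,
            "cc_rank": self.cc_rank,
            "z_bins": dict(zip(Z_BIN_LABELS, self.z_bins)),
            "z_scores": self.z_scores,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def evaluate_selections(pools: list[TargetPool],
                        selections: dict[str, str],
                        predicted_scores: dict[str, np.ndarray] | None = None,
                        method: str = "method",
                        ddof: int = 1) -> EvaluationReport:
    """Build a full report from one method's per-pool selections.

    ``predicted_scores`` (per-pool score vectors aligned with the pool's
    ``model_ids``) enables the CC_rank column; selections alone suffice
    for the other metrics.
    """
    tm_sel, tm_best, losses, zs = [], [], [], {}
    for pool in pools:
        sel = selections[pool.target_id]
        tm_sel.append(_selected_label(pool, sel))
        tm_best.append(float(pool.labels.max()))
        losses.append(tm_loss(pool, sel))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            zs[pool.target_id] = z_score(pool, sel, ddof=ddof)
    z_values = np.array(list(zs.values()))
    counts, _ = z_bin_distribution(z_values)
    finite_z = z_values[np.isfinite(z_values)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cc = pearson(tm_sel, tm_best) if len(tm_sel) >= 2 else float("nan")
        rho = spearman(tm_sel, tm_best) if len(tm_sel) >= 2 else float("nan")
    report = EvaluationReport(
        method=method,
        n_targets=len(pools),
        cc_tm=cc,
        spearman=rho,
        mean_tm_loss=float(np.mean(losses)),
        tm_sum=float(np.sum(tm_sel)),
        z_sum=float(np.sum(finite_z)),
        z_scores=zs,
        z_bins=tuple(int(c) for c in counts),
    )
    if predicted_scores is not None:
        report.cc_rank = cc_rank(pools, predicted_scores)
    return report
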