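"""End-to-end training protocol and pool ranking.

The protocol mirrors standard practice for training a relative-quality
regressor on decoy pools:

1. *Screening* (training only): targets whose pool-mean TM-score is
   below 0.3 are discarded, and within each surviving pool only the top
   half of models by TM-score is kept, so the regressor never learns
   from hopeless decoys.  Screening is never applied at test time.
2. *Normalisation*: every feature column and the TM label are min-max
   mapped to [0, 1] within each pool, making the learned output a
   relative score.
3. *Cross-validation*: targets (never individual models) are randomly
   partitioned into folds; for each fold the (n_tree, m_try) grid is
   searched on the training folds — the combination with the lowest
   out-of-bag mean squared error wins, smaller n_tree breaking ties —
   and metrics are computed on the held-out pools.
4. *Final fit*: one forest on all training rows, defaults n_tree = 3000
   and m_try = 1.
5. *Ranking*: an unscreened, normalised pool is scored by the forest and
   sorted by predicted relative TM, ties broken by model id.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .evaluation import EvaluationReport, evaluate_selections
from .features import FEATURE_NAMES, TargetPool, normalize_pool
from .random_forest import Forest, fit_forest

__all__ = [
    "TrainingConfig",
    "screen_pool",
    "cross_validate",
    "CrossValidationResult",
    "fit_final",
    "rank_pool",
    "feature_hash",
]

DEFAULT_N_TREE = 3000
DEFAULT_M_TRY = 1


@dataclass
class TrainingConfig:
    """Knobs of the training protocol with the standard defaults."""

    screen_top_fraction: float = 0.5
    min_mean_tm: float = 0.3
    cv_folds: int = 5
    n_tree_grid: tuple[int, ...] = tuple(range(500, 10001, 500))
    m_try_grid: tuple[int, ...] = tuple(range(1, 8))
    node_cutoff: int = 5
    seed: int = 0
    label_mode: str = "normalized"       # normalized | raw
    consistency_norm: str = "length"     # length | confidence

    def __post_init__(self) -> None:
        if not 0 < self.screen_top_fraction <= 1:
            raise ParameterError("screen_top_fraction must be in (0, 1]")
        if self.cv_folds < 2:
            raise ParameterError("cv_folds must be >= 2")
        if not self.n_tree_grid or not self.m_try_grid:
            raise ParameterError("hyperparameter grids must be nonempty")
        if self.label_mode not in ("normalized", "raw"):
            raise ParameterError("label_mode must be 'normalized' or 'raw'")

    def grid(self) -> list[tuple[int, int]]:
        """All (n_tree, m_try) combinations, in deterministic order."""
        return [(nt, mt) for nt in self.n_tree_grid for mt in self.m_try_grid]


def feature_hash(config: TrainingConfig) -> str:
    """Hash of the feature order and normalisation variant.

    Embedded in serialized models so that ranking with a model trained
    under a different feature layout fails loudly instead of silently.
    """
    text = "|".join(FEATURE_NAMES) + f"|{config.label_mode}" \
        f"|{config.consistency_norm}"
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def screen_pool(pool: TargetPool, config: TrainingConfig | None = None
                ) -> TargetPool | None:
    """Training-time screening of one labelled pool.

    Returns None when the pool-mean TM (before any screening) falls
    below the exclusion threshold; otherwise keeps the
    ceil(fraction * n) highest-labelled models.
    """
    if config is None:
        config = TrainingConfig()
    if not pool.is_labeled:
        raise ParameterError(f"pool {pool.target_id} has no TM labels")
    if float(pool.labels.mean()) < config.min_mean_tm:
        return None
    n_keep = math.ceil(config.screen_top_fraction * pool.n_models)
    # stable order: label descending, then model id, so ties are deterministic
    order = sorted(range(pool.n_models),
                   key=lambda i: (-pool.labels[i], pool.model_ids[i]))
    keep = sorted(order[:n_keep])
    return TargetPool(
        target_id=pool.target_id,
        model_ids=[pool.model_ids[i] for i in keep],
        features=pool.features[keep],
        labels=pool.labels[keep],
    )


def _training_matrix(pools: list[TargetPool], config: TrainingConfig
                     ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Screen, normalise and stack pools into (X, y, per-row target ids)."""
    xs, ys, prov = [], [], []
    for pool in pools:
        screened = screen_pool(pool, config)
        if screened is None or screened.n_models < 2:
            continue
        norm = normalize_pool(screened)
        xs.append(norm.normalized)
        ys.append(norm.labels_normalized if config.label_mode == "normalized"
                  else norm.labels)
        prov.extend([pool.target_id] * screened.n_models)
    if not xs:
        raise ParameterError("no pool survived screening; nothing to train on")
    return np.vstack(xs), np.concatenate(ys), prov


def fit_final(pools: list[TargetPool], n_tree: int = DEFAULT_N_TREE,
              m_try: int = DEFAULT_M_TRY,
              config: TrainingConfig | None = None) -> Forest:
    """Train the final forest on all (screened, normalised) pools."""
    if config is None:
        config = TrainingConfig()
    x, y, _ = _training_matrix(pools, config)
    return fit_forest(x, y, n_tree=n_tree, m_try=m_try,
                      node_cutoff=config.node_cutoff, seed=config.seed,
                      feature_names=FEATURE_NAMES,
                      feature_hash=feature_hash(config))


def rank_pool(forest: Forest, pool: TargetPool
              ) -> list[tuple[str, float]]:
    """Rank an (unscreened) pool by predicted relative TM-score.

    The pool must be normalised first; ties in the predicted score are
    broken by model id so the ranking is deterministic.  The first entry
    is the selected model.
    """
    if pool.normalized is None:
        raise ParameterError(
            f"pool {pool.target_id} is not normalised; call normalize_pool "
            "before ranking")
    x = pool.normalized
    if x.min() < -1e-9 or x.max() > 1 + 1e-9:
        raise ParameterError("normalised features must lie in [0, 1]")
    scores = np.atleast_1d(forest.predict(x))
    order = sorted(range(pool.n_models),
                   key=lambda i: (-scores[i], pool.model_ids[i]))
    return [(pool.model_ids[i], float(scores[i])) for i in order]


@dataclass
class CrossValidationResult:
    """Outcome of target-level k-fold cross-validation."""

    fold_targets: list[list[str]]
    fold_hyperparams: list[tuple[int, int]]
    fold_reports: list[EvaluationReport]
    aggregate: EvaluationReport
    best_hyperparams: tuple[int, int]
    n_grid_evaluated: int = 0


def _grid_search(x: np.ndarray, y: np.ndarray, config: TrainingConfig
                 ) -> tuple[tuple[int, int], int]:
    """Pick (n_tree, m_try) minimising OOB error; ties to smaller n_tree."""
    best: tuple[int, int] | None = None
    best_err = np.inf
    n_eval = 0
    for n_tree, m_try in config.grid():
        forest = fit_forest(x, y, n_tree=n_tree, m_try=m_try,
                            node_cutoff=config.node_cutoff, seed=config.seed)
        n_eval += 1
        if forest.oob_error < best_err - 1e-12:
            best_err = forest.oob_error
            best = (n_tree, m_try)
    assert best is not None
    return best, n_eval


def cross_validate(pools: list[TargetPool], config: TrainingConfig | None = None
                   ) -> CrossValidationResult:
    """Target-level k-fold cross-validation with per-fold grid search.

    Folds partition *targets*, never models, so no decoy of a held-out
    target can influence training.  Held-out pools are ranked without
    screening, exactly as at deployment.
    """
    if config is None:
        config = TrainingConfig()
    labelled = [p for p in pools if p.is_labeled]
    if len(labelled) < config.cv_folds:
        raise ParameterError(
            f"need at least {config.cv_folds} labelled pools, "
            f"got {len(labelled)}")

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(labelled))
    folds: list[list[int]] = [list(order[k::config.cv_folds])
                              for k in range(config.cv_folds)]

    fold_targets, fold_hyper, fold_reports = [], [], []
    all_selections: dict[str, str] = {}
    all_scores: dict[str, np.ndarray] = {}
    test_pools: list[TargetPool] = []
    n_grid_total = 0
    for fold in folds:
        held = [labelled[i] for i in fold]
        train = [labelled[i] for i in range(len(labelled)) if i not in fold]
        fold_targets.append([p.target_id for p in held])
        x, y, prov = _training_matrix(train, config)
        held_ids = {p.target_id for p in held}
        assert not held_ids & set(prov), "held-out target leaked into training"
        (n_tree, m_try), n_eval = _grid_search(x, y, config)
        n_grid_total += n_eval
        fold_hyper.append((n_tree, m_try))
        forest = fit_forest(x, y, n_tree=n_tree, m_try=m_try,
                            node_cutoff=config.node_cutoff, seed=config.seed,
                            feature_names=FEATURE_NAMES,
                            feature_hash=feature_hash(config))
        selections, scores = {}, {}
        for pool in held:
            ranked = rank_pool(forest, normalize_pool(pool))
            selections[pool.target_id] = ranked[0][0]
            by_id = dict(ranked)
            scores[pool.target_id] = np.array(
                [by_id[m] for m in pool.model_ids])
        fold_reports.append(evaluate_selections(
            held, selections, predicted_scores=scores,
            method=f"fold_{len(fold_reports)}"))
        all_selections.update(selections)
        all_scores.update(scores)
        test_pools.extend(held)

    aggregate = evaluate_selections(test_pools, all_selections,
                                    predicted_scores=all_scores,
                                    method="cross_validation")
    # the most frequently chosen combination, ties to the smaller one
    votes: dict[tuple[int, int], int] = {}
    for hp in fold_hyper:
        votes[hp] = votes.get(hp, 0) + 1
    best = min(votes, key=lambda hp: (-votes[hp], hp))
    return CrossValidationResult(
        fold_targets=fold_targets,
        fold_hyperparams=fold_hyper,
        fold_reports=fold_reports,
        aggregate=aggregate,
        best_hyperparams=best,
        n_grid_evaluated=n_grid_total,
    )
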