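"""Regression random forest with out-of-bag permutation importance.

Implemented from scratch so the training protocol is fully transparent
and reproducible:

* bagging — each tree sees a bootstrap sample of size n drawn uniformly
  with replacement; the left-out rows form the tree's out-of-bag (OOB)
  set;
* random feature selection — at every node, ``m_try`` features are drawn
  without replacement and the best split among them is taken;
* the split criterion is variance reduction (decrease in the sum of
  squared deviations of the response), the regression analogue of the
  impurity-decrease rule; ties go to the lowest feature index, then the
  lowest threshold, so training is deterministic;
* growth stops when a node holds fewer rows than ``node_cutoff``
  (default 5) or cannot be improved; trees are never pruned;
* the forest prediction is the ensemble average of the leaf means;
* feature importance is Breiman's raw permutation importance: the mean
  over trees of the increase in OOB mean squared error after permuting
  the feature among that tree's OOB rows.

Randomness is driven by one root seed; each tree derives its own stream
from a fixed per-tree key, so extending ``n_tree`` never reshuffles the
trees already grown.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError

__all__ = ["RegressionTree", "Forest", "fit_forest", "predict",
           "oob_importance"]

_TIE_EPS = 1e-12


@dataclass
class RegressionTree:
    """One unpruned CART regression tree in flattened-array form.

    ``feature[k] == -1`` marks node *k* as a leaf whose prediction is
    ``value[k]``; otherwise rows with ``x[feature[k]] <= threshold[k]``
    descend to ``left[k]``, the rest to ``right[k]``.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    count: np.ndarray
    bootstrap_indices: np.ndarray
    oob_indices: np.ndarray

    def predict(self, x_matrix: np.ndarray) -> np.ndarray:
        x_matrix = np.atleast_2d(x_matrix)
        idx = np.zeros(len(x_matrix), dtype=int)
        while True:
            feats = self.feature[idx]
            rows = np.nonzero(feats >= 0)[0]
            if len(rows) == 0:
                break
            at = idx[rows]
            go_left = x_matrix[rows, self.feature[at]] <= self.threshold[at]
            idx[rows] = np.where(go_left, self.left[at], self.right[at])
        return self.value[idx]

    @property
    def n_nodes(self) -> int:
        return len(self.feature)


def _best_split(x: np.ndarray, y: np.ndarray, candidates: np.ndarray
                ) -> tuple[int, float, float] | None:
    """Best (feature, threshold, gain) among candidate features.

    Gain is the decrease in sum of squared deviations of y.  Candidate
    thresholds are midpoints between consecutive sorted unique values.
    Returns None when no split improves on the parent node.
    """
    n = len(y)
    parent_sse = float(((y - y.mean()) ** 2).sum())
    best: tuple[int, float, float] | None = None
    for f in np.sort(candidates):
        vals = x[:, f]
        order = np.argsort(vals, kind="stable")
        sv, sy = vals[order], y[order]
        # positions where the value changes -> valid split boundaries
        change = np.nonzero(np.diff(sv) > 0)[0]
        if len(change) == 0:
            continue
        csum = np.cumsum(sy)
        csum2 = np.cumsum(sy * sy)
        total, total2 = csum[-1], csum2[-1]
        n_left = change + 1
        left_sse = csum2[change] - csum[change] ** 2 / n_left
        right_sum = total - csum[change]
        right_sse = (total2 - csum2[change]
                     - right_sum ** 2 / (n - n_left))
        gains = parent_sse - (left_sse + right_sse)
        thresholds = (sv[change] + sv[change + 1]) / 2.0
        # a midpoint between two values closer than 1 ulp can round up to
        # the larger value, which would leave the right child empty
        valid = thresholds < sv[change + 1]
        if not valid.any():
            continue
        gains, thresholds = gains[valid], thresholds[valid]
        top = gains.max()
        # lowest threshold among (near-)equal best gains within the feature
        k = int(np.nonzero(gains >= top - _TIE_EPS)[0][0])
        if best is None or gains[k] > best[2] + _TIE_EPS:
            best = (int(f), float(thresholds[k]), float(gains[k]))
    if best is None or best[2] <= _TIE_EPS:
        return None
    return best


def _grow_tree(x: np.ndarray, y: np.ndarray, m_try: int, node_cutoff: int,
               rng: np.random.Generator) -> dict[str, list]:
    n_features = x.shape[1]
    nodes = {"feature": [], "threshold": [], "left": [], "right": [],
             "value": [], "count": []}

    def new_node() -> int:
        for key in nodes:
            nodes[key].append(0)
        return len(nodes["feature"]) - 1

    def build(rows: np.ndarray) -> int:
        k = new_node()
        y_node = y[rows]
        nodes["value"][k] = float(y_node.mean())
        nodes["count"][k] = len(rows)
        nodes["feature"][k] = -1
        nodes["threshold"][k] = 0.0
        nodes["left"][k] = nodes["right"][k] = -1
        if len(rows) < node_cutoff or np.ptp(y_node) == 0:
            return k
        candidates = rng.choice(n_features, size=m_try, replace=False)
        split = _best_split(x[rows], y_node, candidates)
        if split is None:
            return k
        f, thr, _ = split
        go_left = x[rows, f] <= thr
        if go_left.all() or not go_left.any():
            return k
        nodes["feature"][k] = f
        nodes["threshold"][k] = thr
        nodes["left"][k] = build(rows[go_left])
        nodes["right"][k] = build(rows[~go_left])
        return k

    build(np.arange(len(y)))
    return nodes


def _tree_rng(seed: int, tree_index: int, stream: int = 0
              ) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(tree_index, stream)))


@dataclass
class Forest:
    """Trained ensemble of regression trees."""

    trees: list[RegressionTree]
    n_tree: int
    m_try: int
    node_cutoff: int
    seed: int
    n_features: int
    oob_error: float = float("nan")
    importance: np.ndarray | None = None
    feature_names: tuple[str, ...] | None = None
    feature_hash: str = ""

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Ensemble-average prediction for one row or a matrix of rows."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        x_matrix = np.atleast_2d(x)
        if x_matrix.shape[1] != self.n_features:
            raise ParameterError(
                f"expected {self.n_features} features, got {x_matrix.shape[1]}")
        acc = np.zeros(len(x_matrix))
        for tree in self.trees:
            acc += tree.predict(x_matrix)
        acc /= len(self.trees)
        return float(acc[0]) if single else acc

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "format": "rfmqa-forest-v1",
            "n_tree": self.n_tree,
            "m_try": self.m_try,
            "node_cutoff": self.node_cutoff,
            "seed": self.seed,
            "n_features": self.n_features,
            "oob_error": self.oob_error,
            "importance": None if self.importance is None
            else list(self.importance),
            "feature_names": self.feature_names,
            "feature_hash": self.feature_hash,
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "value": t.value.tolist(),
                    "count": t.count.tolist(),
                    "bootstrap": t.bootstrap_indices.tolist(),
                    "oob": t.oob_indices.tolist(),
                } for t in self.trees
            ],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Forest":
        text = Path(source).read_text() if isinstance(source, Path) or \
            (isinstance(source, str) and not source.lstrip().startswith("{")) \
            else source
        payload = json.loads(text)
        if payload.get("format") != "rfmqa-forest-v1":
            raise ParameterError("not a serialized forest (bad format tag)")
        trees = [
            RegressionTree(
                feature=np.array(t["feature"], dtype=int),
                threshold=np.array(t["threshold"], dtype=float),
                left=np.array(t["left"], dtype=int),
                right=np.array(t["right"], dtype=int),
                value=np.array(t["value"], dtype=float),
                count=np.array(t["count"], dtype=int),
                bootstrap_indices=np.array(t["bootstrap"], dtype=int),
                oob_indices=np.array(t["oob"], dtype=int),
            ) for t in payload["trees"]
        ]
        importance = payload.get("importance")
        return cls(
            trees=trees,
            n_tree=payload["n_tree"],
            m_try=payload["m_try"],
            node_cutoff=payload["node_cutoff"],
            seed=payload["seed"],
            n_features=payload["n_features"],
            oob_error=payload.get("oob_error", float("nan")),
            importance=None if importance is None else np.array(importance),
            feature_names=None if payload.get("feature_names") is None
            else tuple(payload["feature_names"]),
            feature_hash=payload.get("feature_hash", ""),
        )


def fit_forest(x: np.ndarray, y: np.ndarray, n_tree: int, m_try: int,
               node_cutoff: int = 5, seed: int = 0,
               feature_names: tuple[str, ...] | None = None,
               feature_hash: str = "") -> Forest:
    """Train a regression forest on (x, y); reproducible for a fixed seed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or len(x) != len(y):
        raise ParameterError("x must be (n, p) with matching y")
    n, p = x.shape
    if n < 1:
        raise ParameterError("empty training set")
    if not np.isfinite(y).all() or not np.isfinite(x).all():
        raise ParameterError("training data must be finite")
    if n_tree < 1:
        raise ParameterError(f"n_tree must be >= 1, got {n_tree}")
    if not 1 <= m_try <= p:
        raise ParameterError(f"m_try must be in [1, {p}], got {m_try}")

    trees: list[RegressionTree] = []
    oob_sum = np.zeros(n)
    oob_count = np.zeros(n, dtype=int)
    for t in range(n_tree):
        rng = _tree_rng(seed, t)
        bootstrap = np.sort(rng.integers(0, n, size=n))
        oob = np.setdiff1d(np.arange(n), bootstrap)
        nodes = _grow_tree(x[bootstrap], y[bootstrap], m_try, node_cutoff, rng)
        tree = RegressionTree(
            feature=np.array(nodes["feature"], dtype=int),
            threshold=np.array(nodes["threshold"], dtype=float),
            left=np.array(nodes["left"], dtype=int),
            right=np.array(nodes["right"], dtype=int),
            value=np.array(nodes["value"], dtype=float),
            count=np.array(nodes["count"], dtype=int),
            bootstrap_indices=bootstrap,
            oob_indices=oob,
        )
        trees.append(tree)
        if len(oob):
            oob_sum[oob] += tree.predict(x[oob])
            oob_count[oob] += 1

    covered = oob_count > 0
    oob_error = float(np.mean(
        (oob_sum[covered] / oob_count[covered] - y[covered]) ** 2)) \
        if covered.any() else float("nan")
    return Forest(trees=trees, n_tree=n_tree, m_try=m_try,
                  node_cutoff=node_cutoff, seed=seed, n_features=p,
                  oob_error=oob_error, feature_names=feature_names,
                  feature_hash=feature_hash)


def predict(forest: Forest, x: np.ndarray) -> float | np.ndarray:
    """Module-level alias of :meth:`Forest.predict`."""
    return forest.predict(x)


def oob_importance(forest: Forest, x: np.ndarray, y: np.ndarray
                   ) -> np.ndarray:
    """Raw permutation importance per feature.

    For each tree: the OOB mean squared error is computed, each feature
    column is permuted among the OOB rows (with a stream derived from
    the forest seed, so the result is deterministic) and the error
    re-estimated; the importance of a feature is the mean error increase
    over trees.  Trees with an empty OOB set are skipped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p = forest.n_features
    totals = np.zeros(p)
    used = 0
    skipped = 0
    for t, tree in enumerate(forest.trees):
        oob = tree.oob_indices
        if len(oob) == 0:
            skipped += 1
            continue
        x_oob = x[oob]
        y_oob = y[oob]
        base_err = np.mean((tree.predict(x_oob) - y_oob) ** 2)
        rng = _tree_rng(forest.seed, t, stream=1)
        for j in range(p):
            perm = rng.permutation(len(oob))
            x_perm = x_oob.copy()
            x_perm[:, j] = x_oob[perm, j]
            perm_err = np.mean((tree.predict(x_perm) - y_oob) ** 2)
            totals[j] += perm_err - base_err
        used += 1
    if used == 0:
        raise ParameterError("no tree has an out-of-bag set")
    if skipped > 0.1 * len(forest.trees):
        warnings.warn(f"{skipped}/{len(forest.trees)} trees had empty OOB "
                      "sets and were skipped", stacklevel=2)
    importance = totals / used
    forest.importance = importance
    return importance
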