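"""Learning-to-rank core: NDCG, lambdarank gradients, boosted regression trees.

The ranker is a LambdaMART-style gradient-boosted tree ensemble trained on
per-protein groups of pocket descriptors with binary relevance (exactly one
allosteric pocket per group in curated data).  Boosting minimizes the
lambdarank surrogate: logistic pairwise gradients weighted by the |delta
NDCG@K| obtained from swapping the pair in the current predicted order.

Design notes
------------
* Gains are binary, so ``2**G - 1`` is 0 or 1 and IDCG@K of any group with a
  positive is 1 (the single positive ideally sits at rank 1).
* All-zero-relevance groups are degenerate: NDCG is defined as 1.0 and their
  gradients vanish, so prediction-time utilities never crash on them.
* Trees grow best-first to ``max_leaves`` using the Newton gain
  ``0.5 * (GL^2/(HL+r) + GR^2/(HR+r) - G^2/(H+r))`` with ridge ``r``; leaf
  values are the Newton step ``-G/(H+r)``.
* Training is single-threaded and deterministic given the seed; models
  serialize to JSON and round-trip scores bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .structures import FEATURE_NAMES

__all__ = [
    "RankingDataset",
    "LambdaRankParams",
    "RegressionTree",
    "BoostedRanker",
    "dcg_at_k",
    "ndcg_at_k",
    "lambda_gradients",
    "fit_tree",
    "train",
    "rank_pockets",
    "feature_importance",
]

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Dataset container


@dataclass
class RankingDataset:
    """Grouped ranking data: rows are pockets, groups are proteins."""

    features: np.ndarray  # (n_rows, n_features) float64
    relevance: np.ndarray  # (n_rows,) in {0, 1}
    group_sizes: np.ndarray  # (n_groups,) ints summing to n_rows
    group_ids: tuple[str, ...]
    feature_names: tuple[str, ...] = FEATURE_NAMES
    pocket_indices: np.ndarray | None = None  # 1-based FPocket indices per row

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.relevance = np.asarray(self.relevance)
        self.group_sizes = np.asarray(self.group_sizes, dtype=int)
        if self.group_sizes.sum() != len(self.features):
            raise ValueError("group sizes must partition the rows")
        if len(self.group_ids) != len(self.group_sizes):
            raise ValueError("one id per group required")
        if not np.isin(self.relevance, (0, 1)).all():
            raise ValueError("relevance must be binary")
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError("feature count does not match feature_names")

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    def groups(self) -> Iterator[tuple[str, slice]]:
        start = 0
        for gid, size in zip(self.group_ids, self.group_sizes):
            yield gid, slice(start, start + size)
            start += size

    def validate_training(self) -> None:
        """Training data needs exactly one positive pocket per protein."""
        for gid, sl in self.groups():
            if self.relevance[sl].sum() != 1:
                raise ValueError(f"group {gid}: expected exactly one positive pocket")

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "RankingDataset":
        """Build from the curation feature table (rows grouped by protein_id)."""
        if "label" not in df.columns:
            raise ValueError("feature table has no 'label' column")
        sizes, ids, order = [], [], []
        for gid, idx in df.groupby("protein_id", sort=False).indices.items():
            ids.append(str(gid))
            sizes.append(len(idx))
            order.extend(idx)
        df = df.iloc[order]
        return cls(
            features=df[list(FEATURE_NAMES)].to_numpy(dtype=np.float64),
            relevance=df["label"].to_numpy(dtype=int),
            group_sizes=np.array(sizes),
            group_ids=tuple(ids),
            pocket_indices=df["pocket_index"].to_numpy(dtype=int)
            if "pocket_index" in df.columns
            else None,
        )


@dataclass(frozen=True)
class LambdaRankParams:
    """Hyperparameters of the boosted ranker.

    ``k=None`` means NDCG is evaluated at full group depth.  ``sigma`` is the
    logistic steepness of the pairwise surrogate.  ``ridge`` regularizes the
    Newton denominators.  All settings are recorded in the serialized model.
    """

    k: int | None = None
    sigma: float = 1.0
    learning_rate: float = 0.1
    n_trees: int = 500
    max_leaves: int = 31
    min_samples_leaf: int = 5
    feature_subsample: float = 1.0
    ridge: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")
        if min(self.sigma, self.learning_rate, self.feature_subsample, self.ridge) <= 0:
            raise ValueError("sigma, learning_rate, feature_subsample, ridge must be positive")
        if self.n_trees < 0 or self.max_leaves < 2 or self.min_samples_leaf < 1:
            raise ValueError("invalid tree parameters")


# ---------------------------------------------------------------------------
# NDCG family


def _check_binary(relevances: np.ndarray) -> np.ndarray:
    rel = np.asarray(relevances)
    if rel.size and not np.isin(rel, (0, 1)).all():
        raise ValueError("relevance gains must be binary {0, 1}")
    return rel.astype(float)


def dcg_at_k(relevances: Sequence[int], k: int) -> float:
    """Discounted cumulative gain of relevances in predicted order.

    ``sum_{i=1..min(k,n)} (2**G_i - 1) / log2(i + 1)`` with 1-based positions.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rel = _check_binary(relevances)[:k]
    if rel.size == 0:
        return 0.0
    positions = np.arange(1, rel.size + 1)
    return float(((2.0**rel - 1.0) / np.log2(positions + 1)).sum())


def ndcg_at_k(relevances: Sequence[int], k: int) -> float:
    """Normalized DCG in [0, 1]; all-zero groups return 1.0 by convention."""
    rel = _check_binary(relevances)
    ideal = np.sort(rel)[::-1]
    idcg = dcg_at_k(ideal, k)
    if idcg == 0.0:
        return 1.0
    return dcg_at_k(rel, k) / idcg


# ---------------------------------------------------------------------------
# Lambdarank gradients


def lambda_gradients(
    scores: Sequence[float],
    relevances: Sequence[int],
    k: int | None = None,
    sigma: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise lambdarank gradient and curvature for one group.

    For each pair (i, j) with ``G_i > G_j``::

        lambda_ij = -sigma * |dNDCG@K(i<->j)| / (1 + exp(sigma * (s_i - s_j)))

    accumulated as ``grad_i += lambda_ij`` and ``grad_j -= lambda_ij``; the
    curvature is the corresponding second derivative (non-negative).  The
    |dNDCG| term is the absolute NDCG change from swapping i and j in the
    current predicted order, descending scores with ties broken by row index.
    Gradients sum to zero within the group by antisymmetry.
    """
    s = np.asarray(scores, dtype=float)
    rel = _check_binary(relevances)
    if s.shape != rel.shape:
        raise ValueError("scores and relevances must have the same length")
    n = s.size
    grad = np.zeros(n)
    hess = np.zeros(n)
    pos = np.flatnonzero(rel == 1)
    neg = np.flatnonzero(rel == 0)
    if n < 2 or pos.size == 0 or neg.size == 0:
        return grad, hess

    depth = n if k is None else k
    idcg = dcg_at_k(np.sort(rel)[::-1], depth)
    _lambda_into(grad, hess, s, pos, neg, depth, sigma, idcg)
    return grad, hess


def _lambda_into(
    grad: np.ndarray,
    hess: np.ndarray,
    s: np.ndarray,
    pos: np.ndarray,
    neg: np.ndarray,
    depth: int,
    sigma: float,
    idcg: float,
) -> None:
    """Validated-inputs core of :func:`lambda_gradients` (also the hot path)."""
    n = s.size
    order = np.argsort(-s, kind="stable")  # ties -> lower row index first
    position = np.empty(n, dtype=np.intp)
    position[order] = np.arange(1, n + 1)
    discount = np.where(position <= depth, 1.0 / np.log2(position + 1.0), 0.0)

    # binary gains: |2^1 - 2^0| = 1, so dNDCG is just the discount difference
    delta = np.abs(discount[pos][:, None] - discount[neg][None, :]) / idcg
    sdiff = np.clip(sigma * (s[pos][:, None] - s[neg][None, :]), -500.0, 500.0)
    rho = 1.0 / (1.0 + np.exp(sdiff))
    lam = -sigma * delta * rho
    curv = sigma * sigma * delta * rho * (1.0 - rho)
    grad[pos] += lam.sum(axis=1)
    grad[neg] -= lam.sum(axis=0)
    hess[pos] += curv.sum(axis=1)
    hess[neg] += curv.sum(axis=0)


# ---------------------------------------------------------------------------
# Regression trees


@dataclass(eq=False)
class RegressionTree:
    """Binary tree stored as flat arrays; node 0 is the root.

    Internal nodes carry ``(feature, threshold)`` and route ``x[feature] <=
    threshold`` to ``left``; leaves have ``feature == -1`` and carry ``value``.
    """

    feature: np.ndarray  # int, -1 for leaf
    threshold: np.ndarray
    left: np.ndarray  # child node ids, -1 for leaf
    right: np.ndarray
    value: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        node = np.zeros(len(X), dtype=int)
        while True:
            feat = self.feature[node]
            active = feat >= 0
            if not active.any():
                break
            idx = np.flatnonzero(active)
            go_left = X[idx, feat[idx]] <= self.threshold[node[idx]]
            node[idx] = np.where(go_left, self.left[node[idx]], self.right[node[idx]])
        return self.value[node]

    @property
    def n_leaves(self) -> int:
        return int((self.feature < 0).sum())

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "value": self.value.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        return cls(
            feature=np.asarray(d["feature"], dtype=int),
            threshold=np.asarray(d["threshold"], dtype=np.float64),
            left=np.asarray(d["left"], dtype=int),
            right=np.asarray(d["right"], dtype=int),
            value=np.asarray(d["value"], dtype=np.float64),
        )


@dataclass(eq=False)
class _Leaf:
    rows: np.ndarray
    node_id: int
    gain: float = -np.inf
    split_feature: int = -1
    split_threshold: float = 0.0
    left_rows: np.ndarray | None = None
    right_rows: np.ndarray | None = None


def _best_split(
    leaf: _Leaf,
    X: np.ndarray,
    grad: np.ndarray,
    hess: np.ndarray,
    features: np.ndarray,
    sorted_global: np.ndarray,
    in_leaf: np.ndarray,
    min_samples_leaf: int,
    ridge: float,
) -> None:
    """Fill ``leaf`` with its best Newton-gain split (or leave gain at -inf).

    All candidate (feature, threshold) pairs of the leaf are scored at once:
    the leaf submatrix is sorted per feature, prefix sums of gradient and
    curvature give left/right statistics, and candidates must change feature
    value at the cut and keep ``min_samples_leaf`` rows on both sides.
    """
    rows = leaf.rows
    m = len(rows)
    n_feat = len(features)
    # rows of this leaf sorted per feature, extracted from the global presort
    mask = in_leaf[sorted_global]  # (n, F)
    ord_fm = sorted_global.T[mask.T].reshape(n_feat, m)
    vals = X[ord_fm, features[:, None]]  # (F, m)
    g = grad[ord_fm].cumsum(axis=1)[:, :-1]
    h = hess[ord_fm].cumsum(axis=1)[:, :-1]
    G = grad[rows].sum()
    H = hess[rows].sum()
    parent = G * G / (H + ridge)

    counts = np.arange(1, m)[None, :]
    ok = (
        (vals[:, 1:] != vals[:, :-1])
        & (counts >= min_samples_leaf)
        & (m - counts >= min_samples_leaf)
    )
    if not ok.any():
        return
    gain = 0.5 * (g**2 / (h + ridge) + (G - g) ** 2 / (H - h + ridge) - parent)
    gain[~ok] = -np.inf
    f_local, cut = np.unravel_index(int(np.argmax(gain)), gain.shape)
    if gain[f_local, cut] <= 1e-12:  # require strictly positive gain
        return
    leaf.gain = float(gain[f_local, cut])
    leaf.split_feature = int(features[f_local])
    leaf.split_threshold = float((vals[f_local, cut] + vals[f_local, cut + 1]) / 2.0)
    leaf.left_rows = ord_fm[f_local, : cut + 1]
    leaf.right_rows = ord_fm[f_local, cut + 1 :]


def fit_tree(
    features: np.ndarray,
    gradients: np.ndarray,
    curvatures: np.ndarray,
    params: LambdaRankParams,
    feature_subset: np.ndarray | None = None,
    feature_gains: np.ndarray | None = None,
) -> RegressionTree:
    """Fit one regression tree to (gradient, curvature) pairs.

    Best-first growth to ``params.max_leaves``; when no split has positive
    Newton gain the tree is a single leaf with the global Newton step.
    ``feature_gains`` (if given) accumulates realized split gains per feature.
    """
    X = np.asarray(features, dtype=np.float64)
    grad = np.asarray(gradients, dtype=np.float64)
    hess = np.asarray(curvatures, dtype=np.float64)
    n, n_feat = X.shape
    if n < params.min_samples_leaf:
        raise ValueError("fewer rows than min_samples_leaf")
    cand_features = (
        np.arange(n_feat) if feature_subset is None else np.asarray(feature_subset, dtype=int)
    )
    sorted_global = np.argsort(X[:, cand_features], axis=0, kind="stable")
    in_leaf = np.zeros(n, dtype=bool)

    feature_arr = [-1]
    threshold_arr = [0.0]
    left_arr = [-1]
    right_arr = [-1]
    value_arr = [-grad.sum() / (hess.sum() + params.ridge)]

    def evaluate(leaf: _Leaf) -> None:
        if len(leaf.rows) < 2 * params.min_samples_leaf:
            return
        in_leaf.fill(False)
        in_leaf[leaf.rows] = True
        _best_split(
            leaf, X, grad, hess, cand_features, sorted_global, in_leaf,
            params.min_samples_leaf, params.ridge,
        )

    root = _Leaf(rows=np.arange(n), node_id=0)
    evaluate(root)
    open_leaves = [root]
    n_leaves = 1
    while n_leaves < params.max_leaves:
        best = max(open_leaves, key=lambda l: l.gain)
        if not np.isfinite(best.gain) or best.gain <= 0:
            break
        open_leaves.remove(best)
        if feature_gains is not None:
            feature_gains[best.split_feature] += best.gain
        # turn this leaf into an internal node with two fresh leaves
        for child_rows in (best.left_rows, best.right_rows):
            node_id = len(feature_arr)
            feature_arr.append(-1)
            threshold_arr.append(0.0)
            left_arr.append(-1)
            right_arr.append(-1)
            g, h = grad[child_rows].sum(), hess[child_rows].sum()
            value_arr.append(-g / (h + params.ridge))
            child = _Leaf(rows=child_rows, node_id=node_id)
            evaluate(child)
            open_leaves.append(child)
        feature_arr[best.node_id] = best.split_feature
        threshold_arr[best.node_id] = best.split_threshold
        left_arr[best.node_id] = open_leaves[-2].node_id
        right_arr[best.node_id] = open_leaves[-1].node_id
        value_arr[best.node_id] = 0.0
        n_leaves += 1

    return RegressionTree(
        feature=np.asarray(feature_arr, dtype=int),
        threshold=np.asarray(threshold_arr, dtype=np.float64),
        left=np.asarray(left_arr, dtype=int),
        right=np.asarray(right_arr, dtype=int),
        value=np.asarray(value_arr, dtype=np.float64),
    )


# ---------------------------------------------------------------------------
# Boosted ensemble


@dataclass(eq=False)
class BoostedRanker:
    """Ordered tree ensemble: ``score(x) = sum_t learning_rate * tree_t(x)``."""

    trees: list[RegressionTree]
    params: LambdaRankParams
    feature_names: tuple[str, ...]
    feature_gains: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.feature_gains is None:
            self.feature_gains = np.zeros(len(self.feature_names))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got shape {X.shape}"
            )
        scores = np.zeros(len(X))
        for tree in self.trees:
            scores += self.params.learning_rate * tree.predict(X)
        return scores

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        from dataclasses import asdict

        return json.dumps(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "params": asdict(self.params),
                "feature_names": list(self.feature_names),
                "feature_gains": self.feature_gains.tolist(),
                "trees": [t.to_dict() for t in self.trees],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BoostedRanker":
        d = json.loads(text)
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {d.get('format_version')}")
        return cls(
            trees=[RegressionTree.from_dict(t) for t in d["trees"]],
            params=LambdaRankParams(**d["params"]),
            feature_names=tuple(d["feature_names"]),
            feature_gains=np.asarray(d["feature_gains"], dtype=np.float64),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "BoostedRanker":
        return cls.from_json(Path(path).read_text())


def train(dataset: RankingDataset, params: LambdaRankParams = LambdaRankParams()) -> BoostedRanker:
    """Train a boosted ranker with lambdarank gradients.

    Each round recomputes per-group gradients at the current scores, fits one
    tree over all rows, and adds it with the learning rate.  Deterministic
    given ``params.seed`` (which drives only the optional feature subsampling).
    """
    if dataset.features.size == 0 or dataset.n_groups == 0:
        raise ValueError("cannot train on an empty dataset")
    n_feat = dataset.features.shape[1]
    rng = np.random.default_rng(params.seed)
    scores = np.zeros(len(dataset.features))
    trees: list[RegressionTree] = []
    feature_gains = np.zeros(n_feat)
    # group structure is fixed across rounds: precompute masks and IDCG once
    group_info = []
    for _, sl in dataset.groups():
        rel = _check_binary(dataset.relevance[sl])
        pos = np.flatnonzero(rel == 1)
        neg = np.flatnonzero(rel == 0)
        depth = rel.size if params.k is None else params.k
        idcg = dcg_at_k(np.sort(rel)[::-1], depth)
        group_info.append((sl, pos, neg, depth, idcg))

    for _ in range(params.n_trees):
        grad = np.zeros_like(scores)
        hess = np.zeros_like(scores)
        for sl, pos, neg, depth, idcg in group_info:
            if pos.size and neg.size and idcg > 0:
                _lambda_into(
                    grad[sl], hess[sl], scores[sl], pos, neg, depth, params.sigma, idcg
                )
        subset = None
        if params.feature_subsample < 1.0:
            n_sub = max(1, int(round(params.feature_subsample * n_feat)))
            subset = np.sort(rng.choice(n_feat, size=n_sub, replace=False))
        tree = fit_tree(dataset.features, grad, hess, params, subset, feature_gains)
        scores += params.learning_rate * tree.predict(dataset.features)
        trees.append(tree)

    return BoostedRanker(
        trees=trees,
        params=params,
        feature_names=dataset.feature_names,
        feature_gains=feature_gains,
    )


# ---------------------------------------------------------------------------
# Ranking utilities


def rank_pockets(
    model: BoostedRanker,
    features: np.ndarray,
    pocket_indices: Sequence[int] | None = None,
) -> list[tuple[int, float]]:
    """Rank one protein's pockets by model score, descending.

    Ties break toward the lower pocket index.  Returns ``(pocket_index,
    score)`` pairs; indices default to 1..n in row order.
    """
    features = np.asarray(features, dtype=np.float64)
    scores = model.predict(features)
    if pocket_indices is None:
        pocket_indices = list(range(1, len(scores) + 1))
    if len(pocket_indices) != len(scores):
        raise ValueError("one pocket index per feature row required")
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], pocket_indices[i]))
    return [(int(pocket_indices[i]), float(scores[i])) for i in order]


def feature_importance(model: BoostedRanker) -> pd.Series:
    """Total realized split gain per feature, sorted descending."""
    if not isinstance(model, BoostedRanker) or model.feature_gains is None:
        raise ValueError("model is not trained")
    s = pd.Series(model.feature_gains, index=list(model.feature_names), name="gain")
    return s.sort_values(ascending=False, kind="stable")
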