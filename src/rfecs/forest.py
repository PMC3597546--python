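"""Vector random forest with Fisher-discriminant node splits.

Each internal node selects one histone mark and splits samples on a linear
projection of that mark's 20-bin signal vector: the Fisher discriminant
direction ``w = (S_W + ridge*I)^-1 (mu_enh - mu_non)``, where ``S_W`` is the
pooled within-class scatter of the node's samples. The split threshold is
searched exactly over midpoints of consecutive sorted projections, minimizing
the weighted Gini impurity of the induced partition. Using the whole 20-bin
vector lets a node exploit signal *shape* (e.g. the bimodal H3K4me1 dip at
enhancer centers) as well as abundance.

Trees are grown on bootstrap resamples; the out-of-bag (OOB) complement
provides the internal error estimate and the per-mark permutation
importance: the mean increase in a tree's OOB error when the mark's entire
20-bin block is permuted among its OOB samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .training import ENHANCER, NON_ENHANCER, FeatureBlockMatrix

__all__ = [
    "FisherNode",
    "VectorForest",
    "ImportanceReport",
    "fit_fisher_split",
    "grow_tree",
    "fit_forest",
    "predict_votes",
    "oob_error",
    "oob_variable_importance",
    "save_forest",
    "load_forest",
]

FOREST_FORMAT_VERSION = 1

DEFAULT_N_TREES = 65
DEFAULT_MIN_NODE = 5
DEFAULT_RIDGE_SCALE = 1e-6


@dataclass
class FisherNode:
    """One node of a vector decision tree.

    Internal nodes hold ``(mark_index, weights, threshold)``; a sample whose
    projection ``w . v`` is <= threshold goes left. Leaves hold the majority
    class and class fractions (ties break to non-enhancer).
    """

    mark_index: int = -1
    weights: np.ndarray | None = None
    threshold: float = 0.0
    left: "FisherNode | None" = None
    right: "FisherNode | None" = None
    leaf_class: int | None = None
    leaf_class_fractions: tuple[float, float] | None = None  # (non-enh, enh)

    @property
    def is_leaf(self) -> bool:
        return self.leaf_class is not None


@dataclass
class VectorForest:
    """Ensemble of Fisher-split trees plus bookkeeping for OOB estimates."""

    trees: list[FisherNode]
    mark_names: tuple[str, ...]
    bootstrap_indices: list[np.ndarray]
    oob_indices: list[np.ndarray]
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.trees)


@dataclass
class ImportanceReport:
    """Per-mark OOB permutation importance and 1-based ranks (1 = most important)."""

    mark_names: tuple[str, ...]
    importance: np.ndarray
    ranks: np.ndarray

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.mark_names, (float(v) for v in self.importance)))


def _gini(n1: float, n0: float) -> float:
    n = n1 + n0
    if n == 0:
        return 0.0
    p1 = n1 / n
    return 2.0 * p1 * (1.0 - p1)


def fit_fisher_split(
    X: np.ndarray, y: np.ndarray, ridge: float | None = None
) -> tuple[np.ndarray, float, float] | None:
    """Fisher discriminant + exact Gini threshold search for one mark.

    Parameters
    ----------
    X : (n, 20) signal vectors of the candidate mark at this node.
    y : (n,) class labels; both classes must be present.
    ridge : added to the diagonal of the within-class scatter; defaults to
        ``1e-6 * trace(S_W) / 20`` (with a tiny absolute floor) so singular
        scatter from zero-variance bins never aborts a split.

    Returns ``(weights, threshold, impurity_decrease)`` or None when no
    threshold separates the projections (all projections equal).
    """
    y = np.asarray(y)
    pos = y == ENHANCER
    if not pos.any() or pos.all():
        raise ValueError("fit_fisher_split requires both classes at the node")
    X = np.asarray(X, dtype=np.float64)
    mu1 = X[pos].mean(axis=0)
    mu0 = X[~pos].mean(axis=0)
    d1 = X[pos] - mu1
    d0 = X[~pos] - mu0
    sw = d1.T @ d1 + d0.T @ d0
    if ridge is None:
        ridge = DEFAULT_RIDGE_SCALE * np.trace(sw) / X.shape[1]
    ridge = max(ridge, 1e-12)
    w = np.linalg.solve(sw + ridge * np.eye(X.shape[1]), mu1 - mu0)
    norm = np.linalg.norm(w)
    if norm == 0.0:
        return None
    w = w / norm
    proj = X @ w

    order = np.argsort(proj, kind="stable")
    ps = proj[order]
    ys = pos[order]
    n = len(ys)
    cum1 = np.cumsum(ys)
    total1 = cum1[-1]
    # candidate split after sorted position i, only where projections differ
    cand = np.nonzero(np.diff(ps) > 0)[0]
    if cand.size == 0:
        return None
    nl = (cand + 1).astype(np.float64)
    n1l = cum1[cand].astype(np.float64)
    n0l = nl - n1l
    nr = n - nl
    n1r = total1 - n1l
    n0r = nr - n1r
    gini_l = 1.0 - (n1l / nl) ** 2 - (n0l / nl) ** 2
    gini_r = 1.0 - (n1r / nr) ** 2 - (n0r / nr) ** 2
    weighted = (nl * gini_l + nr * gini_r) / n
    k = int(np.argmin(weighted))  # first minimum -> lowest threshold on ties
    threshold = 0.5 * (ps[cand[k]] + ps[cand[k] + 1])
    parent = _gini(float(total1), float(n - total1))
    decrease = parent - float(weighted[k])
    return w, float(threshold), decrease


def _make_leaf(y: np.ndarray) -> FisherNode:
    n1 = int(np.sum(y == ENHANCER))
    n0 = len(y) - n1
    # tie -> non-enhancer (conservative)
    cls = ENHANCER if n1 > n0 else NON_ENHANCER
    frac = (n0 / len(y), n1 / len(y)) if len(y) else (1.0, 0.0)
    return FisherNode(leaf_class=cls, leaf_class_fractions=frac)


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    mtry: int,
    min_node: int,
    rng: np.random.Generator,
) -> FisherNode:
    """Grow one tree on (N, M, 20) features.

    At each node, ``mtry`` candidate marks are drawn without replacement; the
    best Fisher split by Gini decrease wins (ties: lower mark index, then
    lower threshold via first-minimum search). Recursion stops on pure
    nodes, nodes of at most *min_node* samples, or no positive impurity
    decrease.
    """
    n, n_marks, _ = X.shape
    if mtry > n_marks:
        raise ValueError("mtry exceeds number of marks")

    def build(idx: np.ndarray) -> FisherNode:
        ys = y[idx]
        if len(idx) <= min_node or len(np.unique(ys)) == 1:
            return _make_leaf(ys)
        candidates = np.sort(rng.choice(n_marks, size=mtry, replace=False))
        best = None
        for m in candidates:  # ascending order: strict '>' keeps lowest index on ties
            fit = fit_fisher_split(X[idx, m, :], ys)
            if fit is None:
                continue
            w, thr, dec = fit
            if best is None or dec > best[3]:
                best = (m, w, thr, dec)
        if best is None or best[3] <= 0.0:
            return _make_leaf(ys)
        m, w, thr, _ = best
        go_left = X[idx, m, :] @ w <= thr
        if not go_left.any() or go_left.all():  # numerically degenerate
            return _make_leaf(ys)
        node = FisherNode(mark_index=int(m), weights=w, threshold=thr)
        node.left = build(idx[go_left])
        node.right = build(idx[~go_left])
        return node

    return build(np.arange(n))


def fit_forest(
    ts: FeatureBlockMatrix,
    n_trees: int = DEFAULT_N_TREES,
    mtry: int | None = None,
    min_node: int = DEFAULT_MIN_NODE,
    seed: int = 0,
) -> VectorForest:
    """Fit the ensemble: one tree per independent bootstrap of the full set."""
    X, y = ts.values, ts.labels
    n = len(y)
    if n < 2 * min_node:
        raise ValueError(f"training set of {n} samples is too small (min_node={min_node})")
    if not ((y == ENHANCER).any() and (y == NON_ENHANCER).any()):
        raise ValueError("both classes must be present in the training set")
    if mtry is None:
        mtry = int(np.ceil(np.sqrt(ts.n_marks)))
    root_ss = np.random.SeedSequence(seed)
    trees: list[FisherNode] = []
    boots: list[np.ndarray] = []
    oobs: list[np.ndarray] = []
    for child in root_ss.spawn(n_trees):
        rng = np.random.default_rng(child)
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        trees.append(grow_tree(X[boot], y[boot], mtry, min_node, rng))
        boots.append(boot)
        oobs.append(oob)
    params = {"n_trees": n_trees, "mtry": mtry, "min_node": min_node}
    return VectorForest(trees, ts.mark_names, boots, oobs, seed, params)


def _tree_predict(tree: FisherNode, X: np.ndarray) -> np.ndarray:
    """Vectorized class prediction of one tree for (N, M, 20) features."""
    out = np.empty(X.shape[0], dtype=np.int64)

    def walk(node: FisherNode, idx: np.ndarray) -> None:
        if node.is_leaf:
            out[idx] = node.leaf_class
            return
        go_left = X[idx, node.mark_index, :] @ node.weights <= node.threshold
        if go_left.any():
            walk(node.left, idx[go_left])
        if not go_left.all():
            walk(node.right, idx[~go_left])

    if X.shape[0]:
        walk(tree, np.arange(X.shape[0]))
    return out


def predict_votes(forest: VectorForest, features: FeatureBlockMatrix | np.ndarray) -> np.ndarray:
    """Enhancer-vote fraction per sample: (#trees voting enhancer) / n_trees."""
    if isinstance(features, FeatureBlockMatrix):
        if features.mark_names != forest.mark_names:
            missing = set(forest.mark_names) - set(features.mark_names)
            extra = set(features.mark_names) - set(forest.mark_names)
            raise ValueError(
                f"mark mismatch with training order: missing {sorted(missing)}, "
                f"extra {sorted(extra)}"
            )
        X = features.values
    else:
        X = np.asarray(features, dtype=np.float64)
    votes = np.zeros(X.shape[0], dtype=np.float64)
    for tree in forest.trees:
        votes += _tree_predict(tree, X) == ENHANCER
    return votes / forest.n_trees


def oob_error(forest: VectorForest, ts: FeatureBlockMatrix) -> tuple[float, int]:
    """Out-of-bag error: each sample classified by majority vote of the trees
    for which it is out-of-bag (vote ties -> non-enhancer).

    Returns ``(error, n_excluded)`` where *n_excluded* counts samples with no
    OOB tree (left out of the error denominator).
    """
    n = ts.n_samples
    enh_votes = np.zeros(n)
    n_votes = np.zeros(n)
    for tree, oob in zip(forest.trees, forest.oob_indices):
        if oob.size == 0:
            continue
        pred = _tree_predict(tree, ts.values[oob])
        enh_votes[oob] += pred == ENHANCER
        n_votes[oob] += 1
    covered = n_votes > 0
    pred_class = np.where(enh_votes[covered] * 2 > n_votes[covered], ENHANCER, NON_ENHANCER)
    err = float(np.mean(pred_class != ts.labels[covered])) if covered.any() else float("nan")
    return err, int(n - covered.sum())


def oob_variable_importance(
    forest: VectorForest,
    ts: FeatureBlockMatrix,
    n_permutations: int = 5,
    seed: int = 0,
) -> ImportanceReport:
    """Per-mark permutation importance on OOB samples.

    For each mark, each tree's OOB samples have that mark's whole 20-bin
    block permuted among them; the importance is the mean increase in the
    tree's own OOB error, averaged over trees and permutation replicates.
    Can be <= 0 for uninformative marks.
    """
    rng = np.random.default_rng(seed)
    m = ts.n_marks
    increases = np.zeros(m)
    n_terms = 0
    base_errors = []
    oob_data = []
    for tree, oob in zip(forest.trees, forest.oob_indices):
        if oob.size < 2:
            base_errors.append(None)
            oob_data.append(None)
            continue
        Xo = ts.values[oob]
        yo = ts.labels[oob]
        base_errors.append(float(np.mean(_tree_predict(tree, Xo) != yo)))
        oob_data.append((Xo, yo))
    for mark in range(m):
        total = 0.0
        count = 0
        for tree, base, data in zip(forest.trees, base_errors, oob_data):
            if data is None:
                continue
            Xo, yo = data
            for _ in range(n_permutations):
                perm = rng.permutation(len(yo))
                Xp = Xo.copy()
                Xp[:, mark, :] = Xo[perm, mark, :]
                err = float(np.mean(_tree_predict(tree, Xp) != yo))
                total += err - base
                count += 1
        increases[mark] = total / count if count else 0.0
        n_terms = count
    # rank 1 = largest importance; ties broken by mark order
    order = np.argsort(-increases, kind="stable")
    ranks = np.empty(m, dtype=np.int64)
    ranks[order] = np.arange(1, m + 1)
    return ImportanceReport(ts.mark_names, increases, ranks)


def _node_to_dict(node: FisherNode) -> dict:
    if node.is_leaf:
        return {
            "leaf_class": int(node.leaf_class),
            "fractions": list(node.leaf_class_fractions),
        }
    return {
        "mark_index": node.mark_index,
        "weights": [float(v) for v in node.weights],
        "threshold": node.threshold,
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(d: dict) -> FisherNode:
    if "leaf_class" in d:
        return FisherNode(leaf_class=d["leaf_class"], leaf_class_fractions=tuple(d["fractions"]))
    return FisherNode(
        mark_index=d["mark_index"],
        weights=np.array(d["weights"], dtype=np.float64),
        threshold=d["threshold"],
        left=_node_from_dict(d["left"]),
        right=_node_from_dict(d["right"]),
    )


def save_forest(forest: VectorForest, path: str) -> None:
    """Serialize to versioned JSON (mark order, seed, params, trees, OOB sets)."""
    doc = {
        "format_version": FOREST_FORMAT_VERSION,
        "mark_names": list(forest.mark_names),
        "seed": forest.seed,
        "params": forest.params,
        "trees": [_node_to_dict(t) for t in forest.trees],
        "bootstrap_indices": [b.tolist() for b in forest.bootstrap_indices],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_forest(path: str) -> VectorForest:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != FOREST_FORMAT_VERSION:
        raise ValueError(f"unsupported forest format in {path}")
    boots = [np.array(b, dtype=np.int64) for b in doc["bootstrap_indices"]]
    n = len(boots[0]) if boots else 0
    oobs = [np.setdiff1d(np.arange(n), b) for b in boots]
    return VectorForest(
        [_node_from_dict(t) for t in doc["trees"]],
        tuple(doc["mark_names"]),
        boots,
        oobs,
        doc["seed"],
        doc["params"],
    )
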