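"""Conditional inference trees for two-class diagnosis, from first principles.

Variable selection at each node uses the permutation-moment association
test on the linear statistic T = sum_i x_i y_i with its conditional moments

    E[T] = (sum x)(sum y) / n
    V[T] = sum (x - xbar)^2 * sum (y - ybar)^2 / (n - 1)

standardized to z = (T - E)/sqrt(V).  For n below ``exact_permutation_n``
the two-sided p-value comes from full enumeration of the permutation
distribution of T (dedupicated over the binary response's label placements);
otherwise from the normal approximation.  The smallest Bonferroni-adjusted
p-value over candidate covariates must clear ``alpha`` for the node to
split; the split point maximizes the absolute standardized two-sample
statistic over admissible midpoints.  Growth stops on purity, minimum node
size, depth, or failure of the global test — so tree size is controlled by
a familywise error rate, not by pruning.  Evaluation is by leave-one-out
cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CTreeParams:
    alpha: float = 0.05
    min_node_to_split: int = 4
    min_leaf: int = 2
    max_depth: int | None = None
    exact_permutation_n: int = 8   # below this, p by full enumeration

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


@dataclass
class AssocTest:
    covariate: str
    statistic: float        # T
    expectation: float      # E[T]
    variance: float         # V[T]
    z: float
    p_value: float
    p_adjusted: float = 1.0


def assoc_test(
    x: np.ndarray,
    y: np.ndarray,
    covariate: str = "x",
    exact_permutation_n: int = 8,
) -> AssocTest:
    """Permutation-moment association test of numeric x vs binary y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("association test needs n >= 2")
    t_obs = float(np.sum(x * y))
    e = float(x.sum() * y.sum() / n)
    v = float(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2) / (n - 1))
    if v <= 0.0:
        return AssocTest(covariate, t_obs, e, v, 0.0, 1.0)
    z = (t_obs - e) / math.sqrt(v)
    if n < exact_permutation_n:
        p = _exact_permutation_p(x, y, t_obs, e)
    else:
        p = 2.0 * float(stats.norm.sf(abs(z)))
        p = min(p, 1.0)
    return AssocTest(covariate, t_obs, e, v, float(z), p)


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, t_obs: float, e: float) -> float:
    """Two-sided exact p: fraction of label placements with |T - E| >= |T_obs - E|.

    y is binary, so distinct permutations reduce to choices of which indices
    carry the ones.
    """
    ones = int(round(y.sum()))
    n = x.size
    d_obs = abs(t_obs - e)
    hits = 0
    total = 0
    for idx in combinations(range(n), ones):
        t = x[list(idx)].sum()
        total += 1
        if abs(t - e) >= d_obs - 1e-12:
            hits += 1
    return hits / total


@dataclass
class TreeNode:
    n: int
    class_counts: dict[str, int]
    majority: str
    depth: int
    covariate: str | None = None
    threshold: float | None = None
    p_adjusted: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.covariate is None

    def to_dict(self) -> dict:
        d = {"n": self.n, "class_counts": self.class_counts, "majority": self.majority}
        if not self.is_leaf:
            d.update(
                covariate=self.covariate,
                threshold=self.threshold,
                p_adjusted=self.p_adjusted,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d


def select_variable(
    X: pd.DataFrame, y: np.ndarray, params: CTreeParams
) -> tuple[str | None, list[AssocTest]]:
    """Bonferroni-corrected global test: the winning covariate, or None."""
    m = X.shape[1]
    tests = []
    for col in X.columns:
        t = assoc_test(
            X[col].to_numpy(float), y, covariate=str(col),
            exact_permutation_n=params.exact_permutation_n,
        )
        t.p_adjusted = min(1.0, m * t.p_value)
        tests.append(t)
    best = min(tests, key=lambda t: t.p_adjusted)  # ties: first by column order
    if best.p_adjusted <= params.alpha:
        return best.covariate, tests
    return None, tests


def best_split(x: np.ndarray, y: np.ndarray, params: CTreeParams) -> float | None:
    """Threshold (midpoint of adjacent distinct values) maximizing |z| of
    the left-indicator two-sample statistic; ties take the smaller value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    uniq = np.unique(x)
    if uniq.size < 2:
        return None
    best_t, best_score = None, -np.inf
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        thr = (lo + hi) / 2.0
        left = x <= thr
        if left.sum() < params.min_leaf or (~left).sum() < params.min_leaf:
            continue
        t = assoc_test(left.astype(float), y, exact_permutation_n=0)
        score = abs(t.z)
        if score > best_score + 1e-12:
            best_t, best_score = thr, score
    return best_t


def _majority(y: np.ndarray, classes: list[str], fallback: str) -> str:
    counts = {c: int(np.sum(y == c)) for c in classes}
    top = max(counts.values())
    winners = [c for c in classes if counts[c] == top]
    if len(winners) == 1:
        return winners[0]
    if fallback in winners:
        return fallback
    return sorted(winners)[0]


def grow(X: pd.DataFrame, y: np.ndarray, params: CTreeParams | None = None) -> TreeNode:
    """Recursively grow a conditional inference tree on a binary response."""
    params = params or CTreeParams()
    y = np.asarray(y)
    if X.shape[0] != y.size or y.size < 1:
        raise ValueError("X and y must align with n >= 1")
    classes = sorted(set(y.tolist()))
    if len(classes) > 2:
        raise ValueError("binary response required")
    root_majority = _majority(y, classes, fallback=sorted(classes)[0])
    return _grow(X, y, params, classes, depth=0, parent_majority=root_majority)


def _grow(
    X: pd.DataFrame,
    y: np.ndarray,
    params: CTreeParams,
    classes: list[str],
    depth: int,
    parent_majority: str,
) -> TreeNode:
    counts = {c: int(np.sum(y == c)) for c in classes}
    majority = _majority(y, classes, fallback=parent_majority)
    node = TreeNode(n=y.size, class_counts=counts, majority=majority, depth=depth)

    pure = len({v for v in y.tolist()}) <= 1
    depth_capped = params.max_depth is not None and depth >= params.max_depth
    if y.size < params.min_node_to_split or pure or depth_capped:
        return node

    y01 = (y == classes[-1]).astype(float)
    winner, tests = select_variable(X, y01, params)
    if winner is None:
        return node
    threshold = best_split(X[winner].to_numpy(float), y01, params)
    if threshold is None:
        return node

    p_adj = next(t.p_adjusted for t in tests if t.covariate == winner)
    mask = X[winner].to_numpy(float) <= threshold
    node.covariate = winner
    node.threshold = float(threshold)
    node.p_adjusted = p_adj
    node.left = _grow(X[mask], y[mask], params, classes, depth + 1, majority)
    node.right = _grow(X[~mask], y[~mask], params, classes, depth + 1, majority)
    return node


def predict(tree: TreeNode, X: pd.DataFrame) -> np.ndarray:
    """Route samples down the tree; a value at the threshold goes left."""
    out = []
    for _, row in X.iterrows():
        node = tree
        while not node.is_leaf:
            if node.covariate not in row.index:
                raise ValueError(f"missing covariate {node.covariate!r}")
            node = node.left if float(row[node.covariate]) <= node.threshold else node.right
        out.append(node.majority)
    return np.array(out)


@dataclass
class LOOCVResult:
    predictions: np.ndarray
    accuracy: float
    confusion: pd.DataFrame
    trees: list[TreeNode] = field(repr=False, default_factory=list)


def loocv(X: pd.DataFrame, y: np.ndarray, params: CTreeParams | None = None) -> LOOCVResult:
    """Leave-one-out cross-validation: n refits, one held-out prediction each."""
    params = params or CTreeParams()
    y = np.asarray(y)
    n = y.size
    if n < 3:
        raise ValueError("LOOCV needs n >= 3")
    preds = []
    trees = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        tree = grow(X[mask], y[mask], params)
        preds.append(predict(tree, X.iloc[[i]])[0])
        trees.append(tree)
    preds = np.array(preds)
    accuracy = float(np.mean(preds == y))
    classes = sorted(set(y.tolist()))
    confusion = pd.DataFrame(
        [[int(np.sum((y == a) & (preds == b))) for b in classes] for a in classes],
        index=pd.Index(classes, name="true"),
        columns=pd.Index(classes, name="predicted"),
    )
    return LOOCVResult(preds, accuracy, confusion, trees)
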