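"""Recursive-partitioning classification trees (CART/rpart style).

Greedy best-first binary splitting of the ensPLIF analysis table on Gini
impurity, with rpart's stopping controls (minsplit, minbucket, maxdepth),
cost-complexity (weakest-link) pruning at a complexity parameter cp scaled
by the root risk, k-fold cross-validated cp selection, and the model-sanity
checks used in screening work: an overfitting flag from the
cross-validation curve, the cross-correlation of the selected descriptors,
and a y-scrambling (chance-correlation) test.

Classes are "ligand" (y = 1) and "decoy" (y = 0).  Priors default to the
observed class frequencies, as in rpart.  Screening benchmarks are heavily
imbalanced (~50 decoys per active); ``priors='equal'`` re-weights each class
to half of the total weight, which makes splits more sensitive to small
active-enriched pockets — including chance ones: with equal priors,
y-scrambled tables retain spurious splits that observed-frequency pruning
removes, which is why the imbalance-robust observed default is kept.

Determinism: equal-quality splits are broken toward the lowest variable
index and then the smallest threshold; fold assignment and permutations
derive from the seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TreeParams",
    "Node",
    "DecisionTree",
    "SanityReport",
    "fit_tree",
    "predict",
    "cp_table",
    "select_best_cp",
    "sanity_check",
]

_TIE_TOL = 1e-12

LIGAND, DECOY = "ligand", "decoy"


@dataclass(frozen=True)
class TreeParams:
    """rpart-equivalent growth and pruning controls."""

    minsplit: int = 20
    minbucket: int | None = None  # default ceil(minsplit / 3)
    cp: float = 0.01
    maxdepth: int = 30
    xval_folds: int = 10
    priors: str = "observed"  # "observed" (rpart default) | "equal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.minbucket is None:
            object.__setattr__(self, "minbucket", math.ceil(self.minsplit / 3))
        if self.minbucket > self.minsplit:
            raise ValueError("minbucket must not exceed minsplit")
        if not 0 <= self.cp <= 1:
            raise ValueError("cp must lie in [0, 1]")
        if self.priors not in ("equal", "observed"):
            raise ValueError("priors must be 'equal' or 'observed'")


@dataclass
class Node:
    """A tree node; rpart node numbering (root 1, children 2i and 2i+1)."""

    node_id: int
    n_active: int
    n_decoy: int
    w_active: float
    w_decoy: float
    variable: int | None = None   # 1-based descriptor index k ("Vk")
    threshold: float | None = None
    left: "Node | None" = None    # x < threshold
    right: "Node | None" = None   # x >= threshold

    @property
    def is_leaf(self) -> bool:
        return self.variable is None

    @property
    def klass(self) -> str:
        """Weighted-majority class; ties go to the decoy class."""
        return LIGAND if self.w_active > self.w_decoy else DECOY

    @property
    def risk(self) -> float:
        """Weighted misclassification risk of this node as a leaf."""
        return min(self.w_active, self.w_decoy)

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def subtree_risk(self) -> float:
        return sum(leaf.risk for leaf in self.leaves())

    def internal_nodes(self) -> list["Node"]:
        if self.is_leaf:
            return []
        return [self] + self.left.internal_nodes() + self.right.internal_nodes()

    def collapse(self) -> None:
        self.variable = None
        self.threshold = None
        self.left = None
        self.right = None


@dataclass
class DecisionTree:
    root: Node
    params: TreeParams
    n_variables: int

    @property
    def n_nodes(self) -> int:
        return len(self.root.internal_nodes()) + len(self.root.leaves())

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def selected_variables(self) -> list[int]:
        """Sorted 1-based indices of the descriptors used in splits."""
        return sorted({node.variable for node in self.root.internal_nodes()})

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def node_dict(node: Node) -> dict:
            base = {
                "id": node.node_id,
                "n_active": node.n_active,
                "n_decoy": node.n_decoy,
                "class": node.klass,
            }
            if not node.is_leaf:
                base.update({
                    "variable": f"V{node.variable}",
                    "threshold": node.threshold,
                    "left": node_dict(node.left),
                    "right": node_dict(node.right),
                })
            return base

        return {
            "n_variables": self.n_variables,
            "params": {
                "minsplit": self.params.minsplit,
                "minbucket": self.params.minbucket,
                "cp": self.params.cp,
                "maxdepth": self.params.maxdepth,
                "priors": self.params.priors,
                "seed": self.params.seed,
            },
            "root": node_dict(self.root),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "DecisionTree":
        def build(d: dict) -> Node:
            node = Node(
                node_id=d["id"], n_active=d["n_active"], n_decoy=d["n_decoy"],
                w_active=float(d["n_active"]), w_decoy=float(d["n_decoy"]),
            )
            if "variable" in d:
                node.variable = int(str(d["variable"]).lstrip("V"))
                node.threshold = float(d["threshold"])
                node.left = build(d["left"])
                node.right = build(d["right"])
            elif d.get("class") == LIGAND:
                # leaf class survives round-trips even under equal priors
                node.w_active = max(node.w_active, node.w_decoy + 1.0)
            return node

        params = TreeParams(**data.get("params", {}))
        return cls(root=build(data["root"]), params=params,
                   n_variables=data["n_variables"])

    @classmethod
    def from_json(cls, text_or_path) -> "DecisionTree":
        try:
            data = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                data = json.load(fh)
        return cls.from_dict(data)

    def render(self) -> str:
        """Indented text rendering of the tree."""
        lines: list[str] = []

        def walk(node: Node, depth: int, label: str) -> None:
            counts = f"[{node.n_active} active / {node.n_decoy} decoy]"
            if node.is_leaf:
                lines.append(f"{'  ' * depth}{label}-> {node.klass} {counts}")
            else:
                lines.append(
                    f"{'  ' * depth}{label}V{node.variable} "
                    f"(split at {node.threshold:.6g}) {counts}")
                walk(node.left, depth + 1, f"V{node.variable} < {node.threshold:.6g} ")
                walk(node.right, depth + 1, f"V{node.variable} >= {node.threshold:.6g} ")

        walk(self.root, 0, "")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _extract_xy(table) -> tuple[np.ndarray, np.ndarray]:
    """Accept an EnsPlifTable or a y/name/dg/V1..Vn DataFrame."""
    if hasattr(table, "X") and hasattr(table, "y"):
        return np.asarray(table.X, dtype=float), np.asarray(table.y, dtype=int)
    import pandas as pd  # noqa: F401  (DataFrame path)

    v_cols = [c for c in table.columns if c.startswith("V")]
    return table[v_cols].to_numpy(dtype=float), table["y"].to_numpy(dtype=int)


def _class_weights(y: np.ndarray, priors: str) -> np.ndarray:
    """Per-sample weights realising the chosen class priors."""
    n = y.size
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if priors == "observed" or n1 == 0 or n0 == 0:
        return np.ones(n)
    w = np.where(y == 1, 0.5 * n / n1, 0.5 * n / n0)
    return w


def _gini_improvements(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                       minbucket: int) -> tuple[float, float] | None:
    """Best (improvement, threshold) for one variable, or None.

    Thresholds are midpoints of consecutive distinct sorted values; both
    children must contain at least ``minbucket`` observations.  Among equal
    improvements the smallest threshold wins.
    """
    order = np.argsort(x, kind="stable")
    xs, ys, ws = x[order], y[order], w[order]
    n = xs.size
    w1 = np.cumsum(ws * ys)           # weighted actives left of cut i (first i+1 rows)
    wt = np.cumsum(ws)
    W1, W = w1[-1], wt[-1]
    # candidate cut after position i (0-based): left = rows 0..i
    distinct = np.nonzero(np.diff(xs) > 0)[0]
    if distinct.size == 0:
        return None
    counts_left = distinct + 1
    valid = (counts_left >= minbucket) & (n - counts_left >= minbucket)
    distinct = distinct[valid]
    if distinct.size == 0:
        return None
    wl, wl1 = wt[distinct], w1[distinct]
    wr, wr1 = W - wl, W1 - wl1
    # improvement = W*G(parent) - Wl*G(left) - Wr*G(right); Gini via 2pq form
    def wgini(total: np.ndarray, ones: np.ndarray) -> np.ndarray:
        zeros = total - ones
        with np.errstate(divide="ignore", invalid="ignore"):
            g = 2.0 * ones * zeros / total
        return np.where(total > 0, g, 0.0)

    improvement = wgini(np.array([W]), np.array([W1]))[0] - wgini(wl, wl1) - wgini(wr, wr1)
    best = improvement.max()
    if best <= _TIE_TOL:
        return None
    idx = int(np.nonzero(improvement >= best - _TIE_TOL)[0][0])  # smallest threshold
    i = distinct[idx]
    threshold = 0.5 * (xs[i] + xs[i + 1])
    return float(improvement[idx]), float(threshold)


def _grow(X: np.ndarray, y: np.ndarray, w: np.ndarray, rows: np.ndarray,
          params: TreeParams, depth: int, node_id: int) -> Node:
    yr, wr = y[rows], w[rows]
    node = Node(
        node_id=node_id,
        n_active=int(yr.sum()), n_decoy=int((1 - yr).sum()),
        w_active=float(wr[yr == 1].sum()), w_decoy=float(wr[yr == 0].sum()),
    )
    if (rows.size < params.minsplit or depth >= params.maxdepth
            or node.n_active == 0 or node.n_decoy == 0):
        return node
    best: tuple[float, int, float] | None = None  # (improvement, var, threshold)
    for k in range(X.shape[1]):
        res = _gini_improvements(X[rows, k], yr, wr, params.minbucket)
        if res is None:
            continue
        improvement, threshold = res
        if best is None or improvement > best[0] + _TIE_TOL:
            best = (improvement, k, threshold)
        # ties: keep the earlier (lower-index) variable
    if best is None:
        return node
    _, k, threshold = best
    node.variable = k + 1
    node.threshold = threshold
    mask = X[rows, k] < threshold
    node.left = _grow(X, y, w, rows[mask], params, depth + 1, 2 * node_id)
    node.right = _grow(X, y, w, rows[~mask], params, depth + 1, 2 * node_id + 1)
    return node


def _prune(root: Node, alpha: float) -> None:
    """Weakest-link pruning: collapse internal nodes with link strength
    g(t) = (R(t) - R(T_t)) / (|leaves| - 1) <= alpha, weakest first.

    alpha <= 0 prunes nothing: the full grown tree, including splits that
    improve impurity without changing any classification (g = 0), is the
    cp = 0 tree, as in rpart.
    """
    if alpha <= _TIE_TOL:
        return
    while True:
        internals = root.internal_nodes()
        if not internals:
            return
        gs = []
        for node in internals:
            n_leaves = len(node.leaves())
            g = (node.risk - node.subtree_risk()) / (n_leaves - 1)
            gs.append(g)
        g_min = min(gs)
        if g_min > alpha + _TIE_TOL:
            return
        for node, g in zip(internals, gs):
            if g <= g_min + _TIE_TOL:
                node.collapse()


def fit_tree(table, params: TreeParams | None = None) -> DecisionTree:
    """Grow and cp-prune a classification tree on an ensPLIF table.

    Splits maximise the weighted Gini impurity decrease over all
    (variable, threshold) candidates, thresholds being midpoints of
    consecutive distinct sorted values.  After growth the tree is pruned at
    ``alpha = cp * R(root)`` where R is the weighted misclassification risk.
    A single-class table yields a single-leaf tree with a warning.
    """
    params = params or TreeParams()
    X, y = _extract_xy(table)
    if X.shape[0] == 0:
        raise ValueError("empty table")
    w = _class_weights(y, params.priors)
    if len(np.unique(y)) < 2:
        logger.warning("single-class table: returning a single-leaf tree")
        root = _grow(X, y, w, np.arange(y.size), replace(params, maxdepth=0), 0, 1)
        return DecisionTree(root=root, params=params, n_variables=X.shape[1])
    root = _grow(X, y, w, np.arange(y.size), params, 0, 1)
    _prune(root, params.cp * root.risk)
    return DecisionTree(root=root, params=params, n_variables=X.shape[1])


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict(tree: DecisionTree, table, trace: bool = False):
    """Class labels for the rows of ``table``; with ``trace=True`` also the
    node-id path each row takes from root to leaf."""
    X, _ = _extract_xy(table) if hasattr(table, "X") or hasattr(table, "columns") \
        else (np.asarray(table, dtype=float), None)
    if isinstance(table, np.ndarray):
        X = np.asarray(table, dtype=float)
    labels: list[str] = []
    paths: list[list[int]] = []
    for row in X:
        node = tree.root
        path = [node.node_id]
        while not node.is_leaf:
            node = node.left if row[node.variable - 1] < node.threshold else node.right
            path.append(node.node_id)
        labels.append(node.klass)
        paths.append(path)
    labels_arr = np.array(labels)
    return (labels_arr, paths) if trace else labels_arr


# ---------------------------------------------------------------------------
# Cross-validation and cp selection
# ---------------------------------------------------------------------------

def _alpha_sequence(root: Node) -> list[tuple[float, int]]:
    """(alpha, n_leaves) pairs of the weakest-link pruning sequence."""
    import copy

    tree = copy.deepcopy(root)
    seq = [(0.0, len(tree.leaves()))]
    while tree.internal_nodes():
        internals = tree.internal_nodes()
        gs = [(node.risk - node.subtree_risk()) / (len(node.leaves()) - 1)
              for node in internals]
        g_min = min(gs)
        for node, g in zip(internals, gs):
            if g <= g_min + _TIE_TOL:
                node.collapse()
        seq.append((max(g_min, 0.0), len(tree.leaves())))
    return seq


def cp_table(table, params: TreeParams | None = None) -> list[dict]:
    """rpart-style cp table with cross-validated error per pruning level.

    Each row holds the cp value (alpha / root risk, with geometric-mean
    midpoints between successive levels), the number of leaves, the
    resubstitution relative error, and the cross-validated error (xerror)
    with its standard error (xstd), both relative to the root risk.
    """
    params = params or TreeParams()
    X, y = _extract_xy(table)
    w = _class_weights(y, params.priors)
    full_params = replace(params, cp=0.0)
    full = fit_tree(table, full_params)
    r_root = full.root.risk
    if r_root <= 0:
        return [{"cp": params.cp, "n_leaves": 1, "rel_error": 0.0,
                 "xerror": 0.0, "xstd": 0.0}]
    seq = _alpha_sequence(full.root)
    alphas = [a for a, _ in seq]
    # geometric-mean representative alpha per pruning interval
    reps = []
    for i, (a, n_leaves) in enumerate(seq):
        upper = alphas[i + 1] if i + 1 < len(alphas) else a * 10 + r_root
        lo = max(a, 1e-12)
        rep = min(math.sqrt(lo * max(upper, lo)), r_root)  # cp is capped at 1
        reps.append((rep, a, n_leaves))

    rng = np.random.default_rng(params.seed)
    folds = _stratified_folds(y, params.xval_folds, rng)
    heldout_risk = {i: [] for i in range(len(reps))}
    for fold_ids in folds:
        mask = np.zeros(y.size, dtype=bool)
        mask[fold_ids] = True
        sub = _ArrayTable(X[~mask], y[~mask])
        if len(np.unique(sub.y)) < 2:
            continue
        fold_full = fit_tree(sub, full_params)
        for i, (_, alpha_lo, _) in enumerate(reps):
            import copy
            pruned = copy.deepcopy(fold_full.root)
            _prune(pruned, alpha_lo)
            t = DecisionTree(pruned, full_params, X.shape[1])
            labels = predict(t, X[mask])
            wrong = (labels == LIGAND) != (y[mask] == 1)
            heldout_risk[i].append(float((w[mask] * wrong).sum()))
    out = []
    for i, (rep_alpha, alpha_lo, n_leaves) in enumerate(reps):
        import copy
        pruned = copy.deepcopy(full.root)
        _prune(pruned, alpha_lo)
        rel = DecisionTree(pruned, full_params, X.shape[1]).root.subtree_risk() / r_root
        risks = heldout_risk[i]
        if risks:
            per_fold = np.array(risks) / (r_root / len(folds))
            xerr = float(np.sum(risks) / r_root)
            xstd = float(np.std(per_fold, ddof=1) / math.sqrt(len(per_fold))) \
                if len(per_fold) > 1 else 0.0
        else:
            xerr, xstd = float("nan"), float("nan")
        out.append({"cp": rep_alpha / r_root, "n_leaves": n_leaves,
                    "rel_error": rel, "xerror": xerr, "xstd": xstd})
    return out


def select_best_cp(table, params: TreeParams | None = None,
                   one_se: bool = False) -> float:
    """cp minimising the cross-validated error (optionally the 1-SE rule)."""
    rows = [r for r in cp_table(table, params) if not math.isnan(r["xerror"])]
    if not rows:
        return (params or TreeParams()).cp
    best = min(rows, key=lambda r: r["xerror"])
    if one_se:
        cutoff = best["xerror"] + best["xstd"]
        candidates = [r for r in rows if r["xerror"] <= cutoff]
        best = max(candidates, key=lambda r: r["cp"])
    return float(best["cp"])


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    k = min(k, y.size)
    folds: list[list[int]] = [[] for _ in range(k)]
    for label in (1, 0):
        ids = np.flatnonzero(y == label)
        rng.shuffle(ids)
        for i, idx in enumerate(ids):
            folds[i % k].append(int(idx))
    return [np.array(sorted(f), dtype=int) for f in folds if f]


class _ArrayTable:
    """Minimal X/y view so array subsets can be refit."""

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.X = X
        self.y = y


# ---------------------------------------------------------------------------
# Model sanity checks
# ---------------------------------------------------------------------------

@dataclass
class SanityReport:
    xval_curve: list[dict]
    overfitting: bool
    selected_variables: list[int]
    cross_correlation: np.ndarray      # |Pearson r|, selected x selected
    cross_correlated: bool             # any off-diagonal |r| >= threshold
    real_f_measure: float
    scramble_f_measures: np.ndarray
    chance_fraction: float             # fraction of scrambles >= real
    percentile: float                  # percentile of the real score
    n_permutations: int
    seed: int


def _training_f_measure(tree: DecisionTree, X: np.ndarray, y: np.ndarray) -> float:
    labels = predict(tree, X)
    pred1 = labels == LIGAND
    tp = int(np.sum(pred1 & (y == 1)))
    fp = int(np.sum(pred1 & (y == 0)))
    fn = int(np.sum(~pred1 & (y == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return (2 * precision * recall / (precision + recall)
            if precision + recall else 0.0)


def sanity_check(table, tree: DecisionTree, n_permutations: int = 100,
                 seed: int = 0, corr_threshold: float = 0.95) -> SanityReport:
    """The three screening-model diagnostics.

    Overfitting: the cross-validated error at the tree's cp exceeds the
    minimum cross-validated error by more than one standard error.
    Cross-correlation: |Pearson r| among the selected descriptors.
    Chance correlation: refit on y-scrambled copies and report the fraction
    of scrambles whose training F-measure reaches the real tree's.
    """
    X, y = _extract_xy(table)
    curve = cp_table(table, tree.params)
    finite = [r for r in curve if not math.isnan(r["xerror"])]
    overfit = False
    if finite:
        best = min(finite, key=lambda r: r["xerror"])
        at_cp = [r for r in finite if r["cp"] <= tree.params.cp] or finite
        chosen = min(at_cp, key=lambda r: abs(r["cp"] - tree.params.cp))
        overfit = chosen["xerror"] > best["xerror"] + best["xstd"] + 1e-12

    selected = tree.selected_variables()
    if selected:
        sub = X[:, [k - 1 for k in selected]]
        with np.errstate(invalid="ignore"):
            corr = np.abs(np.corrcoef(sub, rowvar=False))
        corr = np.atleast_2d(np.nan_to_num(corr))
    else:
        corr = np.zeros((0, 0))
    off = corr - np.eye(corr.shape[0]) if corr.size else corr
    cross_correlated = bool(off.size and np.any(off >= corr_threshold))

    real_f = _training_f_measure(tree, X, y)
    rng = np.random.default_rng(seed)
    scramble_fs = np.empty(n_permutations)
    for i in range(n_permutations):
        y_perm = rng.permutation(y)
        perm_tree = fit_tree(_ArrayTable(X, y_perm), tree.params)
        scramble_fs[i] = _training_f_measure(perm_tree, X, y_perm)
    chance_fraction = float(np.mean(scramble_fs >= real_f))
    percentile = float(100.0 * np.mean(scramble_fs < real_f))
    return SanityReport(
        xval_curve=curve, overfitting=overfit, selected_variables=selected,
        cross_correlation=corr, cross_correlated=cross_correlated,
        real_f_measure=real_f, scramble_f_measures=scramble_fs,
        chance_fraction=chance_fraction, percentile=percentile,
        n_permutations=n_permutations, seed=seed,
    )
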