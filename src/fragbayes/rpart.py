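"""Depth-bounded CART-style recursive partitioning over mixed features.

Binary fragment-presence features and continuous descriptors share one
feature table; splits are greedy Gini-impurity splits with deterministic
tie-breaking (lowest column index wins).  Binary splits send feature-present
rows right; numeric splits send ``value > threshold`` right; missing values
route to the child that received more training examples.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from fragbayes.errors import FitError, ParameterError
from fragbayes.evalx import ConfusionCounts, MetricsReport, compute_metrics, stratified_folds
from fragbayes.featurize.featureset import FeatureSet
from fragbayes.nbayes import as_binary_labels

BINARY = "binary_presence"
NUMERIC = "numeric_threshold"


@dataclass
class FeatureTable:
    """Dense feature matrix with named, kind-annotated columns.

    Columns are ordered binary-first then numeric, each block sorted by
    feature id, so column index is a deterministic tie-break key.
    """

    column_ids: list[str]
    column_kinds: list[str]
    X: np.ndarray  # (n, p) float64, NaN = missing

    @classmethod
    def from_featuresets(
        cls,
        featuresets: Sequence[FeatureSet],
        descriptor_rows: Sequence[dict] | None = None,
        min_support: int = 1,
        binary_ids: list[str] | None = None,
    ) -> "FeatureTable":
        """Build a table from fragment feature sets (+ optional descriptors).

        ``min_support`` drops fragment columns present in fewer compounds.
        ``binary_ids`` freezes the binary-column vocabulary (for transforming
        a test set against a training-set table).
        """
        n = len(featuresets)
        if binary_ids is None:
            support: dict[str, int] = {}
            for fs in featuresets:
                for key in fs.features:
                    kid = _key_id(key)
                    support[kid] = support.get(kid, 0) + 1
            binary_ids = sorted(k for k, s in support.items() if s >= min_support)
        num_ids: list[str] = []
        if descriptor_rows:
            if len(descriptor_rows) != n:
                raise ParameterError("descriptor_rows length must match featuresets")
            seen = {k for row in descriptor_rows for k in row}
            # keep only descriptors that are non-missing somewhere
            num_ids = sorted(
                k
                for k in seen
                if any(not _nan(row.get(k)) for row in descriptor_rows)
            )
        p = len(binary_ids) + len(num_ids)
        X = np.zeros((n, p), dtype=float)
        col_of = {kid: j for j, kid in enumerate(binary_ids)}
        for i, fs in enumerate(featuresets):
            for key in fs.features:
                j = col_of.get(_key_id(key))
                if j is not None:
                    X[i, j] = 1.0
        for j, name in enumerate(num_ids, start=len(binary_ids)):
            for i, row in enumerate(descriptor_rows):
                v = row.get(name)
                X[i, j] = float("nan") if _nan(v) else float(v)
        return cls(
            column_ids=list(binary_ids) + num_ids,
            column_kinds=[BINARY] * len(binary_ids) + [NUMERIC] * len(num_ids),
            X=X,
        )

    @property
    def binary_ids(self) -> list[str]:
        return [c for c, k in zip(self.column_ids, self.column_kinds) if k == BINARY]


def _key_id(key) -> str:
    return f"{key.family}/{key.level}/{key.key}"


def _nan(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


@dataclass
class TreeNode:
    n_pos: int
    n_neg: int
    feature: int | None = None  # column index
    kind: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    missing_goes_right: bool = False

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class DecisionTree:
    root: TreeNode
    max_depth: int
    min_leaf: int
    column_ids: list[str]
    column_kinds: list[str]

    def to_dict(self) -> dict:
        def node(nd: TreeNode) -> dict:
            d = {"n_pos": nd.n_pos, "n_neg": nd.n_neg}
            if not nd.is_leaf:
                d.update(
                    feature=self.column_ids[nd.feature],
                    kind=nd.kind,
                    threshold=nd.threshold,
                    missing_goes_right=nd.missing_goes_right,
                    left=node(nd.left),
                    right=node(nd.right),
                )
            return d

        return {
            "max_depth": self.max_depth,
            "min_leaf": self.min_leaf,
            "columns": list(zip(self.column_ids, self.column_kinds)),
            "root": node(self.root),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    def render(self) -> str:
        """Indented-text rule tree (feature / yes–not branches / leaf class)."""
        lines: list[str] = []

        def walk(nd: TreeNode, indent: int, prefix: str) -> None:
            pad = "  " * indent
            if nd.is_leaf:
                label = "inhibitor" if nd.n_pos >= nd.n_neg else "non_inhibitor"
                lines.append(f"{pad}{prefix}-> {label} ({nd.n_pos} inh / {nd.n_neg} non)")
                return
            fid = self.column_ids[nd.feature]
            if nd.kind == BINARY:
                lines.append(f"{pad}{prefix}[{fid}]")
                walk(nd.left, indent + 1, "not: ")
                walk(nd.right, indent + 1, "yes: ")
            else:
                lines.append(f"{pad}{prefix}[{fid} > {nd.threshold:.4g}]")
                walk(nd.left, indent + 1, "no:  ")
                walk(nd.right, indent + 1, "yes: ")

        walk(self.root, 0, "")
        return "\n".join(lines)


def _gini_counts(pos: np.ndarray, tot: np.ndarray) -> np.ndarray:
    """Gini impurity for vectors of (positive, total) counts; 0 where empty."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, pos / np.maximum(tot, 1), 0.0)
    return 2.0 * p * (1.0 - p)


def _best_split(X, kinds, y, rows, min_leaf):
    """Best (gain, col, threshold) over candidate splits; None if infeasible.

    Splits with zero gain are allowed (required for XOR-type interactions);
    ties resolve to the lowest column index, then the smallest threshold.
    """
    m = rows.size
    y_r = y[rows]
    n_pos = int(y_r.sum())
    parent_gini = _gini_counts(np.array([n_pos]), np.array([m]))[0]
    best = None  # (neg_gain, col, threshold)
    bin_cols = np.flatnonzero(kinds == 0)
    if bin_cols.size:
        Xb = X[np.ix_(rows, bin_cols)] > 0.5
        n_right = Xb.sum(axis=0)
        p_right = (Xb & y_r[:, None]).sum(axis=0)
        n_left = m - n_right
        p_left = n_pos - p_right
        feasible = (n_right >= min_leaf) & (n_left >= min_leaf)
        if feasible.any():
            child = (
                n_right * _gini_counts(p_right, n_right)
                + n_left * _gini_counts(p_left, n_left)
            ) / m
            gain = np.where(feasible, parent_gini - child, -np.inf)
            j = int(np.argmax(gain))  # first max = lowest column index
            if gain[j] > -np.inf:
                best = (gain[j], int(bin_cols[j]), 0.5)
    for c in np.flatnonzero(kinds == 1):
        v = X[rows, c]
        ok = ~np.isnan(v)
        if ok.sum() < 2 * min_leaf:
            continue
        vv = v[ok]
        yy = y_r[ok]
        order = np.argsort(vv, kind="stable")
        vs = vv[order]
        ys = yy[order]
        mm = vs.size
        pos_tot = int(ys.sum())
        cum_pos = np.cumsum(ys)
        # candidate cut after position i (0-based) where value changes
        cut = np.flatnonzero(vs[1:] > vs[:-1])
        if cut.size == 0:
            continue
        n_left = cut + 1
        n_right = mm - n_left
        feas = (n_left >= min_leaf) & (n_right >= min_leaf)
        if not feas.any():
            continue
        p_left = cum_pos[cut]
        p_right = pos_tot - p_left
        child = (
            n_left * _gini_counts(p_left, n_left)
            + n_right * _gini_counts(p_right, n_right)
        ) / mm
        gain = np.where(feas, _gini_counts(np.array([pos_tot]), np.array([mm]))[0] - child, -np.inf)
        j = int(np.argmax(gain))
        g = gain[j]
        if g == -np.inf:
            continue
        thr = 0.5 * (vs[cut[j]] + vs[cut[j] + 1])
        if best is None or g > best[0]:
            best = (g, c, float(thr))
    return best


def grow_tree(
    table: FeatureTable, labels, max_depth: int, min_leaf: int = 10
) -> DecisionTree:
    """Grow a greedy Gini decision tree (deterministic)."""
    if max_depth < 1:
        raise ParameterError("max_depth must be >= 1")
    if min_leaf < 1:
        raise ParameterError("min_leaf must be >= 1")
    y = as_binary_labels(labels)
    n = y.size
    if n < 2:
        raise FitError("need at least two examples")
    X = table.X
    kinds = np.array([0 if k == BINARY else 1 for k in table.column_kinds])

    def build(rows: np.ndarray, depth: int) -> TreeNode:
        n_pos = int(y[rows].sum())
        node = TreeNode(n_pos=n_pos, n_neg=rows.size - n_pos)
        if n_pos == 0 or n_pos == rows.size or depth >= max_depth:
            return node
        choice = _best_split(X, kinds, y, rows, min_leaf)
        if choice is None:
            return node
        _, col, thr = choice
        v = X[rows, col]
        missing = np.isnan(v)
        go_right = np.where(missing, False, v > thr)
        n_right_known = int(go_right[~missing].sum())
        n_left_known = int((~missing).sum()) - n_right_known
        missing_right = n_right_known >= n_left_known
        go_right = np.where(missing, missing_right, go_right)
        right_rows = rows[go_right]
        left_rows = rows[~go_right]
        if right_rows.size == 0 or left_rows.size == 0:
            return node
        node.feature = col
        node.kind = table.column_kinds[col]
        node.threshold = thr
        node.missing_goes_right = missing_right
        node.left = build(left_rows, depth + 1)
        node.right = build(right_rows, depth + 1)
        return node

    root = build(np.arange(n), 0)
    return DecisionTree(
        root=root,
        max_depth=max_depth,
        min_leaf=min_leaf,
        column_ids=list(table.column_ids),
        column_kinds=list(table.column_kinds),
    )


def predict_tree(tree: DecisionTree, row: np.ndarray) -> tuple[str, float]:
    """Route one feature row; returns (label, leaf majority fraction)."""
    nd = tree.root
    while not nd.is_leaf:
        v = row[nd.feature]
        if math.isnan(v):
            nd = nd.right if nd.missing_goes_right else nd.left
        else:
            nd = nd.right if v > nd.threshold else nd.left
    total = nd.n_pos + nd.n_neg
    if nd.n_pos >= nd.n_neg:
        return "inhibitor", nd.n_pos / total if total else 0.5
    return "non_inhibitor", nd.n_neg / total if total else 0.5


def predict_table(tree: DecisionTree, table: FeatureTable) -> list[str]:
    return [predict_tree(tree, table.X[i])[0] for i in range(table.X.shape[0])]


@dataclass
class DepthSweepResult:
    per_depth: dict[int, MetricsReport]
    confusions: dict[int, ConfusionCounts]
    selected_depth: int
    mode: str = "cv"


def tune_depth(
    table: FeatureTable,
    labels,
    depths: Sequence[int] = tuple(range(3, 21)),
    folds: int = 5,
    seed: int = 0,
    min_leaf: int = 10,
    test_table: FeatureTable | None = None,
    test_labels=None,
    mode: str = "cv",
) -> DepthSweepResult:
    """Depth sweep with stratified k-fold CV (default) or test-set selection.

    ``mode='cv'`` pools per-fold confusions at each depth and selects the
    depth maximizing Matthews C (ties -> smallest depth).  ``mode='test'``
    replicates selection on an external test set (leaky; for replication
    studies only).
    """
    y = as_binary_labels(labels)
    per_depth: dict[int, MetricsReport] = {}
    confusions: dict[int, ConfusionCounts] = {}
    if mode == "test":
        if test_table is None or test_labels is None:
            raise ParameterError("mode='test' requires test_table and test_labels")
        yt = as_binary_labels(test_labels)
        for depth in depths:
            tree = grow_tree(table, y, depth, min_leaf)
            pred = as_binary_labels(predict_table(tree, test_table))
            cc = ConfusionCounts.from_arrays(yt, pred)
            confusions[depth] = cc
            per_depth[depth] = compute_metrics(cc)
    elif mode == "cv":
        fold_ix = stratified_folds(y, folds, seed)
        for depth in depths:
            tp = fn = tn = fp = 0
            for k in range(folds):
                test_mask = np.zeros(y.size, dtype=bool)
                test_mask[fold_ix[k]] = True
                sub = FeatureTable(table.column_ids, table.column_kinds, table.X[~test_mask])
                tree = grow_tree(sub, y[~test_mask], depth, min_leaf)
                pred = np.array(
                    [predict_tree(tree, table.X[i])[0] == "inhibitor" for i in fold_ix[k]]
                )
                truth = y[fold_ix[k]]
                tp += int((pred & truth).sum())
                fn += int((~pred & truth).sum())
                tn += int((~pred & ~truth).sum())
                fp += int((pred & ~truth).sum())
            cc = ConfusionCounts(tp, fn, tn, fp)
            confusions[depth] = cc
            per_depth[depth] = compute_metrics(cc)
    else:
        raise ParameterError(f"unknown tune mode {mode!r}")
    selected = min(
        per_depth,
        key=lambda d: (-(per_depth[d].C if per_depth[d].C is not None else -2.0), d),
    )
    return DepthSweepResult(per_depth, confusions, selected, mode=mode)
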