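"""Time calibration of fossil trees and squared-change parsimony (SCP)
ancestral estimation of PC scores.

Calibration takes the fossil record at face value: each tip is fixed at its
taxon's midpoint age, and each internal node is placed as young as the
minimum-branch-length constraint allows (post-order, age = oldest child age
+ minimum branch length).  Hypothetical ancestors therefore fall in the
youngest time bin they could possibly occupy.

SCP estimates internal-node values by minimizing the sum of squared changes
along branches, optionally weighted by inverse branch length.  The weighted
form is the generalized-least-squares / Brownian-motion maximum-likelihood
reconstruction on the same tree; it is the default here because the tree is
explicitly time-calibrated.  The criterion is quadratic, so the exact
optimum is obtained from the linear system of its stationarity conditions;
polytomies need no special handling.
"""

from __future__ import annotations

from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "midpoint_age",
    "calibrate_tree",
    "node_ages",
    "internal_node_labels",
    "squared_change_parsimony",
    "ancestral_pc_scores",
    "SquaredChangeParsimony",
]


def midpoint_age(fad: float, lad: float) -> float:
    """Midpoint of a taxon's stratigraphic uncertainty range (Ma)."""
    if fad < lad:
        raise ValueError(f"fad {fad} < lad {lad}")
    return (fad + lad) / 2.0


def _label(node: dendropy.Node) -> str | None:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def _ensure_internal_labels(tree: dendropy.Tree) -> None:
    """Assign stable preorder labels node_1, node_2, ... where missing."""
    used = {_label(n) for n in tree if _label(n) is not None}
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if _label(node) is None:
            i += 1
            while f"node_{i}" in used:
                i += 1
            node.label = f"node_{i}"


def calibrate_tree(
    tree: dendropy.Tree,
    tip_ages: Mapping[str, float],
    min_bl: float = 0.1,
) -> dendropy.Tree:
    """Date every node from tip ages with a minimum branch length (Myr).

    Returns a clone of ``tree`` with a ``.age`` (Ma) on every node and edge
    lengths set to parent age minus child age.  Tips keep their assigned
    ages, so the tree is non-ultrametric.
    """
    if min_bl <= 0:
        raise ValueError("min_bl must be positive")
    tree = tree.clone(depth=1)
    _ensure_internal_labels(tree)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            taxon = node.taxon.label
            if taxon not in tip_ages:
                raise ValueError(f"tip {taxon!r} has no age")
            node.age = float(tip_ages[taxon])
        else:
            node.age = max(child.age + min_bl for child in node.child_nodes())
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age - node.age
    return tree


def node_ages(tree: dendropy.Tree) -> dict[str, float]:
    """Label -> age (Ma) for every node of a calibrated tree."""
    return {_label(n): float(n.age) for n in tree}


def internal_node_labels(tree: dendropy.Tree) -> list[str]:
    return [_label(n) for n in tree.preorder_node_iter() if not n.is_leaf()]


def _scp_solve(
    tree: dendropy.Tree, tip_values: np.ndarray, tip_index: dict[str, int], weighted: bool
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Exact SCP solution via the stationarity linear system.

    ``tip_values`` is tips x traits.  Returns (internal labels, internal
    values as nodes x traits, per-trait minimal cost).
    """
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    idx = {id(n): i for i, n in enumerate(internals)}
    n_int = len(internals)
    n_traits = tip_values.shape[1]
    A = np.zeros((n_int, n_int))
    b = np.zeros((n_int, n_traits))
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if weighted:
            length = node.edge.length
            if length is None or length <= 0:
                raise ValueError(
                    f"non-positive branch length above {_label(node)!r} in weighted mode"
                )
            w = 1.0 / length
        else:
            w = 1.0
        p = idx[id(node.parent_node)]
        A[p, p] += w
        if node.is_leaf():
            b[p] += w * tip_values[tip_index[node.taxon.label]]
        else:
            c = idx[id(node)]
            A[c, c] += w
            A[p, c] -= w
            A[c, p] -= w
    values = np.linalg.solve(A, b)
    # cost of the optimum
    cost = np.zeros(n_traits)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        w = (1.0 / node.edge.length) if weighted else 1.0
        parent_val = values[idx[id(node.parent_node)]]
        child_val = (
            tip_values[tip_index[node.taxon.label]]
            if node.is_leaf()
            else values[idx[id(node)]]
        )
        cost += w * (parent_val - child_val) ** 2
    labels = [_label(n) for n in internals]
    return labels, values, cost


def squared_change_parsimony(
    tree: dendropy.Tree,
    tip_values: Mapping[str, float],
    weighted: bool = True,
) -> tuple[dict[str, float], float]:
    """Single-trait SCP: internal node values and the minimal cost.

    Minimizes sum over branches of (change)^2 / length (weighted) or
    (change)^2 (unweighted); the optimum solves the linear stationarity
    system exactly.
    """
    tips = [n.taxon.label for n in tree.leaf_node_iter()]
    missing = [t for t in tips if t not in tip_values]
    if missing:
        raise ValueError(f"tips without values: {missing}")
    _ensure_internal_labels(tree)
    vals = np.array([[float(tip_values[t])] for t in tips])
    labels, values, cost = _scp_solve(tree, vals, {t: i for i, t in enumerate(tips)}, weighted)
    return dict(zip(labels, values[:, 0])), float(cost[0])


def ancestral_pc_scores(
    tree: dendropy.Tree,
    scores: pd.DataFrame,
    weighted: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """SCP applied independently to each PC column.

    ``scores`` is indexed by taxon (covering every tip).  Returns a frame of
    reconstructed values indexed by internal node label, and the per-column
    minimal costs.
    """
    tips = [n.taxon.label for n in tree.leaf_node_iter()]
    missing = [t for t in tips if t not in scores.index]
    if missing:
        raise ValueError(f"tips without scores: {missing}")
    _ensure_internal_labels(tree)
    vals = scores.loc[tips].to_numpy(dtype=float)
    labels, values, cost = _scp_solve(tree, vals, {t: i for i, t in enumerate(tips)}, weighted)
    return pd.DataFrame(values, index=labels, columns=scores.columns), cost


class SquaredChangeParsimony(BaseEstimator):
    """Ancestral state estimation as a fit/predict estimator.

    Parameters
    ----------
    weighted : bool, default True
        Inverse-branch-length weighting (the Brownian-motion GLS form).

    After ``fit(tree, scores)``:

    ancestral_scores_ : DataFrame
        Reconstructed values, indexed by internal node label.
    cost_ : ndarray
        Minimal squared-change cost per trait column.
    """

    def __init__(self, weighted: bool = True):
        self.weighted = weighted

    def fit(self, tree: dendropy.Tree, scores: pd.DataFrame):
        self.ancestral_scores_, self.cost_ = ancestral_pc_scores(
            tree, scores, weighted=self.weighted
        )
        return self

    def predict(self, node_labels=None) -> pd.DataFrame:
        """Reconstructed scores for the given internal nodes (all by default)."""
        if not hasattr(self, "ancestral_scores_"):
            raise ValueError("SquaredChangeParsimony is not fitted")
        if node_labels is None:
            return self.ancestral_scores_
        return self.ancestral_scores_.loc[list(node_labels)]
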