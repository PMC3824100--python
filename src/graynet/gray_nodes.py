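"""Overlapping modules via extended modularity over ternary assignments.

The bipartition quadratic form is maximised over vectors with entries in
{-1, 0, +1} instead of {-1, +1}.  Nodes assigned 0 in an accepted
division are *gray nodes*: they join both child modules at once (or, at
the top level, no module side exclusively).  The proportion of gray nodes
indexes the overlap in the modular architecture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .graph_core import Graph, TernaryVector
from .spectral_modularity import (
    DivisionNode,
    OptimizerSettings,
    _as_vector,
    _division_seed,
    leading_bipartition,
    modularity_matrix,
    subgraph_modularity_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GrayDecomposition",
    "ternary_score",
    "optimize_ternary",
    "brute_force_ternary",
    "recursive_divide_gray",
    "gray_proportion_curve",
]

#: exhaustive ternary enumeration refuses above this size (3^12 ~ 531k vectors)
TERNARY_BRUTE_FORCE_CAP = 12


@dataclass
class GrayDecomposition:
    """Result of recursive ternary division.

    ``modules`` may overlap: a node zeroed in an accepted division is
    passed to both children.  ``gray_nodes`` collects every node assigned
    0 in at least one accepted division; ``gray_by_level`` breaks the same
    sets down by recursion depth (level 0 = root division).
    """

    division_tree: DivisionNode
    modules: list
    gray_nodes: set
    q_threshold: float
    n_nodes: int
    gray_by_level: dict = field(default_factory=dict)

    @property
    def gray_proportion(self) -> float:
        return len(self.gray_nodes) / self.n_nodes if self.n_nodes else 0.0

    @property
    def n_modules(self) -> int:
        return len(self.modules)


def ternary_score(B, s_e) -> float:
    """``(1/4m) s_e^T B s_e`` for a ternary assignment; no maximisation.

    Restricted to {-1,+1} vectors this equals ``bipartition_score``
    exactly (sign vectors are a subset of ternary vectors).
    """
    v = _as_vector(s_e, B.n)
    return float(v @ B.matrix @ v) / (4.0 * B.m)


def _tie_key(values: np.ndarray):
    """Fewest zeros first, then lexicographically smallest."""
    return (int(np.sum(values == 0)), tuple(values.tolist()))


def _coordinate_descent(M: np.ndarray, s: np.ndarray, rng) -> np.ndarray:
    """Single-node {-1,0,+1} moves to a local maximum of s^T M s.

    Nodes are visited in a seeded random order each sweep; only strictly
    improving moves are taken, so the loop terminates.
    """
    s = s.astype(float).copy()
    n = len(s)
    grad = M @ s
    diag = np.diag(M)
    candidates = (1.0, -1.0, 0.0)
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            a = s[i]
            base = grad[i] - diag[i] * a
            best_b, best_gain = a, 0.0
            for b in candidates:
                if b == a:
                    continue
                gain = 2.0 * (b - a) * base + diag[i] * (b * b - a * a)
                if gain > best_gain + 1e-12:
                    best_b, best_gain = b, gain
            if best_b != a:
                grad += (best_b - a) * M[:, i]
                s[i] = best_b
                improved = True
    return s


def optimize_ternary(
    B,
    opt: OptimizerSettings = OptimizerSettings(),
    seed: int = 0,
):
    """Heuristic maximiser of the ternary quadratic form.

    The search starts from the best sign vector found by
    :func:`leading_bipartition` (so the result is never worse than it) and
    runs seeded coordinate descent over {-1,0,+1}; further restarts perturb
    the start.  Ties between equal-score vectors are broken by fewest
    zeros, then lexicographic order.  Deterministic given ``seed``.
    """
    M = B.matrix
    n = M.shape[0]
    s0, _ = leading_bipartition(B, opt, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence((abs(int(seed)), 0x7E12)))
    start = s0.values.astype(float)
    best_v = None
    best_score = -np.inf
    for r in range(opt.restarts):
        if r == 0:
            init = start
        else:  # perturb ~25% of the entries of the spectral start
            init = start.copy()
            mask = rng.random(n) < 0.25
            init[mask] = rng.choice((-1.0, 0.0, 1.0), size=int(mask.sum()))
        v = _coordinate_descent(M, init, rng)
        score = float(v @ M @ v) / (4.0 * B.m)
        iv = v.astype(np.int64)
        if score > best_score + 1e-12 or (
            abs(score - best_score) <= 1e-12
            and best_v is not None
            and _tie_key(iv) < _tie_key(best_v)
        ):
            best_v, best_score = iv, score
    return TernaryVector(best_v), best_score


def brute_force_ternary(B):
    """Exhaustive maximum of ``(1/4m) s_e^T B s_e`` over all 3^n ternary vectors.

    Ties broken by fewest zeros, then lexicographic order.  Refuses above
    ``TERNARY_BRUTE_FORCE_CAP`` nodes.
    """
    n = B.n
    if n > TERNARY_BRUTE_FORCE_CAP:
        raise InputError(f"ternary brute force capped at n = {TERNARY_BRUTE_FORCE_CAP} (got {n})")
    codes = np.arange(3**n, dtype=np.int64)
    digits = (codes[:, None] // (3 ** np.arange(n, dtype=np.int64))) % 3
    S = digits.astype(np.float64) - 1.0  # entries in {-1, 0, +1}
    scores = np.einsum("ij,ij->i", S @ B.matrix, S) / (4.0 * B.m)
    best = np.max(scores)
    tied = np.flatnonzero(scores >= best - 1e-12)
    vecs = S[tied].astype(np.int64)
    pick = min(range(len(tied)), key=lambda i: _tie_key(vecs[i]))
    return TernaryVector(vecs[pick]), float(scores[tied[pick]])


def recursive_divide_gray(
    g: Graph,
    q_threshold: float,
    opt: OptimizerSettings = OptimizerSettings(),
    seed: int = 0,
    gray_membership: str = "both",
) -> GrayDecomposition:
    """Recursive division optimising the ternary quadratic form.

    At an accepted division, nodes assigned 0 are recorded as gray and (by
    default) handed to *both* children, so child member sets may overlap;
    ``gray_membership="neither"`` drops them instead.  A division needs at
    least one +1 and one -1 node to be valid, which keeps children strictly
    smaller than their parent.
    """
    if q_threshold < 0:
        raise InputError("q_threshold must be >= 0")
    if gray_membership not in ("both", "neither"):
        raise InputError("gray_membership must be 'both' or 'neither'")
    B = modularity_matrix(g)
    gray: set = set()
    by_level: dict = {}
    root = _divide_gray(
        B, tuple(range(g.n)), q_threshold, opt, seed, True, gray_membership, gray, by_level, 0
    )
    modules = [set(node.members) for node in _gray_leaves(root)]
    return GrayDecomposition(root, modules, gray, q_threshold, g.n, by_level)


def _divide_gray(B, members, q_threshold, opt, seed, is_root, membership, gray, by_level, level):
    node = DivisionNode(members=members)
    if len(members) == 1:
        return node
    matrix = B if is_root else subgraph_modularity_matrix(B, members)
    s_e, contribution = optimize_ternary(matrix, opt, seed=_division_seed(seed, members))
    vals = s_e.values
    idx = np.asarray(members)
    has_plus = bool(np.any(vals > 0))
    has_minus = bool(np.any(vals < 0))
    if contribution < q_threshold or not has_plus or not has_minus:
        return node  # indivisible (the all-zero vector is never a valid division)
    zeros = idx[vals == 0]
    gray.update(int(i) for i in zeros)
    by_level.setdefault(level, set()).update(int(i) for i in zeros)
    if membership == "both":
        plus = tuple(idx[vals >= 0].tolist())
        minus = tuple(idx[vals <= 0].tolist())
    else:
        plus = tuple(idx[vals > 0].tolist())
        minus = tuple(idx[vals < 0].tolist())
    node.contribution = contribution
    node.assignment = vals
    node.children = [
        _divide_gray(B, plus, q_threshold, opt, seed, False, membership, gray, by_level, level + 1),
        _divide_gray(B, minus, q_threshold, opt, seed, False, membership, gray, by_level, level + 1),
    ]
    return node


def _gray_leaves(root: DivisionNode):
    stack, out = [root], []
    while stack:
        node = stack.pop()
        if node.is_leaf:
            out.append(node)
        else:
            stack.extend(reversed(node.children))
    return out


def _gray_pruned(node: DivisionNode, threshold: float, acc: set):
    """Collect gray nodes of divisions that survive pruning at ``threshold``."""
    if node.is_leaf or node.contribution < threshold:
        return 1
    vals = node.assignment
    idx = np.asarray(node.members)
    acc.update(int(i) for i in idx[vals == 0])
    return sum(_gray_pruned(c, threshold, acc) for c in node.children)


def gray_proportion_curve(
    g: Graph,
    thresholds,
    opt: OptimizerSettings = OptimizerSettings(),
    seed: int = 0,
):
    """Gray-node proportion (and module count) at each ascending threshold.

    Computed by building the full ternary division tree once at the
    smallest threshold and pruning, exactly as
    :func:`~graynet.spectral_modularity.module_count_curve`.  Returns a
    list of ``(gray_proportion, module_count)`` pairs aligned with
    ``thresholds``.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise InputError("thresholds must be sorted ascending")
    deco = recursive_divide_gray(g, min(thresholds), opt=opt, seed=seed)
    out = []
    for t in thresholds:
        acc: set = set()
        count = _gray_pruned(deco.division_tree, t, acc)
        out.append((len(acc) / g.n if g.n else 0.0, count))
    return out
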