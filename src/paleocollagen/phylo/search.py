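"""Maximum-likelihood tree search by nearest-neighbour interchange, with
nonparametric bootstrap support.

The search starts from a neighbour-joining tree on p-distances (pairwise
deletion of missing sites), then repeatedly evaluates both NNI alternatives
at every internal edge, applies the best strictly-improving swap and
re-optimises branch lengths, until no swap improves the log likelihood. The
procedure is deterministic given its inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .likelihood import Alignment, TreeLikelihood
from .model import SubstitutionModel
from .tree import Node, Tree, nj_tree

logger = logging.getLogger(__name__)


@dataclass
class SearchResult:
    tree: Tree
    log_likelihood: float
    n_swaps: int


def nj_start_tree(alignment: Alignment,
                  pattern_weights: np.ndarray | None = None) -> Tree:
    """Neighbour-joining start tree on pairwise-deletion p-distances.

    Distances are computed over compressed site patterns so bootstrap
    replicates (which reweight patterns) get a matching start tree.
    """
    from .likelihood import MISSING_CODE

    w = alignment.pattern_weights if pattern_weights is None else pattern_weights
    pats = alignment.patterns  # (ntaxa, npatterns)
    n = len(alignment.taxa)
    d = np.zeros((n, n))
    observed = pats != MISSING_CODE
    for i in range(n):
        for j in range(i + 1, n):
            both = observed[i] & observed[j]
            total = float(w[both].sum())
            if total == 0:
                d[i, j] = d[j, i] = 0.75  # no overlap: maximally uninformative
                continue
            diff = float(w[both & (pats[i] != pats[j])].sum())
            d[i, j] = d[j, i] = diff / total
    return nj_tree(d, list(alignment.taxa))


def _nni_candidates(tree: Tree):
    """Yield (node, child_index) pairs describing the two NNI alternatives
    per internal edge: swap the node's child with a fixed sibling subtree."""
    for node in tree.postorder():
        if node.is_leaf or node.parent is None:
            continue
        if len(node.children) != 2:
            continue
        yield (node, 0)
        yield (node, 1)


def _apply_nni(node: Node, child_index: int) -> None:
    """Swap ``node.children[child_index]`` with a sibling subtree at the
    parent. Branch lengths travel with their subtrees."""
    parent = node.parent
    sibling = next(c for c in parent.children if c is not node)
    child = node.children[child_index]
    node.children[child_index] = sibling
    sibling.parent = node
    idx = parent.children.index(sibling)
    parent.children[idx] = child
    child.parent = parent


def nni_search(
    start_tree: Tree,
    alignment: Alignment,
    model: SubstitutionModel,
    pattern_weights: np.ndarray | None = None,
    candidate_sweeps: int = 2,
    loglik_tol: float = 1e-4,
    max_iterations: int = 50,
    xtol: float = 1e-6,
) -> SearchResult:
    """Hill-climb over NNI rearrangements to a local maximum-likelihood tree.

    Candidate swaps are scored with a few branch-length sweeps
    (``candidate_sweeps``); the accepted tree is then fully re-optimised.
    Trees with fewer than four taxa are returned after branch-length
    optimisation only (no rearrangement exists).
    """
    tree = start_tree.copy()
    tree.unroot()
    calc = TreeLikelihood(tree, alignment, model, pattern_weights=pattern_weights)
    best = calc.optimize_branch_lengths(xtol=xtol, loglik_tol=loglik_tol)
    if len(tree.leaves()) < 4:
        return SearchResult(tree, best, 0)
    n_swaps = 0
    for _ in range(max_iterations):
        best_candidate = None
        best_score = best
        for node, child_index in _nni_candidates(tree):
            _apply_nni(node, child_index)
            calc.invalidate()
            trial = TreeLikelihood(
                tree.copy(), alignment, model, pattern_weights=pattern_weights
            )
            # candidates are scored with loose tolerances; the accepted tree
            # is re-optimised at full precision below
            score = trial.optimize_branch_lengths(max_sweeps=candidate_sweeps,
                                                  xtol=1e-3)
            _apply_nni(node, child_index)  # revert (swap is an involution)
            calc.invalidate()
            if score > best_score + loglik_tol:
                best_score = score
                best_candidate = (node, child_index)
        if best_candidate is None:
            break
        _apply_nni(*best_candidate)
        calc.invalidate()
        best = calc.optimize_branch_lengths(xtol=xtol, loglik_tol=loglik_tol)
        n_swaps += 1
        logger.debug("accepted NNI swap %d, logL %.4f", n_swaps, best)
    return SearchResult(tree, best, n_swaps)


def ml_pipeline(
    alignment: Alignment,
    model: SubstitutionModel,
    optimize_params: bool = True,
    pattern_weights: np.ndarray | None = None,
) -> tuple[SearchResult, SubstitutionModel]:
    """NJ start, optional model-parameter fitting, NNI search."""
    start = nj_start_tree(alignment)
    if optimize_params:
        calc = TreeLikelihood(start.copy(), alignment, model,
                              pattern_weights=pattern_weights)
        previous = -np.inf
        for _ in range(4):  # alternate until the joint fit stabilises
            calc.optimize_branch_lengths()
            current = calc.optimize_model()
            if current - previous < 0.01:
                break
            previous = current
        model = calc.model
    result = nni_search(start, alignment, model, pattern_weights=pattern_weights)
    return result, model


def bootstrap_support(
    alignment: Alignment,
    model: SubstitutionModel,
    n_reps: int = 100,
    seed: int = 0,
    ml_tree: Tree | None = None,
    candidate_sweeps: int = 1,
) -> Tree:
    """Nonparametric bootstrap: resample sites, re-search, map split
    frequencies (percent) onto the full-data ML tree.

    With a fixed ``seed`` the supports are reproducible; the replicate
    searches use the supplied model parameters unchanged.
    """
    if n_reps < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    if ml_tree is None:
        ml_tree = nni_search(nj_start_tree(alignment), alignment, model).tree
    counts: dict[frozenset, int] = {}
    for rep in range(n_reps):
        weights = alignment.bootstrap_weights(rng)
        start = nj_start_tree(alignment, pattern_weights=weights)
        # replicate searches only need the topology, so loose tolerances
        result = nni_search(start, alignment, model, pattern_weights=weights,
                            candidate_sweeps=candidate_sweeps,
                            xtol=1e-3, loglik_tol=1e-2)
        for split in result.tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    out = ml_tree.copy()
    all_labels = frozenset(out.leaf_labels())
    for node in out.postorder():
        if node.is_leaf or node.parent is None:
            continue
        side = frozenset(l.label for l in node.postorder() if l.is_leaf)
        other = all_labels - side
        if len(side) < 2 or len(other) < 2:
            continue
        key = min(side, other, key=lambda s: (len(s), sorted(s)))
        node.support = 100.0 * counts.get(key, 0) / n_reps
    return out
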