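"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from paleocollagen.phylo import Alignment, SubstitutionModel, Tree
from paleocollagen.phylo.jtt import AA_ORDER


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def jtt_model():
    return SubstitutionModel.jtt(alpha=0.7, p_inv=0.2, k=4)


def enumeration_log_likelihood(tree: Tree, alignment: Alignment,
                               model: SubstitutionModel) -> float:
    """Independent likelihood oracle: exhaustive sum over internal-node states.

    Evaluates the +I+G mixture directly from its definition, without any
    pruning recursion: for every site and rate category, sums the joint
    probability over all assignments of the 20 states to internal nodes.
    Only feasible for tiny trees; that is the point.
    """
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    leaves = [n for n in nodes if n.is_leaf]
    rates = model.category_rates
    pi = model.frequencies
    row = {t: i for i, t in enumerate(alignment.taxa)}
    codes = alignment.codes
    n_internal = len(internals)
    internal_index = {id(n): i for i, n in enumerate(internals)}
    assignments = np.array(
        list(itertools.product(range(20), repeat=n_internal)), dtype=np.intp
    )  # (n_comb, n_internal)
    root_states = assignments[:, internal_index[id(tree.root)]]
    trans_by_cat = [
        {id(n): model.transition_matrix(n.length, rates[c])
         for n in nodes if n.parent is not None}
        for c in range(model.k)
    ]
    total = 0.0
    for site in range(alignment.n_sites):
        var_like = 0.0
        for c in range(model.k):
            trans = trans_by_cat[c]
            prob = pi[root_states].copy()
            for n in nodes:
                if n.parent is None:
                    continue
                parent_states = assignments[:, internal_index[id(n.parent)]]
                if n.is_leaf:
                    code = codes[row[n.label], site]
                    if code < 20:
                        prob *= trans[id(n)][parent_states, code]
                else:
                    child_states = assignments[:, internal_index[id(n)]]
                    prob *= trans[id(n)][parent_states, child_states]
            var_like += prob.sum() / model.k
        observed = [codes[row[l.label], site] for l in leaves]
        observed = [o for o in observed if o < 20]
        if not observed:
            inv = 1.0
        elif all(o == observed[0] for o in observed):
            inv = pi[observed[0]]
        else:
            inv = 0.0
        site_like = model.p_inv * inv + (1.0 - model.p_inv) * var_like
        total += np.log(site_like)
    return float(total)


def random_tiny_tree(rng: np.random.Generator, n_taxa: int) -> Tree:
    """A random unrooted topology (trifurcating root) with random lengths."""
    from paleocollagen.phylo.tree import Node

    labels = [chr(ord("A") + i) for i in range(n_taxa)]
    rng.shuffle(labels)
    nodes = [Node(label=l, length=float(rng.uniform(0.01, 0.8))) for l in labels]
    while len(nodes) > 3:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes))))
        parent = Node(length=float(rng.uniform(0.01, 0.5)))
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    root = Node()
    for n in nodes:
        root.add_child(n)
    return Tree(root)


def random_tiny_alignment(rng: np.random.Generator, taxa: list[str],
                          n_sites: int, missing_prob: float = 0.25) -> Alignment:
    """Random amino-acid alignment with X/?/- missing symbols mixed in."""
    seqs = {}
    missing_symbols = "X?-"
    for t in taxa:
        chars = []
        for _ in range(n_sites):
            if rng.random() < missing_prob:
                chars.append(missing_symbols[int(rng.integers(3))])
            else:
                chars.append(AA_ORDER[int(rng.integers(20))])
        seqs[t] = "".join(chars)
    return Alignment(seqs)
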