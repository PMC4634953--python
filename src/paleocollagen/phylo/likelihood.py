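"""Felsenstein pruning likelihood for amino-acid alignments with missing data.

Partial consensus sequences are mostly gaps and X characters; all of
X / ? / - (and any other non-standard letter) are treated as fully missing
states whose conditional likelihood vector is all ones. Site patterns are
compressed once; per-pattern scaling keeps partial likelihoods in range on
larger trees. Branch lengths are optimised one edge at a time with Brent's
method against cached partial likelihoods above and below the edge, which
makes each one-dimensional evaluation O(patterns x 400) instead of a full
tree traversal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .model import SubstitutionModel, N_STATES
from .tree import Node, Tree
from . import jtt

MISSING_CODE = N_STATES
_AA_INDEX = {aa: i for i, aa in enumerate(jtt.AA_ORDER)}

_TINY = 1e-300


class LikelihoodError(ValueError):
    pass


class Alignment:
    """Taxa-by-sites character matrix with compressed site patterns.

    Characters outside the 20 standard amino acids (X, ?, -, etc.) are
    missing data. ``weights`` are per-site multiplicities, used directly for
    nonparametric bootstrap resampling.
    """

    def __init__(self, sequences: dict[str, str], weights: np.ndarray | None = None):
        if not sequences:
            raise LikelihoodError("empty alignment")
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise LikelihoodError("sequences must have equal aligned length")
        self.taxa = list(sequences)
        (self.n_sites,) = lengths
        if self.n_sites == 0:
            raise LikelihoodError("alignment has zero sites")
        codes = np.empty((len(self.taxa), self.n_sites), dtype=np.int8)
        for row, taxon in enumerate(self.taxa):
            codes[row] = [_AA_INDEX.get(ch.upper(), MISSING_CODE)
                          for ch in sequences[taxon]]
        self.codes = codes
        if weights is None:
            weights = np.ones(self.n_sites)
        self.site_weights = np.asarray(weights, dtype=float)
        patterns, inverse, counts = np.unique(
            codes.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns.T  # (ntaxa, npatterns)
        self.pattern_weights = np.bincount(
            inverse, weights=self.site_weights, minlength=patterns.shape[0]
        )
        self.pattern_of_site = inverse
        self.n_patterns = patterns.shape[0]

    def subset(self, taxa: list[str]) -> "Alignment":
        seqs = {}
        for t in taxa:
            row = self.codes[self.taxa.index(t)]
            seqs[t] = "".join(
                jtt.AA_ORDER[c] if c < N_STATES else "X" for c in row
            )
        return Alignment(seqs, weights=self.site_weights)

    def bootstrap_weights(self, rng: np.random.Generator) -> np.ndarray:
        """Pattern weights after resampling sites with replacement."""
        total = int(round(self.site_weights.sum()))
        probs = self.pattern_weights / self.pattern_weights.sum()
        return rng.multinomial(total, probs).astype(float)


def _leaf_partial(codes: np.ndarray) -> np.ndarray:
    """(npatterns, 20) conditional likelihoods for one leaf."""
    npat = codes.shape[0]
    partial = np.zeros((npat, N_STATES))
    observed = codes < N_STATES
    partial[observed, codes[observed]] = 1.0
    partial[~observed, :] = 1.0
    return partial


class TreeLikelihood:
    """Likelihood machinery bound to one (tree, alignment, model) triple.

    The tree is modified in place by the optimisers; the topology must not
    be altered externally while an instance is alive unless
    :meth:`invalidate` is called.
    """

    def __init__(self, tree: Tree, alignment: Alignment, model: SubstitutionModel,
                 pattern_weights: np.ndarray | None = None):
        missing = set(l.label for l in tree.leaves()) - set(alignment.taxa)
        if missing:
            raise LikelihoodError(f"tree leaves absent from alignment: {sorted(missing)}")
        self.tree = tree
        self.alignment = alignment
        self.model = model
        self.pattern_weights = (
            alignment.pattern_weights if pattern_weights is None
            else np.asarray(pattern_weights, dtype=float)
        )
        self._leaf_partials = {}
        for leaf in tree.leaves():
            row = alignment.taxa.index(leaf.label)
            self._leaf_partials[id(leaf)] = _leaf_partial(alignment.patterns[row])
        self._invariant = self._invariant_pattern_likelihood()
        self.invalidate()

    # -- bookkeeping -------------------------------------------------------

    def invalidate(self) -> None:
        """Drop cached partials (call after any external topology change)."""
        self._down: dict[int, np.ndarray] = {}
        self._down_scale: dict[int, np.ndarray] = {}

    def set_model(self, model: SubstitutionModel) -> None:
        self.model = model
        self.invalidate()

    def _invariant_pattern_likelihood(self) -> np.ndarray:
        """Per-pattern probability under the invariant-sites component.

        A pattern is compatible with constancy iff all observed characters
        agree; its likelihood is the stationary frequency of that character
        (or one if every taxon is missing).
        """
        rows = [self.alignment.taxa.index(l.label) for l in self.tree.leaves()]
        pats = self.alignment.patterns[rows]  # leaves x npatterns
        pi = self.model.frequencies
        out = np.zeros(self.alignment.n_patterns)
        for p in range(self.alignment.n_patterns):
            col = pats[:, p]
            observed = col[col < N_STATES]
            if observed.size == 0:
                out[p] = 1.0
            elif np.all(observed == observed[0]):
                out[p] = pi[observed[0]]
        return out

    # -- core passes -------------------------------------------------------

    def _transition_stack(self, t: float) -> np.ndarray:
        """(k, 20, 20) transition matrices for one edge across rate categories."""
        rates = self.model.category_rates
        return np.stack([self.model.transition_matrix(t, r) for r in rates])

    def _message(self, node: Node) -> tuple[np.ndarray, np.ndarray]:
        """Contribution of ``node``'s subtree through its parent edge:
        (k, npat, 20) array and (npat,) log-scaler."""
        down, scale = self._down_partial(node)
        p = self._transition_stack(node.length)
        msg = down @ p.transpose(0, 2, 1)
        return msg, scale

    def _down_partial(self, node: Node) -> tuple[np.ndarray, np.ndarray]:
        key = id(node)
        if key in self._down:
            return self._down[key], self._down_scale[key]
        if node.is_leaf:
            leaf = self._leaf_partials[key]
            k = self.model.k
            down = np.broadcast_to(leaf, (k, *leaf.shape)).copy()
            scale = np.zeros(leaf.shape[0])
        else:
            down = None
            scale = np.zeros(self.alignment.n_patterns)
            for child in node.children:
                msg, child_scale = self._message(child)
                down = msg if down is None else down * msg
                scale = scale + child_scale
            # rescale per pattern to keep products in range
            peak = down.max(axis=(0, 2))
            mask = peak > 0
            factor = np.ones_like(peak)
            factor[mask] = peak[mask]
            down = down / factor[None, :, None]
            scale = scale + np.log(np.where(mask, factor, 1.0))
        self._down[key] = down
        self._down_scale[key] = scale
        return down, scale

    def _site_log_likelihoods(self) -> np.ndarray:
        """Per-pattern log likelihood combining gamma and invariant parts."""
        root = self.tree.root
        down, scale = self._down_partial(root)
        pi = self.model.frequencies
        var = (down @ pi).mean(axis=0)  # mean over categories
        return self._combine(var, scale)

    def _combine(self, var: np.ndarray, scale: np.ndarray) -> np.ndarray:
        p_inv = self.model.p_inv
        if p_inv > 0:
            inv = self._invariant
            # site L = p_inv*inv + (1-p_inv)*var*exp(scale); pull scale out
            with np.errstate(over="ignore"):
                shifted_inv = inv * np.exp(np.clip(-scale, None, 700.0))
            core = (1.0 - p_inv) * var + p_inv * shifted_inv
        else:
            core = var
        return scale + np.log(np.maximum(core, _TINY))

    def log_likelihood(self) -> float:
        return float(self._site_log_likelihoods() @ self.pattern_weights)

    def site_log_likelihoods(self) -> np.ndarray:
        """Per-site (not per-pattern) log likelihoods, in input site order."""
        per_pattern = self._site_log_likelihoods()
        return per_pattern[self.alignment.pattern_of_site]

    # -- branch-length optimisation ---------------------------------------

    def _edge_log_likelihood(self, above: np.ndarray, above_scale: np.ndarray,
                             below: np.ndarray, below_scale: np.ndarray,
                             t: float) -> float:
        p = self._transition_stack(t)
        var = ((above @ p) * below).sum(axis=2).mean(axis=0)
        site = self._combine(var, above_scale + below_scale)
        return float(site @ self.pattern_weights)

    def optimize_branch_lengths(self, min_length: float = 1e-8,
                                max_length: float = 20.0,
                                xtol: float = 1e-6,
                                loglik_tol: float = 1e-4,
                                max_sweeps: int = 20) -> float:
        """Iterative per-edge Brent optimisation; returns the final log
        likelihood. The log likelihood never decreases."""
        previous = self.log_likelihood()
        for _ in range(max_sweeps):
            self._sweep(min_length, max_length, xtol)
            current = self.log_likelihood()
            if current - previous < loglik_tol:
                break
            previous = current
        return self.log_likelihood()

    def _sweep(self, min_length: float, max_length: float, xtol: float) -> None:
        self.invalidate()
        root = self.tree.root
        self._down_partial(root)
        k = self.model.k
        npat = self.alignment.n_patterns
        pi = self.model.frequencies
        root_above = np.broadcast_to(
            pi, (k, npat, N_STATES)
        ).copy()
        stack = [(child, root_above, np.zeros(npat)) for child in root.children]
        # depth-first; each child's "above" uses already-updated ancestor edges
        while stack:
            node, parent_above, parent_scale = stack.pop()
            above = parent_above
            above_scale = parent_scale.copy()
            for sibling in node.parent.children:
                if sibling is node:
                    continue
                msg, s = self._message(sibling)
                above = above * msg
                above_scale = above_scale + s
            peak = above.max(axis=(0, 2))
            mask = peak > 0
            factor = np.where(mask, peak, 1.0)
            above = above / factor[None, :, None]
            above_scale = above_scale + np.log(factor)
            below, below_scale = self._down_partial(node)
            current = self._edge_log_likelihood(
                above, above_scale, below, below_scale, node.length
            )
            res = minimize_scalar(
                lambda t: -self._edge_log_likelihood(
                    above, above_scale, below, below_scale, t
                ),
                bounds=(min_length, max_length),
                method="bounded",
                options={"xatol": xtol},
            )
            if -res.fun > current:
                node.length = float(res.x)
            if not node.is_leaf:
                p = self._transition_stack(node.length)
                child_above = above @ p
                for child in node.children:
                    stack.append((child, child_above, above_scale))
        self.invalidate()

    # -- model parameter optimisation -------------------------------------

    def optimize_model(self, alpha_bounds=(0.05, 20.0), p_inv_bounds=(0.0, 0.8),
                       xtol: float = 1e-4) -> float:
        """Joint fit of gamma shape and invariant proportion.

        The two parameters are strongly correlated (a small alpha mimics a
        larger invariant fraction), leaving a narrow likelihood ridge on
        which one-parameter-at-a-time updates stall; a Nelder-Mead simplex
        over (log alpha, p_inv) follows the ridge instead. Likelihood is
        non-decreasing: the optimum is only adopted if it improves on the
        current parameter values.
        """
        from scipy.optimize import minimize

        start_alpha, start_p_inv = self.model.alpha, self.model.p_inv
        current = self.log_likelihood()

        def clipped(x) -> tuple[float, float]:
            alpha = float(np.clip(np.exp(x[0]), *alpha_bounds))
            p_inv = float(np.clip(x[1], *p_inv_bounds))
            return alpha, p_inv

        def objective(x):
            alpha, p_inv = clipped(x)
            self.set_model(self.model.with_params(alpha=alpha, p_inv=p_inv))
            return -self.log_likelihood()

        res = minimize(objective, [np.log(start_alpha), start_p_inv],
                       method="Nelder-Mead",
                       options={"xatol": xtol, "fatol": 1e-6})
        if -res.fun > current:
            alpha, p_inv = clipped(res.x)
            self.set_model(self.model.with_params(alpha=alpha, p_inv=p_inv))
        else:
            self.set_model(self.model.with_params(alpha=start_alpha,
                                                  p_inv=start_p_inv))
        return self.log_likelihood()
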