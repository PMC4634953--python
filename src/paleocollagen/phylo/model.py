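"""Amino-acid substitution model: JTT exchangeabilities with invariant sites
and discrete-gamma rate heterogeneity.

The rate matrix is Q = S diag(pi) with rows forced to sum to zero and scaled
so the expected substitution rate at stationarity is one, making branch
lengths expected substitutions per site. Rate heterogeneity follows the
usual +I+G parameterisation: a proportion ``p_inv`` of sites never change,
the remainder draw a relative rate from a mean-one gamma distribution with
shape ``alpha`` discretised into ``k`` equal-probability categories (the
category rate is the conditional mean of its bin). Because invariant sites
absorb probability mass, gamma rates are rescaled by 1/(1 - p_inv) so the
overall mean rate stays exactly one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special, stats

from . import jtt

N_STATES = 20


class ModelError(ValueError):
    pass


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean-of-bin discretisation of the mean-one gamma rate distribution.

    The gamma(alpha, 1/alpha) density is cut into ``k`` equal-probability
    bins; each category's rate is the conditional mean of its bin, computed
    in closed form from the regularised incomplete gamma function. The
    returned rates average to one exactly.
    """
    if alpha <= 0:
        raise ModelError("gamma shape alpha must be positive")
    if k < 1:
        raise ModelError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    # Bin boundaries on the rate axis; Gamma(shape=alpha, scale=1/alpha).
    probs = np.arange(1, k) / k
    cuts = stats.gamma.ppf(probs, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], cuts, [np.inf]])
    # E[X | a<X<b] * P(a<X<b) = gammainc(alpha+1, b*alpha) - gammainc(alpha+1, a*alpha)
    upper = special.gammainc(alpha + 1, np.where(np.isinf(edges), np.inf, edges * alpha))
    mass = np.diff(upper)  # integral of x*f(x) over each bin, mean 1 overall
    rates = mass * k
    return rates / rates.mean()  # exact renormalisation against ppf round-off


@dataclass
class SubstitutionModel:
    """JTT(+F)+I+G model specification and derived linear algebra."""

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    p_inv: float = 0.0
    alpha: float = 1.0
    k: int = 4

    def __post_init__(self):
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.exchangeabilities.shape != (N_STATES, N_STATES):
            raise ModelError("exchangeability matrix must be 20x20")
        if not np.allclose(self.exchangeabilities, self.exchangeabilities.T):
            raise ModelError("exchangeability matrix must be symmetric")
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ModelError("frequencies must sum to 1 within 1e-12")
        if np.any(self.frequencies <= 0):
            raise ModelError("frequencies must be strictly positive")
        if not (0.0 <= self.p_inv < 1.0):
            raise ModelError("p_inv must lie in [0, 1)")
        if self.alpha <= 0:
            raise ModelError("alpha must be positive")
        self._build()

    @classmethod
    def jtt(cls, alpha: float = 1.0, p_inv: float = 0.0, k: int = 4,
            frequencies: np.ndarray | None = None) -> "SubstitutionModel":
        """The JTT model with its own published frequencies (pass
        ``frequencies`` for a +F variant with empirical frequencies)."""
        freqs = jtt.JTT_FREQUENCIES if frequencies is None else np.asarray(frequencies)
        freqs = freqs / freqs.sum()
        return cls(jtt.exchangeability_matrix(), freqs, p_inv=p_inv, alpha=alpha, k=k)

    def with_params(self, alpha: float | None = None, p_inv: float | None = None
                    ) -> "SubstitutionModel":
        return replace(
            self,
            alpha=self.alpha if alpha is None else alpha,
            p_inv=self.p_inv if p_inv is None else p_inv,
        )

    def _build(self) -> None:
        pi = self.frequencies
        q = self.exchangeabilities * pi[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()  # mean rate at stationarity
        q /= mu
        self.rate_matrix = q
        # Symmetrised form diag(sqrt pi) Q diag(1/sqrt pi) has a real spectrum
        # for any reversible Q; eigendecompose once and exponentiate cheaply.
        sqrt_pi = np.sqrt(pi)
        sym = sqrt_pi[:, None] * q / sqrt_pi[None, :]
        eigval, eigvec = np.linalg.eigh((sym + sym.T) / 2.0)
        self._eigval = eigval
        self._left = eigvec / sqrt_pi[:, None]      # diag(1/sqrt pi) U
        self._right = (eigvec * sqrt_pi[:, None]).T  # U^T diag(sqrt pi)
        rates = discrete_gamma_rates(self.alpha, self.k)
        if self.p_inv > 0:
            rates = rates / (1.0 - self.p_inv)
        self._category_rates = rates

    @property
    def category_rates(self) -> np.ndarray:
        """Rates of the variable-site categories after the 1/(1-p_inv) rescale."""
        return self._category_rates

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q t rate); rows sum to one."""
        if t < 0:
            raise ModelError("branch length must be non-negative")
        p = (self._left * np.exp(self._eigval * t * rate)) @ self._right
        np.clip(p, 0.0, None, out=p)
        return p
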