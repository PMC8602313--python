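"""Coverage-dependent beta-binomial model of MDA allelic amplification bias.

Multiple displacement amplification (MDA) of the DNA of a single diploid
cell amplifies the two alleles of a site unevenly, up to the complete
dropout of one allele.  The observable alternative-read fraction
``rho_s = k / l`` at a site covered by ``l`` reads is therefore a distorted
measurement of the true underlying allele frequency
``theta_s in {0, 1/2, 1}``.  This module provides the distortion
distributions ``P(rho_s = k/l | theta_s)``:

* homozygous reference (``theta_s = 0``): a single beta-binomial
  ``BB(k, l; alpha(l), beta(l))`` whose mass away from ``k = 0`` captures
  amplified copy errors of the Phi29 polymerase;
* heterozygous (``theta_s = 1/2``): a two-component mixture of symmetric
  beta-binomials ``w(l) BB(k, l; a1(l), a1(l)) + (1-w(l)) BB(k, l; a2(l),
  a2(l))`` which peaks at the extreme counts ``k = 0`` and ``k = l`` --
  exactly the allele-dropout phenomenon;
* homozygous alternative (``theta_s = 1``): the ``theta_s = 0`` case with
  the shape parameters swapped.

All five shape/weight parameters scale linearly with the site coverage
``l``, so the amount of distortion the model expects varies locally along
the genome with the observed coverage.  The linear coefficients are
empirical constants derived from MDA single-neuron sequencing data; they
are kept in :data:`BIAS_COEFFICIENTS` as the single canonical copy.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy.special import betaln, gammaln, logsumexp

__all__ = [
    "BIAS_COEFFICIENTS",
    "SHAPE_FLOOR",
    "THETA_S_VALUES",
    "BiasParams",
    "bias_params",
    "beta_binomial_logpmf",
    "beta_binomial_pmf",
    "sc_freq_log_pmf",
    "sc_freq_likelihood",
]

#: ``parameter -> (slope, intercept)`` of the linear coverage scaling of the
#: amplification-bias model.  ``alpha``/``beta`` shape the homozygous
#: beta-binomial, ``alpha1``/``alpha2`` the two symmetric heterozygous
#: components, and ``w`` is the heterozygous mixture weight.
BIAS_COEFFICIENTS: dict[str, tuple[float, float]] = {
    "alpha": (-0.00003, 0.06857),
    "beta": (0.00745, 2.36749),
    "w": (0.00055, 0.54040),
    "alpha1": (0.05738, 0.66973),
    "alpha2": (0.00323, 0.39926),
}

#: Lower clamp for beta-binomial shape parameters.  The linear scaling of
#: ``alpha`` has a negative slope and crosses zero near l ~ 2285; shapes
#: must stay positive.
SHAPE_FLOOR: float = 1e-6

#: The three admissible true allele frequencies of a diploid cell.
THETA_S_VALUES: tuple[Fraction, ...] = (Fraction(0), Fraction(1, 2), Fraction(1))


@dataclass(frozen=True)
class BiasParams:
    """Amplification-bias parameters evaluated at one site coverage ``l``."""

    l: int
    alpha: float
    beta: float
    w: float
    alpha1: float
    alpha2: float


def bias_params(l: int) -> BiasParams:
    """Evaluate the linear coverage scaling of all bias parameters at ``l``.

    Shapes are floored at :data:`SHAPE_FLOOR` and the mixture weight is
    clipped to ``[0, 1]``; outside those ranges the linear extrapolation is
    not a valid distribution parameter.
    """
    if l < 0 or int(l) != l:
        raise ValueError(f"coverage l must be a non-negative integer, got {l!r}")
    l = int(l)

    def line(name: str) -> float:
        slope, intercept = BIAS_COEFFICIENTS[name]
        return slope * l + intercept

    return BiasParams(
        l=l,
        alpha=max(line("alpha"), SHAPE_FLOOR),
        beta=max(line("beta"), SHAPE_FLOOR),
        w=min(max(line("w"), 0.0), 1.0),
        alpha1=max(line("alpha1"), SHAPE_FLOOR),
        alpha2=max(line("alpha2"), SHAPE_FLOOR),
    )


def beta_binomial_logpmf(k, l: int, a: float, b: float):
    """Log beta-binomial mass ``log BB(k, l; a, b)``.

    Evaluated with log-gamma throughout so that high coverages do not
    underflow.  ``k`` may be a scalar or an integer array.
    """
    if a <= 0 or b <= 0:
        raise ValueError(f"beta-binomial shapes must be positive, got a={a}, b={b}")
    k = np.asarray(k)
    if np.any(k < 0) or np.any(k > l):
        raise ValueError("require 0 <= k <= l")
    out = (
        gammaln(l + 1)
        - gammaln(k + 1)
        - gammaln(l - k + 1)
        + betaln(k + a, l - k + b)
        - betaln(a, b)
    )
    return out if out.ndim else float(out)


def beta_binomial_pmf(k, l: int, a: float, b: float):
    """Beta-binomial mass ``BB(k, l; a, b)`` on the linear scale."""
    return np.exp(beta_binomial_logpmf(k, l, a, b))


def sc_freq_log_pmf(l: int, theta_s) -> np.ndarray:
    """Log of ``P(rho_s = k/l | theta_s)`` for every ``k`` in ``0..l``.

    This is the full distortion distribution of the observed alternative
    read count under MDA amplification bias, at the coverage-specific
    parameters of :func:`bias_params`.  Results are cached per coverage.
    """
    return _sc_freq_log_pmf_cached(int(l), Fraction(theta_s))


@lru_cache(maxsize=4096)
def _sc_freq_log_pmf_cached(l: int, theta_s: Fraction) -> np.ndarray:
    if theta_s not in THETA_S_VALUES:
        raise ValueError(f"theta_s must be one of 0, 1/2, 1; got {theta_s}")
    p = bias_params(l)
    k = np.arange(l + 1)
    if theta_s == 0:
        return beta_binomial_logpmf(k, l, p.alpha, p.beta)
    if theta_s == 1:
        # symmetric to theta_s = 0 with the shape parameters swapped
        return beta_binomial_logpmf(k, l, p.beta, p.alpha)
    comp1 = beta_binomial_logpmf(k, l, p.alpha1, p.alpha1)
    comp2 = beta_binomial_logpmf(k, l, p.alpha2, p.alpha2)
    with np.errstate(divide="ignore"):
        logw = np.log(p.w)
        log1mw = np.log1p(-p.w)
    if p.w == 0.0:
        return comp2
    if p.w == 1.0:
        return comp1
    return logsumexp(np.stack([logw + comp1, log1mw + comp2]), axis=0)


def sc_freq_likelihood(k: int, l: int, theta_s) -> float:
    """``P(rho_s = k/l | theta_s)`` for a single observed count ``k``."""
    if not 0 <= k <= l:
        raise ValueError("require 0 <= k <= l")
    return float(np.exp(sc_freq_log_pmf(l, theta_s)[k]))
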