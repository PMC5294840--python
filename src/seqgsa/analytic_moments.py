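"""Closed-form moments of the maxmean statistic under a two-group model.

Each gene's z statistic follows the mixture ``z_i ~ p0 f0(z) + p1 f1i(z)``
with ``f0`` standard normal and per-gene symmetric alternatives ``f1i`` — a
two-component normal mixture with means ``+-mu1_i`` and common component sd.
A gene-length bias is modelled by letting ``mu1_i`` grow with the gene-length
rank ``i``: long genes produce more extreme z values than equally expressed
short genes.

With independent z and a set S of size ``n_S``:

* ``mu_plus = E(S+) = p0/sqrt(2*pi) + (p1/n_S) * sum_i int_0^inf z f1i(z) dz``
  and, by symmetry of ``f1i``, ``mu_minus = mu_plus``.
* ``sigma_plus^2 = sigma_minus^2 = n_S^{-2} * sum_i Var(z_i^+)`` with
  ``z^+ = z * I{z > 0}``.
* ``Cov(S+, S-) = -n_S^{-2} * sum_i (E z_i^+)^2``  (genes cannot contribute
  to both sides at once, cross terms factor by independence).
* With ``theta^2 = Var(S+ - S-) = sigma_plus^2 - 2 Cov + sigma_minus^2`` the
  bivariate-normal maximum has mean::

      E(S) = mu_plus * Phi(d) + mu_minus * Phi(-d) + theta * phi(-d),
      d = (mu_plus - mu_minus) / theta,

  which for the symmetric case reduces to ``E(S) = mu_plus + theta * phi(0)``
  — and is then exact at any n_S, because ``S+ - S- = mean(z)``.

These formulas serve as the independent oracle for the randomization
machinery, and show why weighted randomization helps: for a seed set of
short genes the length-weighted draw selects genes with smaller half-line
integrals, so the weighted randomization mean lies below the unweighted one.

Half-line integrals are evaluated by adaptive quadrature; the standard-normal
constants ``E(z^+) = 1/sqrt(2*pi)`` and ``E((z^+)^2) = 1/2`` are exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple, Union

import numpy as np
from scipy import integrate, stats

from . import length_weighting

__all__ = [
    "MixtureSpec",
    "MaxmeanMoments",
    "length_biased_spec",
    "mu_plus",
    "mu_minus",
    "maxmean_moments",
    "expected_maxmean",
    "weighted_vs_unweighted_mu",
]

_PHI0 = 1.0 / np.sqrt(2.0 * np.pi)  # phi(0) = E(z^+) under N(0,1)


@dataclass(frozen=True)
class MixtureSpec:
    """Two-group mixture model of gene-level z statistics.

    ``mu1`` holds the per-gene alternative mean magnitudes, indexed in
    gene-length order; under a length bias ``mu1`` is non-decreasing. The
    alternative density of gene i is the symmetric two-component mixture
    ``0.5 N(-mu1_i, sd1^2) + 0.5 N(+mu1_i, sd1^2)``.
    """

    p0: float
    p1: float
    mu1: np.ndarray
    sd1: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu1", np.asarray(self.mu1, dtype=float))
        if abs(self.p0 + self.p1 - 1.0) > 1e-12:
            raise ValueError("p0 + p1 must equal 1")
        if not (0.0 <= self.p0 <= 1.0):
            raise ValueError("p0 must lie in [0, 1]")
        if np.any(self.mu1 < 0):
            raise ValueError("mu1 magnitudes must be non-negative")
        if self.sd1 <= 0:
            raise ValueError("sd1 must be positive")

    @property
    def n(self) -> int:
        return self.mu1.size

    def f1_pdf(self, i: int, z):
        """Alternative density of gene i (symmetric in z)."""
        m, s = self.mu1[i], self.sd1
        return 0.5 * (stats.norm.pdf(z, -m, s) + stats.norm.pdf(z, m, s))

    def sample_z(self, members, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw z vectors for the given genes; shape (size, len(members))."""
        members = np.asarray(members)
        mu = self.mu1[members]
        is_alt = rng.random((size, members.size)) < self.p1
        signs = np.where(rng.random((size, members.size)) < 0.5, -1.0, 1.0)
        mean = np.where(is_alt, signs * mu[None, :], 0.0)
        sd = np.where(is_alt, self.sd1, 1.0)
        return rng.normal(mean, sd)


@dataclass(frozen=True)
class MaxmeanMoments:
    mu_plus: float
    mu_minus: float
    sigma_plus2: float
    sigma_minus2: float
    cov: float
    eta: float
    theta: float
    expected_S: float


def length_biased_spec(
    n: int, p0: float = 0.9, mu_lo: float = 0.5, mu_hi: float = 3.0, sd1: float = 1.0
) -> MixtureSpec:
    """A spec whose alternative means grow linearly with length rank."""
    return MixtureSpec(p0, 1.0 - p0, np.linspace(mu_lo, mu_hi, n), sd1)


def _half_line_moment(spec: MixtureSpec, i: int, power: int) -> float:
    """``int_0^inf z^power f1i(z) dz`` by adaptive quadrature."""
    val, err = integrate.quad(
        lambda z: z ** power * spec.f1_pdf(i, z), 0.0, np.inf, limit=200
    )
    if not np.isfinite(val) or err > 1e-7 * max(1.0, abs(val)):
        raise ValueError(f"half-line integral for gene {i} did not converge")
    return val


def _pos_part_moments(spec: MixtureSpec, members) -> Tuple[np.ndarray, np.ndarray]:
    """Per-gene E(z^+) and E((z^+)^2) under the mixture."""
    members = np.asarray(members)
    m1 = np.empty(members.size)
    m2 = np.empty(members.size)
    for k, i in enumerate(members):
        if spec.p1 == 0.0:
            i1 = i2 = 0.0
        else:
            i1 = _half_line_moment(spec, int(i), 1)
            i2 = _half_line_moment(spec, int(i), 2)
        m1[k] = spec.p0 * _PHI0 + spec.p1 * i1
        m2[k] = spec.p0 * 0.5 + spec.p1 * i2
    return m1, m2


def mu_plus(spec: MixtureSpec, members) -> float:
    """``E(S+)`` for the set of gene indices ``members``.

    Note: for the pure-null spec this is ``1/sqrt(2*pi) ~ 0.39894`` (the
    half-line first moment of the standard normal).
    """
    m1, _ = _pos_part_moments(spec, members)
    return float(m1.mean())


def mu_minus(spec: MixtureSpec, members) -> float:
    """``E(S-)``; equals :func:`mu_plus` by the symmetry of ``f1i``."""
    return mu_plus(spec, members)


def maxmean_moments(spec: MixtureSpec, members) -> MaxmeanMoments:
    """All bivariate-normal moments of ``(S+, S-)`` and the implied E(S)."""
    members = np.asarray(members)
    n_S = members.size
    m1, m2 = _pos_part_moments(spec, members)
    mu_p = float(m1.mean())
    var_pos = m2 - m1 ** 2
    sigma2 = float(var_pos.sum() / n_S ** 2)
    cov = float(-(m1 ** 2).sum() / n_S ** 2)
    eta = cov / sigma2 if sigma2 > 0 else 0.0
    theta2 = 2.0 * sigma2 - 2.0 * cov  # Var(S+ - S-)
    theta = float(np.sqrt(max(theta2, 0.0)))
    expected = _expected_from(mu_p, mu_p, theta)
    return MaxmeanMoments(
        mu_plus=mu_p,
        mu_minus=mu_p,
        sigma_plus2=sigma2,
        sigma_minus2=sigma2,
        cov=cov,
        eta=float(eta),
        theta=theta,
        expected_S=expected,
    )


def _expected_from(mu_p: float, mu_m: float, theta: float) -> float:
    if theta <= 0:
        if mu_p == mu_m:
            return mu_p
        raise ValueError("theta undefined (non-positive radicand)")
    d = (mu_p - mu_m) / theta
    return float(
        mu_p * stats.norm.cdf(d) + mu_m * stats.norm.cdf(-d) + theta * stats.norm.pdf(d)
    )


def expected_maxmean(moments: MaxmeanMoments) -> float:
    """Mean of ``S = max(S+, S-)`` for bivariate-normal ``(S+, S-)``.

    Uses the exact ``phi(0) = 1/sqrt(2*pi)`` in the symmetric branch rather
    than a rounded 0.40 constant.
    """
    return _expected_from(moments.mu_plus, moments.mu_minus, moments.theta)


def weighted_vs_unweighted_mu(
    spec: MixtureSpec,
    seed_members,
    lengths: Union[Sequence[float], None] = None,
    weights: Union[np.ndarray, None] = None,
) -> Tuple[float, float]:
    """Expected randomization means ``(mu_plus_w, mu_plus)`` for a seed set.

    The unweighted randomization mean averages the per-gene half-line
    integrals uniformly over all n genes; the weighted mean averages them
    with the length-similarity selection probabilities ``q_Sj`` of the seed
    set (computed from ``lengths``, or supplied directly via ``weights``).
    Under a length bias and a short-gene seed set, ``mu_plus_w < mu_plus``.
    """
    if weights is None:
        if lengths is None:
            raise ValueError("either lengths or weights must be supplied")
        F = length_weighting.ecdf(lengths)
        weights = length_weighting._set_probs_from_indices(
            np.asarray(seed_members), F
        )
    weights = np.asarray(weights, dtype=float)
    if weights.size != spec.n:
        raise ValueError("weights must cover all genes of the spec")
    m1, _ = _pos_part_moments(spec, np.arange(spec.n))
    mu_w = float(weights @ m1)
    mu_u = float(m1.mean())
    return mu_w, mu_u
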