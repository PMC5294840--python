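"""The maxmean gene-set statistic.

For the z values of a gene set of size ``n_S``::

    S+ = (1/n_S) * sum(z_i * I{z_i > 0})
    S- = -(1/n_S) * sum(z_i * I{z_i < 0})
    S  = max(S+, S-)

Both one-sided averages divide by the full set size (not by the count of
positive or negative genes), so S responds to a coordinated shift of a
fraction of the set. Genes with z exactly 0 contribute to neither side.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .datatypes import DegenerateRandomizationError

__all__ = ["maxmean", "maxmean_batch", "standardize"]


def maxmean(z_subset) -> Tuple[float, float, float]:
    """Return ``(S_plus, S_minus, S)`` for one vector of gene z values."""
    z = np.asarray(z_subset, dtype=float)
    if z.size == 0:
        raise ValueError("maxmean of an empty gene set")
    s_plus = float(z[z > 0].sum() / z.size)
    s_minus = float(-z[z < 0].sum() / z.size)
    return s_plus, s_minus, max(s_plus, s_minus)


def maxmean_batch(Z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Maxmean S along ``axis`` of an array of z values (vectorized)."""
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[axis]
    if n == 0:
        raise ValueError("maxmean of an empty gene set")
    s_plus = np.maximum(Z, 0.0).sum(axis=axis) / n
    s_minus = -np.minimum(Z, 0.0).sum(axis=axis) / n
    return np.maximum(s_plus, s_minus)


def standardize(S, mu_dag: float, sigma_dag: float):
    """Standardized maxmean ``S* = (S - mu_dag) / sigma_dag``.

    Raises
    ------
    DegenerateRandomizationError
        If ``sigma_dag`` is not strictly positive.
    """
    if np.any(np.asarray(sigma_dag) <= 0):
        raise DegenerateRandomizationError("degenerate randomization distribution")
    return (S - mu_dag) / sigma_dag
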