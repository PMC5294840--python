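"""Gene-length similarity weights for the randomization step.

Randomized gene sets that ignore gene length are biased competitors for
RNA-seq data, where expected counts (and hence gene-level test statistics)
grow with gene length. The weighted scheme replaces gene ``i`` of the seed
set with gene ``j`` with probability proportional to::

    w_ij = 1 - |F(l_i) - F(l_j)|

where ``F`` is the empirical CDF of gene length over all ``n`` genes. For a
whole set S the per-gene selection probabilities aggregate the normalized
rows of ``w`` over the members::

    q_Sj ~ sum_{i in S} q_ij   (normalized over j)

Randomized sets are then drawn without replacement with probabilities
proportional to ``q_Sj`` (Gumbel top-k, equivalent to sequential weighted
draws); with all lengths equal the weights collapse to the uniform scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GeneSet

__all__ = [
    "ecdf",
    "pairwise_weight",
    "SetSamplingWeights",
    "set_selection_probs",
    "uniform_selection_probs",
    "draw_random_set",
    "draw_random_sets",
]


def ecdf(lengths) -> np.ndarray:
    """Empirical CDF values ``F(l_i) = #{j : l_j <= l_i} / n`` per gene.

    Right-continuous; tied lengths share one value; ``max(F) == 1``.
    """
    l = np.asarray(lengths)
    if l.size == 0:
        raise ValueError("empty length vector")
    if np.any(l <= 0):
        raise ValueError("gene lengths must be positive")
    order = np.sort(l)
    return np.searchsorted(order, l, side="right") / l.size


def pairwise_weight(F_i, F_j):
    """Length-similarity weight ``1 - |F_i - F_j|`` (in [0, 1])."""
    return 1.0 - np.abs(np.asarray(F_i, dtype=float) - np.asarray(F_j, dtype=float))


@dataclass(frozen=True)
class SetSamplingWeights:
    """Selection probability ``q[j]`` of each of the n genes for one seed set."""

    set_name: str
    q: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))
        if np.any(self.q < 0) or abs(self.q.sum() - 1.0) > 1e-12:
            raise ValueError("selection probabilities must be >= 0 and sum to 1")


def _set_probs_from_indices(member_idx: np.ndarray, F: np.ndarray) -> np.ndarray:
    # row-normalize w_ij over j, then aggregate rows over the members
    W = pairwise_weight(F[member_idx][:, None], F[None, :])
    Q = W / W.sum(axis=1, keepdims=True)
    q = Q.sum(axis=0)
    return q / q.sum()


def set_selection_probs(gene_set: GeneSet, table: pd.DataFrame) -> SetSamplingWeights:
    """Selection probabilities of all genes for randomizing ``gene_set``.

    ``table`` is the per-gene table (index: gene id, column ``length``).
    Members missing from the table are ignored; seed-set members are *not*
    excluded from the sampling universe.
    """
    idx = table.index.get_indexer(list(gene_set.members))
    idx = idx[idx >= 0]
    if idx.size == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no members in the gene table")
    F = ecdf(table["length"].to_numpy())
    return SetSamplingWeights(gene_set.name, _set_probs_from_indices(idx, F))


def uniform_selection_probs(n: int) -> np.ndarray:
    """Uniform selection probabilities (the unweighted scheme)."""
    return np.full(n, 1.0 / n)


def _as_prob_array(weights) -> np.ndarray:
    q = weights.q if isinstance(weights, SetSamplingWeights) else np.asarray(weights, float)
    return q


def draw_random_sets(weights, n_S: int, K: int, rng: np.random.Generator) -> np.ndarray:
    """Draw K randomized sets of ``n_S`` distinct gene indices.

    Sampling is without replacement with inclusion probabilities proportional
    to ``q`` via the Gumbel top-k trick: per draw, ``n_S`` indices with the
    largest ``log q_j + Gumbel_j`` are selected, which reproduces sequential
    weighted sampling without replacement. Returns an (K, n_S) index array.
    """
    q = _as_prob_array(weights)
    n = q.size
    if n_S > n:
        raise ValueError(f"cannot draw {n_S} distinct genes from {n}")
    with np.errstate(divide="ignore"):
        log_q = np.log(q)
    keys = log_q[None, :] + rng.gumbel(size=(K, n))
    return np.argpartition(keys, n - n_S, axis=1)[:, n - n_S:]


def draw_random_set(weights, n_S: int, rng: np.random.Generator) -> np.ndarray:
    """Draw one randomized set of ``n_S`` distinct gene indices."""
    return draw_random_sets(weights, n_S, 1, rng)[0]
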