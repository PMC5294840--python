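"""Restandardized maxmean testing of gene sets (the SeqGSA test).

For each gene set the test combines the two classical null constructions:

1. *Randomization* (competitive): the mean ``mu_dag`` and standard deviation
   ``sigma_dag`` of the maxmean statistic over K randomly assembled sets of
   the same size — drawn uniformly, or with gene-length-similarity weights to
   remove the RNA-seq length bias.
2. *Standardization*: ``S* = (S - mu_dag) / sigma_dag``.
3. *Permutation* (self-contained): sample labels are permuted B times; for
   each permutation the gene-level z values and the randomization moments are
   recomputed on the permuted z, giving ``S*b``. The p-value is the right
   tail ``p = #{b : S*b > S*} / B``.

The selection weights depend only on gene lengths and are therefore shared
between the observed data and every permutation.
"""

from __future__ import annotations

import zlib
from typing import Sequence, Tuple, Union

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import gene_level, length_weighting
from .datatypes import (
    CountMatrix,
    DegenerateRandomizationError,
    GeneSet,
    GeneSetCollection,
    RestandardizationResult,
    RunConfig,
    logger,
)
from .maxmean import maxmean_batch, standardize

__all__ = [
    "bh_adjust",
    "randomization_moments",
    "permutation_masks",
    "run_set",
    "run_collection",
    "run_collection_both",
]

# elements per chunk when gathering (P, K, n_S) blocks of z values
_CHUNK_ELEMENTS = 8_000_000


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _set_rng(seed: int, name: str, stream: int = 0) -> np.random.Generator:
    # deterministic per-set substream, independent of collection order
    return np.random.default_rng([seed, stream, zlib.crc32(name.encode())])


def randomization_moments(
    z,
    weights,
    n_S: int,
    K: int,
    rng: Union[int, np.random.Generator],
) -> Tuple[float, float]:
    """Mean and sd of the maxmean over K randomized sets of size ``n_S``.

    ``weights`` is a probability vector over all genes (or a
    :class:`~seqgsa.length_weighting.SetSamplingWeights`); ``rng`` a seed or
    Generator. Raises :class:`DegenerateRandomizationError` when all draws
    give an identical statistic.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    z = np.asarray(z, dtype=float)
    idx = length_weighting.draw_random_sets(weights, n_S, K, rng)
    S = maxmean_batch(z[idx], axis=1)
    mu = float(S.mean())
    sd = float(S.std(ddof=1))
    if sd <= 0:
        raise DegenerateRandomizationError("degenerate randomization distribution")
    return mu, sd


def permutation_masks(groups, B: int, rng: np.random.Generator) -> np.ndarray:
    """Observed labeling plus B uniform label permutations.

    Returns a (B+1, n_samples) boolean array of reference-group masks; row 0
    is the observed assignment. Permutations are drawn independently with
    replacement from the permutation space (the identity is not excluded).
    """
    groups = np.asarray(groups)
    ref = groups == pd.unique(groups)[0]
    masks = np.empty((B + 1, groups.size), dtype=bool)
    masks[0] = ref
    for b in range(1, B + 1):
        masks[b] = ref[rng.permutation(groups.size)]
    return masks


def _members_index(gene_set: GeneSet, table: pd.DataFrame) -> np.ndarray:
    idx = table.index.get_indexer(list(gene_set.members))
    missing = int((idx < 0).sum())
    if missing:
        logger.warning(
            "gene set %r: dropping %d member(s) missing from the gene table",
            gene_set.name, missing,
        )
    idx = idx[idx >= 0]
    if idx.size == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no members in the gene table")
    return idx


def _moments_over_rows(
    Zp: np.ndarray, idx: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-row randomization moments of ``Zp`` ((P, n)) over K index sets."""
    P = Zp.shape[0]
    K, n_S = idx.shape
    mu = np.empty(P)
    sd = np.empty(P)
    step = max(1, _CHUNK_ELEMENTS // (K * n_S))
    for s in range(0, P, step):
        G = Zp[s:s + step][:, idx]  # (p, K, n_S)
        S = maxmean_batch(G, axis=2)
        mu[s:s + step] = S.mean(axis=1)
        sd[s:s + step] = S.std(axis=1, ddof=1)
    return mu, sd


def _analyze_set(
    Zp: np.ndarray,
    members: np.ndarray,
    q: np.ndarray,
    config: RunConfig,
    rng: np.random.Generator,
    name: str,
) -> RestandardizationResult:
    """Restandardized test of one set against precomputed z rows ``Zp``."""
    n_S = members.size
    S_obs = maxmean_batch(Zp[:, members], axis=1)  # (B+1,)
    if config.redraw_sets:
        K_perm = config.K_perm or config.K
        mu = np.empty(Zp.shape[0])
        sd = np.empty(Zp.shape[0])
        for b in range(Zp.shape[0]):
            K_b = config.K if b == 0 else K_perm
            idx = length_weighting.draw_random_sets(q, n_S, K_b, rng)
            S = maxmean_batch(Zp[b][idx], axis=1)
            mu[b], sd[b] = S.mean(), S.std(ddof=1)
    else:
        idx = length_weighting.draw_random_sets(q, n_S, config.K, rng)
        mu, sd = _moments_over_rows(Zp, idx)
    if np.any(sd <= 0):
        raise DegenerateRandomizationError(
            f"degenerate randomization distribution for set {name!r}"
        )
    S_star = standardize(S_obs, mu, sd)
    exceed = int((S_star[1:] > S_star[0]).sum())
    B = S_star.size - 1
    if config.add_one_smoothing:
        p = (1 + exceed) / (1 + B)
    else:
        p = exceed / B
    return RestandardizationResult(
        name=name,
        n_used=int(n_S),
        S=float(S_obs[0]),
        mu_dag=float(mu[0]),
        sigma_dag=float(sd[0]),
        S_star=float(S_star[0]),
        perm_S_star=S_star[1:].copy(),
        p_value=float(p),
    )


def _prepare(
    cm: CountMatrix, table: pd.DataFrame, config: RunConfig
) -> Tuple[CountMatrix, pd.DataFrame, np.ndarray]:
    """Align table with counts, equalize libraries, compute the z matrix."""
    if not table.index.equals(cm.gene_ids):
        table = table.reindex(cm.gene_ids)
        if table["length"].isna().any():
            raise ValueError("gene table is missing lengths for some genes in counts")
    cm = gene_level.equalize_library_sizes(cm)
    dispersion = config.dispersion
    if dispersion == "auto":
        dispersion = gene_level.estimate_common_dispersion(cm)
    rng_perm = np.random.default_rng([config.seed, 0xA11])
    masks = permutation_masks(cm.groups, config.B, rng_perm)
    Zp = gene_level.z_for_masks(cm, masks, dispersion=float(dispersion), z_max=config.z_max).T
    return cm, table, Zp


def _run_sets_on_z(
    Zp: np.ndarray,
    table: pd.DataFrame,
    collection: GeneSetCollection,
    config: RunConfig,
    weighted: bool,
) -> list:
    n = Zp.shape[1]
    F = length_weighting.ecdf(table["length"].to_numpy()) if weighted else None
    results = []
    for gene_set in collection:
        members = _members_index(gene_set, table)
        if weighted:
            q = length_weighting._set_probs_from_indices(members, F)
        else:
            q = length_weighting.uniform_selection_probs(n)
        rng = _set_rng(config.seed, gene_set.name)
        results.append(_analyze_set(Zp, members, q, config, rng, gene_set.name))
    qvals = bh_adjust([r.p_value for r in results])
    for r, qv in zip(results, qvals):
        r.q_value = float(qv)
    return results


def run_collection(
    cm: CountMatrix,
    table: pd.DataFrame,
    collection: GeneSetCollection,
    config: RunConfig,
) -> list:
    """Run the SeqGSA test for every set of a collection.

    Gene-level permutation z values are computed once and shared across sets;
    per-set randomization streams derive deterministically from the master
    seed and the set name, so results do not depend on collection order.
    Returns a list of :class:`RestandardizationResult` with BH-adjusted
    q-values computed across the collection.
    """
    if len(collection) == 0:
        return []
    cm, table, Zp = _prepare(cm, table, config)
    return _run_sets_on_z(Zp, table, collection, config, config.weighted)


def run_collection_both(
    cm: CountMatrix,
    table: pd.DataFrame,
    collection: GeneSetCollection,
    config: RunConfig,
) -> Tuple[list, list]:
    """Run the weighted and unweighted procedures on shared permutation z's.

    Both runs see identical data, label permutations and per-set
    randomization streams, so on an equal-length gene universe the two sets
    of results coincide exactly; in general this pairing makes power
    comparisons between the procedures well matched.
    """
    if len(collection) == 0:
        return [], []
    cm, table, Zp = _prepare(cm, table, config)
    weighted = _run_sets_on_z(Zp, table, collection, config, weighted=True)
    unweighted = _run_sets_on_z(Zp, table, collection, config, weighted=False)
    return weighted, unweighted


def run_set(
    cm: CountMatrix,
    table: pd.DataFrame,
    gene_set: GeneSet,
    config: RunConfig,
) -> RestandardizationResult:
    """Run the SeqGSA test for a single gene set (q-value equals p-value)."""
    results = run_collection(cm, table, GeneSetCollection([gene_set]), config)
    return results[0]
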