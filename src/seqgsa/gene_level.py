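"""Gene-level differential expression statistics for two-group count data.

The set-level maxmean statistic consumes one signed z value per gene. For
RNA-seq counts the gene-level test is the exact negative binomial test: given
a common dispersion ``phi``, the sum of a gene's counts in the reference group
is compared with its conditional distribution given the gene's total count,
under the null of equal means in both groups. With ``phi = 0`` this reduces to
the classical conditional binomial (Poisson) exact test. Two-sided p-values
are obtained by doubling the smaller tail (capped at 1), and are mapped to
signed z values via ``z = sign(logFC) * Phi^{-1}(1 - p/2)``.

The test conditions on per-gene totals and therefore assumes equal library
sizes; :func:`equalize_library_sizes` rescales unequal libraries to a common
depth with total-count size factors beforehand.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp, ndtri

from .datatypes import CountMatrix, make_gene_table

logger = logging.getLogger("seqgsa")

__all__ = [
    "exact_nb_test",
    "p_to_z",
    "compute_gene_z",
    "estimate_common_dispersion",
    "equalize_library_sizes",
    "z_for_masks",
]

#: Clamp for |z| so that p = 0 maps to a finite value.
Z_MAX = 8.0


def equalize_library_sizes(cm: CountMatrix) -> CountMatrix:
    """Rescale samples to a common library size with total-count size factors.

    Counts are multiplied by ``mean(libsize)/libsize_j`` and rounded to the
    nearest integer. A no-op when library sizes are already equal.
    """
    lib = cm.library_sizes().astype(float)
    if np.all(lib == lib[0]):
        return cm
    factors = np.where(lib > 0, lib.mean() / np.where(lib > 0, lib, 1.0), 1.0)
    scaled = np.rint(cm.counts.to_numpy() * factors[None, :]).astype(np.int64)
    logger.info("equalized library sizes (size factors %s)", np.round(factors, 3))
    return CountMatrix(
        pd.DataFrame(scaled, index=cm.counts.index, columns=cm.counts.columns),
        cm.groups,
    )


def estimate_common_dispersion(cm: CountMatrix) -> float:
    """Method-of-moments common NB dispersion.

    For each gene the within-group variance is pooled across the two groups
    and compared with the overall mean; the common dispersion is the median
    over genes of ``(pooled_var - mean) / mean^2``, floored at 0 (Poisson).
    """
    x = cm.counts.to_numpy().astype(float)
    ref = cm.reference_mask
    x_ref, x_alt = x[:, ref], x[:, ~ref]
    n_ref, n_alt = x_ref.shape[1], x_alt.shape[1]
    dof = n_ref + n_alt - 2
    if dof <= 0:
        return 0.0
    v = (
        x_ref.var(axis=1, ddof=1) * (n_ref - 1)
        + x_alt.var(axis=1, ddof=1) * (n_alt - 1)
    ) / dof
    m = x.mean(axis=1)
    ok = m > 0
    if not np.any(ok):
        return 0.0
    phi = float(np.median((v[ok] - m[ok]) / m[ok] ** 2))
    return max(0.0, phi)


def _nb_conditional_pmf(t: int, n_ref: int, n_alt: int, phi: float) -> np.ndarray:
    """Conditional pmf of the reference-group sum given the gene total ``t``.

    Under NB(mu, phi) per sample with a common mean, the group sums are
    NB with sizes ``n_g/phi`` and the conditional pmf over ``k = 0..t`` is
    proportional to ``f_ref(k) * f_alt(t-k)``. The pmf is built from the
    log-ratio recursion, in which the NB probability parameter cancels, so the
    ``phi -> 0`` limit reproduces the conditional binomial exactly.
    """
    if t == 0:
        return np.ones(1)
    k = np.arange(t, dtype=float)
    if phi == 0.0:
        log_ratio = np.log(t - k) - np.log(k + 1) + np.log(n_ref) - np.log(n_alt)
    else:
        r_ref = n_ref / phi
        r_alt = n_alt / phi
        log_ratio = (
            np.log(r_ref + k)
            + np.log(t - k)
            - np.log(k + 1)
            - np.log(r_alt + t - k - 1)
        )
    log_pmf = np.concatenate([[0.0], np.cumsum(log_ratio)])
    log_pmf -= logsumexp(log_pmf)
    return np.exp(log_pmf)


def _doubled_tail_from_pmf(pmf: np.ndarray, a: np.ndarray) -> np.ndarray:
    lower = np.cumsum(pmf)
    upper = np.cumsum(pmf[::-1])[::-1]
    p = 2.0 * np.minimum(lower[a], upper[a])
    return np.minimum(p, 1.0)


def _conditional_pvalues(
    A: np.ndarray, t: np.ndarray, n_ref: int, n_alt: int, phi: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided conditional p-values and signs.

    Parameters
    ----------
    A
        (n_genes, P) reference-group sums, one column per label assignment.
    t
        (n_genes,) per-gene totals (invariant to label permutation).

    Returns
    -------
    p, sign
        Arrays of shape (n_genes, P). ``sign`` is the direction of the
        normalized mean difference, second group minus reference group.
    """
    t_col = t[:, None]
    sign = np.sign(n_ref * (t_col - A) - n_alt * A).astype(np.int8)
    if phi == 0.0:
        prop = n_ref / (n_ref + n_alt)
        lower = stats.binom.cdf(A, t_col, prop)
        upper = stats.binom.sf(A - 1, t_col, prop)
        p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    else:
        p = np.empty_like(A, dtype=float)
        for i in range(A.shape[0]):
            pmf = _nb_conditional_pmf(int(t[i]), n_ref, n_alt, phi)
            p[i] = _doubled_tail_from_pmf(pmf, A[i])
    return p, sign


def exact_nb_test(
    cm: CountMatrix, dispersion: Union[float, str] = "auto", equalize: bool = True
) -> list:
    """Exact negative binomial test for each gene of a two-group count matrix.

    Parameters
    ----------
    cm
        Count matrix with exactly two groups. Unequal library sizes are
        equalized with total-count size factors first.
    dispersion
        Common NB dispersion; ``0`` gives the Poisson conditional binomial
        test, ``"auto"`` estimates it by method of moments.

    Returns
    -------
    list of (gene_id, p_value, log_fc_sign)
        Two-sided exact p-value from the conditional distribution of the
        reference-group sum given the total, and the direction of the
        (normalized) mean difference. A gene with no counts has p = 1 and
        sign = 0.
    """
    if equalize:
        cm = equalize_library_sizes(cm)
    if dispersion == "auto":
        dispersion = estimate_common_dispersion(cm)
    elif isinstance(dispersion, str):
        raise ValueError("dispersion must be a non-negative number or 'auto'")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    ref = cm.reference_mask
    x = cm.counts.to_numpy()
    A = x[:, ref].sum(axis=1)[:, None]
    t = x.sum(axis=1)
    p, sign = _conditional_pvalues(A, t, int(ref.sum()), int((~ref).sum()), float(dispersion))
    return list(zip(cm.gene_ids, p[:, 0], sign[:, 0].astype(int)))


def p_to_z(
    p_value, log_fc_sign, z_max: float = Z_MAX
):
    """Convert two-sided p-values and directions to signed z statistics.

    ``z = sign * Phi^{-1}(1 - p/2)``, clamped to ``[-z_max, z_max]``; genes
    with sign 0 map to z = 0. Accepts scalars or arrays.
    """
    p = np.asarray(p_value, dtype=float)
    s = np.asarray(log_fc_sign, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore", over="ignore"):
        q = ndtri(1.0 - p / 2.0)
    q = np.clip(q, -z_max, z_max)
    z = np.where(s == 0, 0.0, s * q)
    if z.ndim == 0:
        return float(z)
    return z


def compute_gene_z(
    cm: CountMatrix,
    method: Union[str, Callable[[CountMatrix], Iterable]] = "exact_nb",
    dispersion: Union[float, str] = "auto",
    z_max: float = Z_MAX,
) -> pd.DataFrame:
    """Compute per-gene signed z statistics from a count matrix.

    ``method`` is either ``"exact_nb"`` or any callable mapping a
    :class:`CountMatrix` to an iterable of ``(gene_id, p_value, sign)``
    triples, making the gene-level stage pluggable.

    Returns a DataFrame indexed by gene id with columns ``p_value``, ``sign``
    and ``z``, preserving the gene order of ``cm``.
    """
    if method == "exact_nb":
        rows = exact_nb_test(cm, dispersion=dispersion)
    elif callable(method):
        rows = list(method(cm))
    else:
        raise ValueError(f"unknown gene-level method {method!r}")
    out = pd.DataFrame(rows, columns=["gene_id", "p_value", "sign"]).set_index("gene_id")
    if list(out.index) != list(cm.gene_ids):
        out = out.reindex(cm.gene_ids)
        if out.isna().any().any():
            raise ValueError("gene-level method did not return all genes")
    pv = out["p_value"].to_numpy(dtype=float)
    if np.any((pv < 0) | (pv > 1)) or np.any(np.isnan(pv)):
        raise ValueError("gene-level method returned p-values outside [0, 1]")
    out["z"] = p_to_z(pv, out["sign"].to_numpy(), z_max=z_max)
    return out


def z_for_masks(
    cm: CountMatrix,
    ref_masks: np.ndarray,
    dispersion: float = 0.0,
    z_max: float = Z_MAX,
) -> np.ndarray:
    """Signed z matrix for a batch of sample-label assignments.

    ``ref_masks`` is a (P, n_samples) boolean array whose rows mark the
    samples assigned to the reference group (row 0 is normally the observed
    labeling, the rest label permutations). Per-gene totals are invariant to
    relabeling, so the conditional pmf is built once per gene and evaluated
    for all P assignments at once. Returns a (n_genes, P) float array.
    """
    ref_masks = np.asarray(ref_masks, dtype=bool)
    n_ref = int(ref_masks[0].sum())
    if not np.all(ref_masks.sum(axis=1) == n_ref):
        raise ValueError("all label assignments must preserve group sizes")
    n_alt = ref_masks.shape[1] - n_ref
    x = cm.counts.to_numpy()
    A = x @ ref_masks.T.astype(np.int64)
    t = x.sum(axis=1)
    p, sign = _conditional_pvalues(A, t, n_ref, n_alt, float(dispersion))
    return np.asarray(p_to_z(p, sign, z_max=z_max))
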