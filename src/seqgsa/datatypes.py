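"""Core containers shared across the SeqGSA pipeline.

The pipeline operates on three kinds of objects: a two-group RNA-seq count
matrix (:class:`CountMatrix`), a per-gene table carrying lengths and gene-level
z statistics (a plain :class:`pandas.DataFrame`, see :func:`make_gene_table`),
and named gene sets (:class:`GeneSet` / :class:`GeneSetCollection`, typically
read from GMT files).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger("seqgsa")

__all__ = [
    "CountMatrix",
    "GeneSet",
    "GeneSetCollection",
    "RestandardizationResult",
    "RunConfig",
    "DegenerateRandomizationError",
    "make_gene_table",
]


class DegenerateRandomizationError(RuntimeError):
    """Raised when the randomization distribution has zero spread."""


@dataclass
class CountMatrix:
    """A genes x samples matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame indexed by unique gene ids, one column per sample.
    groups
        Sample-aligned sequence of group labels with exactly two levels
        (e.g. ``["control"]*4 + ["treatment"]*4``).
    """

    counts: pd.DataFrame
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups)
        if not self.counts.index.is_unique:
            raise ValueError("gene ids must be unique")
        if len(self.groups) != self.counts.shape[1]:
            raise ValueError(
                f"groups has length {len(self.groups)} but counts has "
                f"{self.counts.shape[1]} samples"
            )
        levels = pd.unique(self.groups)
        if len(levels) != 2:
            raise ValueError("two groups required")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(values < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def levels(self) -> tuple:
        """The two group labels, in order of first appearance."""
        lv = pd.unique(self.groups)
        return (lv[0], lv[1])

    @property
    def reference_mask(self) -> np.ndarray:
        """Boolean mask of samples in the first (reference) group."""
        return np.asarray(self.groups == self.levels[0])

    def library_sizes(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=0)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of member gene ids."""

    name: str
    members: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if len(self.members) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely named gene sets."""

    sets: list = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("gene set names must be unique")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, key: Union[int, str]) -> GeneSet:
        if isinstance(key, str):
            for s in self.sets:
                if s.name == key:
                    return s
            raise KeyError(key)
        return self.sets[key]

    @property
    def names(self) -> list:
        return [s.name for s in self.sets]

    def filter_min_size(self, gene_ids: Sequence[str], min_size: int = 6) -> "GeneSetCollection":
        """Drop sets with fewer than ``min_size`` members mapped to ``gene_ids``.

        The default keeps sets with at least 6 mapped genes, i.e. pathways
        with 5 or fewer mapped genes are removed.
        """
        universe = set(gene_ids)
        kept = []
        for s in self.sets:
            n_mapped = sum(1 for m in s.members if m in universe)
            if n_mapped < min_size:
                logger.warning(
                    "dropping gene set %r: %d mapped genes < min_size %d",
                    s.name, n_mapped, min_size,
                )
            else:
                kept.append(s)
        return GeneSetCollection(kept, source=self.source)


@dataclass
class RunConfig:
    """Configuration of a SeqGSA run.

    Attributes
    ----------
    B
        Number of sample-label permutations.
    K
        Number of randomized gene sets used to estimate the restandardization
        moments (mu_dag, sigma_dag).
    weighted
        If True, randomized sets are drawn with gene-length-similarity
        weights; otherwise uniformly.
    seed
        Master seed; all permutation and randomization streams derive from it
        deterministically, so runs are reproducible and per-set results do not
        depend on collection order.
    fdr
        Target false discovery rate for the BH-adjusted q-values (reporting
        only; all p/q values are returned regardless).
    dispersion
        Negative binomial dispersion for the gene-level exact test; 0 gives
        the Poisson conditional binomial test, "auto" estimates a common
        dispersion by method of moments.
    K_perm
        Randomization draws per permutation when ``redraw_sets`` is True
        (defaults to K).
    add_one_smoothing
        If True report p = (1 + #exceedances)/(1 + B) instead of the plain
        #exceedances/B.
    redraw_sets
        Redraw the K randomized sets independently for every permutation
        instead of reusing one common set of draws.
    """

    B: int = 1000
    K: int = 1000
    weighted: bool = True
    seed: int = 0
    fdr: float = 0.1
    alpha: float = 0.05
    dispersion: Union[float, str] = "auto"
    K_perm: Union[int, None] = None
    add_one_smoothing: bool = False
    redraw_sets: bool = False
    z_max: float = 8.0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if isinstance(self.dispersion, str):
            if self.dispersion != "auto":
                raise ValueError("dispersion must be a non-negative number or 'auto'")
        elif self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


@dataclass
class RestandardizationResult:
    """Per-gene-set output of the restandardized maxmean test."""

    name: str
    n_used: int
    S: float
    mu_dag: float
    sigma_dag: float
    S_star: float
    perm_S_star: np.ndarray
    p_value: float
    q_value: float = float("nan")


def make_gene_table(
    gene_ids: Sequence[str],
    length_bp: Sequence[int],
    z: Union[Sequence[float], None] = None,
) -> pd.DataFrame:
    """Assemble the per-gene table (index: gene id; columns: length, z).

    Lengths must be strictly positive; ``z`` may be omitted when it is to be
    computed later from a count matrix.
    """
    idx = pd.Index(gene_ids, name="gene_id")
    if not idx.is_unique:
        raise ValueError("gene ids must be unique")
    length = np.asarray(length_bp)
    if np.any(length <= 0):
        raise ValueError("gene lengths must be positive")
    table = pd.DataFrame({"length": length}, index=idx)
    if z is not None:
        table["z"] = np.asarray(z, dtype=float)
    return table
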