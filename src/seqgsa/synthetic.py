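"""Synthetic count data emulating the validation study designs.

Three generators are provided:

* :func:`generate_sim1` — independent Poisson counts whose means are
  proportional to gene length (``mu_i = l_i / 10``), with the gene universe
  partitioned into length-ordered sets so a length bias exists between sets.
  Differential expression multiplies treatment means by ``1 +- beta``.
* :func:`generate_no_bias` — the identical model with genes assigned to sets
  at random, removing the between-set length bias.
* :func:`generate_correlated_set` — a gene set built around a "hub" gene via
  a latent Gaussian copula, so that members are intra-correlated (latent
  correlation with the hub at least ``rho_min``), on top of an independent
  background universe. This stands in for set construction from real
  RNA-seq data, which is out of scope here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CountMatrix, GeneSet, GeneSetCollection, make_gene_table

__all__ = [
    "Sim1Design",
    "Sim1Data",
    "CorrelatedSetDesign",
    "CorrelatedSetData",
    "generate_sim1",
    "generate_no_bias",
    "generate_correlated_set",
]


@dataclass(frozen=True)
class Sim1Design:
    """Design of the length-biased Poisson simulation.

    1000 genes with lengths uniform on [1000, 3000] bp are partitioned into
    20 sets of 50 by length rank (set 1 = shortest genes). Every set carries
    ``n_de`` differentially expressed genes (split half up-, half
    down-regulated; odd counts put the extra gene in the up direction), so
    with the default ``n_de = 2`` all sets are null at the set level.
    ``n_de_first`` overrides the count for set 1 to create one true DE set.
    """

    n_genes: int = 1000
    n_sets: int = 20
    set_size: int = 50
    length_range: Tuple[int, int] = (1000, 3000)
    beta: float = 0.15
    n_de: int = 2
    n_de_first: Union[int, None] = None
    n_control: int = 4
    n_treat: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sets * self.set_size != self.n_genes:
            raise ValueError("sets must partition the genes")
        for nd in (self.n_de, self.n_de_first):
            if nd is not None and not (0 <= nd <= self.set_size):
                raise ValueError(f"n_de must lie in [0, {self.set_size}]")
        if not (0 <= self.beta < 1):
            raise ValueError("beta must lie in [0, 1)")


@dataclass
class Sim1Data:
    counts: CountMatrix
    table: pd.DataFrame  # index gene_id, column 'length'
    sets: GeneSetCollection
    truth: pd.DataFrame  # per gene: set, direction
    set_truth: pd.DataFrame  # per set: n_de, is_de


def _sim1(design: Sim1Design, biased: bool) -> Sim1Data:
    rng = np.random.default_rng(design.seed)
    n = design.n_genes
    gene_ids = np.array([f"g{i:04d}" for i in range(n)])
    lo, hi = design.length_range
    lengths = rng.integers(lo, hi + 1, size=n)

    if biased:
        order = np.argsort(lengths, kind="stable")
    else:
        order = rng.permutation(n)

    set_names = [f"set{k + 1:02d}" for k in range(design.n_sets)]
    set_of = np.empty(n, dtype=object)
    direction = np.zeros(n, dtype=int)
    sets = []
    set_rows = []
    for k, name in enumerate(set_names):
        members = order[k * design.set_size:(k + 1) * design.set_size]
        set_of[members] = name
        n_de = design.n_de
        if k == 0 and design.n_de_first is not None:
            n_de = design.n_de_first
        n_up = math.ceil(n_de / 2)
        direction[members[:n_up]] = 1
        direction[members[n_up:n_de]] = -1
        sets.append(GeneSet(name, tuple(gene_ids[members])))
        set_rows.append({"set": name, "n_de": n_de, "is_de": n_de > design.n_de})

    mu = lengths / 10.0
    mu_treat = mu * (1.0 + design.beta * direction)
    control = rng.poisson(mu[:, None], size=(n, design.n_control))
    treat = rng.poisson(mu_treat[:, None], size=(n, design.n_treat))
    samples = [f"c{j + 1}" for j in range(design.n_control)] + [
        f"t{j + 1}" for j in range(design.n_treat)
    ]
    counts = pd.DataFrame(
        np.hstack([control, treat]), index=pd.Index(gene_ids, name="gene_id"),
        columns=samples,
    )
    groups = np.array(["control"] * design.n_control + ["treatment"] * design.n_treat)
    truth = pd.DataFrame(
        {"set": set_of, "direction": direction},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return Sim1Data(
        counts=CountMatrix(counts, groups),
        table=make_gene_table(gene_ids, lengths),
        sets=GeneSetCollection(sets, source="sim1" if biased else "sim1-nobias"),
        truth=truth,
        set_truth=pd.DataFrame(set_rows).set_index("set"),
    )


def generate_sim1(design: Sim1Design) -> Sim1Data:
    """Length-ordered sets of independent Poisson genes (length bias present)."""
    return _sim1(design, biased=True)


def generate_no_bias(design: Sim1Design) -> Sim1Data:
    """Same Poisson model with random set assignment (no length bias)."""
    return _sim1(design, biased=False)


@dataclass(frozen=True)
class CorrelatedSetDesign:
    """Design of the hub-gene correlated-set simulation.

    A set of ``set_size`` genes with lengths in the ``set_length_window``
    fraction of the length range (default: the shortest quarter) is generated
    around a hub: gene i's latent Gaussian is
    ``rho_i * hub + sqrt(1 - rho_i^2) * noise`` with ``rho_i`` uniform on
    ``rho_range`` (the hub itself has rho = 1), then mapped through Poisson
    quantiles with mean ``l_i / 10``. A fraction ``de_prop`` of the members
    (hub first) is differentially expressed with effect ``beta``, all in the
    hub's (up) direction — members are recruited by their correlation with
    the hub, so their shifts are coordinated.

    The ``n_genes - set_size`` background genes are independent Poisson genes
    across the full length range, of which a fraction ``bg_de_prop`` is
    weakly differentially expressed (effect ``bg_beta``, half up, half down).
    This emulates a real two-condition experiment, where gene-level z spread
    grows with gene length: the same relative effect produces a larger z for
    a longer (higher-count) gene, so randomized competitor sets are length
    biased — the situation the weighted procedure targets.
    """

    n_genes: int = 2000
    set_size: int = 50
    n_control: int = 10
    n_treat: int = 10
    rho_range: Tuple[float, float] = (0.4, 0.9)
    de_prop: float = 0.5
    beta: float = 0.3
    bg_de_prop: float = 0.3
    bg_beta: float = 0.1
    length_range: Tuple[int, int] = (1000, 3000)
    set_length_window: Tuple[float, float] = (0.0, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rho_range[0] <= self.rho_range[1] <= 1):
            raise ValueError("infeasible correlation range")
        for prop in (self.de_prop, self.bg_de_prop):
            if not (0 <= prop <= 1):
                raise ValueError("DE proportions must lie in [0, 1]")
        if self.set_size > self.n_genes:
            raise ValueError("set_size exceeds the gene universe")
        w_lo, w_hi = self.set_length_window
        if not (0 <= w_lo < w_hi <= 1):
            raise ValueError("set_length_window must be an interval within [0, 1]")


@dataclass
class CorrelatedSetData:
    counts: CountMatrix
    table: pd.DataFrame
    gene_set: GeneSet
    truth: pd.DataFrame  # per set member: rho, direction
    is_de: bool


def generate_correlated_set(design: CorrelatedSetDesign) -> CorrelatedSetData:
    """Generate a hub-correlated gene set over a length-biased background."""
    rng = np.random.default_rng(design.seed)
    m = design.n_control + design.n_treat
    lo, hi = design.length_range
    n_bg = design.n_genes - design.set_size

    w_lo, w_hi = design.set_length_window
    set_lo = lo + int(round(w_lo * (hi - lo)))
    set_hi = lo + int(round(w_hi * (hi - lo)))
    set_lengths = rng.integers(set_lo, max(set_hi, set_lo + 1) + 1, size=design.set_size)
    bg_lengths = rng.integers(lo, hi + 1, size=n_bg)

    rho = rng.uniform(*design.rho_range, size=design.set_size)
    rho[0] = 1.0  # the hub
    hub_latent = rng.standard_normal(m)
    noise = rng.standard_normal((design.set_size, m))
    latent = rho[:, None] * hub_latent[None, :] + np.sqrt(1 - rho[:, None] ** 2) * noise
    U = stats.norm.cdf(latent)
    # numerical guard for the quantile transform
    U = np.clip(U, 1e-12, 1 - 1e-12)

    # DE members (hub first) all shift in the hub's direction: they are
    # recruited by correlation with the hub, so their changes are coordinated
    n_de = int(round(design.de_prop * design.set_size))
    direction = np.zeros(design.set_size, dtype=int)
    direction[:n_de] = 1

    mu = set_lengths / 10.0
    mu_mat = np.tile(mu[:, None], (1, m)).astype(float)
    treat_cols = np.arange(design.n_control, m)
    mu_mat[:, treat_cols] *= (1.0 + design.beta * direction)[:, None]
    set_counts = stats.poisson.ppf(U, mu_mat).astype(np.int64)

    # background: independent genes, a fraction weakly DE in both directions
    n_bg_de = int(round(design.bg_de_prop * n_bg))
    bg_direction = np.zeros(n_bg, dtype=int)
    de_idx = rng.choice(n_bg, size=n_bg_de, replace=False)
    bg_direction[de_idx[: n_bg_de // 2]] = 1
    bg_direction[de_idx[n_bg_de // 2:]] = -1
    bg_mu = np.tile((bg_lengths / 10.0)[:, None], (1, m))
    bg_mu[:, treat_cols] *= (1.0 + design.bg_beta * bg_direction)[:, None]
    bg_counts = rng.poisson(bg_mu)

    gene_ids = np.array(
        [f"s{i:03d}" for i in range(design.set_size)]
        + [f"b{i:04d}" for i in range(n_bg)]
    )
    samples = [f"c{j + 1}" for j in range(design.n_control)] + [
        f"t{j + 1}" for j in range(design.n_treat)
    ]
    counts = pd.DataFrame(
        np.vstack([set_counts, bg_counts]),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=samples,
    )
    groups = np.array(["control"] * design.n_control + ["treatment"] * design.n_treat)
    lengths = np.concatenate([set_lengths, bg_lengths])
    member_ids = tuple(gene_ids[: design.set_size])
    truth = pd.DataFrame(
        {"rho": rho, "direction": direction},
        index=pd.Index(member_ids, name="gene_id"),
    )
    return CorrelatedSetData(
        counts=CountMatrix(counts, groups),
        table=make_gene_table(gene_ids, lengths),
        gene_set=GeneSet("hub_set", member_ids),
        truth=truth,
        is_de=n_de > 0,
    )
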