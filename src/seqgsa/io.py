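"""Readers and writers for the tabular interchange formats.

Formats: GMT gene-set files (Broad dialect: name, description, member ids,
tab-separated), TSV/CSV count matrices (first column gene id, header row of
sample ids), two-column gene length tables, and the results TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, GeneSet, GeneSetCollection

logger = logging.getLogger("seqgsa")

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_counts",
    "read_lengths",
    "write_results",
    "parse_groups",
]

RESULT_COLUMNS = [
    "set",
    "n_S_used",
    "S",
    "mu_dag",
    "sigma_dag",
    "S_star",
    "p_value",
    "q_value",
]


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file into a collection, preserving file order.

    Each line must have at least three tab-separated fields (name,
    description, one or more member ids). Duplicate member ids within a set
    are removed with a warning; a malformed line raises with its number.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: malformed GMT line {lineno}: expected at least "
                    f"3 tab-separated fields, found {len(fields)}"
                )
            name = fields[0]
            members = [f for f in fields[2:] if f]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                logger.warning(
                    "GMT set %r (line %d): removed %d duplicate member id(s)",
                    name, lineno, len(members) - len(unique),
                )
            if not unique:
                raise ValueError(f"{path}: malformed GMT line {lineno}: no member ids")
            sets.append(GeneSet(name, tuple(unique)))
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, "na", *s.members]) + "\n")


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def parse_groups(spec: Union[str, Sequence[str]], samples: Sequence[str]) -> np.ndarray:
    """Resolve a group specification against the sample ids.

    ``spec`` is either a comma-separated label string aligned with the
    samples (``"a,a,b,b"``), a sequence of labels, or the path of a
    two-column TSV (sample id, group label).
    """
    if isinstance(spec, (str, Path)) and Path(str(spec)).exists():
        design = pd.read_csv(spec, sep="\t", header=None, names=["sample", "group"])
        design = design.set_index("sample")["group"]
        missing = [s for s in samples if s not in design.index]
        if missing:
            raise ValueError(f"design file lacks group labels for samples {missing}")
        return design.loc[list(samples)].to_numpy()
    if isinstance(spec, str):
        labels = [g.strip() for g in spec.split(",")]
    else:
        labels = list(spec)
    if len(labels) != len(samples):
        raise ValueError(
            f"{len(labels)} group labels for {len(samples)} samples"
        )
    return np.asarray(labels)


def read_counts(
    path,
    groups: Union[str, Sequence[str]],
    min_avg_count: float = 1.0,
) -> CountMatrix:
    """Read a count matrix and attach two-group labels.

    Genes whose average count falls below ``min_avg_count`` are filtered out
    (logged); entries must be non-negative integers.
    """
    df = _read_table(path)
    labels = parse_groups(groups, list(df.columns))
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: counts must be non-negative")
    low = df.mean(axis=1) < min_avg_count
    if low.any():
        logger.info(
            "filtered %d gene(s) with average count below %g", int(low.sum()), min_avg_count
        )
        df = df.loc[~low]
    return CountMatrix(df, labels)


def read_lengths(path) -> pd.Series:
    """Read a two-column gene length table (gene id, length in bp)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "length"], comment="#")
    numeric = pd.to_numeric(df["length"], errors="coerce")
    if len(df) and np.isnan(numeric.iloc[0]) and not numeric.iloc[1:].isna().any():
        df, numeric = df.iloc[1:], numeric.iloc[1:]  # tolerate a header row
    if numeric.isna().any():
        raise ValueError(f"{path}: non-numeric gene lengths")
    df = df.assign(length=numeric)
    if (df["length"] <= 0).any():
        raise ValueError("gene lengths must be positive")
    out = df.set_index("gene_id")["length"]
    if not out.index.is_unique:
        raise ValueError("duplicate gene ids in length table")
    return out


def write_results(results, path) -> None:
    """Write restandardization results as a TSV with fixed column order."""
    rows = [
        {
            "set": r.name,
            "n_S_used": r.n_used,
            "S": r.S,
            "mu_dag": r.mu_dag,
            "sigma_dag": r.sigma_dag,
            "S_star": r.S_star,
            "p_value": r.p_value,
            "q_value": r.q_value,
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
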