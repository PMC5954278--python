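"""Expression-matrix handling: reading, replicate merging, upper-quartile
normalization and variance filtering.

The normalization scales each sample so that the upper quartile of its
nonzero FPKM values equals the cross-sample mean of those quartiles:

    rho_i = (1/n * sum_j k_j) / k_i

where ``k_i`` is the 75th percentile of sample *i*'s nonzero values.  Zeros
are untouched (a zero times any factor stays zero), so the operation is a
pure per-sample rescaling of the detected transcriptome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

BIOTYPES = ("coding", "lncRNA")


class ExpressionFormatError(ValueError):
    """Raised when an expression table violates the expected format."""


class ExpressionValidationError(ValueError):
    """Raised when values or metadata fail validation."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of nonnegative abundances with biotype labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
    biotype
        Mapping gene id -> ``"coding"`` or ``"lncRNA"``, defined for every
        gene in ``values``.
    tissue
        Optional mapping sample id -> tissue label.
    """

    values: pd.DataFrame
    biotype: pd.Series
    tissue: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ExpressionFormatError(f"duplicate gene ids: {list(dupes)[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise ExpressionFormatError(f"duplicate sample ids: {list(dupes)[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ExpressionValidationError("non-numeric expression values")
        if np.isnan(arr).any():
            raise ExpressionValidationError("NaN expression values")
        if (arr < 0).any():
            raise ExpressionValidationError("negative expression values")
        self.biotype = pd.Series(self.biotype)
        missing = self.values.index.difference(self.biotype.index)
        if len(missing):
            raise ExpressionValidationError(
                f"biotype missing for genes: {list(missing)[:5]}"
            )
        bad = set(self.biotype.loc[self.values.index]) - set(BIOTYPES)
        if bad:
            raise ExpressionValidationError(f"unknown biotypes: {sorted(bad)}")
        # restrict metadata to the genes actually present, preserving order
        self.biotype = self.biotype.loc[self.values.index]
        if self.tissue is not None:
            self.tissue = pd.Series(self.tissue)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def genes_of_biotype(self, biotype: str) -> list[str]:
        return [g for g in self.values.index if self.biotype[g] == biotype]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            self.biotype.copy(),
            None if self.tissue is None else self.tissue.copy(),
        )


@dataclass
class ScalingFactors:
    """Per-sample upper quartiles ``k`` and scaling factors ``rho``."""

    k: pd.Series
    rho: pd.Series
    n: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n == 0:
            self.n = len(self.k)
        if (self.rho <= 0).any():
            raise ExpressionValidationError("scaling factors must be positive")


def read_expression(
    path, biotype_path, tissue_path=None
) -> ExpressionMatrix:
    """Read an expression matrix TSV plus its biotype (and tissue) tables.

    The matrix TSV has a ``gene_id`` column followed by one column per
    sample; the biotype table is two columns (gene_id, biotype); the
    optional tissue table is two columns (sample_id, tissue).
    """
    try:
        values = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ExpressionFormatError(f"cannot parse expression table {path}: {exc}")
    bio = pd.read_csv(biotype_path, sep="\t", index_col=0).iloc[:, 0]
    tissue = None
    if tissue_path is not None:
        tissue = pd.read_csv(tissue_path, sep="\t", index_col=0).iloc[:, 0]
    unknown = values.index.difference(bio.index)
    if len(unknown):
        raise ExpressionValidationError(
            f"genes absent from biotype table: {list(unknown)[:5]}"
        )
    return ExpressionMatrix(values, bio, tissue)


def write_expression(m: ExpressionMatrix, path, biotype_path=None, tissue_path=None):
    m.values.to_csv(path, sep="\t", index_label="gene_id")
    if biotype_path is not None:
        m.biotype.rename("biotype").to_csv(
            biotype_path, sep="\t", index_label="gene_id"
        )
    if tissue_path is not None and m.tissue is not None:
        m.tissue.rename("tissue").to_csv(
            tissue_path, sep="\t", index_label="sample_id"
        )


def merge_replicates(
    m: ExpressionMatrix, grouping: Mapping[str, str] | Callable[[str], str]
) -> ExpressionMatrix:
    """Collapse replicate samples to their arithmetic mean, one column per group."""
    if callable(grouping):
        grouping = {s: grouping(s) for s in m.sample_ids}
    unmapped = [s for s in m.sample_ids if s not in grouping]
    if unmapped:
        raise ExpressionValidationError(f"samples without group: {unmapped[:5]}")
    groups: dict[str, list[str]] = {}
    for s in m.sample_ids:  # preserve first-appearance group order
        groups.setdefault(grouping[s], []).append(s)
    for g, members in groups.items():
        if not members:
            raise ExpressionValidationError(f"empty group {g!r}")
    merged = pd.DataFrame(
        {g: m.values[members].mean(axis=1) for g, members in groups.items()},
        index=m.values.index,
    )
    tissue = None
    if m.tissue is not None:
        tissue = pd.Series(
            {g: m.tissue[members[0]] for g, members in groups.items()}
        )
    return ExpressionMatrix(merged, m.biotype, tissue)


def upper_quartile_normalize(
    m: ExpressionMatrix,
) -> tuple[ExpressionMatrix, ScalingFactors]:
    """Scale each sample by rho_i = mean(k)/k_i with k_i its nonzero upper quartile.

    Requires at least 4 nonzero values per sample; a sample of zeros has no
    detected transcriptome to scale and is reported by name.
    """
    ks = {}
    for s in m.sample_ids:
        col = m.values[s].to_numpy()
        nz = col[col > 0]
        if nz.size == 0:
            raise ExpressionValidationError(f"sample {s!r} is all zeros")
        if nz.size < 4:
            raise ExpressionValidationError(
                f"sample {s!r} has fewer than 4 nonzero values"
            )
        ks[s] = float(np.percentile(nz, 75))  # linear-interpolation quartile
    k = pd.Series(ks)
    rho = k.mean() / k
    scaled = m.values.mul(rho, axis=1)
    out = ExpressionMatrix(scaled, m.biotype, m.tissue)
    return out, ScalingFactors(k=k, rho=rho, n=len(k))


def variance_filter(
    m: ExpressionMatrix, keep_fraction: float = 0.75
) -> ExpressionMatrix:
    """Keep the ``ceil(keep_fraction * G)`` genes with highest sample variance.

    Retained genes keep their original order.  Variance is the unbiased
    sample variance across samples.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    variances = m.values.var(axis=1, ddof=1)
    n_keep = math.ceil(keep_fraction * len(variances))
    if n_keep == 0:
        raise ExpressionValidationError("variance filter would drop every gene")
    # stable sort: ties resolved by original position
    keep = set(variances.sort_values(ascending=False, kind="stable").index[:n_keep])
    kept_order = [g for g in m.gene_ids if g in keep]
    return ExpressionMatrix(m.values.loc[kept_order], m.biotype, m.tissue)
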