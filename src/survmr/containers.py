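"""Core in-memory containers shared across the pipeline.

All containers are thin, validated wrappers around :class:`pandas.DataFrame`
so that every stage exchanges plain tabular data and round-trips through TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Allowed expression scales, in the only legal processing order.
SCALES = ("raw", "uq_normalized", "log2")


class PipelineOrderError(RuntimeError):
    """Raised when preprocessing steps are applied out of order."""


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with per-variant metadata.

    Parameters
    ----------
    dosages
        DataFrame indexed by sample id, one column per variant id, values in
        [0, 2] counting copies of the effect (alt) allele.
    variant_meta
        DataFrame indexed by variant id with at least columns ``chrom``,
        ``pos`` (1-based), ``ref``, ``alt`` and ``maf``.
    """

    dosages: pd.DataFrame
    variant_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.variant_meta.index):
            missing = set(self.dosages.columns) ^ set(self.variant_meta.index)
            raise ValueError(f"dosage columns and variant metadata disagree: {sorted(missing)[:5]}")
        vals = self.dosages.to_numpy()
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def samples(self) -> pd.Index:
        return self.dosages.index

    @property
    def variants(self) -> pd.Index:
        return self.dosages.columns

    def empirical_maf(self) -> pd.Series:
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset_samples(self, samples) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[samples], self.variant_meta)

    def flip_variants(self, variant_ids) -> "GenotypeMatrix":
        """Return a copy with the named variants' effect alleles swapped."""
        d = self.dosages.copy()
        meta = self.variant_meta.copy()
        for v in variant_ids:
            d[v] = 2.0 - d[v]
            meta.loc[v, ["ref", "alt"]] = meta.loc[v, ["alt", "ref"]].to_numpy()
        return GenotypeMatrix(d, meta)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus per-gene TSS annotation.

    ``scale`` tracks where the matrix sits in the mandatory processing chain
    raw -> uq_normalized -> log2; preprocessing operations refuse inputs on
    the wrong scale.
    """

    values: pd.DataFrame
    gene_meta: pd.DataFrame  # index gene_id; columns chrom, tss
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        if self.scale == "raw" and self.values.size and self.values.to_numpy().min() < 0:
            raise ValueError("raw counts must be non-negative")
        missing = self.values.index.difference(self.gene_meta.index)
        if len(missing):
            raise ValueError(f"genes lack TSS annotation: {list(missing[:5])}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def require_scale(self, scale: str, op: str) -> None:
        if self.scale != scale:
            raise PipelineOrderError(
                f"{op} requires expression on the {scale!r} scale, got {self.scale!r}; "
                f"the pipeline order is raw -> uq_normalized -> log2"
            )

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.gene_meta.loc[values.index], scale or self.scale)


@dataclass
class ClinicalTable:
    """Per-sample survival outcome, treatment arm and clinical covariates.

    Required columns: ``os_time`` (positive), ``os_event`` (0/1), ``arm``.
    Typical extra columns: ``age``, ``gender``, ``braf_v600e``, ``all_ras``,
    ``tumor_location``, ``cms``.
    """

    table: pd.DataFrame
    required: tuple = ("os_time", "os_event", "arm")

    def __post_init__(self) -> None:
        for col in self.required:
            if col not in self.table.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        if (self.table["os_time"] <= 0).any():
            bad = self.table.index[self.table["os_time"] <= 0][:5]
            raise ValueError(f"non-positive OS times for samples {list(bad)}")
        ev = set(self.table["os_event"].unique())
        if not ev <= {0, 1}:
            raise ValueError(f"os_event must be 0/1, saw {sorted(ev)}")

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    def arm_samples(self, arm: str) -> pd.Index:
        return self.table.index[self.table["arm"] == arm]


@dataclass
class CovariateTable:
    """Per-sample numeric covariates used to adjust every model fit.

    Optionally includes immune-cell abundance columns (fractions in [0, 1])
    and expression principal components.
    """

    table: pd.DataFrame
    abundance_cols: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.table.isna().any().any():
            bad = self.table.columns[self.table.isna().any()]
            raise ValueError(f"covariates contain missing values in {list(bad)}")
        for col in self.abundance_cols:
            v = self.table[col]
            if (v < 0).any():
                raise ValueError(f"abundance column {col!r} has negative entries")
        if self.abundance_cols:
            tot = self.table[self.abundance_cols].sum(axis=1)
            if (tot > 1.0 + 1e-6).any():
                raise ValueError("abundance fractions sum to more than 1 for some samples")

    @property
    def samples(self) -> pd.Index:
        return self.table.index
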