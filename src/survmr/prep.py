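"""RNA-seq preprocessing, normalization and QC.

The mandatory processing chain is

    sample QC -> gene filtering (raw counts) -> upper-quartile normalization
    -> log2(x + 1) transform,

enforced through the ``scale`` flag on :class:`ExpressionMatrix`; applying a
step out of order raises :class:`PipelineOrderError`.

Filtering conventions
---------------------
* Genes are dropped when their zero fraction exceeds 30% (strict) or their
  across-sample standard deviation falls below 0.5.  The SD is evaluated on
  log2(count + 1) by default — an SD cutoff of 0.5 is only meaningful on a
  log scale — with ``sd_scale='raw'`` available as a switch.
* Immune-cell abundance columns are kept when at most 30% of scores are zero
  and the SD is strictly greater than 0.12.
* Samples with more than 50% zero-count genes are removed before gene
  filtering; duplicate samples are flagged both by exact id duplication and
  by an expression Pearson correlation >= 0.999.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from survmr.containers import ExpressionMatrix

GENE_SD_MIN = 0.5
GENE_ZERO_FRAC_MAX = 0.30
SAMPLE_ZERO_FRAC_MAX = 0.50
ABUNDANCE_SD_MIN = 0.12
ABUNDANCE_ZERO_FRAC_MAX = 0.30
DUPLICATE_CORR = 0.999


def remove_low_coverage_samples(E: ExpressionMatrix, max_zero_frac: float = SAMPLE_ZERO_FRAC_MAX):
    """Drop samples with more than ``max_zero_frac`` zero-count genes."""
    E.require_scale("raw", "sample QC")
    zf = (E.values == 0).mean(axis=0)
    keep = zf <= max_zero_frac
    removed = list(E.samples[~keep])
    return E.with_values(E.values.loc[:, keep]), removed


def find_duplicate_samples(E: ExpressionMatrix, corr_threshold: float = DUPLICATE_CORR) -> dict:
    """Report (never silently drop) duplicate samples.

    Two criteria are reported separately: exact sample-id duplication, and
    pairs of distinct samples whose expression Pearson correlation reaches
    ``corr_threshold``.
    """
    ids = pd.Index(E.samples)
    dup_ids = sorted(set(ids[ids.duplicated()]))
    corr = np.corrcoef(E.values.to_numpy(dtype=float).T)
    iu = np.triu_indices(len(ids), k=1)
    hits = [
        (ids[i], ids[j], float(corr[i, j]))
        for i, j in zip(*iu)
        if corr[i, j] >= corr_threshold
    ]
    return {"duplicated_ids": dup_ids, "correlated_pairs": hits}


def filter_genes(
    E: ExpressionMatrix,
    sd_min: float = GENE_SD_MIN,
    max_zero_frac: float = GENE_ZERO_FRAC_MAX,
    sd_scale: str = "log2",
):
    """Drop low-variation and low-count genes from a raw count matrix.

    Retains exactly the genes with standard deviation >= ``sd_min`` (on
    log2(count+1) unless ``sd_scale='raw'``) AND zero fraction <=
    ``max_zero_frac``; gene order is preserved.  The operation is idempotent.
    """
    E.require_scale("raw", "gene filtering")
    counts = E.values.to_numpy(dtype=float)
    vals = np.log2(counts + 1.0) if sd_scale == "log2" else counts
    sd = vals.std(axis=1, ddof=1)
    zero_frac = (counts == 0).mean(axis=1)
    keep = (sd >= sd_min) & (zero_frac <= max_zero_frac)
    if not keep.any():
        raise ValueError("gene filtering removed every gene")
    removed = [
        {"gene_id": g, "sd": float(s), "zero_frac": float(z)}
        for g, s, z, k in zip(E.genes, sd, zero_frac, keep)
        if not k
    ]
    return E.with_values(E.values.loc[keep]), removed


def upper_quartile_normalize(E: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample by its 75th percentile of nonzero counts.

    Values are divided by the per-sample upper quartile (linear-interpolation
    percentile of the sample's nonzero counts) and multiplied by the
    across-sample mean of those quartiles, so the output stays on a
    count-like scale and every sample's nonzero upper quartile is identical
    afterwards.
    """
    E.require_scale("raw", "upper-quartile normalization")
    counts = E.values.to_numpy(dtype=float)
    q = np.empty(counts.shape[1])
    for j in range(counts.shape[1]):
        nz = counts[:, j][counts[:, j] > 0]
        if nz.size == 0:
            raise ValueError(f"sample {E.samples[j]!r} has all-zero counts")
        q[j] = np.percentile(nz, 75)
    scaled = counts / q[None, :] * q.mean()
    out = pd.DataFrame(scaled, index=E.genes, columns=E.samples)
    return E.with_values(out, scale="uq_normalized")


def log2_transform(E: ExpressionMatrix) -> ExpressionMatrix:
    """x -> log2(x + 1), normalized scale only."""
    E.require_scale("uq_normalized", "log2 transform")
    vals = E.values.to_numpy(dtype=float)
    if vals.min() < 0:
        raise ValueError("negative expression values before log transform")
    return E.with_values(np.log2(E.values + 1.0), scale="log2")


def infer_genetic_sex(E: ExpressionMatrix, chry_genes, reported=None, seed: int = 0):
    """2-means clustering on chromosome-Y expression to infer genetic sex.

    The cluster with the higher mean chrY expression is labeled male (1).
    Returns the inferred labels and, when reported labels are supplied, the
    list of mismatched samples.
    """
    E.require_scale("log2", "sex inference")
    chry = [g for g in chry_genes if g in E.genes]
    if len(chry) < 2:
        raise ValueError("need at least two chromosome-Y genes for sex inference")
    X = E.values.loc[chry].to_numpy(dtype=float).T  # samples x chrY genes
    if X.shape[0] < 2:
        raise ValueError("need at least two samples to form two clusters")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("all chromosome-Y genes constant: clustering degenerate")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(X)
    means = [X[km.labels_ == c].mean() for c in (0, 1)]
    male_cluster = int(np.argmax(means))
    inferred = pd.Series((km.labels_ == male_cluster).astype(int), index=E.samples, name="inferred_male")
    mismatches = []
    if reported is not None:
        rep = pd.Series(reported, index=E.samples) if not isinstance(reported, pd.Series) else reported
        mismatches = list(E.samples[inferred.to_numpy() != rep.loc[E.samples].to_numpy()])
    return inferred, mismatches


def filter_cell_abundance(
    A: pd.DataFrame,
    sd_min: float = ABUNDANCE_SD_MIN,
    max_zero_frac: float = ABUNDANCE_ZERO_FRAC_MAX,
) -> list:
    """Return the enriched cell types of an abundance table (samples x types).

    A cell type is enriched when at most 30% of its scores are zero and its
    standard deviation is strictly greater than 0.12.
    """
    vals = A.to_numpy(dtype=float)
    if vals.min() < -1e-12 or vals.max() > 1 + 1e-9:
        raise ValueError("abundances must lie in [0, 1]")
    sd = vals.std(axis=0, ddof=1)
    zf = (vals == 0).mean(axis=0)
    keep = [c for c, s, z in zip(A.columns, sd, zf) if (z <= max_zero_frac and s > sd_min)]
    if not keep:
        warnings.warn("no cell type passed the enrichment filter", stacklevel=2)
    return keep


def pca_qc(E: ExpressionMatrix, k: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-k principal components of the sample x gene matrix.

    Genes are centered across samples; components are ordered by decreasing
    explained variance, and each component's sign is fixed so its
    largest-magnitude gene loading is positive.  Returns (scores, explained
    variance ratio).
    """
    E.require_scale("log2", "PCA QC")
    n_genes, n_samples = E.values.shape
    if not (0 < k < min(n_genes, n_samples)):
        raise ValueError(f"k must lie in (0, {min(n_genes, n_samples)})")
    X = E.values.to_numpy(dtype=float).T  # samples x genes
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            pca.components_[j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(k)]
    return pd.DataFrame(scores, index=E.samples, columns=cols), pca.explained_variance_ratio_
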