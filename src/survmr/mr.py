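"""The causal pipeline: screening, pleiotropy exclusion, IV pruning and MR.

One-sample Mendelian randomization proceeds in three steps, run separately
for each treatment arm:

1. *Screen* — genes are partitioned into k = 4 k-means clusters and each
   cluster's genes enter one multivariable Aalen additive-hazard fit together
   with the clinical covariates; genes with p < 0.1 advance.
2. *Instrument validity* — every candidate instrument (cis-eQTL variant) is
   tested for a direct effect on overall survival with a covariate-adjusted
   Cox model on the pooled arms (a survival GWAS); variants with Wald
   p < 1e-4 are excluded as pleiotropic.
3. *Causal test* — surviving instruments are pruned by complete-linkage
   hierarchical clustering on 1 - r^2 (clusters formed at r^2 > 0.1, one
   best-eQTL proxy per cluster); the gene's expression is predicted as
   g_hat = Q W from the proxies' dosages Q and marginal eQTL slopes W, and
   g_hat enters an arm-specific multivariable additive-hazard model.

Two-sample replication predicts expression in a genotype-only cohort as
g_hat* = Q* (Q'Q)^{-1} Q' g — the joint least-squares fit of observed
expression on proxy dosages in the discovery cohort applied to validation
dosages — and repeats the arm-specific additive-hazard test, calling a
replication when the p-value passes and the effect direction is concordant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from survmr.containers import ClinicalTable, CovariateTable, ExpressionMatrix, GenotypeMatrix
from survmr.hazards import aalen_test, fit_aalen, fit_coxph

SCREEN_ALPHA = 0.1
PLEIOTROPY_ALPHA = 1e-4
R2_THRESHOLD = 0.1
MR_ALPHA = 0.05
N_CLUSTERS = 4
COLLINEAR_TOL = 1e-8


@dataclass
class IvSet:
    """A gene's pruned instruments with their eQTL weights."""

    gene_id: str
    ivs: list  # [(variant_id, weight)]

    def __post_init__(self) -> None:
        if not self.ivs:
            raise ValueError(f"empty instrument set for {self.gene_id}")

    @property
    def variants(self) -> list:
        return [v for v, _ in self.ivs]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.ivs], dtype=float)


@dataclass
class MrResult:
    gene_id: str
    arm: str
    stage: str  # screen | one_sample | two_sample
    p_value: float
    direction: int  # sign of the standardized hazard effect
    n_ivs: int = 0
    statistic: float = 0.0
    replicated: bool | None = None


@dataclass
class ScreenReport:
    results: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


def cluster_genes(E: ExpressionMatrix, k: int = N_CLUSTERS, seed: int = 0) -> pd.Series:
    """k-means partition of genes on standardized expression profiles.

    Genes are the points, samples the dimensions; each gene profile is
    z-scored across samples first.  Returns cluster ids 1..k.
    """
    E.require_scale("log2", "gene clustering")
    X = E.values.to_numpy(dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of genes ({X.shape[0]})")
    sd = X.std(axis=1, keepdims=True)
    Z = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Z)
    return pd.Series(km.labels_ + 1, index=E.genes, name="cluster")


def _design_from(parts: list, index) -> tuple[np.ndarray, list]:
    names, cols = ["intercept"], [np.ones(len(index))]
    for name, series in parts:
        names.append(name)
        cols.append(np.asarray(series, dtype=float))
    return np.column_stack(cols), names


def _covariate_parts(C: CovariateTable | pd.DataFrame | None, samples) -> list:
    if C is None:
        return []
    tab = C.table if isinstance(C, CovariateTable) else C
    return [(c, tab.loc[samples, c].to_numpy(dtype=float)) for c in tab.columns]


def screen_gene_os(
    E: ExpressionMatrix,
    clinical: ClinicalTable,
    C: CovariateTable | pd.DataFrame | None,
    clusters: pd.Series,
    arm: str,
    alpha: float = SCREEN_ALPHA,
    min_events: int = 20,
) -> ScreenReport:
    """Gene–OS association screen within one treatment arm.

    Per gene cluster, one multivariable additive-hazard fit containing all
    the cluster's (centered log2) expression values plus the covariates;
    genes with additive-hazard test p strictly below ``alpha`` pass.  A
    cluster larger than events/5 is sub-split (overfitting guard) with a
    warning.
    """
    E.require_scale("log2", "gene-OS screen")
    report = ScreenReport()
    samples = clinical.arm_samples(arm).intersection(E.samples)
    tab = clinical.table.loc[samples]
    n_events = int(tab["os_event"].sum())
    if n_events < min_events:
        raise ValueError(f"arm {arm!r} has only {n_events} events (< {min_events})")

    for cid in sorted(clusters.unique()):
        genes = list(clusters.index[clusters == cid])
        chunks = [genes]
        max_genes = max(1, n_events // 5)
        if len(genes) > max_genes:
            msg = f"cluster {cid} has {len(genes)} genes for {n_events} events; sub-splitting"
            warnings.warn(msg, stacklevel=2)
            report.warnings.append(msg)
            chunks = [genes[i : i + max_genes] for i in range(0, len(genes), max_genes)]
        for chunk in chunks:
            parts = []
            for g in chunk:
                x = E.values.loc[g, samples].to_numpy(dtype=float)
                parts.append((g, x - x.mean()))
            parts += _covariate_parts(C, samples)
            X, names = _design_from(parts, samples)
            fit = fit_aalen(X, tab["os_time"], tab["os_event"], names)
            for g in chunk:
                stat, z, p = aalen_test(fit, g)
                if p < alpha:
                    report.results.append(
                        MrResult(g, arm, "screen", p, int(np.sign(z)), statistic=float(z))
                    )
    return report


def pleiotropy_screen(
    G: GenotypeMatrix,
    clinical: ClinicalTable,
    C: CovariateTable | pd.DataFrame | None,
    candidate_ivs,
    alpha: float = PLEIOTROPY_ALPHA,
) -> tuple[set, pd.Series]:
    """Survival GWAS on candidate instruments; excludes pleiotropic variants.

    Per variant, a Cox proportional-hazards fit of OS on dosage plus the
    covariates, arms pooled; variants with Wald p strictly below ``alpha``
    are excluded.  A non-converging fit excludes the variant conservatively.
    Returns (excluded variant set, per-variant p-values).
    """
    samples = clinical.samples.intersection(G.samples)
    tab = clinical.table.loc[samples]
    cov_parts = _covariate_parts(C, samples)
    excluded, pvals = set(), {}
    for v in candidate_ivs:
        if v not in G.variants:
            raise KeyError(f"candidate instrument {v!r} absent from genotypes")
        parts = [("dosage", G.dosages.loc[samples, v].to_numpy(dtype=float))] + cov_parts
        X = np.column_stack([c for _, c in parts])
        names = [n for n, _ in parts]
        try:
            fit = fit_coxph(X, tab["os_time"], tab["os_event"], names)
        except np.linalg.LinAlgError:
            excluded.add(v)
            pvals[v] = np.nan
            warnings.warn(f"Cox fit failed for {v}; excluded conservatively", stacklevel=2)
            continue
        if not fit.converged:
            excluded.add(v)
            pvals[v] = np.nan
            warnings.warn(f"Cox fit did not converge for {v}; excluded conservatively", stacklevel=2)
            continue
        p = float(fit.wald_p[0])
        pvals[v] = p
        if p < alpha:
            excluded.add(v)
    return excluded, pd.Series(pvals, name="p_gwas")


def prune_ivs(
    gene_eqtls: pd.DataFrame,
    G: GenotypeMatrix,
    r2_threshold: float = R2_THRESHOLD,
) -> IvSet:
    """LD-prune one gene's instruments to one proxy per correlation cluster.

    Complete-linkage hierarchical clustering on distance 1 - r^2, cut so that
    any merged cluster has all pairwise r^2 strictly above ``r2_threshold``;
    the proxy of each cluster is its variant with the smallest eQTL nominal
    p-value, and the proxy's weight is its marginal eQTL slope.
    """
    if gene_eqtls.empty:
        raise ValueError("no surviving instruments to prune")
    gene_ids = gene_eqtls["gene_id"].unique()
    if len(gene_ids) != 1:
        raise ValueError("prune_ivs expects the eQTL records of a single gene")
    recs = gene_eqtls.sort_values(["p_nominal", "variant_id"]).reset_index(drop=True)
    vids = list(recs["variant_id"])
    if len(vids) == 1:
        row = recs.iloc[0]
        return IvSet(gene_ids[0], [(row["variant_id"], float(row["beta"]))])

    dos = G.dosages[vids].to_numpy(dtype=float)
    r2 = np.corrcoef(dos.T) ** 2
    np.fill_diagonal(r2, 1.0)
    dist = squareform(1.0 - r2, checks=False)
    tree = linkage(dist, method="complete")
    # merge while cophenetic distance < 1 - threshold, i.e. r^2 > threshold
    labels = fcluster(tree, t=(1.0 - r2_threshold) - 1e-12, criterion="distance")
    ivs = []
    for c in np.unique(labels):
        members = recs.iloc[np.flatnonzero(labels == c)]
        best = members.iloc[0]  # records pre-sorted by (p_nominal, variant_id)
        ivs.append((best["variant_id"], float(best["beta"])))
    ivs.sort(key=lambda t: t[0])
    return IvSet(gene_ids[0], ivs)


def predict_expression_one_sample(ivset: IvSet, G: GenotypeMatrix) -> pd.Series:
    """g_hat = Q W: proxy dosages times marginal eQTL weights."""
    for v in ivset.variants:
        if v not in G.variants:
            raise KeyError(f"proxy variant {v!r} absent from genotypes")
    Q = G.dosages[ivset.variants].to_numpy(dtype=float)
    return pd.Series(Q @ ivset.weights, index=G.samples, name=ivset.gene_id)


def _drop_collinear(parts: list, n: int) -> tuple[list, list]:
    """Greedily drop later gene columns that are collinear with earlier ones."""
    kept, dropped = [], []
    basis = [np.ones(n) / np.sqrt(n)]
    for name, col in parts:
        v = np.asarray(col, dtype=float).copy()
        norm0 = np.linalg.norm(v)
        for b in basis:
            v -= (v @ b) * b
        if norm0 == 0 or np.linalg.norm(v) < COLLINEAR_TOL * max(norm0, 1.0):
            dropped.append(name)
            continue
        basis.append(v / np.linalg.norm(v))
        kept.append((name, col))
    return kept, dropped


def _mr_hazard_fit(predictions: dict, clinical: ClinicalTable, C, arm: str, stage: str, alpha: float):
    samples = clinical.arm_samples(arm)
    for g in predictions:
        samples = samples.intersection(predictions[g].index)
    tab = clinical.table.loc[samples]
    gene_parts = []
    for g, ghat in predictions.items():
        x = ghat.loc[samples].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"predicted expression of {g} is constant in arm {arm!r}")
        gene_parts.append((g, x - x.mean()))
    gene_parts, dropped = _drop_collinear(gene_parts, len(samples))
    if dropped:
        warnings.warn(f"collinear predictions dropped in {stage}: {dropped}", stacklevel=3)
    parts = gene_parts + _covariate_parts(C, samples)
    X, names = _design_from(parts, samples)
    fit = fit_aalen(X, tab["os_time"], tab["os_event"], names)
    out = []
    for g, _ in gene_parts:
        stat, z, p = aalen_test(fit, g)
        out.append(
            MrResult(g, arm, stage, p, int(np.sign(z)) if z != 0 else 0,
                     n_ivs=0, statistic=float(z))
        )
    return out, dropped


def one_sample_mr(
    predictions: dict,
    clinical: ClinicalTable,
    C: CovariateTable | pd.DataFrame | None,
    arm: str,
    alpha_mr: float = MR_ALPHA,
    ivsets: dict | None = None,
) -> list:
    """Arm-specific multivariable additive-hazard test of all g_hat jointly.

    ``predictions`` maps gene id to its per-sample predicted expression.
    Returns an MrResult per tested gene (all genes, so callers can both
    read off significant hits and audit near-misses); ``p_value < alpha_mr``
    is the causal call.
    """
    results, _ = _mr_hazard_fit(predictions, clinical, C, arm, "one_sample", alpha_mr)
    if ivsets:
        for r in results:
            if r.gene_id in ivsets:
                r.n_ivs = len(ivsets[r.gene_id].ivs)
    return results


def predict_expression_two_sample(Q_discovery, g_discovery, Q_validation, ridge_rel: float = 1e-8):
    """g_hat* = Q* (Q'Q)^{-1} Q' g for a genotype-only cohort.

    ``Q_discovery``/``Q_validation`` are dosage matrices over the same
    proxies aligned to the same effect alleles; ``g_discovery`` is the
    discovery cohort's observed expression.  A singular Q'Q falls back to a
    ridge solve with penalty ``ridge_rel * trace(Q'Q) / p`` (warned).
    """
    Q = np.asarray(Q_discovery, dtype=float)
    Qs = np.asarray(Q_validation, dtype=float)
    g = np.asarray(g_discovery, dtype=float)
    if Q.shape[1] != Qs.shape[1]:
        raise ValueError("discovery and validation proxy sets differ")
    QtQ = Q.T @ Q
    Qtg = Q.T @ g
    sv = np.linalg.svd(QtQ, compute_uv=False)
    if sv[-1] <= 1e-12 * sv[0]:
        lam = ridge_rel * np.trace(QtQ) / Q.shape[1]
        warnings.warn(f"singular Q'Q; ridge fallback with penalty {lam:.3g}", stacklevel=2)
        QtQ = QtQ + lam * np.eye(Q.shape[1])
    theta = np.linalg.solve(QtQ, Qtg)
    return Qs @ theta


def two_sample_mr(
    predictions_validation: dict,
    clinical_validation: ClinicalTable,
    C: CovariateTable | pd.DataFrame | None,
    arm: str,
    one_sample_directions: dict | None = None,
    alpha: float = MR_ALPHA,
) -> list:
    """Replication test of predicted expression in the validation cohort.

    A gene replicates when its arm-specific additive-hazard p-value is below
    ``alpha`` AND its effect direction matches the one-sample result.
    """
    results, _ = _mr_hazard_fit(
        predictions_validation, clinical_validation, C, arm, "two_sample", alpha
    )
    for r in results:
        if one_sample_directions and r.gene_id in one_sample_directions:
            r.replicated = bool(r.p_value < alpha and r.direction == one_sample_directions[r.gene_id])
    return results


def results_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "arm": r.arm,
                "stage": r.stage,
                "p_value": r.p_value,
                "direction": r.direction,
                "n_ivs": r.n_ivs,
                "statistic": r.statistic,
                "replicated": r.replicated,
            }
            for r in results
        ]
    )
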