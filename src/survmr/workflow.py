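"""End-to-end orchestration of the discovery and validation analyses.

:func:`run_discovery` executes preprocessing -> cis-eQTL mapping -> gene-OS
screen -> pleiotropy screen -> instrument pruning -> one-sample MR -> subtype
enrichment on a discovery cohort (genotypes + RNA-seq + clinical), recording
sample/gene/variant counts after every filter in a run manifest.

:func:`run_validation` replicates the one-sample causal hits in a
genotype-only cohort by two-sample MR, harmonizing effect alleles between the
cohorts first.  The validation cohort has no RNA-seq, so only the clinical
covariates are adjusted for there.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from survmr import cms as cms_mod
from survmr import eqtl as eqtl_mod
from survmr import mr as mr_mod
from survmr import prep
from survmr.containers import ClinicalTable, CovariateTable, ExpressionMatrix, GenotypeMatrix

log = logging.getLogger("survmr")

CLINICAL_COVARIATES = ("age", "gender", "braf_v600e", "all_ras")


@dataclass
class RunConfig:
    """Every pipeline threshold in one audited location.

    Defaults are the analysis constants of the published workflow; the
    manifest echoes the configuration verbatim.
    """

    gene_sd_min: float = 0.5
    gene_zero_frac_max: float = 0.30
    sample_zero_frac_max: float = 0.50
    abundance_sd_min: float = 0.12
    abundance_zero_frac_max: float = 0.30
    cis_window: int = 1_000_000
    maf_min: float = 0.05
    egene_alpha: float = 0.05
    iv_nominal_alpha: float = 0.05
    screen_alpha: float = 0.1
    pleiotropy_alpha: float = 1e-4
    r2_threshold: float = 0.1
    mr_alpha: float = 0.05
    enrichment_rate: float = 0.70
    k_clusters: int = 4
    n_perm: int = 10_000
    adaptive_stop: int | None = 100
    n_pcs: int = 2
    min_events: int = 20
    seed: int = 0
    arms: tuple = ("bevacizumab", "cetuximab")


@dataclass
class DiscoveryResult:
    manifest: dict
    expression_log2: ExpressionMatrix
    genotypes: GenotypeMatrix
    covariates: pd.DataFrame          # model covariates (clinical + abundances)
    eqtls: pd.DataFrame
    gene_level: list
    egenes: list
    clusters: pd.Series
    screen_results: list
    excluded_variants: set
    gwas_pvalues: pd.Series
    ivsets: dict
    predictions: dict
    mr_results: list = field(default_factory=list)
    causal: list = field(default_factory=list)
    enrichment: pd.DataFrame | None = None

    def causal_directions(self, arm: str) -> dict:
        return {r.gene_id: r.direction for r in self.causal if r.arm == arm}


def _manifest_entry(manifest: dict, key: str, value) -> None:
    manifest[key] = value
    log.info("%s = %s", key, value)


def run_discovery(
    G: GenotypeMatrix,
    E_raw: ExpressionMatrix,
    clinical: ClinicalTable,
    covariates: pd.DataFrame | None = None,
    abundances: pd.DataFrame | None = None,
    cfg: RunConfig | None = None,
) -> DiscoveryResult:
    """Run the full discovery workflow; see the module docstring.

    ``covariates`` defaults to the clinical columns age / gender /
    braf_v600e / all_ras; enriched immune-cell abundance columns (from
    ``abundances``) are appended for the eQTL, screen and MR models.
    """
    cfg = cfg or RunConfig()
    manifest: dict = {"config": asdict(cfg), "counts": {}}
    counts = manifest["counts"]
    samples = E_raw.samples.intersection(G.samples).intersection(clinical.samples)
    if len(samples) == 0:
        raise ValueError("discovery stages share no samples")
    E_raw = E_raw.with_values(E_raw.values[samples])
    _manifest_entry(counts, "samples_in", len(samples))
    _manifest_entry(counts, "genes_in", len(E_raw.genes))
    _manifest_entry(counts, "variants_in", len(G.variants))

    # ---- sample and gene QC, normalization -------------------------------
    E_qc, removed_samples = prep.remove_low_coverage_samples(E_raw, cfg.sample_zero_frac_max)
    dup_report = prep.find_duplicate_samples(E_qc)
    E_filt, removed_genes = prep.filter_genes(E_qc, cfg.gene_sd_min, cfg.gene_zero_frac_max)
    E_log2 = prep.log2_transform(prep.upper_quartile_normalize(E_filt))
    samples = E_log2.samples
    _manifest_entry(counts, "samples_after_qc", len(samples))
    _manifest_entry(counts, "genes_after_filter", len(E_log2.genes))
    manifest["removed_samples"] = list(removed_samples)
    manifest["duplicate_report"] = {
        "duplicated_ids": dup_report["duplicated_ids"],
        "n_correlated_pairs": len(dup_report["correlated_pairs"]),
    }

    # ---- genotype MAF filter ---------------------------------------------
    maf = G.empirical_maf()
    keep_variants = maf.index[maf >= cfg.maf_min]
    G = GenotypeMatrix(G.dosages[keep_variants], G.variant_meta.loc[keep_variants])
    _manifest_entry(counts, "variants_after_maf", len(keep_variants))

    # ---- covariates -------------------------------------------------------
    if covariates is None:
        cov = clinical.table.loc[samples, list(CLINICAL_COVARIATES)].astype(float)
    else:
        cov = covariates.loc[samples].astype(float)
    enriched_types: list = []
    if abundances is not None:
        enriched_types = prep.filter_cell_abundance(
            abundances.loc[samples], cfg.abundance_sd_min, cfg.abundance_zero_frac_max
        )
        cov = cov.join(abundances.loc[samples, enriched_types])
    _manifest_entry(counts, "enriched_cell_types", len(enriched_types))
    pcs, _ = prep.pca_qc(E_log2, cfg.n_pcs)

    # ---- cis-eQTL mapping -------------------------------------------------
    eqtls = eqtl_mod.map_cis_eqtl(E_log2, G, cov, cfg.cis_window)
    gene_level = [
        eqtl_mod.permute_gene_pvalue(
            g, E_log2, G, cov, n_perm=cfg.n_perm, seed=cfg.seed,
            window=cfg.cis_window, adaptive_stop=cfg.adaptive_stop,
        )
        for g in E_log2.genes
        if not eqtls.empty and (eqtls["gene_id"] == g).any()
    ]
    egenes = eqtl_mod.select_egenes(gene_level, cfg.egene_alpha)
    _manifest_entry(counts, "egenes", len(egenes))
    E_egenes = E_log2.with_values(E_log2.values.loc[egenes])
    if not egenes:
        raise ValueError("no e-gene passed the permutation threshold; nothing to screen")

    # ---- gene-OS screen ---------------------------------------------------
    clusters = mr_mod.cluster_genes(E_egenes, k=min(cfg.k_clusters, len(egenes)), seed=cfg.seed)
    screen_results = []
    for arm in cfg.arms:
        rep = mr_mod.screen_gene_os(
            E_egenes, clinical, cov, clusters, arm, cfg.screen_alpha, cfg.min_events
        )
        screen_results.extend(rep.results)
        _manifest_entry(counts, f"screened_{arm}", sum(r.arm == arm for r in rep.results))
    screened_genes = sorted({r.gene_id for r in screen_results})

    # ---- pleiotropy screen ------------------------------------------------
    candidate = eqtls[
        eqtls["gene_id"].isin(screened_genes) & (eqtls["p_nominal"] < cfg.iv_nominal_alpha)
    ]
    gwas_cov = cov[[c for c in cov.columns if c in CLINICAL_COVARIATES]].join(pcs[["PC1"]])
    excluded, gwas_p = mr_mod.pleiotropy_screen(
        G, clinical, gwas_cov, sorted(candidate["variant_id"].unique()), cfg.pleiotropy_alpha
    )
    _manifest_entry(counts, "candidate_ivs", candidate["variant_id"].nunique())
    _manifest_entry(counts, "pleiotropic_excluded", len(excluded))

    # ---- IV pruning and one-sample MR ------------------------------------
    ivsets, predictions = {}, {}
    for g in screened_genes:
        recs = candidate[(candidate["gene_id"] == g) & ~candidate["variant_id"].isin(excluded)]
        if recs.empty:
            log.info("gene %s lost all instruments; skipped in MR", g)
            continue
        ivsets[g] = mr_mod.prune_ivs(recs, G, cfg.r2_threshold)
        predictions[g] = mr_mod.predict_expression_one_sample(ivsets[g], G)
    _manifest_entry(counts, "genes_with_instruments", len(ivsets))

    mr_results, causal = [], []
    for arm in cfg.arms:
        arm_genes = {r.gene_id for r in screen_results if r.arm == arm}
        preds = {g: predictions[g] for g in sorted(arm_genes) if g in predictions}
        if not preds:
            continue
        res = mr_mod.one_sample_mr(preds, clinical, cov, arm, cfg.mr_alpha, ivsets)
        mr_results.extend(res)
        causal.extend([r for r in res if r.p_value < cfg.mr_alpha])
    _manifest_entry(counts, "causal_genes", len({r.gene_id for r in causal}))

    # ---- subtype enrichment ----------------------------------------------
    enrichment = None
    if "cms" in clinical.table.columns and causal:
        enrichment = cms_mod.enrich_causal_genes(
            E_egenes, causal, clinical.table.loc[samples, "cms"], cfg.enrichment_rate
        )
        _manifest_entry(
            counts, "enriched_gene_subtypes",
            0 if enrichment.empty else int(enrichment["enriched"].sum()),
        )

    return DiscoveryResult(
        manifest=manifest,
        expression_log2=E_log2,
        genotypes=G,
        covariates=cov,
        eqtls=eqtls,
        gene_level=gene_level,
        egenes=egenes,
        clusters=clusters,
        screen_results=screen_results,
        excluded_variants=excluded,
        gwas_pvalues=gwas_p,
        ivsets=ivsets,
        predictions=predictions,
        mr_results=mr_results,
        causal=causal,
        enrichment=enrichment,
    )


def harmonize_alleles(G_val: GenotypeMatrix, meta_disc: pd.DataFrame, variants) -> GenotypeMatrix:
    """Align validation dosages to the discovery cohort's effect alleles.

    Variants whose ref/alt are swapped between cohorts are flipped
    (dosage -> 2 - dosage); any other allele mismatch aborts with the
    offending variants listed.
    """
    flips, bad = [], []
    for v in variants:
        if v not in G_val.variants:
            bad.append(v)
            continue
        rd, ad = meta_disc.loc[v, "ref"], meta_disc.loc[v, "alt"]
        rv, av = G_val.variant_meta.loc[v, "ref"], G_val.variant_meta.loc[v, "alt"]
        if (rd, ad) == (rv, av):
            continue
        if (rd, ad) == (av, rv):
            flips.append(v)
        else:
            bad.append(v)
    if bad:
        raise ValueError(f"allele mismatch between cohorts for variants: {bad[:10]}")
    if flips:
        log.info("flipped %d variants to the discovery effect allele", len(flips))
        G_val = G_val.flip_variants(flips)
    return G_val


def run_validation(
    G_val: GenotypeMatrix,
    clinical_val: ClinicalTable,
    discovery: DiscoveryResult,
    cfg: RunConfig | None = None,
    covariates_val: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Two-sample MR replication of the discovery causal genes.

    Returns the replication table (gene, arm, p, direction, concordance
    flag); empty when the discovery run found no causal genes.
    """
    cfg = cfg or RunConfig()
    causal_genes = sorted({r.gene_id for r in discovery.causal})
    if not causal_genes:
        return mr_mod.results_frame([])

    needed = sorted({v for g in causal_genes for v in discovery.ivsets[g].variants})
    G_val = harmonize_alleles(G_val, discovery.genotypes.variant_meta, needed)
    val_samples = clinical_val.samples.intersection(G_val.samples)
    disc_samples = discovery.expression_log2.samples

    predictions = {}
    for g in causal_genes:
        proxies = discovery.ivsets[g].variants
        Q = discovery.genotypes.dosages.loc[disc_samples, proxies].to_numpy(dtype=float)
        gvec = discovery.expression_log2.values.loc[g, disc_samples].to_numpy(dtype=float)
        Qstar = G_val.dosages.loc[val_samples, proxies].to_numpy(dtype=float)
        # the projection formula carries no intercept: center expression and
        # dosages (validation dosages by the DISCOVERY means) so the
        # through-origin fit estimates slopes, not means, and allele-flip
        # invariance holds
        mu = Q.mean(axis=0)
        predictions[g] = pd.Series(
            mr_mod.predict_expression_two_sample(Q - mu, gvec - gvec.mean(), Qstar - mu),
            index=val_samples, name=g,
        )

    if covariates_val is None:
        cols = [c for c in CLINICAL_COVARIATES if c in clinical_val.table.columns]
        covariates_val = clinical_val.table[cols].astype(float)

    results = []
    for arm in cfg.arms:
        directions = discovery.causal_directions(arm)
        arm_preds = {g: predictions[g] for g in causal_genes if g in directions}
        if not arm_preds:
            continue
        results.extend(
            mr_mod.two_sample_mr(
                arm_preds, clinical_val, covariates_val.loc[val_samples], arm,
                one_sample_directions=directions, alpha=cfg.mr_alpha,
            )
        )
    return mr_mod.results_frame(results)
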