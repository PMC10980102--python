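"""Repeated-simulation studies of the pipeline's operating characteristics.

Each function runs the relevant pipeline stages on freshly generated
synthetic cohorts under fixed study conditions and reports an operating
characteristic: type-I error of the one-sample MR causal test, power and
two-sample replication under a planted arm-specific effect, pleiotropy-screen
sensitivity/specificity, subtype-enrichment recovery, and permutation
calibration of the gene-level eQTL p-value.

Study conditions (sample sizes, effect magnitudes, number of instruments)
are fixed here as the scenarios the package documents; see
``docs/methods.md`` for the reasoning behind each number.

The calibration study deliberately bypasses the p < 0.1 association screen:
the screen shares the survival outcome with the causal test, so the
*conditional* rejection rate after screening is not the causal test's size.
What is reported is the unconditional level of the MR additive-hazard test
under valid instruments and no causal effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from survmr import eqtl as eqtl_mod
from survmr import mr as mr_mod
from survmr import prep
from survmr.cms import dichotomize, enrichment
from survmr.containers import ClinicalTable, ExpressionMatrix, GenotypeMatrix
from survmr.synth import GroundTruth, SimConfig, make_fixed_truth, simulate_dataset

#: eQTL effect (natural-log counts per dosage) giving a two-instrument
#: prediction R^2 of ~0.2 against NB(size 3) noise at MAF ~0.3.
IV_BETA_R2_20 = 0.32


def _clinical_subset(clinical: ClinicalTable, samples) -> ClinicalTable:
    return ClinicalTable(clinical.table.loc[samples])


def _pipeline_one_sample(data, run_pleiotropy: bool = True, mr_alpha: float = 0.05):
    """eQTL weights -> pleiotropy screen -> pruning -> one-sample MR.

    Returns (results per arm dict, ivsets, discovery-like state for the
    two-sample stage).
    """
    disc = data.discovery_samples
    G = data.genotypes.subset_samples(disc)
    clin = _clinical_subset(data.clinical, disc)
    E_filt, _ = prep.filter_genes(data.expression)
    E_log2 = prep.log2_transform(prep.upper_quartile_normalize(E_filt))
    cov = data.covariates.table.loc[disc, ["age", "gender", "braf_v600e", "all_ras"]]

    eqtls = eqtl_mod.map_cis_eqtl(E_log2, G, cov)
    candidate = eqtls[eqtls["p_nominal"] < 0.05]
    if run_pleiotropy:
        pcs, _ = prep.pca_qc(E_log2, 1)
        gwas_cov = cov.join(pcs)
        excluded, _ = mr_mod.pleiotropy_screen(
            G, clin, gwas_cov, sorted(candidate["variant_id"].unique())
        )
    else:
        excluded = set()

    ivsets, predictions = {}, {}
    for g in E_log2.genes:
        recs = candidate[(candidate["gene_id"] == g) & ~candidate["variant_id"].isin(excluded)]
        if recs.empty:
            continue
        ivsets[g] = mr_mod.prune_ivs(recs, G)
        predictions[g] = mr_mod.predict_expression_one_sample(ivsets[g], G)

    results = {}
    for arm in ("bevacizumab", "cetuximab"):
        if predictions:
            results[arm] = mr_mod.one_sample_mr(predictions, clin, cov, arm, mr_alpha, ivsets)
        else:
            results[arm] = []
    state = {"E_log2": E_log2, "G": G, "ivsets": ivsets, "clin": clin, "cov": cov}
    return results, state


def mr_null_calibration(n_reps: int = 500, n_per_arm: int = 300, n_genes: int = 6,
                        seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I error of the one-sample MR causal test under a complete null.

    Valid instruments (planted eQTLs, no pleiotropy), no causal gene; every
    gene with instruments enters the arm-specific causal test; the rejection
    rate at ``alpha`` across reps x genes x arms estimates the test's size.
    """
    rng = np.random.default_rng(seed)
    tests = rejected = 0
    for rep in range(n_reps):
        cfg = SimConfig(
            n_discovery=2 * n_per_arm, n_validation=2, n_genes=n_genes,
            snps_per_gene=3, ld_block_rho=0.0, maf_range=(0.25, 0.35),
            seed=int(rng.integers(2**31 - 1)),
        )
        truth = make_fixed_truth(cfg, IV_BETA_R2_20)
        data = simulate_dataset(cfg, truth=truth)
        results, _ = _pipeline_one_sample(data, run_pleiotropy=False)
        for arm in results:
            for r in results[arm]:
                tests += 1
                rejected += r.p_value < alpha
    return {"rejection_rate": rejected / tests, "n_tests": tests, "n_reps": n_reps}


def mr_power_study(n_reps: int = 200, n_per_arm: int = 400, n_validation: int = 600,
                   slope: float = 0.6, seed: int = 0, alpha: float = 0.05) -> dict:
    """Power and replication for a planted arm-specific causal gene.

    One gene with two independent instruments (prediction R^2 ~ 0.2) and an
    additive hazard slope ``slope * baseline_hazard`` per log2-expression
    unit in the bevacizumab arm.  Detection requires one-sample p < alpha in
    that arm with the planted sign; replication requires a sign-concordant
    two-sample hit in an independent genotype-only cohort.
    """
    rng = np.random.default_rng(seed)
    detected = replicated = wrong_arm = 0
    causal_gene = "gene_0000"
    for rep in range(n_reps):
        cfg = SimConfig(
            n_discovery=2 * n_per_arm, n_validation=n_validation, n_genes=4,
            snps_per_gene=3, ld_block_rho=0.0, maf_range=(0.25, 0.35),
            causal_effects=[(causal_gene, "bevacizumab", slope)],
            seed=int(rng.integers(2**31 - 1)),
        )
        truth = make_fixed_truth(cfg, IV_BETA_R2_20)
        data = simulate_dataset(cfg, truth=truth)
        results, state = _pipeline_one_sample(data, run_pleiotropy=False)
        hit = [r for r in results["bevacizumab"]
               if r.gene_id == causal_gene and r.p_value < alpha and r.direction == np.sign(slope)]
        if not hit:
            continue
        detected += 1
        other = [r for r in results["cetuximab"]
                 if r.gene_id == causal_gene and r.p_value < alpha]
        wrong_arm += bool(other)

        # two-sample replication in the independent genotype-only cohort
        val = data.validation_samples
        clin_val = _clinical_subset(data.clinical, val)
        cov_val = data.covariates.table.loc[val, ["age", "gender", "braf_v600e", "all_ras"]]
        ivset = state["ivsets"].get(causal_gene)
        if ivset is None:
            continue
        Q = state["G"].dosages[ivset.variants].to_numpy(dtype=float)
        gvec = state["E_log2"].values.loc[causal_gene].to_numpy(dtype=float)
        Qstar = data.genotypes.dosages.loc[val, ivset.variants].to_numpy(dtype=float)
        mu = Q.mean(axis=0)
        ghat = pd.Series(
            mr_mod.predict_expression_two_sample(Q - mu, gvec - gvec.mean(), Qstar - mu),
            index=val,
        )
        res2 = mr_mod.two_sample_mr({causal_gene: ghat}, clin_val, cov_val,
                                    "bevacizumab",
                                    one_sample_directions={causal_gene: int(np.sign(slope))},
                                    alpha=alpha)
        replicated += bool(res2 and res2[0].replicated)
    return {
        "power_one_sample": detected / n_reps,
        "replication_rate": replicated / max(detected, 1),
        "replication_overall": replicated / n_reps,
        "wrong_arm_rate": wrong_arm / max(detected, 1),
        "n_reps": n_reps,
    }


def pleiotropy_screen_study(n_reps: int = 60, n: int = 800, n_null: int = 1500,
                            direct_slope_loghr: float = 0.6, seed: int = 0) -> dict:
    """Sensitivity and specificity of the pleiotropy (survival-GWAS) screen.

    The planted variant's additive dosage slope is (e^b - 1) * lam0 so its
    per-allele log hazard ratio near dosage 0 is ``b``; it must be excluded.
    Null variants estimate the nominal exclusion rate at p < 1e-4.
    """
    rng = np.random.default_rng(seed)
    planted_excluded = 0
    for rep in range(n_reps):
        cfg = SimConfig(
            n_discovery=n, n_validation=2, n_genes=2, snps_per_gene=3,
            ld_block_rho=0.0, maf_range=(0.25, 0.35),
            pleiotropic_effects={"gene_0000_v0": float(np.expm1(direct_slope_loghr))},
            seed=int(rng.integers(2**31 - 1)),
        )
        data = simulate_dataset(cfg)
        disc = data.discovery_samples
        clin = _clinical_subset(data.clinical, disc)
        cov = data.covariates.table.loc[disc, ["age", "gender", "braf_v600e", "all_ras"]]
        excluded, _ = mr_mod.pleiotropy_screen(
            data.genotypes.subset_samples(disc), clin, cov, ["gene_0000_v0"]
        )
        planted_excluded += "gene_0000_v0" in excluded

    # null specificity: 20 variants per simulated cohort
    null_excluded = null_total = 0
    while null_total < n_null:
        cfg = SimConfig(
            n_discovery=n, n_validation=2, n_genes=5, snps_per_gene=4,
            ld_block_rho=0.0, maf_range=(0.25, 0.35),
            seed=int(rng.integers(2**31 - 1)),
        )
        data = simulate_dataset(cfg)
        disc = data.discovery_samples
        clin = _clinical_subset(data.clinical, disc)
        cov = data.covariates.table.loc[disc, ["age", "gender", "braf_v600e", "all_ras"]]
        variants = list(data.genotypes.variants)
        excluded, _ = mr_mod.pleiotropy_screen(
            data.genotypes.subset_samples(disc), clin, cov, variants
        )
        null_excluded += len(excluded)
        null_total += len(variants)
    return {
        "planted_exclusion_rate": planted_excluded / n_reps,
        "null_exclusion_rate": null_excluded / null_total,
        "n_null": null_total,
        "n_reps": n_reps,
    }


def enrichment_recovery_study(n_reps: int = 60, n_subtype: int = 100,
                              shift: float = 1.5, seed: int = 0) -> dict:
    """Exact recovery of a planted (gene, subtype) enrichment pattern.

    gene_0000 is shifted up in CMS1 and down in CMS4 (balanced, so the other
    subtypes stay at ~50% above-median); with the hazard direction mapping
    high expression to "beneficial", the truth is {(CMS1, beneficial),
    (CMS4, non_beneficial)}, and the 19 unshifted genes must produce no
    enrichment at all.  A realistic gene count keeps the per-sample upper
    quartile stable, so the planted shift does not bleed into other genes
    through normalization.
    """
    rng = np.random.default_rng(seed)
    rule = {"gene_0000": {"CMS1": shift, "CMS4": -shift}}
    truth_set = {("CMS1", "beneficial"), ("CMS4", "non_beneficial")}
    exact = 0
    for rep in range(n_reps):
        cfg = SimConfig(
            n_discovery=4 * n_subtype, n_validation=2, n_genes=20,
            snps_per_gene=2, cms_rule=rule,
            cms_proportions=(0.25, 0.25, 0.25, 0.25),
            seed=int(rng.integers(2**31 - 1)),
        )
        data = simulate_dataset(cfg)
        E_filt, _ = prep.filter_genes(data.expression)
        E_log2 = prep.log2_transform(prep.upper_quartile_normalize(E_filt))
        cms = data.clinical.table.loc[E_log2.samples, "cms"]
        found = set()
        for g in E_log2.genes:
            cats = dichotomize(E_log2, g, effect_direction=-1)  # high = beneficial
            for res in enrichment(cats, cms):
                if res.enriched:
                    found.add((g, res.subtype, res.category))
        expected = {("gene_0000", st, cat) for st, cat in truth_set}
        exact += found == expected
    return {"exact_recovery_rate": exact / n_reps, "n_reps": n_reps}


def permutation_calibration_study(n_genes: int = 500, n_samples: int = 150,
                                  n_perm: int = 1000, seed: int = 0,
                                  alpha: float = 0.05) -> dict:
    """Gene-level permutation p under the null across many genes.

    Null expression (no planted eQTL) against real cis genotypes; reports the
    fraction of genes declared e-genes at ``alpha`` and the mean p.
    """
    cfg = SimConfig(n_discovery=n_samples, n_validation=2, n_genes=n_genes,
                    snps_per_gene=4, ld_block_rho=0.5, seed=seed)
    truth = GroundTruth(set(), {g: [] for g in
                                [f"gene_{i:04d}" for i in range(n_genes)]}, {})
    data = simulate_dataset(cfg, truth=truth)
    E_filt, _ = prep.filter_genes(data.expression)
    E_log2 = prep.log2_transform(prep.upper_quartile_normalize(E_filt))
    G = data.genotypes.subset_samples(data.discovery_samples)
    cov = data.covariates.table.loc[E_log2.samples, ["age", "gender"]]
    ps = [
        eqtl_mod.permute_gene_pvalue(g, E_log2, G, cov, n_perm=n_perm,
                                     seed=seed, adaptive_stop=100).p_permutation
        for g in E_log2.genes
    ]
    ps = np.asarray(ps)
    return {
        "egene_rate": float(np.mean(ps < alpha)),
        "mean_p": float(np.mean(ps)),
        "n_genes": len(ps),
    }
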