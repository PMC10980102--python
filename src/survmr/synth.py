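"""Synthetic cohort generator with known causal ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, at desk scale:

* LD-blocked biallelic genotype dosages (Gaussian-copula haplotypes under
  Hardy–Weinberg equilibrium) with every variant's empirical minor allele
  frequency at least 0.05;
* cis-eQTL effects on negative-binomial RNA-seq counts (log link);
* treatment-arm-specific additive-hazard survival with clinical covariates
  and independent exponential censoring;
* consensus-molecular-subtype (CMS) labels whose planted expression shifts
  are applied before count generation, so subtype enrichment is recoverable.

Every quantity a downstream stage is supposed to discover (eQTL effects,
causal gene-arm pairs, pleiotropic variants, subtype shifts) is recorded in
:class:`GroundTruth` and never re-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from survmr.containers import ClinicalTable, CovariateTable, ExpressionMatrix, GenotypeMatrix

ARMS = ("bevacizumab", "cetuximab")

#: Gene TSS spacing; > 2x the 1 Mb cis window so cis windows never overlap.
TSS_SPACING = 2_500_000
SNP_SPAN = 400_000  # SNPs placed within +/- this distance of their gene's TSS


class HazardPositivityError(ValueError):
    """A simulated subject's additive hazard would be non-positive."""


@dataclass
class SimConfig:
    """Parameters of a simulated two-cohort trial.

    The defaults describe a desk-scale randomized cohort: overdispersed
    RNA-seq counts (NB size 3, i.e. log2-scale SD around 0.8, comfortably
    above the SD >= 0.5 expression filter), a baseline hazard of 1 per time
    unit, and light exponential censoring (~13% censored).

    ``hazard_floor`` caps the additive linear predictor from below at
    ``-(1 - hazard_floor) * baseline_hazard`` (a saturating-tails convention
    that keeps the hazard positive for unbounded continuous exposures).  Set
    it to ``None`` to demand strict positivity, in which case any violating
    subject is a hard failure naming the offending row.
    """

    n_discovery: int = 300
    n_validation: int = 300
    n_genes: int = 20
    snps_per_gene: int = 5
    ld_block_rho: float = 0.5
    maf_range: tuple = (0.1, 0.5)
    eqtl_effect_sd: float = 0.3
    n_causal_ivs_per_gene: int = 2
    baseline_hazard: float = 1.0
    causal_effects: list = field(default_factory=list)  # (gene_id, arm, slope)
    censoring_rate: float = 0.15
    nb_dispersion: float = 3.0
    nb_log_mean: float = np.log(300.0)
    covariate_hazard_effects: dict = field(default_factory=dict)
    expr_covariate_effects: dict = field(default_factory=dict)
    pleiotropic_effects: dict = field(default_factory=dict)  # variant -> additive slope
    cms_proportions: tuple = (0.15, 0.40, 0.15, 0.30)
    cms_rule: dict = field(default_factory=dict)  # gene -> {subtype: log-mean shift}
    hazard_floor: float | None = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_discovery", "n_validation", "n_genes", "snps_per_gene", "n_causal_ivs_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if not (0.0 <= self.ld_block_rho < 1.0):
            raise ValueError("ld_block_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if lo <= 0.05 or hi > 0.5 or lo >= hi:
            raise ValueError("maf_range must satisfy 0.05 < lo < hi <= 0.5 (variants below MAF 0.05 are excluded)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be non-negative")
        for gene, arm, _ in self.causal_effects:
            if arm not in ARMS:
                raise ValueError(f"unknown arm {arm!r} in causal_effects")

    @property
    def n_total(self) -> int:
        return self.n_discovery + self.n_validation


@dataclass
class GroundTruth:
    """What the generator planted, queryable by every downstream check."""

    causal_gene_arm_pairs: set  # {(gene_id, arm, slope)}
    eqtl_map: dict  # gene_id -> [(variant_id, beta)]
    pleiotropic_variants: dict  # variant_id -> additive hazard slope
    cms_rule: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, _, _ in self.causal_gene_arm_pairs:
            if not self.eqtl_map.get(gene):
                raise ValueError(f"causal gene {gene!r} has no eQTL")
        all_eqtl_variants = {v for lst in self.eqtl_map.values() for v, _ in lst}
        extra = set(self.pleiotropic_variants) - all_eqtl_variants
        if extra:
            raise ValueError(f"pleiotropic variants are not eQTL variants: {sorted(extra)[:5]}")

    def causal_genes(self) -> set:
        return {g for g, _, _ in self.causal_gene_arm_pairs}


def gene_ids(n_genes: int) -> list:
    return [f"gene_{i:04d}" for i in range(n_genes)]


def _gene_layout(n_genes: int, snps_per_gene: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign TSS and SNP positions, one LD block per gene on chromosome 1."""
    genes = gene_ids(n_genes)
    tss = TSS_SPACING * (np.arange(n_genes) + 1)
    gene_meta = pd.DataFrame({"chrom": "1", "tss": tss}, index=pd.Index(genes, name="gene_id"))
    rows = []
    for gi, g in enumerate(genes):
        offs = np.linspace(-SNP_SPAN, SNP_SPAN, snps_per_gene).astype(int)
        for j, off in enumerate(offs):
            rows.append((f"{g}_v{j}", "1", int(tss[gi] + off), g))
    vm = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "block"]).set_index("variant_id")
    return gene_meta, vm


def _sample_block_dosages(n, mafs, rho, rng, max_tries=1000):
    """Dosages for one LD block via an equicorrelated Gaussian copula.

    Each haplotype's latent vector is sqrt(rho) * shared + sqrt(1-rho) *
    idiosyncratic noise; the allele is carried when the latent falls below
    the MAF quantile, so haplotype allele frequency equals the target MAF and
    the dosage (sum of two independent haplotypes) is in HWE.  Blocks whose
    empirical MAF dips below 0.05 for any variant are resampled whole.
    """
    m = len(mafs)
    thr = stats.norm.ppf(mafs)
    for _ in range(max_tries):
        shared = rng.standard_normal((2, n, 1))
        noise = rng.standard_normal((2, n, m))
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        dos = (z[0] < thr).astype(float) + (z[1] < thr).astype(float)
        freq = dos.mean(axis=0) / 2.0
        if np.all(np.minimum(freq, 1 - freq) >= 0.05):
            return dos
    raise RuntimeError("could not sample an LD block with empirical MAF >= 0.05")


def simulate_genotypes(cfg: SimConfig, n: int | None = None, rng=None) -> GenotypeMatrix:
    """Simulate LD-blocked genotype dosages for ``n`` samples.

    One block per gene with within-block latent correlation
    ``cfg.ld_block_rho``; target MAFs drawn uniformly from ``cfg.maf_range``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_total if n is None else n
    _, vm = _gene_layout(cfg.n_genes, cfg.snps_per_gene)
    cols, mafs_all = [], []
    for g in gene_ids(cfg.n_genes):
        block = vm.index[vm["block"] == g]
        mafs = rng.uniform(*cfg.maf_range, size=len(block))
        dos = _sample_block_dosages(n, mafs, cfg.ld_block_rho, rng)
        cols.append(pd.DataFrame(dos, columns=block))
        mafs_all.append(mafs)
    dosages = pd.concat(cols, axis=1)
    dosages.index = pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id")
    meta = vm.copy()
    meta["ref"] = "A"
    meta["alt"] = "C"
    meta["maf"] = np.concatenate(mafs_all)
    return GenotypeMatrix(dosages, meta)


def make_ground_truth(cfg: SimConfig, G: GenotypeMatrix, rng=None, beta_magnitude=None) -> GroundTruth:
    """Plant cis-eQTLs for every gene and record the causal structure.

    ``cfg.n_causal_ivs_per_gene`` variants per block, chosen maximally spread
    within the block; effect sizes drawn N(0, eqtl_effect_sd) on the natural-log
    count scale, or of fixed ``beta_magnitude`` with alternating sign.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    eqtl_map = {}
    for g in gene_ids(cfg.n_genes):
        block = [v for v in G.variants if v.startswith(f"{g}_v")]
        k = min(cfg.n_causal_ivs_per_gene, len(block))
        picks = [block[i] for i in np.linspace(0, len(block) - 1, k).astype(int)]
        if beta_magnitude is None:
            betas = rng.normal(0.0, cfg.eqtl_effect_sd, size=k)
        else:
            betas = beta_magnitude * np.array([(-1.0) ** j for j in range(k)])
        eqtl_map[g] = list(zip(picks, betas))
    return GroundTruth(
        causal_gene_arm_pairs={(g, a, s) for g, a, s in cfg.causal_effects},
        eqtl_map=eqtl_map,
        pleiotropic_variants=dict(cfg.pleiotropic_effects),
        cms_rule=dict(cfg.cms_rule),
    )


def make_fixed_truth(cfg: SimConfig, beta_magnitude: float) -> GroundTruth:
    """Deterministic ground truth with fixed-magnitude, alternating-sign eQTLs.

    Uses the generator's deterministic variant naming, so no genotype draw is
    needed; handy for power/calibration studies that fix the instrument
    strength.
    """
    eqtl_map = {}
    for g in gene_ids(cfg.n_genes):
        k = min(cfg.n_causal_ivs_per_gene, cfg.snps_per_gene)
        picks = np.linspace(0, cfg.snps_per_gene - 1, k).astype(int)
        eqtl_map[g] = [
            (f"{g}_v{j}", beta_magnitude * (-1.0) ** i) for i, j in enumerate(picks)
        ]
    return GroundTruth(
        causal_gene_arm_pairs={(g, a, s) for g, a, s in cfg.causal_effects},
        eqtl_map=eqtl_map,
        pleiotropic_variants=dict(cfg.pleiotropic_effects),
        cms_rule=dict(cfg.cms_rule),
    )


def simulate_covariates(n: int, rng) -> pd.DataFrame:
    """Baseline clinical covariates for a metastatic CRC trial population."""
    return pd.DataFrame(
        {
            "age": np.clip(rng.normal(61.0, 10.0, n), 30, 85).round(1),
            "gender": rng.binomial(1, 0.6, n),
            "braf_v600e": rng.binomial(1, 0.08, n),
            "all_ras": rng.binomial(1, 0.45, n),
            "tumor_location": rng.choice(["left", "right"], size=n, p=[0.6, 0.4]),
        },
        index=pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id"),
    )


def simulate_cms(n: int, proportions, rng) -> pd.Series:
    """Assign CMS1..CMS4 labels with deterministic subtype sizes.

    Sizes are the largest-remainder apportionment of ``proportions``; a
    subtype requested with positive proportion but receiving zero samples is
    an error.
    """
    props = np.asarray(proportions, dtype=float)
    props = props / props.sum()
    counts = np.floor(props * n).astype(int)
    for i in np.argsort(-(props * n - counts))[: n - counts.sum()]:
        counts[i] += 1
    if np.any((props > 0) & (counts == 0)):
        raise ValueError("requested CMS proportions leave a subtype empty at this sample size")
    labels = np.repeat([f"CMS{i + 1}" for i in range(4)], counts)
    rng.shuffle(labels)
    return pd.Series(labels, index=pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id"), name="cms")


def simulate_expression(
    G: GenotypeMatrix,
    truth: GroundTruth,
    covariates: pd.DataFrame,
    cfg: SimConfig,
    cms_labels: pd.Series | None = None,
    rng=None,
) -> ExpressionMatrix:
    """Negative-binomial counts with planted cis-eQTL and subtype effects.

    The log-mean of gene g in sample s is

        intercept_g + sum_v beta_gv * dosage_sv + gamma' covariates_s
                    + shift_g(cms_s),

    with NB dispersion ``cfg.nb_dispersion`` (variance mu + mu^2/size;
    ``inf`` gives Poisson counts).
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    n = len(G.samples)
    genes = gene_ids(cfg.n_genes)
    gene_meta, _ = _gene_layout(cfg.n_genes, cfg.snps_per_gene)

    eta = np.full((len(genes), n), cfg.nb_log_mean)
    eta += rng.normal(0.0, 0.3, size=(len(genes), 1))  # per-gene baseline
    for gi, g in enumerate(genes):
        for v, beta in truth.eqtl_map.get(g, []):
            if v not in G.variants:
                raise KeyError(f"eQTL variant {v!r} absent from the genotype matrix")
            eta[gi] += beta * G.dosages[v].to_numpy()
        shifts = truth.cms_rule.get(g, {})
        if shifts:
            if cms_labels is None:
                raise ValueError("cms_rule planted but no CMS labels supplied")
            for subtype, delta in shifts.items():
                eta[gi] += delta * (cms_labels.loc[G.samples].to_numpy() == subtype)
    for col, gamma in cfg.expr_covariate_effects.items():
        x = covariates.loc[G.samples, col].to_numpy(dtype=float)
        eta += gamma * (x - x.mean())[None, :]

    mu = np.exp(eta)
    if np.isinf(cfg.nb_dispersion):
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=cfg.nb_dispersion, scale=mu / cfg.nb_dispersion)
        counts = rng.poisson(lam)
    values = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=G.samples)
    return ExpressionMatrix(values, gene_meta, scale="raw")


def sample_additive_hazard_times(X, alpha, lam0, rng, breaks=None, alpha_t=None, floor=None):
    """Draw event times from h(t) = lam0 + x' alpha(t).

    With constant coefficients this is exact exponential sampling at each
    subject's hazard; with ``breaks``/``alpha_t`` (piecewise-constant
    coefficients on a time grid) the times come from piecewise-exponential
    inversion.  ``floor`` (in (0, 1)) caps the linear predictor from below at
    -(1 - floor) * lam0; ``None`` enforces strict positivity with a hard
    failure naming the first offending row.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]

    def hazards(a):
        lp = X @ np.asarray(a, dtype=float)
        if floor is None:
            bad = np.flatnonzero(lam0 + lp <= 0)
            if len(bad):
                raise HazardPositivityError(
                    f"non-positive additive hazard for sample row {bad[0]} (h = {lam0 + lp[bad[0]]:.4g})"
                )
        else:
            lp = np.maximum(lp, -(1.0 - floor) * lam0)
        return lam0 + lp

    if alpha_t is None:
        h = hazards(alpha)
        return rng.exponential(1.0 / h)

    breaks = np.asarray(breaks, dtype=float)
    if breaks[0] != 0 or np.any(np.diff(breaks) <= 0):
        raise ValueError("breaks must start at 0 and increase")
    rates = np.column_stack([hazards(a) for a in alpha_t])  # (n, K)
    widths = np.diff(np.append(breaks, np.inf))
    target = rng.exponential(1.0, size=n)  # unit-exponential cumulative hazard
    times = np.empty(n)
    for i in range(n):
        acc, t = 0.0, 0.0
        for k, w in enumerate(widths):
            seg = rates[i, k] * w
            if acc + seg >= target[i] or np.isinf(w):
                t = breaks[k] + (target[i] - acc) / rates[i, k]
                break
            acc += seg
        times[i] = t
    return times


def simulate_survival(design: pd.DataFrame, coef: dict, cfg: SimConfig, rng=None,
                      breaks=None, coef_t=None) -> pd.DataFrame:
    """Observed survival = min(event, censoring) under the additive hazard.

    ``coef`` maps design columns to constant hazard slopes; ``coef_t`` maps
    them to per-interval slopes on ``breaks`` for time-varying effects.
    Censoring is independent exponential at ``cfg.censoring_rate`` (0 means
    none).
    """
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    cols = list(coef if coef_t is None else coef_t)
    X = design[cols].to_numpy(dtype=float)
    if coef_t is None:
        t_event = sample_additive_hazard_times(
            X, [coef[c] for c in cols], cfg.baseline_hazard, rng, floor=cfg.hazard_floor
        )
    else:
        alpha_t = [np.array([coef_t[c][k] for c in cols]) for k in range(len(breaks))]
        t_event = sample_additive_hazard_times(
            X, None, cfg.baseline_hazard, rng, breaks=breaks, alpha_t=alpha_t, floor=cfg.hazard_floor
        )
    if cfg.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / cfg.censoring_rate, size=len(design))
    else:
        t_cens = np.full(len(design), np.inf)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"os_time": os_time, "os_event": os_event}, index=design.index)


@dataclass
class SimulatedData:
    """Everything a full-pipeline run consumes, plus the planted truth."""

    genotypes: GenotypeMatrix            # all samples (discovery + validation)
    expression: ExpressionMatrix         # discovery samples only (observed)
    clinical: ClinicalTable              # all samples
    covariates: CovariateTable           # all samples (clinical covariates)
    truth: GroundTruth
    discovery_samples: pd.Index
    validation_samples: pd.Index
    latent_log2_expression: pd.DataFrame  # genes x all samples, generator-internal

    def discovery(self):
        return self.discovery_samples

    def validation(self):
        return self.validation_samples


def simulate_dataset(cfg: SimConfig, truth: GroundTruth | None = None) -> SimulatedData:
    """Generate a complete two-cohort study with known ground truth.

    Expression is simulated for every sample (tumors express genes whether or
    not RNA-seq was performed) and drives the hazard; only the discovery
    cohort's counts are exposed as observed data.  Causal gene effects enter
    the hazard through the centered log2 expression, arm-specifically; planted
    pleiotropic variants add a direct dosage term in both arms.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_total
    G = simulate_genotypes(cfg, n=n, rng=rng)
    if truth is None:
        truth = make_ground_truth(cfg, G, rng=rng)
    cov = simulate_covariates(n, rng)
    cms = simulate_cms(n, cfg.cms_proportions, rng)
    E_all = simulate_expression(G, truth, cov, cfg, cms_labels=cms, rng=rng)

    log2e = np.log2(E_all.values.to_numpy(dtype=float) + 1.0)
    log2e = pd.DataFrame(log2e, index=E_all.genes, columns=E_all.samples)

    arm = pd.Series(np.where(rng.binomial(1, 0.5, n) == 1, ARMS[0], ARMS[1]),
                    index=G.samples, name="arm")

    # hazard design: arm-specific centered expression terms, direct variant
    # terms, and clinical covariate terms
    design = pd.DataFrame(index=G.samples)
    coef = {}
    for gene, a, slope in truth.causal_gene_arm_pairs:
        gc = log2e.loc[gene] - log2e.loc[gene].mean()
        colname = f"{gene}:{a}"
        design[colname] = gc * (arm == a).astype(float)
        coef[colname] = slope
    for v, slope in truth.pleiotropic_variants.items():
        design[f"iv:{v}"] = G.dosages[v]
        coef[f"iv:{v}"] = slope
    for c, slope in cfg.covariate_hazard_effects.items():
        x = cov[c].astype(float) if c != "tumor_location" else (cov[c] == "right").astype(float)
        design[f"cov:{c}"] = x - x.mean()
        coef[f"cov:{c}"] = slope
    if not coef:
        design["null"] = 0.0
        coef["null"] = 0.0

    surv = simulate_survival(design, coef, cfg, rng=rng)
    clin = pd.concat([surv, arm, cov, cms], axis=1)
    clinical = ClinicalTable(clin)
    covariates = CovariateTable(cov.drop(columns=["tumor_location"]).astype(float).join(
        (cov["tumor_location"] == "right").astype(float).rename("tumor_location_right")))

    disc = G.samples[: cfg.n_discovery]
    val = G.samples[cfg.n_discovery:]
    E_disc = ExpressionMatrix(E_all.values[disc], E_all.gene_meta, scale="raw")
    return SimulatedData(
        genotypes=G,
        expression=E_disc,
        clinical=clinical,
        covariates=covariates,
        truth=truth,
        discovery_samples=disc,
        validation_samples=val,
        latent_log2_expression=log2e,
    )


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Serialize the planted truth as a JSON sidecar."""
    import json

    payload = {
        "causal_gene_arm_pairs": sorted([list(x) for x in truth.causal_gene_arm_pairs]),
        "eqtl_map": {g: [[v, float(b)] for v, b in lst] for g, lst in truth.eqtl_map.items()},
        "pleiotropic_variants": {v: float(s) for v, s in truth.pleiotropic_variants.items()},
        "cms_rule": truth.cms_rule,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
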