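"""Tests of the synthetic-cohort generator against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from survmr.synth import (
    ARMS,
    GroundTruth,
    HazardPositivityError,
    SimConfig,
    _sample_block_dosages,
    make_ground_truth,
    sample_additive_hazard_times,
    simulate_cms,
    simulate_covariates,
    simulate_dataset,
    simulate_expression,
    simulate_genotypes,
    simulate_survival,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"maf_range": (0.05, 0.5)},   # lower bound must exceed 0.05
            {"maf_range": (0.01, 0.4)},
            {"maf_range": (0.3, 0.2)},
            {"n_genes": 0},
            {"baseline_hazard": 0.0},
            {"nb_dispersion": -1.0},
            {"ld_block_rho": 1.0},
            {"censoring_rate": -0.1},
            {"causal_effects": [("g", "nonsense_arm", 0.5)]},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestGenotypes:
    def test_independent_variants_uncorrelated(self):
        cfg = SimConfig(n_genes=2, snps_per_gene=5, ld_block_rho=0.0, seed=4)
        G = simulate_genotypes(cfg, n=10_000)
        dos = G.dosages.to_numpy()
        r2 = np.corrcoef(dos.T) ** 2
        iu = np.triu_indices_from(r2, k=1)
        assert r2[iu].mean() <= 0.001 + 3 / 10_000

    def test_block_r2_matches_copula_oracle(self):
        # brute-force two-locus oracle: sample the same Gaussian-copula pair
        # directly and compare the within-block mean dosage r^2
        rho, maf, n = 0.8, 0.3, 10_000
        rng = np.random.default_rng(0)
        thr = stats.norm.ppf(maf)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=(2, n))
        dos = (z < thr).sum(axis=0)  # two haplotypes
        oracle_r2 = np.corrcoef(dos.T)[0, 1] ** 2

        cfg = SimConfig(n_genes=1, snps_per_gene=5, ld_block_rho=rho,
                        maf_range=(0.299, 0.301), seed=1)
        G = simulate_genotypes(cfg, n=n)
        r2 = np.corrcoef(G.dosages.to_numpy().T) ** 2
        iu = np.triu_indices(5, k=1)
        assert abs(r2[iu].mean() - oracle_r2) < 0.1

    def test_maf_half_mean_dosage_one(self):
        cfg = SimConfig(n_genes=1, snps_per_gene=4, maf_range=(0.499, 0.5), seed=2)
        G = simulate_genotypes(cfg, n=20_000)
        assert np.allclose(G.dosages.mean(axis=0), 1.0, atol=0.03)

    def test_empirical_maf_floor(self):
        cfg = SimConfig(n_genes=3, snps_per_gene=4, maf_range=(0.06, 0.12), seed=3)
        G = simulate_genotypes(cfg, n=120)
        assert (G.empirical_maf() >= 0.05).all()

    def test_variant_metadata_defines_cis_windows(self):
        cfg = SimConfig(n_genes=3, snps_per_gene=2, seed=0)
        G = simulate_genotypes(cfg, n=20)
        assert {"chrom", "pos", "maf"} <= set(G.variant_meta.columns)
        # each gene's variants lie within 1 Mb of its TSS and blocks don't mix
        for g, grp in G.variant_meta.groupby("block"):
            assert grp["pos"].max() - grp["pos"].min() <= 2_000_000

    def test_determinism(self):
        cfg = SimConfig(n_genes=2, snps_per_gene=3, seed=9)
        a = simulate_genotypes(cfg, n=50).dosages
        b = simulate_genotypes(cfg, n=50).dosages
        pd.testing.assert_frame_equal(a, b)


class TestGroundTruth:
    def test_causal_gene_without_eqtl_rejected(self):
        with pytest.raises(ValueError, match="no eQTL"):
            GroundTruth({("gX", "bevacizumab", 0.5)}, {"gX": []}, {})

    def test_pleiotropic_must_be_eqtl_variant(self):
        with pytest.raises(ValueError, match="pleiotropic"):
            GroundTruth(set(), {"g": [("v1", 0.2)]}, {"v_other": 0.3})


class TestExpression:
    @pytest.fixture
    def small_world(self):
        cfg = SimConfig(n_genes=4, snps_per_gene=3, seed=5)
        G = simulate_genotypes(cfg, n=400)
        cov = simulate_covariates(400, np.random.default_rng(5))
        return cfg, G, cov

    def test_null_beta_slope_ci_covers_zero(self, small_world):
        cfg, G, cov = small_world
        truth = GroundTruth(set(), {g: [] for g in G.variant_meta["block"].unique()}, {})
        E = simulate_expression(G, truth, cov, cfg, rng=np.random.default_rng(6))
        log2e = np.log2(E.values.to_numpy() + 1.0)
        covered = 0
        for gi, g in enumerate(E.genes):
            d = G.dosages[f"{g}_v0"].to_numpy()
            res = stats.linregress(d, log2e[gi])
            lo = res.slope - 1.96 * res.stderr
            hi = res.slope + 1.96 * res.stderr
            covered += lo <= 0 <= hi
        assert covered >= len(E.genes) - 1

    def test_poisson_limit_mean_ratio(self, small_world):
        # dosage-2 vs dosage-0 group means must differ by ~exp(2 beta)
        cfg, G, cov = small_world
        beta = 0.5
        genes = list(G.variant_meta["block"].unique())
        truth = GroundTruth(set(), {g: ([("gene_0000_v0", beta)] if g == "gene_0000" else []) for g in genes}, {})
        cfg2 = SimConfig(n_genes=4, snps_per_gene=3, nb_dispersion=np.inf, seed=5)
        E = simulate_expression(G, truth, cov, cfg2, rng=np.random.default_rng(7))
        d = G.dosages["gene_0000_v0"].round().to_numpy()
        counts = E.values.loc["gene_0000"].to_numpy()
        m2, m0 = counts[d == 2].mean(), counts[d == 0].mean()
        assert m2 / m0 == pytest.approx(np.exp(2 * beta), rel=0.15)

    def test_exchangeability_without_covariate_effects(self, small_world):
        cfg, G, cov = small_world
        truth = GroundTruth(set(), {g: [] for g in G.variant_meta["block"].unique()}, {})
        E = simulate_expression(G, truth, cov, cfg, rng=np.random.default_rng(8))
        x = np.log2(E.values.iloc[0].to_numpy() + 1.0)
        assert stats.ks_2samp(x[:200], x[200:]).pvalue > 0.01

    def test_unknown_eqtl_variant_errors(self, small_world):
        cfg, G, cov = small_world
        truth = GroundTruth(set(), {"gene_0000": [("nope_v9", 0.2)]}, {})
        with pytest.raises(KeyError, match="nope_v9"):
            simulate_expression(G, truth, cov, cfg)


class TestSurvival:
    def test_no_effect_exponential_median(self):
        rng = np.random.default_rng(9)
        lam0 = 0.8
        t = sample_additive_hazard_times(np.zeros((5000, 1)), [0.0], lam0, rng)
        assert np.median(t) == pytest.approx(np.log(2) / lam0, rel=0.06)

    def test_group_hazard_ratio_vs_nelson_aalen_oracle(self):
        from survmr.hazards import nelson_aalen

        rng = np.random.default_rng(10)
        n, lam0, a = 5000, 1.0, 0.7
        x = rng.binomial(1, 0.5, n).astype(float)
        t = sample_additive_hazard_times(x[:, None], [a], lam0, rng)
        d = np.ones(n, int)
        _, ch1 = nelson_aalen(t[x == 1], d[x == 1])
        _, ch0 = nelson_aalen(t[x == 0], d[x == 0])
        # compare cumulative hazards early (30th percentile), where both
        # at-risk sets are still large and the NA estimator is precise
        tq = np.quantile(t, 0.3)
        et1, _ = nelson_aalen(t[x == 1], d[x == 1])
        et0, _ = nelson_aalen(t[x == 0], d[x == 0])
        h1 = ch1[np.searchsorted(et1, tq) - 1]
        h0 = ch0[np.searchsorted(et0, tq) - 1]
        assert h1 / h0 == pytest.approx((lam0 + a) / lam0, rel=0.1)

    def test_zero_censoring_all_events(self):
        cfg = SimConfig(censoring_rate=0.0, seed=1)
        design = pd.DataFrame({"x": np.zeros(100)})
        out = simulate_survival(design, {"x": 0.0}, cfg)
        assert (out["os_event"] == 1).all()

    def test_positivity_hard_failure_names_row(self):
        rng = np.random.default_rng(2)
        X = np.array([[0.0], [5.0]])
        with pytest.raises(HazardPositivityError, match="row 1"):
            sample_additive_hazard_times(X, [-0.5], 1.0, rng, floor=None)

    def test_hazard_floor_keeps_sampling_feasible(self):
        rng = np.random.default_rng(3)
        X = np.array([[0.0], [5.0]])
        t = sample_additive_hazard_times(X, [-0.5], 1.0, rng, floor=0.05)
        assert np.all(t > 0)

    def test_piecewise_constant_equals_exponential(self):
        # identical rates in every interval must reproduce the exponential law
        rng = np.random.default_rng(4)
        X = np.zeros((4000, 1))
        t = sample_additive_hazard_times(
            X, None, 1.2, rng, breaks=[0.0, 0.5, 1.5], alpha_t=[[0.0], [0.0], [0.0]]
        )
        assert stats.kstest(t, "expon", args=(0, 1 / 1.2)).pvalue > 0.01

    def test_piecewise_rate_change_matches_inversion_oracle(self):
        # hazard 2.0 before t=1, 0.5 after: survival S(t) piecewise exponential
        rng = np.random.default_rng(5)
        t = sample_additive_hazard_times(
            np.ones((20000, 1)), None, 1.0, rng,
            breaks=[0.0, 1.0], alpha_t=[[1.0], [-0.5]],
        )
        # P(T > 1) = exp(-2); median of tail law checked empirically
        assert np.mean(t > 1.0) == pytest.approx(np.exp(-2.0), abs=0.01)


class TestCms:
    def test_all_one_subtype(self):
        labels = simulate_cms(50, (1.0, 0.0, 0.0, 0.0), np.random.default_rng(0))
        assert (labels == "CMS1").all()

    def test_empty_subtype_errors(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_cms(3, (0.97, 0.01, 0.01, 0.01), np.random.default_rng(0))

    def test_null_shift_rates_near_half(self):
        cfg = SimConfig(n_genes=3, n_discovery=400, n_validation=10, seed=21)
        data = simulate_dataset(cfg)
        log2e = data.latent_log2_expression
        cms = data.clinical.table["cms"]
        for g in log2e.index:
            med = log2e.loc[g].median()
            for st in ("CMS1", "CMS2", "CMS3", "CMS4"):
                rate = (log2e.loc[g][cms == st] > med).mean()
                assert 0.3 < rate < 0.7

    def test_planted_shift_recoverable(self):
        # large shift in CMS1, balanced by a negative shift in CMS4; the
        # two-group normal-shift oracle says the above-median rate in CMS1
        # is essentially 1 for a 2.2-log2 shift against SD ~0.85
        rule = {"gene_0000": {"CMS1": 1.5, "CMS4": -1.5}}
        cfg = SimConfig(n_genes=3, n_discovery=400, n_validation=10,
                        cms_rule=rule, cms_proportions=(0.25, 0.25, 0.25, 0.25), seed=22)
        data = simulate_dataset(cfg)
        g = data.latent_log2_expression.loc["gene_0000"]
        cms = data.clinical.table["cms"]
        rate = (g[cms == "CMS1"] > g.median()).mean()
        assert rate > 0.7


class TestDataset:
    def test_seed_determinism_bit_identical(self):
        cfg = SimConfig(n_genes=4, n_discovery=60, n_validation=40, seed=33)
        a, b = simulate_dataset(cfg), simulate_dataset(cfg)
        pd.testing.assert_frame_equal(a.genotypes.dosages, b.genotypes.dosages)
        pd.testing.assert_frame_equal(a.expression.values, b.expression.values)
        pd.testing.assert_frame_equal(a.clinical.table, b.clinical.table)

    def test_truth_queryable_without_rederiving(self):
        cfg = SimConfig(n_genes=4, n_discovery=50, n_validation=30, seed=34,
                        causal_effects=[("gene_0001", "cetuximab", -0.5)])
        data = simulate_dataset(cfg)
        assert data.truth.causal_genes() == {"gene_0001"}
        assert all(len(v) > 0 for v in data.truth.eqtl_map.values())

    def test_arm_assignment_balanced(self):
        cfg = SimConfig(n_genes=2, n_discovery=400, n_validation=400, seed=35)
        data = simulate_dataset(cfg)
        frac = (data.clinical.table["arm"] == ARMS[0]).mean()
        assert 0.4 < frac < 0.6

    def test_cohort_split_sizes(self):
        cfg = SimConfig(n_genes=2, n_discovery=70, n_validation=50, seed=36)
        data = simulate_dataset(cfg)
        assert len(data.discovery_samples) == 70
        assert len(data.validation_samples) == 50
        assert len(data.expression.samples) == 70
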