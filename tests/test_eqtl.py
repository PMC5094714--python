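import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mtexpress import expression, synthdata
from mtexpress.eqtl import (
    GenotypeMatrix,
    background_contrast,
    bonferroni_threshold,
    build_covariate_matrix,
    encode_design,
    fit_linear,
    scan,
    site_filters,
    stratified_scan,
)


def haploid_matrix(rows: dict, samples: list) -> GenotypeMatrix:
    return GenotypeMatrix(
        data=pd.DataFrame(rows, index=samples).T, ploidy="haploid"
    )


def ols_oracle(y, x_cols):
    """Normal equations + explicit t CDF, independent of the implementation."""
    X = np.column_stack(list(x_cols) + [np.ones(len(y))])
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(cov[0, 0])
    t = beta[0] / se
    p = 2 * stats.t.sf(abs(t), df)
    return beta[0], se, t, df, p


class TestSiteFilters:
    def test_nine_carriers_dropped_ten_retained(self):
        samples = [f"s{i}" for i in range(454)]
        gm = haploid_matrix(
            {"site9": ["C"] * 9 + ["A"] * 445, "site10": ["C"] * 10 + ["A"] * 444},
            samples,
        )
        kept = site_filters(gm, min_carriers=10, max_major_freq=0.99)
        assert kept.sites == ["site10"]

    def test_major_allele_frequency_ceiling(self):
        samples = [f"s{i}" for i in range(100)]
        gm = haploid_matrix(
            {"rare": ["C"] * 4 + ["A"] * 96, "common": ["C"] * 20 + ["A"] * 80},
            samples,
        )
        kept = site_filters(gm, min_carriers=2, max_major_freq=0.95)
        assert kept.sites == ["common"]  # 96% major exceeds the 95% ceiling

    def test_exactly_95_percent_major_retained(self):
        samples = [f"s{i}" for i in range(100)]
        gm = haploid_matrix({"edge": ["C"] * 5 + ["A"] * 95}, samples)
        assert site_filters(gm, min_carriers=5, max_major_freq=0.95).sites == ["edge"]

    def test_missing_excluded_from_denominator(self):
        samples = [f"s{i}" for i in range(100)]
        # 50 N, 48 A, 2 C: major frequency among called = 48/50 = 96%
        gm = haploid_matrix({"s": ["N"] * 50 + ["A"] * 48 + ["C"] * 2}, samples)
        assert site_filters(gm, min_carriers=2, max_major_freq=0.95).sites == []

    def test_diploid_filtering_by_carriers(self):
        samples = [f"s{i}" for i in range(100)]
        data = pd.DataFrame(
            {"snp1": [1] * 9 + [0] * 91, "snp2": [1] * 30 + [0] * 70},
            index=samples,
        ).T
        gm = GenotypeMatrix(data=data, ploidy="diploid")
        assert site_filters(gm, min_carriers=10, max_major_freq=0.99).sites == ["snp2"]


class TestEncodeDesign:
    def test_biallelic_site_single_indicator(self):
        designs = encode_design("s", np.array(["A"] * 7 + ["C"] * 3), "haploid")
        assert len(designs) == 1
        assert designs[0].allele == "C"
        assert designs[0].x.sum() == 3

    def test_triallelic_site_two_designs_minor_vs_rest(self):
        row = np.array(["A"] * 30 + ["C"] * 15 + ["G"] * 12)
        designs = encode_design("s", row, "haploid", min_carriers=10)
        assert [d.allele for d in designs] == ["C", "G"]
        for d in designs:
            assert set(d.x) == {0.0, 1.0}

    def test_rare_minor_not_tested(self):
        row = np.array(["A"] * 30 + ["C"] * 15 + ["G"] * 3)
        designs = encode_design("s", row, "haploid", min_carriers=10)
        assert [d.allele for d in designs] == ["C"]

    def test_constant_covariate_dropped_within_called_subset(self):
        row = np.array(["A", "A", "C", "C", "N", "N"])
        cov = build_covariate_matrix(
            pd.DataFrame({"lab": ["x", "x", "x", "x", "y", "y"]})
        )
        designs = encode_design("s", row, "haploid", cov)
        # lab varies overall but is constant among called samples
        assert designs[0].covariates is None

    def test_diploid_additive_dosage(self):
        row = np.array([0, 1, 2, 1, np.nan])
        designs = encode_design("s", row, "diploid")
        assert len(designs) == 1
        assert np.array_equal(designs[0].x, [0, 1, 2, 1])
        assert designs[0].mask.sum() == 4


class TestFitLinear:
    def test_exact_linear_relationship(self):
        x = np.array([0.0, 1.0] * 10)
        y = 2.0 * x
        result = fit_linear(y, x)
        assert result.effect == pytest.approx(2.0)
        assert result.p == 0.0 or result.p < 1e-200

    def test_matches_normal_equations_oracle_on_fixed_fixture(self):
        # 10 samples, one allele indicator, one numeric covariate
        y = np.array([4.1, 5.2, 3.9, 6.8, 7.1, 2.9, 5.5, 6.1, 4.4, 7.9])
        x = np.array([0.0, 1, 0, 1, 1, 0, 0, 1, 0, 1])
        z = np.array([1.2, 0.4, 2.2, 1.9, 0.1, 2.8, 1.1, 0.7, 1.5, 0.3])
        cov = pd.DataFrame({"z": z})
        result = fit_linear(y, x, cov)
        eff, se, t, df, p = ols_oracle(y, [x, z])
        assert result.effect == pytest.approx(eff, abs=1e-10)
        assert result.se == pytest.approx(se, abs=1e-10)
        assert result.t == pytest.approx(t, abs=1e-10)
        assert result.df == df
        assert result.p == pytest.approx(p, abs=1e-10)
        assert result.n == 10

    def test_agrees_with_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        x = rng.integers(0, 2, 50).astype(float)
        z = rng.normal(size=50)
        y = 0.4 * x + 0.2 * z + rng.normal(size=50)
        result = fit_linear(y, x, pd.DataFrame({"z": z}))
        fit = sm.OLS(y, sm.add_constant(np.column_stack([x, z]))).fit()
        assert result.effect == pytest.approx(fit.params[1], abs=1e-10)
        assert result.p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_rank_deficient_design_names_columns(self):
        x = np.array([0.0, 1, 0, 1, 0, 1, 0, 1])
        cov = pd.DataFrame({"copy_of_x": x})
        with pytest.raises(ValueError, match="collinear"):
            fit_linear(np.arange(8.0), x, cov)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_linear(np.arange(8.0), np.ones(8))

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 2, 60).astype(float)
        pvals = []
        for _ in range(500):
            y = rng.normal(size=60)
            pvals.append(fit_linear(y, x).p)
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01


class TestScan:
    def test_single_pair_equals_fit_linear(self, normalized_planted, planted_cohort):
        gm = planted_cohort["genotypes"]
        cov = planted_cohort["covariates"]
        site = gm.sites[0]
        gene = normalized_planted.index[0]
        results = scan(
            normalized_planted.loc[[gene]],
            GenotypeMatrix(data=gm.data.loc[[site]], ploidy="haploid"),
            cov,
        )
        assert len(results) == 1
        row = results.iloc[0]
        designs = encode_design(
            site, gm.data.loc[site], "haploid",
            build_covariate_matrix(cov.loc[gm.samples]), min_carriers=10,
        )
        direct = fit_linear(
            normalized_planted.loc[gene, gm.samples].to_numpy()[designs[0].mask],
            designs[0].x, designs[0].covariates,
        )
        assert row["effect"] == pytest.approx(direct.effect, abs=1e-10)
        assert row["p"] == pytest.approx(direct.p, abs=1e-10)

    def test_every_scan_pvalue_matches_oracle(
        self, normalized_planted, planted_cohort
    ):
        gm = planted_cohort["genotypes"]
        cov = planted_cohort["covariates"]
        sub = normalized_planted.iloc[:6]
        results = scan(sub, gm, cov)
        cov_num = build_covariate_matrix(cov.loc[gm.samples])
        for _, row in results.iterrows():
            designs = encode_design(
                row["site"] if row["site"] in gm.data.index else int(row["site"]),
                gm.data.loc[int(row["site"])], "haploid", cov_num,
                min_carriers=10,
            )
            design = next(d for d in designs if d.allele == row["allele"])
            y = sub.loc[row["gene"], gm.samples].to_numpy()[design.mask]
            cols = [design.x] + (
                [design.covariates[c].to_numpy() for c in design.covariates]
                if design.covariates is not None else []
            )
            eff, se, t, df, p = ols_oracle(y, cols)
            assert row["effect"] == pytest.approx(eff, abs=1e-10)
            assert row["p"] == pytest.approx(p, abs=1e-10)

    def test_monomorphic_genotypes_give_empty_result(self):
        samples = [f"s{i}" for i in range(20)]
        gm = haploid_matrix({"s1": ["A"] * 20}, samples)
        expr = pd.DataFrame(
            np.random.default_rng(0).normal(size=(3, 20)),
            index=["g1", "g2", "g3"], columns=samples,
        )
        results = scan(expr, gm, None, min_carriers=1)
        assert len(results) == 0
        assert results.attrs["n_tests"] == 0

    def test_family_size_equals_emitted_rows(
        self, normalized_planted, planted_cohort
    ):
        results = scan(
            normalized_planted, planted_cohort["genotypes"],
            planted_cohort["covariates"],
        )
        assert results.attrs["n_tests"] == len(results)
        assert (results["family"] == "mtDNA-scan").all()
        assert (results["p"].diff().dropna() >= 0).all()  # sorted


class TestBonferroni:
    def test_published_threshold_arithmetic(self):
        # 7,665 nuclear-SNP × mtDNA-gene tests at alpha 0.05
        assert bonferroni_threshold(0.05, 7665) == pytest.approx(6.52e-6, abs=5e-9)
        # 15 mtDNA genes × 63,662 nuclear genes in the co-expression screen
        assert bonferroni_threshold(0.05, 15 * 63662) == pytest.approx(
            5.23e-8, abs=1e-10
        )

    def test_single_test_returns_alpha(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestCovariateAdjustment:
    def test_lab_confounding_controlled_by_adjustment(self):
        # lab is pushed toward lab1 for L samples and lab1 carries its own
        # expression effect on every gene; adjusting for lab keeps the null
        # SNP rejection rate at alpha, omitting it inflates the rate
        # the effect hits only half the genes — a lab effect on every gene
        # would be indistinguishable from a library-size factor and be
        # absorbed by normalization
        genes = {f"G{i}": 300.0 for i in range(120)}
        affected = [f"G{i}" for i in range(60)]
        effects = tuple((g, "lab=lab1", 0.5) for g in affected)
        config = synthdata.SimulationConfig(
            n_samples=300, baseline_means=genes, planted_effects=effects,
            confound_lab_with_clade=0.8, nb_dispersion=0.05,
            libsize_sigma=0.0, reference_length=2000, seed=13,
        )
        ref = synthdata.simulate_reference(config)
        hapdef, haps = synthdata.simulate_haplotypes(config, ref)
        samples = synthdata.simulate_cohort(config, haps)
        counts = synthdata.simulate_counts(samples, config)
        norm = expression.normalize(counts, expression.size_factors(counts))
        gm = synthdata.true_site_matrix(samples, hapdef, haps)
        cov = samples[["sex", "lab"]]
        adjusted = scan(norm, gm, cov)
        unadjusted = scan(norm, gm, None)
        adj_aff = adjusted[adjusted.gene.isin(affected)]
        raw_aff = unadjusted[unadjusted.gene.isin(affected)]
        rate_adj = (adj_aff["p"] < 0.05).mean()
        rate_raw = (raw_aff["p"] < 0.05).mean()
        assert rate_adj <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(adj_aff))
        assert rate_raw > rate_adj + 0.1


class TestStratifiedScan:
    def _stratum_cohort(self, seed=14):
        config = synthdata.SimulationConfig(
            n_samples=300, baseline_means={f"G{i}": 500.0 for i in range(10)},
            nb_dispersion=0.05, libsize_sigma=0.0, reference_length=2000,
            seed=seed,
        )
        ref = synthdata.simulate_reference(config)
        hapdef, haps = synthdata.simulate_haplotypes(config, ref)
        samples = synthdata.simulate_cohort(config, haps)
        counts = synthdata.simulate_counts(samples, config)
        norm = expression.normalize(counts, expression.size_factors(counts))
        gm = synthdata.true_site_matrix(samples, hapdef, haps)
        return samples, norm, gm

    def test_stratum_specific_effect_found_only_in_its_stratum(self):
        samples, norm, gm = self._stratum_cohort()
        rng = np.random.default_rng(15)
        strata = pd.Series(
            rng.choice(["P1", "P2"], size=len(samples)), index=samples.index
        )
        site = gm.sites[0]
        alleles = gm.data.loc[site]
        minor = alleles.value_counts().index[-1]
        in_p1 = (strata == "P1").to_numpy()
        carrier = (alleles == minor).to_numpy()
        norm = norm.copy()
        norm.loc["G0"] = norm.loc["G0"] + 600.0 * (carrier & in_p1)
        results = stratified_scan(norm, gm, None, strata, min_stratum_n=30)
        p1_hits = results["P1"]
        p1_row = p1_hits[
            (p1_hits.gene == "G0") & (p1_hits.site == str(site))
            & (p1_hits.allele == minor)
        ]
        p2_row = results["P2"][
            (results["P2"].gene == "G0") & (results["P2"].site == str(site))
            & (results["P2"].allele == minor)
        ]
        assert p1_row.iloc[0]["p"] < 1e-8
        assert p2_row.iloc[0]["p"] > 1e-4

    def test_single_stratum_equals_unstratified(self):
        samples, norm, gm = self._stratum_cohort(seed=16)
        strata = pd.Series("only", index=samples.index)
        stratified = stratified_scan(norm, gm, None, strata, min_stratum_n=30)
        plain = scan(norm, gm, None)
        merged = stratified["only"].drop(columns="family")
        pd.testing.assert_frame_equal(
            merged.reset_index(drop=True),
            plain.drop(columns="family").reset_index(drop=True),
        )

    def test_small_stratum_skipped(self):
        samples, norm, gm = self._stratum_cohort(seed=17)
        strata = pd.Series("big", index=samples.index)
        strata.iloc[:5] = "tiny"
        results = stratified_scan(norm, gm, None, strata, min_stratum_n=30)
        assert set(results) == {"big"}


class TestBackgroundContrast:
    def _masked_data(self, seed, delta=3.0, n_per=120):
        rng = np.random.default_rng(seed)
        backgrounds = np.repeat(["B1", "B2"], n_per)
        alleles = np.where(rng.random(2 * n_per) < 0.5, "T", "C")
        signed = np.where(backgrounds == "B1", delta, -delta)
        y = signed * (alleles == "T") + rng.normal(size=2 * n_per)
        return y, alleles, backgrounds

    def test_opposite_effects_masked_in_pooled_analysis(self):
        y, alleles, backgrounds = self._masked_data(seed=18)
        report = background_contrast(y, alleles, backgrounds, allele="T")
        assert report.per_background["B1"].p < 1e-6
        assert report.per_background["B2"].p < 1e-6
        assert report.pooled.p > 0.01
        assert report.heterogeneity_p < 1e-6
        assert report.heterogeneity_df == 1

    def test_homogeneous_effects_give_null_heterogeneity(self):
        rng = np.random.default_rng(19)
        pvals = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            backgrounds = np.repeat(["B1", "B2"], 60)
            alleles = np.where(r.random(120) < 0.5, "T", "C")
            y = 1.0 * (alleles == "T") + r.normal(size=120)
            report = background_contrast(y, alleles, backgrounds, allele="T")
            pvals.append(report.heterogeneity_p)
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_background_missing_an_allele_is_excluded(self):
        y = np.arange(40.0)
        alleles = np.array(["T"] * 10 + ["C"] * 10 + ["C"] * 20)
        backgrounds = np.array(["B1"] * 20 + ["B2"] * 20)
        report = background_contrast(y, alleles, backgrounds, allele="T")
        assert report.excluded_backgrounds == ("B2",)
        assert list(report.per_background) == ["B1"]
        assert report.heterogeneity_stat is None
        assert report.heterogeneity_p is None
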