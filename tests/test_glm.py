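"""Quasi-binomial GLM engine, analysis of deviance and phenotype extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import cgvscreen as cgv
from cgvscreen.glm import DesignSpec, QuasiBinomialLogit, _Design


def irls_normal_equations(X, dead, m, tol=1e-13, max_iter=500):
    """Independent oracle: explicit normal-equations IRLS loop, no GLM library."""
    mu = (dead + 0.5) / (m + 1.0)
    for _ in range(max_iter):
        eta = logit(mu)
        w = m * mu * (1 - mu)
        z = eta + (dead / m - mu) / (mu * (1 - mu))
        A = (X * w[:, None]).T @ X
        beta = np.linalg.solve(A, (X * w[:, None]).T @ z)
        mu_new = expit(X @ beta)
        if np.max(np.abs(mu_new - mu)) < tol:
            return beta
        mu = mu_new
    return beta


class TestEngine:
    def test_intercept_only_closed_form(self):
        X = np.ones((1, 1))
        y = np.array([[30.0, 70.0]])
        eng = QuasiBinomialLogit().fit(X, y)
        assert eng.params_["estimate"].iloc[0] == pytest.approx(logit(0.30), abs=1e-6)
        assert eng.fitted_[0] == pytest.approx(0.30, abs=1e-8)

    def test_pearson_dispersion_definitional_identity(self, tame_screen):
        _, _, wells, _ = tame_screen
        fit = cgv.fit_quasibinomial_glm(wells)
        m = (wells.n_dead + wells.n_larvae).to_numpy(float)
        phat = wells.n_dead.to_numpy(float) / m
        mu = fit.fitted
        pearson = np.sum(m * (phat - mu) ** 2 / (mu * (1 - mu)))
        assert fit.dispersion == pytest.approx(pearson / fit.df_resid, rel=1e-12)

    def test_coefficients_match_normal_equations_oracle(self, tame_screen):
        _, _, wells, _ = tame_screen
        spec = DesignSpec(term_order=("strain", "gene", "adults", "strain:gene"))
        fit = cgv.fit_quasibinomial_glm(wells, spec)
        assert not fit.params["separated"].any()
        d = _Design(wells, spec)
        y = wells[["n_dead", "n_larvae"]].to_numpy(float)
        beta = irls_normal_equations(d.X, y[:, 0], y.sum(1))
        assert np.max(np.abs(fit.params["estimate"].to_numpy() - beta)) < 1e-6

    def test_cross_check_against_statsmodels(self, tame_screen):
        """Same coefficients and Pearson chi-square as an independent GLM library."""
        sm = pytest.importorskip("statsmodels.api")
        _, _, wells, _ = tame_screen
        spec = DesignSpec(term_order=("strain", "gene", "adults", "strain:gene"))
        fit = cgv.fit_quasibinomial_glm(wells, spec)
        d = _Design(wells, spec)
        res = sm.GLM(wells[["n_dead", "n_larvae"]].to_numpy(float), d.X, family=sm.families.Binomial()).fit()
        assert np.max(np.abs(res.params - fit.params["estimate"].to_numpy())) < 1e-8
        assert res.pearson_chi2 == pytest.approx(fit.dispersion * fit.df_resid, rel=1e-10)
        assert res.deviance == pytest.approx(fit.deviance, abs=1e-5)

    def test_fit_invariant_to_row_order(self, tame_screen):
        _, _, wells, _ = tame_screen
        fit1 = cgv.fit_quasibinomial_glm(wells)
        shuffled = wells.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit2 = cgv.fit_quasibinomial_glm(shuffled)
        pd.testing.assert_series_equal(fit1.params["estimate"], fit2.params["estimate"], atol=1e-9, rtol=1e-7)

    def test_zero_offspring_wells_dropped_with_count(self, tame_screen):
        _, _, wells, _ = tame_screen
        wells = wells.copy()
        wells.loc[wells.index[:3], ["n_dead", "n_larvae"]] = 0
        fit = cgv.fit_quasibinomial_glm(wells)
        assert fit.n_dropped_wells == 3
        assert fit.n_obs == len(wells) - 3

    def test_complete_separation_flagged_not_silent(self):
        # one strain always dies, the other never: logit coefficient unbounded
        rows = []
        for s, frac in (("A", 0), ("B", 1)):
            for w in range(4):
                rows.append({"strain": s, "gene": "g1", "adults": 10, "date": "d1", "n_dead": 50 * frac, "n_larvae": 50 * (1 - frac)})
        wells = pd.DataFrame(rows)
        fit = cgv.fit_quasibinomial_glm(wells, DesignSpec(term_order=("strain",)))
        assert fit.params["separated"].any()

    def test_single_strain_rejected(self):
        wells = pd.DataFrame({"strain": ["A"] * 4, "gene": ["g"] * 4, "adults": 10, "date": "d", "n_dead": [3, 4, 5, 6], "n_larvae": 50})
        with pytest.raises(ValueError, match="2 strains"):
            cgv.fit_quasibinomial_glm(wells)


class TestSequentialAnova:
    def test_deviance_additivity_against_refit(self, tame_screen):
        _, _, wells, _ = tame_screen
        table = cgv.sequential_anova(wells)
        null_dev = table.loc[table.term == "NULL", "resid_dev"].iloc[0]
        final = table["resid_dev"].iloc[-1]
        assert table["deviance"].iloc[1:].sum() == pytest.approx(null_dev - final, rel=1e-9)
        # residual deviance non-increasing, df bookkeeping closed
        assert (np.diff(table["resid_dev"]) <= 1e-8).all()
        assert table["df"].iloc[1:].sum() + table["resid_df"].iloc[-1] == table["resid_df"].iloc[0]

    def test_aliased_term_gets_zero_df_row(self, tame_screen):
        """Date batches assigned by strain blocks are aliased with strain."""
        _, _, wells, _ = tame_screen
        table = cgv.sequential_anova(wells)
        date_row = table[table.term == "date"].iloc[0]
        assert date_row["df"] == 0
        assert np.isnan(date_row["F"])

    def test_null_term_f_near_one_under_label_permutation(self):
        """Strain labels permuted within gene (preserving balance): F ~ 1.

        Permuting across genes would unbalance the strain x gene layout and
        let the sequentially-first strain term absorb genuine gene effects.
        """
        rng = np.random.default_rng(0)
        fs = []
        for rep in range(30):
            cfg = cgv.SimulationConfig(
                n_strains=8, n_genes=3, wells_per_cell=4, offspring_per_well=80, n_snps=20,
                seed=rep, n_resistant_strains=0, n_informational_loci=0, per_gene_modifier_loci=0,
                adults_effect=0.0, date_effects=(0.0,),
            )
            g = cgv.simulate_genotypes(cfg)
            wells, _ = cgv.simulate_screen(cfg, g)
            wells["strain"] = wells.groupby("gene")["strain"].transform(lambda s: rng.permutation(s.to_numpy()))
            t = cgv.sequential_anova(wells, DesignSpec(term_order=("strain", "gene", "strain:gene")))
            fs.append(float(t.loc[t.term == "strain", "F"].iloc[0]))
        assert np.mean(fs) == pytest.approx(1.0, abs=0.25)


class TestPartitionDeviance:
    def test_all_terms_identity(self, tame_screen):
        _, _, wells, _ = tame_screen
        table = cgv.sequential_anova(wells)
        pct = cgv.partition_deviance(table, [t for t in table.term if t != "NULL"])
        null_dev = table.loc[table.term == "NULL", "resid_dev"].iloc[0]
        assert pct == pytest.approx(100 * (1 - table["resid_dev"].iloc[-1] / null_dev), rel=1e-12)

    def test_single_term_equal_to_null_gives_100(self):
        table = pd.DataFrame(
            {"term": ["NULL", "strain"], "df": [np.nan, 5], "deviance": [np.nan, 1000.0],
             "resid_df": [10, 5], "resid_dev": [1000.0, 0.0], "F": [np.nan, 1], "p": [np.nan, 0.5]}
        )
        assert cgv.partition_deviance(table, ["strain"]) == pytest.approx(100.0)

    def test_missing_null_row_rejected(self):
        table = pd.DataFrame({"term": ["strain"], "df": [5], "deviance": [10.0], "resid_df": [5], "resid_dev": [1.0], "F": [1], "p": [0.5]})
        with pytest.raises(ValueError, match="NULL"):
            cgv.partition_deviance(table, ["strain"])


class TestPhenotypeExtraction:
    def test_reference_row_and_column_are_structural_zeros(self, tame_screen):
        _, _, wells, _ = tame_screen
        fit = cgv.fit_quasibinomial_glm(wells)
        ph = cgv.extract_cgv_phenotypes(fit)
        assert (ph.estimates.loc[ph.reference_strain] == 0).all()
        assert (ph.estimates[ph.reference_gene] == 0).all()
        assert ph.coding == "treatment"

    def test_coding_invariance_of_identifiable_contrast(self, tame_screen):
        """Treatment and sum-to-zero fits agree on the doubly centered interaction."""
        _, _, wells, _ = tame_screen
        spec_t = DesignSpec(term_order=("strain", "gene", "adults", "strain:gene"))
        spec_s = DesignSpec(term_order=("strain", "gene", "adults", "strain:gene"), coding="sum")
        pt = cgv.extract_cgv_phenotypes(cgv.fit_quasibinomial_glm(wells, spec_t))
        ps = cgv.extract_cgv_phenotypes(cgv.fit_quasibinomial_glm(wells, spec_s))
        dt = cgv.identifiable_contrast(pt.estimates, coding="sum")
        ds = cgv.identifiable_contrast(ps.estimates, coding="sum")
        assert np.max(np.abs(dt.to_numpy() - ds.to_numpy())) < 1e-6

    def test_per_gene_centering_recorded(self, tame_screen):
        _, _, wells, _ = tame_screen
        fit = cgv.fit_quasibinomial_glm(wells)
        ph = cgv.extract_cgv_phenotypes(fit, center=True)
        assert ph.centered
        assert np.allclose(ph.estimates.mean(axis=0), 0.0, atol=1e-12)


class TestIntrogressionTest:
    @staticmethod
    def plates(counts_by_strain):
        rows = []
        for strain, plate_counts in counts_by_strain.items():
            for dead, larv in plate_counts:
                rows.append({"strain": strain, "n_dead": dead, "n_larvae": larv})
        return pd.DataFrame(rows)

    def test_identical_counts_give_f_zero_p_one(self):
        plates = self.plates({s: [(10, 90)] * 3 for s in ("A", "B", "C")})
        F, df, p = cgv.introgression_test(plates)
        assert F == 0.0 and df == 2 and p == 1.0

    def test_f_grows_with_strain_effect(self):
        rng = np.random.default_rng(2)
        fs = []
        for diff in (0.0, 1.0, 2.0):
            p0, p1 = expit(-1.0), expit(-1.0 + diff)
            plates = self.plates(
                {"A": [(rng.binomial(200, p0), 0) for _ in range(6)], "B": [(rng.binomial(200, p1), 0) for _ in range(6)]}
            )
            plates["n_larvae"] = 200 - plates["n_dead"]
            F, _, _ = cgv.introgression_test(plates)
            fs.append(F)
        assert fs[0] < fs[1] < fs[2]

    def test_single_strain_rejected(self):
        with pytest.raises(ValueError, match="2 strains"):
            cgv.introgression_test(self.plates({"A": [(5, 95)] * 3}))
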