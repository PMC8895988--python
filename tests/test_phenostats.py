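import numpy as np
import pandas as pd
import pytest

from phenopred import phenostats, simulate
from phenopred.errors import DesignError, UndefinedStatisticError
from phenopred.phenostats import VarianceComponents, heritability


def anova_components(plots, trait="trait"):
    """Balanced-design ANOVA method-of-moments oracle for the plot model
    without blocks (genotype x env with replicates nested in env)."""
    wide = plots.pivot_table(
        index="genotype", columns=["environment", "replicate"], values=trait
    )
    n_env = plots["environment"].nunique()
    n_rep = plots["replicate"].nunique()
    arr = wide.to_numpy().reshape(len(wide), n_env, n_rep)
    a, b, r = arr.shape
    gm = arr.mean()
    mg = arr.mean(axis=(1, 2))
    me = arr.mean(axis=(0, 2))
    mge = arr.mean(axis=2)
    mr = arr.mean(axis=0)
    ms_g = b * r * ((mg - gm) ** 2).sum() / (a - 1)
    ms_e = a * r * ((me - gm) ** 2).sum() / (b - 1)
    ms_ge = (
        r * ((mge - mg[:, None] - me[None, :] + gm) ** 2).sum()
        / ((a - 1) * (b - 1))
    )
    ms_r = a * ((mr - me[:, None]) ** 2).sum() / (b * (r - 1))
    ms_err = (
        (arr - mge[:, :, None] - mr[None, :, :] + me[None, :, None]) ** 2
    ).sum() / ((a - 1) * b * (r - 1))
    return {
        "sigma2_g": (ms_g - ms_ge) / (b * r),
        "sigma2_gxe": (ms_ge - ms_err) / r,
        "sigma2_env": (ms_e - ms_ge - (ms_r - ms_err)) / (a * r),
        "sigma2_rep": (ms_r - ms_err) / a,
        "sigma2_eps": ms_err,
    }


class TestFitPlotModel:
    def test_noise_free_blues_are_the_cell_values(self):
        g = pd.Series([10.0, 12.0], index=["g1", "g2"])
        vc = dict(sigma2_env=0, sigma2_gxe=0, sigma2_rep=0, sigma2_block=0,
                  sigma2_eps=0, mu=0.0)
        plots = simulate.simulate_plots(
            g, simulate.DesignConfig(1, 1, 1), vc, seed=0
        )
        fit = phenostats.fit_plot_model(plots, "trait", genotype_fixed=True)
        assert fit.blues.tolist() == [10.0, 12.0]

    def test_reml_matches_balanced_anova_oracle(self, balanced_plots):
        plots, _, _ = balanced_plots
        fit = phenostats.fit_plot_model(plots, "trait")
        oracle = anova_components(plots)
        got = fit.vc.as_dict()
        for key, val in oracle.items():
            assert got[key] == pytest.approx(val, abs=1e-6), key

    def test_blues_equal_genotype_means_in_balanced_design(
        self, balanced_plots
    ):
        plots, _, _ = balanced_plots
        fit = phenostats.fit_plot_model(plots, "trait", genotype_fixed=True)
        means = plots.groupby("genotype")["trait"].mean()
        assert np.abs(fit.blues - means).max() < 1e-9

    def test_component_recovery_over_seeds(self):
        truth = dict(sigma2_env=1.0, sigma2_gxe=2.0, sigma2_rep=0.2,
                     sigma2_block=0.0, sigma2_eps=4.0, mu=0.0)
        est = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            g = pd.Series(rng.normal(0, 2, 60),
                          index=[f"g{i:02d}" for i in range(60)])
            plots = simulate.simulate_plots(
                g, simulate.DesignConfig(3, 2, 1), truth, seed=seed
            )
            fit = phenostats.fit_plot_model(plots, "trait")
            est.append((fit.vc.sigma2_g, fit.vc.sigma2_gxe, fit.vc.sigma2_eps))
        mean = np.mean(est, axis=0)
        assert mean[0] == pytest.approx(4.0, rel=0.15)  # var of g draws
        assert mean[1] == pytest.approx(2.0, rel=0.15)
        assert mean[2] == pytest.approx(4.0, rel=0.15)

    def test_unbalanced_blues_match_dense_gls_oracle(self, balanced_plots):
        plots, _, _ = balanced_plots
        unbal = plots.drop(index=plots.index[5]).reset_index(drop=True)
        fit = phenostats.fit_plot_model(unbal, "trait", genotype_fixed=True)
        # direct GLS with V assembled from the fitted components
        y, X, Z, meta = phenostats._build_design(unbal, "trait", True)
        V = fit.vc.sigma2_eps * np.eye(len(y))
        comp = {"env": fit.vc.sigma2_env, "gxe": fit.vc.sigma2_gxe,
                "rep": fit.vc.sigma2_rep}
        for f, mat in Z.items():
            V += comp[f] * (mat @ mat.T).toarray()
        Xd = X.toarray()
        Vi = np.linalg.inv(V)
        blues = np.linalg.solve(Xd.T @ Vi @ Xd, Xd.T @ Vi @ y)
        assert np.abs(fit.blues.to_numpy() - blues).max() < 1e-6

    def test_constant_trait_gives_constant_blues(self):
        g = pd.Series([0.0, 0.0, 0.0], index=list("abc"))
        vc = dict(sigma2_env=0, sigma2_gxe=0, sigma2_rep=0, sigma2_block=0,
                  sigma2_eps=0, mu=7.5)
        plots = simulate.simulate_plots(
            g, simulate.DesignConfig(2, 2, 1), vc, seed=0
        )
        fit = phenostats.fit_plot_model(plots, "trait", genotype_fixed=True)
        assert np.allclose(fit.blues, 7.5)

    def test_too_few_genotypes_rejected(self):
        plots = pd.DataFrame(
            {"genotype": ["a"] * 4, "environment": ["E1", "E1", "E2", "E2"],
             "replicate": [1, 2, 1, 2], "block": 1, "trait": [1.0, 2, 3, 4]}
        )
        with pytest.raises(DesignError):
            phenostats.fit_plot_model(plots, "trait")


class TestHeritability:
    def make_vc(self, g=4.0, ge=2.0, eps=4.0, ne=3, nr=2):
        return VarianceComponents(
            sigma2_g=g, sigma2_gxe=ge, sigma2_env=1.0, sigma2_rep=0.1,
            sigma2_block=0.1, sigma2_eps=eps, ne=ne, nr=nr,
        )

    def test_worked_value(self):
        assert heritability(self.make_vc()) == pytest.approx(0.75, abs=1e-12)

    def test_zero_genotypic_variance(self):
        assert heritability(self.make_vc(g=0.0)) == 0.0

    def test_limit_of_many_environments(self):
        prev = 0.0
        for ne in (1, 2, 5, 20, 200):
            h = heritability(self.make_vc(ne=ne, nr=ne))
            assert h >= prev
            prev = h
        assert prev > 0.99

    def test_monotone_in_each_component(self):
        base = heritability(self.make_vc())
        assert heritability(self.make_vc(g=5.0)) > base
        assert heritability(self.make_vc(ge=3.0)) < base
        assert heritability(self.make_vc(eps=5.0)) < base
        assert heritability(self.make_vc(ne=4)) > base
        assert heritability(self.make_vc(nr=3)) > base

    def test_all_zero_components_signalled(self):
        with pytest.raises(UndefinedStatisticError):
            heritability(self.make_vc(g=0.0, ge=0.0, eps=0.0))


class TestGroupHeritabilities:
    def test_orders_groups_by_genotypic_variance(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            ga = pd.Series(rng.normal(0, 1.0, 30),
                           index=[f"A{i:02d}" for i in range(30)])
            gb = pd.Series(rng.normal(0, 3.0, 30),
                           index=[f"B{i:02d}" for i in range(30)])
            vc = dict(sigma2_env=1.0, sigma2_gxe=0.5, sigma2_rep=0.1,
                      sigma2_block=0.0, sigma2_eps=2.0, mu=0.0)
            plots = simulate.simulate_plots(
                pd.concat([ga, gb]), simulate.DesignConfig(3, 2, 1), vc,
                seed=seed,
            )
            gmap = pd.DataFrame(
                {"genotype_id": list(ga.index) + list(gb.index),
                 "subgroup": ["A"] * 30 + ["B"] * 30}
            )
            h2 = phenostats.group_heritabilities(plots, "trait", gmap)
            hits += h2["B"] > h2["A"]
        assert hits >= int(0.95 * n_seeds)

    def test_zero_variance_group_has_near_zero_h2(self):
        rng = np.random.default_rng(0)
        g = pd.Series(np.zeros(50), index=[f"g{i:02d}" for i in range(50)])
        vc = dict(sigma2_env=1.0, sigma2_gxe=0.5, sigma2_rep=0.1,
                  sigma2_block=0.0, sigma2_eps=2.0, mu=0.0)
        plots = simulate.simulate_plots(
            g, simulate.DesignConfig(3, 2, 1), vc, seed=1
        )
        gmap = pd.DataFrame({"genotype_id": g.index, "subgroup": "Z"})
        fit = phenostats.fit_plot_model(plots, "trait")
        assert heritability(fit.vc) <= 0.1

    def test_single_genotype_group_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        g = pd.Series(rng.normal(0, 1, 31),
                      index=[f"g{i:02d}" for i in range(31)])
        vc = dict(sigma2_env=0.5, sigma2_gxe=0.5, sigma2_rep=0.1,
                  sigma2_block=0.0, sigma2_eps=1.0, mu=0.0)
        plots = simulate.simulate_plots(
            g, simulate.DesignConfig(2, 2, 1), vc, seed=3
        )
        gmap = pd.DataFrame(
            {"genotype_id": g.index,
             "subgroup": ["A"] * 30 + ["solo"]}
        )
        with pytest.warns(UserWarning, match="solo"):
            h2 = phenostats.group_heritabilities(plots, "trait", gmap)
        assert set(h2) == {"A"}


class TestOutliers:
    def clean_plots(self, seed=0, n=50):
        rng = np.random.default_rng(seed)
        g = pd.Series(rng.normal(0, 2, n),
                      index=[f"g{i:02d}" for i in range(n)])
        vc = dict(sigma2_env=1.0, sigma2_gxe=0.3, sigma2_rep=0.1,
                  sigma2_block=0.0, sigma2_eps=1.0, mu=20.0)
        return simulate.simulate_plots(
            g, simulate.DesignConfig(2, 2, 1), vc, seed=seed
        )

    def test_clean_data_unflagged(self):
        flags = phenostats.detect_outliers(self.clean_plots(), "trait")
        assert flags.sum() == 0

    def test_gross_outlier_is_flagged_exactly(self):
        plots = self.clean_plots(seed=4)
        plots.loc[17, "trait"] += 100.0
        flags = phenostats.detect_outliers(plots, "trait")
        assert flags.sum() == 1 and bool(flags.loc[17])

    def test_family_wise_error_rate_under_null(self):
        n_seeds = 150
        false_alarms = 0
        for seed in range(n_seeds):
            flags = phenostats.detect_outliers(
                self.clean_plots(seed=1000 + seed), "trait", alpha=0.05
            )
            false_alarms += flags.any()
        fwer = false_alarms / n_seeds
        mc_sd = np.sqrt(0.05 * 0.95 / n_seeds)
        assert fwer <= 0.05 + 2 * mc_sd

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            phenostats.detect_outliers(self.clean_plots(), "trait", alpha=1.5)


def test_compute_blues_multiple_traits(balanced_plots):
    plots, _, _ = balanced_plots
    plots = plots.copy()
    plots["second"] = plots["trait"] * 2 + 1
    out = phenostats.compute_blues(plots, ["trait", "second"])
    assert list(out.columns) == ["trait", "second"]
    np.testing.assert_allclose(out["second"], out["trait"] * 2 + 1, rtol=1e-8)
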