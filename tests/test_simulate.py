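import numpy as np
import pandas as pd
import pytest

from phenopred import simulate
from phenopred.errors import ConfigError, DesignError


def hudson_fst(p1, p2):
    """Textbook Hudson estimator from population allele frequencies
    (ratio of averages across loci)."""
    num = (p1 - p2) ** 2
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(np.mean(num) / np.mean(den))


class TestPopulation:
    def test_study_panel_sizes(self):
        cfg = simulate.SimConfig(
            population=simulate.PopulationConfig(n_markers=200), seed=1
        )
        gm, gmap, _ = simulate.simulate_population(cfg)
        assert gm.n_genotypes == 400
        counts = gmap["subgroup"].value_counts().to_dict()
        assert counts == simulate.STUDY_GROUP_SIZES
        assert gmap["major_group"].value_counts().to_dict() == {
            "LR": 200, "ED": 100, "EF": 100
        }

    def test_determinism_bit_identical(self):
        cfg = simulate.SimConfig(
            population=simulate.PopulationConfig(
                group_sizes={"A": 10, "B": 10}, n_markers=100
            ),
            seed=7,
        )
        a = simulate.simulate_population(cfg)[0]
        b = simulate.simulate_population(cfg)[0]
        np.testing.assert_array_equal(a.calls, b.calls)

    def test_fst_limit_no_structure(self):
        cfg = simulate.SimConfig(
            population=simulate.PopulationConfig(
                group_sizes={"A": 5, "B": 5}, n_markers=2000, fst=1e-4
            ),
            seed=3,
        )
        _, _, truth = simulate.simulate_population(cfg)
        dev = (truth.group_freqs.sub(truth.ancestral_freqs, axis=0)).abs()
        assert dev.to_numpy().max() < 0.05

    def test_fst_recovered_by_hudson_estimator(self):
        cfg = simulate.SimConfig(
            population=simulate.PopulationConfig(
                group_sizes={"A": 50, "B": 50}, n_markers=5000, fst=0.2
            ),
            seed=9,
        )
        _, _, truth = simulate.simulate_population(cfg)
        est = hudson_fst(
            truth.group_freqs["A"].to_numpy(),
            truth.group_freqs["B"].to_numpy(),
        )
        assert abs(est - 0.2) < 0.03

    def test_invalid_fst_rejected(self):
        with pytest.raises(ConfigError):
            simulate.PopulationConfig(fst=1.5)
        with pytest.raises(ConfigError):
            simulate.PopulationConfig(fst=0.0)


class TestTrait:
    def build(self, delta=0.0, effects=None, n_markers=500, n_qtl=50, seed=2):
        cfg = simulate.SimConfig(
            population=simulate.PopulationConfig(
                group_sizes={"A": 50, "B": 50}, n_markers=n_markers
            ),
            trait=simulate.TraitConfig(n_qtl=n_qtl, group_mean_shift=delta),
            seed=seed,
        )
        gm, gmap, truth = simulate.simulate_population(cfg)
        vals = simulate.simulate_trait(
            gm, gmap, truth, cfg.trait, cfg.seed, effects=effects
        )
        return vals, gmap, truth

    def test_zero_effects_zero_delta_gives_zero_values(self):
        vals, _, _ = self.build(effects=np.zeros(50))
        assert np.allclose(vals, 0.0)

    def test_large_delta_separates_group_means(self):
        vals, gmap, _ = self.build(delta=3.0)
        sub = gmap.set_index("genotype_id")["subgroup"]
        means = vals.groupby(sub).mean()
        within_sd = vals.groupby(sub).std(ddof=1).mean()
        assert means.max() - means.min() >= 3.0 * within_sd * 0.9

    def test_between_group_variance_matches_fst_prediction(self):
        # with delta=0 the only between-group variance comes from allele
        # frequency divergence; for fully inbred lines the per-locus group
        # mean is 2*p_g, so between/within = Var(2p_g)/E[4p_g(1-p_g)]
        # = F/(1-F) under Balding-Nichols (Monte-Carlo check)
        ratios = []
        for seed in range(40):
            vals, gmap, _ = self.build(seed=seed, n_markers=400)
            sub = gmap.set_index("genotype_id")["subgroup"]
            between = vals.groupby(sub).mean().var(ddof=1)
            within = vals.groupby(sub).var(ddof=1).mean()
            ratios.append(between / within)
        expected = 0.15 / (1 - 0.15)
        assert np.mean(ratios) == pytest.approx(expected, rel=0.5)


class TestPlots:
    def test_noise_free_plots_are_exact(self):
        g = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        vc = dict(sigma2_env=0.0, sigma2_gxe=0.0, sigma2_rep=0.0,
                  sigma2_block=0.0, sigma2_eps=0.0, mu=10.0)
        plots = simulate.simulate_plots(
            g, simulate.DesignConfig(n_env=1, n_rep=1, n_blocks=1), vc, seed=0
        )
        assert plots["trait"].tolist() == [11.0, 12.0, 13.0]

    def test_study_design_yields_2400_plots(self):
        g = pd.Series(np.zeros(400), index=[f"g{i}" for i in range(400)])
        vc = dict(sigma2_env=1, sigma2_gxe=1, sigma2_rep=1, sigma2_block=1,
                  sigma2_eps=1)
        plots = simulate.simulate_plots(
            g, simulate.DesignConfig(n_env=3, n_rep=2, n_blocks=20), vc, seed=0
        )
        assert len(plots) == 2400

    def test_invalid_design_rejected(self):
        with pytest.raises(DesignError):
            simulate.DesignConfig(n_env=0, n_rep=1)

    def test_negative_variance_rejected(self):
        g = pd.Series([1.0, 2.0], index=["a", "b"])
        vc = dict(sigma2_env=-1, sigma2_gxe=0, sigma2_rep=0, sigma2_block=0,
                  sigma2_eps=0)
        with pytest.raises(ConfigError):
            simulate.simulate_plots(
                g, simulate.DesignConfig(1, 1, 1), vc, seed=0
            )


class TestSpectra:
    def layout(self, ids):
        return pd.DataFrame(
            {"genotype": ids, "environment": "E1", "replicate": 1, "block": 1}
        )

    def test_zero_loadings_zero_noise_gives_baseline(self):
        cfg = simulate.SpectraConfig(
            grid=(1250, 1299), n_bands=3, band_height_scale=0.0,
            noise_sd=0.0, env_effect_sd=0.0,
        )
        latent = pd.DataFrame({"latent1": [1.0, -1.0]}, index=["a", "b"])
        out = simulate.simulate_spectra(latent, self.layout(["a", "b"]), cfg,
                                        seed=0)
        wl = [c for c in out.columns if isinstance(c, (int, np.integer))]
        vals = out[wl].to_numpy()
        np.testing.assert_allclose(vals[0], vals[1])

    def test_band_height_tracks_latent_exactly_without_noise(self):
        cfg = simulate.SpectraConfig(
            grid=(1250, 1299), n_bands=1, band_centers=(1275,),
            band_sigma=5.0, noise_sd=0.0, env_effect_sd=0.0,
        )
        latent = pd.DataFrame(
            {"latent1": np.linspace(-2, 2, 9)},
            index=[f"g{i}" for i in range(9)],
        )
        out = simulate.simulate_spectra(latent, self.layout(latent.index), cfg,
                                        seed=0)
        r = np.corrcoef(out[1275], latent["latent1"])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-12)

    def test_band_centers_outside_grid_rejected(self):
        cfg = simulate.SpectraConfig(grid=(1250, 1299), band_centers=(2000,))
        latent = pd.DataFrame({"latent1": [0.0]}, index=["a"])
        with pytest.raises(ConfigError):
            simulate.simulate_spectra(latent, self.layout(["a"]), cfg, seed=0)

    def test_repetitions_average_matches_emitted_repetitions(self):
        cfg = simulate.SpectraConfig(grid=(1250, 1269), n_bands=2,
                                     n_repetitions=4)
        latent = pd.DataFrame({"latent1": [0.5, -0.5]}, index=["a", "b"])
        reps = simulate.simulate_spectra(
            latent, self.layout(["a", "b"]), cfg, seed=3, emit_repetitions=True
        )
        assert len(reps) == 8 and "repetition" in reps.columns


def test_dataset_determinism(small_dataset):
    ds2 = simulate.simulate_dataset(small_dataset.config)
    np.testing.assert_array_equal(ds2.genotypes.calls,
                                  small_dataset.genotypes.calls)
    pd.testing.assert_frame_equal(ds2.plots, small_dataset.plots)
    pd.testing.assert_frame_equal(ds2.spectra, small_dataset.spectra)


def test_markers_carry_structure_but_spectra_do_not(small_dataset):
    """DAPC recovers the subpopulations from marker data but performs at
    chance on the raw spectra, whose variation is latent chemistry plus
    noise with no group component."""
    from phenopred import evaluate, markers

    ds = small_dataset
    sub = ds.group_map.set_index("genotype_id")["subgroup"]
    cleaned, _ = markers.qc_overall(ds.genotypes)
    dos = markers.impute_naive({"all": cleaned})["all"].to_frame()
    marker_dapc = evaluate.dapc(dos, sub.reindex(dos.index))
    assert marker_dapc.reassignment_rate >= 0.90

    wl = [c for c in ds.spectra.columns
          if isinstance(c, (int, np.integer))]
    spec = ds.spectra.groupby("genotype")[wl].mean()
    spec_dapc = evaluate.dapc(spec, sub.reindex(spec.index))
    chance = sub.value_counts(normalize=True).max()
    assert spec_dapc.reassignment_rate <= chance + 0.10


def test_realized_h2_near_target(small_dataset):
    assert small_dataset.truth.realized_h2() == pytest.approx(0.6, abs=0.1)
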