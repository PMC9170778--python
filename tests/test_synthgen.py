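"""Generator: mixture sampling, rendering physics, experiment structure."""

import numpy as np
import pandas as pd
import pytest

import siderocell as sc
from siderocell.synthgen import (
    GrowthModel,
    MixtureAnchor,
    cells_to_frame,
    mixture_linear_mean,
)


def flat_schedule(on_fraction, mu_off=2.0, mu_on=3.5, sigma_off=0.2, sigma_on=0.2):
    a = MixtureAnchor(on_fraction, mu_off, mu_on, sigma_off, sigma_on)
    return sc.GeneSchedule(anchors=((3.0, a), (24.0, a)))


class TestSamplePopulation:
    def test_degenerate_mixture_collapses_to_mu_off(self, double_reporter):
        pop = sc.PopulationParams(
            genes={"pvdA": flat_schedule(0.0, sigma_off=1e-12, sigma_on=1e-12),
                   "pchEF": flat_schedule(0.0, sigma_off=1e-12, sigma_on=1e-12)},
            beta={"pvdA": 0.0, "pchEF": 0.0},
            sigma_m=0.0, pyoverdine=None, n_cells_per_field=50,
        )
        cells = sc.sample_population(pop, 3.0, double_reporter, rng=0)
        vals = np.array([c.log_expr["mcherry"] for c in cells])
        assert np.allclose(vals, 2.0, atol=1e-9)

    def test_on_fraction_converges_to_configured_value(self, double_reporter):
        # binomial oracle: the empirical on-share of a p=0.16 mixture at
        # n=5000 lies within 3*sqrt(p(1-p)/n) of p
        p = 0.16
        pop = sc.PopulationParams(
            genes={"pvdA": flat_schedule(1.0), "pchEF": flat_schedule(p)},
            pyoverdine=None, n_cells_per_field=5000,
            length_range_px=(8.0, 10.0), width_range_px=(3.0, 4.0),
        )
        cells = sc.sample_population(pop, 3.0, double_reporter, rng=3,
                                     image_shape=(2048, 2048))
        share = np.mean([c.component["egfp"] == "on" for c in cells])
        assert abs(share - p) <= 3 * np.sqrt(p * (1 - p) / 5000)

    def test_same_seed_gives_identical_cell_tables(self, double_reporter):
        pop = sc.PopulationParams(n_cells_per_field=40)
        a = cells_to_frame(sc.sample_population(pop, 6.0, double_reporter, rng=9))
        b = cells_to_frame(sc.sample_population(pop, 6.0, double_reporter, rng=9))
        pd.testing.assert_frame_equal(a, b)

    def test_wildtype_gets_autofluorescence_only(self, wildtype):
        pop = sc.PopulationParams(n_cells_per_field=300, pyoverdine=None)
        cells = sc.sample_population(pop, 3.0, wildtype, rng=4)
        assert all(c.component["mcherry"] == "auto" for c in cells)
        vals = np.array([c.log_expr["egfp"] for c in cells])
        assert abs(vals.mean() - pop.autofluo_mu["egfp"]) < 5 * pop.autofluo_sd / np.sqrt(300)

    def test_unknown_time_rejected(self, double_reporter):
        pop = sc.PopulationParams()
        with pytest.raises(ValueError, match="time"):
            sc.sample_population(pop, 4.5, double_reporter, rng=0)

    def test_unknown_reporter_gene_rejected(self):
        pop = sc.PopulationParams()
        bad = sc.StrainSpec("bad", {"mcherry": "nonexistent"})
        with pytest.raises(ValueError, match="unknown gene"):
            sc.sample_population(pop, 3.0, bad, rng=0)

    def test_density_cap_raises(self, double_reporter):
        pop = sc.PopulationParams(n_cells_per_field=500)
        with pytest.raises(ValueError, match="density|image too small"):
            sc.sample_population(pop, 3.0, double_reporter, rng=0,
                                 image_shape=(128, 128))

    def test_geometry_invariant_length_exceeds_width(self, small_field):
        cells, _, _ = small_field
        assert all(c.length_px > c.width_px > 0 for c in cells)


class TestSharedFactor:
    def test_cross_gene_correlation_matches_closed_form(self, double_reporter):
        # unimodal scenario so the closed form applies exactly
        s1, s2, b1, b2, sm = 0.2, 0.25, 0.6, 0.9, 0.3
        pop = sc.PopulationParams(
            genes={"pchEF": flat_schedule(1.0, mu_on=3.0, sigma_on=s1),
                   "pvdA": flat_schedule(1.0, mu_on=3.0, sigma_on=s2)},
            beta={"pchEF": b1, "pvdA": b2}, sigma_m=sm, pyoverdine=None,
            n_cells_per_field=10_000,
            length_range_px=(8.0, 10.0), width_range_px=(3.0, 4.0),
        )
        cells = sc.sample_population(pop, 3.0, double_reporter, rng=17,
                                     image_shape=(3000, 3000))
        x = np.array([c.log_expr["egfp"] for c in cells])
        y = np.array([c.log_expr["mcherry"] for c in cells])
        r_emp = np.corrcoef(x, y)[0, 1]
        r_th = sc.shared_factor_correlation(b1, b2, sm, s1, s2)
        assert abs(r_emp - r_th) < 3 * (1 - r_th**2) / np.sqrt(10_000)

    def test_zero_loading_gives_independent_channels(self, double_reporter):
        pop = sc.PopulationParams(
            genes={"pchEF": flat_schedule(1.0), "pvdA": flat_schedule(1.0)},
            beta={"pchEF": 0.0, "pvdA": 0.0}, sigma_m=0.3, pyoverdine=None,
            n_cells_per_field=10_000,
            length_range_px=(8.0, 10.0), width_range_px=(3.0, 4.0),
        )
        cells = sc.sample_population(pop, 3.0, double_reporter, rng=21,
                                     image_shape=(3000, 3000))
        x = np.array([c.log_expr["egfp"] for c in cells])
        y = np.array([c.log_expr["mcherry"] for c in cells])
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.05


class TestRenderField:
    def test_empty_field_equals_vignette_plus_background(self, noiseless_optics):
        img = sc.render_field([], noiseless_optics, rng=0,
                              fluor_channels=["mcherry"])
        expected = noiseless_optics.vignette_field() + noiseless_optics.pad_background_mu
        np.testing.assert_allclose(img.channels["mcherry"], expected)

    def test_single_cell_flux_conservation(self, double_reporter):
        # analytic oracle: total background-subtracted flux equals
        # photon_scale * 10**expr (PSF mass ~1 away from borders)
        opt = sc.OpticsParams(image_shape_px=(128, 128), vignette_amplitude=0.0,
                              pad_background_sd=0.0, read_noise_sd=0.0)
        pop = sc.PopulationParams(n_cells_per_field=1, pyoverdine=None)
        cells = sc.sample_population(pop, 3.0, double_reporter, rng=5,
                                     image_shape=(128, 128), margin=40.0)
        img = sc.render_field(cells, opt, rng=0)
        for ch in ("mcherry", "egfp"):
            flux = (img.channels[ch] - opt.pad_background_mu).sum()
            expected = opt.photon_scale * 10 ** cells[0].log_expr[ch]
            assert abs(flux - expected) / expected < 1e-6

    def test_noise_has_zero_mean(self, double_reporter, noiseless_optics):
        from dataclasses import replace
        pop = sc.PopulationParams(n_cells_per_field=5)
        cells = sc.sample_population(pop, 3.0, double_reporter, rng=6,
                                     image_shape=(256, 256))
        noisy_opt = replace(noiseless_optics, read_noise_sd=3.0)
        clean = sc.render_field(cells, noiseless_optics, rng=8).channels["mcherry"]
        noisy = sc.render_field(cells, noisy_opt, rng=8).channels["mcherry"]
        diff = noisy - clean
        # mean of 256*256 N(0,3) draws
        assert abs(diff.mean()) < 5 * 3.0 / 256

    def test_out_of_bounds_cell_rejected(self, double_reporter, noiseless_optics):
        pop = sc.PopulationParams(n_cells_per_field=1)
        cells = sc.sample_population(pop, 3.0, double_reporter, rng=7,
                                     image_shape=(256, 256))
        cells[0].row = 1.0
        with pytest.raises(ValueError, match="bounds"):
            sc.render_field(cells, noiseless_optics, rng=0)

    def test_invalid_vignette_profile_rejected(self):
        opt = sc.OpticsParams(vignette_profile=(1.0, -5.0))
        with pytest.raises(ValueError, match="vignette"):
            opt.validate()


class TestGenerateExperiment:
    def test_structure_has_declared_counts(self, tmp_path, wildtype, double_reporter):
        cfg = sc.ExperimentConfig(
            conditions=("caa",), strains=(wildtype, double_reporter),
            repeats=1, n_cell_fields=2, n_blank_fields=4,
            population=sc.PopulationParams(n_cells_per_field=5,
                                           time_points_h=(3.0, 6.0)),
            optics=sc.OpticsParams(image_shape_px=(192, 192)),
            condition_mu_shift={}, seed=3,
        )
        exp = sc.generate_experiment(cfg)
        exp.write(tmp_path)
        d = tmp_path / "caa" / "3" / "double_reporter" / "r1"
        # 4 channels (phase + 3 fluorescence) per field
        assert len(list(d.glob("field*_*.tif"))) == 2 * 4
        assert len(list(d.glob("blank*_*.tif"))) == 4 * 4
        assert (tmp_path / "ground_truth.csv").exists()
        assert (tmp_path / "plate_reader.csv").exists()
        gt = pd.read_csv(tmp_path / "ground_truth.csv")
        assert len(gt) == 1 * 2 * 2 * 1 * 2 * 5  # cond*times*strains*reps*fields*cells

    def test_missing_wildtype_rejected(self, double_reporter):
        cfg = sc.ExperimentConfig(strains=(double_reporter,))
        with pytest.raises(ValueError, match="wildtype"):
            cfg.validate()

    def test_zero_growth_rate_gives_flat_od_at_inoculum(self):
        gm = GrowthModel(mu=0.0)
        t = np.linspace(0, 24, 97)
        np.testing.assert_allclose(gm.od(t), 1e-4)

    def test_seeding_contract_across_repeats(self, mini_experiment_config):
        from dataclasses import replace
        exp1 = sc.generate_experiment(mini_experiment_config)
        exp2 = sc.generate_experiment(mini_experiment_config)
        pd.testing.assert_frame_equal(exp1.ground_truth, exp2.ground_truth)
        # different seed -> different draws
        exp3 = sc.generate_experiment(replace(mini_experiment_config, seed=8))
        assert not exp1.ground_truth["expr_mcherry"].equals(exp3.ground_truth["expr_mcherry"])
        # the two repeats within one experiment differ
        gt = exp1.ground_truth
        m1 = gt[(gt.repeat == 1) & (gt.strain == "double_reporter")]["expr_mcherry"].mean()
        m2 = gt[(gt.repeat == 2) & (gt.strain == "double_reporter")]["expr_mcherry"].mean()
        assert m1 != m2

    def test_plate_rfu_tracks_density_times_expression(self, mini_experiment_config):
        exp = sc.generate_experiment(mini_experiment_config)
        pr = exp.plate_reader
        one = pr[(pr.strain == "double_reporter") & (pr.repeat == 1)]
        od = one[one.channel == "od600"].set_index("time_h")["value"]
        rfu = one[one.channel == "mcherry"].set_index("time_h")["value"]
        # late-time RFU/OD should be within noise of the closed-form mean
        cfg = mini_experiment_config
        anchor = cfg.population.genes["pvdA"].at(24.0)
        expected = cfg.rfu_scale * mixture_linear_mean(
            anchor, cfg.population.beta["pvdA"], cfg.population.sigma_m)
        ratio = rfu.loc[24.0] / od.loc[24.0]
        assert abs(ratio - expected) / expected < 0.1
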