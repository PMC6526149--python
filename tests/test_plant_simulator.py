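"""Virtual plant: reactor chemistry, spectral forward models, campaigns."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flownmr import plant_simulator as ps
from flownmr.nir_chemometrics import snv
from flownmr.steady_state import ConcentrationSeries, classify_steady


class TestReactor:
    def test_saturation_limit_converts_all_limiting_reactant(self):
        feeds = ps.default_feeds()
        feeds["LiHMDS"] = ps.FeedStream("LiHMDS", 500.0, 1.10)
        params = ps.PlantParams(smoothing=0.0)
        out = ps.reactor_steady_state(feeds, params)
        limiting = min(feeds["aniline"].molar_flow, feeds["oFNB"].molar_flow)
        assert out.molar_flows["LiNDPA"] > 0.995 * limiting

    def test_zero_aniline_gives_no_product(self):
        feeds = ps.default_feeds()
        feeds["aniline"] = ps.FeedStream("aniline", 0.0, 0.96)
        out = ps.reactor_steady_state(feeds)
        assert out.molar_flows["LiNDPA"] == 0.0
        assert out.molar_flows["Lianiline"] == 0.0

    def test_startup_point_against_hand_mole_balance(self):
        """Start-up feeds, k_sat 0.05, moisture sink 0.3 mol/h, hard
        min: the oracle recomputes the balance from first principles."""
        params = ps.PlantParams(k_sat=0.05, moisture_sink=0.3, smoothing=0.0)
        feeds = ps.default_feeds()
        out = ps.reactor_steady_state(feeds, params)
        # oracle: molar flows by hand
        n_an = 3.68 / 0.90 * 0.96
        n_fnb = 5.60 / 0.90 * 0.63
        n_li = 6.89 / 0.90 * 1.10 - 0.3
        limiting = min(n_an, n_fnb)
        excess = n_li / (2 * limiting)
        extent = min(limiting, n_li / 2) * excess / (excess + 0.05)
        lian = min(0.30 * (n_an - extent), n_li - 2 * extent)
        vol = (3.68 + 6.89 + 5.60) / 900.0
        assert np.isclose(out.concentrations["LiNDPA"], extent / vol)
        assert np.isclose(out.concentrations["aniline"],
                          (n_an - extent - lian) / vol)
        assert np.isclose(out.concentrations["LiHMDS"],
                          (n_li - 2 * extent - lian) / vol)

    def test_true_plant_equals_nominal_when_params_match(self):
        feeds = ps.default_feeds()
        p = ps.PlantParams()
        assert ps.true_plant(feeds, p).concentrations \
            == ps.reactor_steady_state(feeds, p).concentrations

    def test_mismatch_shifts_the_profit_optimum(self):
        """Under the default mismatch the profit-optimal feed set of
        plant and model differ (location and, grossly, value)."""
        from flownmr import rto_mawqa as rto
        model = rto.nominal_model()
        u_model, p_model = rto.grid_optimum(lambda u: model(u), n=41)
        u_plant, p_plant = rto.grid_optimum(rto.simulated_plant(), n=41)
        assert not np.allclose(u_model, u_plant)
        assert p_model > 1.5 * p_plant  # the model badly overpromises

    def test_zero_total_flow_rejected(self):
        feeds = {s: ps.FeedStream(s, 0.0, 1.0)
                 for s in ("aniline", "LiHMDS", "oFNB")}
        with pytest.raises(ValueError):
            ps.reactor_steady_state(feeds)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(u1=st.floats(0.1, 9.0), u2=st.floats(0.1, 9.0),
           u3=st.floats(0.1, 9.0))
    def test_mole_balances_conserved(self, u1, u2, u3):
        feeds = ps.default_feeds((u1, u2, u3))
        out = ps.true_plant(feeds)
        f = out.molar_flows
        aryl = f["aniline"] + f["Lianiline"] + f["LiNDPA"]
        fluoro = f["oFNB"] + f["LiNDPA"]
        assert abs(aryl - feeds["aniline"].molar_flow) \
            <= 1e-9 * max(feeds["aniline"].molar_flow, 1.0)
        assert abs(fluoro - feeds["oFNB"].molar_flow) \
            <= 1e-9 * max(feeds["oFNB"].molar_flow, 1.0)
        assert all(v >= -1e-12 for v in out.concentrations.values())

    def test_production_monotone_in_lihmds_feed(self):
        # molar production of Li-NDPA rises with LiHMDS feed; outlet
        # concentration eventually falls again because the extra feed
        # also dilutes the stream
        flows = []
        for u2 in np.linspace(3.0, 9.0, 25):
            feeds = ps.default_feeds((3.68, u2, 5.60))
            flows.append(ps.true_plant(feeds).molar_flows["LiNDPA"])
        assert all(b >= a - 1e-9 for a, b in zip(flows, flows[1:]))


class TestNMRSynthesis:
    def test_zero_concentrations_give_pure_noise(self, model_library, rng):
        spec = ps.synth_nmr_spectrum({}, model_library, noise_sd=0.01, rng=rng)
        assert np.abs(spec.intensity).max() < 0.06  # ~5 sigma

    def test_linearity_in_concentration(self, model_library):
        c = {"aniline": 0.3, "LiNDPA": 0.2}
        s1 = ps.synth_nmr_spectrum(c, model_library)
        s2 = ps.synth_nmr_spectrum({k: 2 * v for k, v in c.items()},
                                   model_library)
        np.testing.assert_allclose(s2.intensity, 2 * s1.intensity, atol=1e-10)

    def test_quantification_round_trip(self, model_library, nu_map):
        from flownmr import ihm
        conc = {"aniline": 0.4, "oFNB": 0.3, "LiNDPA": 0.5}
        spec = ps.synth_nmr_spectrum(conc, model_library)
        fit = ihm.fit_mixture(spec, model_library, n_starts=1)
        out = ihm.quantify(fit, ihm.CalibrationFactor(ps.XI_TRUE), nu_map)
        for k, v in conc.items():
            assert abs(out[k] - v) < 1e-3

    def test_fid_round_trip(self, model_library):
        from flownmr.nmr_processing import ProcessingParams, process_fid
        spec = ps.synth_nmr_spectrum({"oFNB": 0.5}, model_library)
        fid = ps.spectrum_to_fid(spec)
        back = process_fid(fid, ProcessingParams(zero_fill_to=fid.n_points,
                                                 line_broadening=0.0,
                                                 carrier_ppm=5.5))
        # FFT round trip reproduces the spectrum up to grid convention
        np.testing.assert_allclose(np.sort(back.intensity)[-5:],
                                   np.sort(spec.intensity)[-5:], rtol=1e-6)


class TestNIRSynthesis:
    def test_zero_concentration_is_solvent_baseline(self):
        spec = ps.synth_nir_spectrum({}, noise_sd=0.0, scatter=False)
        again = ps.synth_nir_spectrum({"LiNDPA": 0.0}, noise_sd=0.0,
                                      scatter=False)
        np.testing.assert_allclose(spec.intensity, again.intensity)
        assert spec.intensity.max() > 0  # solvent bands present

    def test_snv_removes_multiplicative_gain(self, model_library):
        base = ps.synth_nir_spectrum({"LiNDPA": 0.4}, noise_sd=0.0,
                                     scatter=False)
        gained = base.copy(intensity=1.3 * base.intensity)
        np.testing.assert_allclose(snv(gained.intensity),
                                   snv(base.intensity), atol=1e-9)

    def test_band_heights_linear_in_concentration(self):
        s1 = ps.synth_nir_spectrum({"LiNDPA": 0.2}, noise_sd=0.0, scatter=False)
        s2 = ps.synth_nir_spectrum({"LiNDPA": 0.4}, noise_sd=0.0, scatter=False)
        d1 = s1.intensity - ps.synth_nir_spectrum({}, noise_sd=0.0,
                                                  scatter=False).intensity
        d2 = s2.intensity - ps.synth_nir_spectrum({}, noise_sd=0.0,
                                                  scatter=False).intensity
        np.testing.assert_allclose(d2, 2 * d1, atol=1e-12)

    def test_edge_regions_are_noise_amplified(self, rng):
        spec = ps.synth_nir_spectrum({}, noise_sd=0.002, scatter=False,
                                     rng=rng)
        clean = ps.synth_nir_spectrum({}, noise_sd=0.0, scatter=False)
        resid = spec.intensity - clean.intensity
        hi = np.abs(resid[spec.axis >= 8975.0]).std()
        mid = np.abs(resid[(spec.axis > 4611.0) & (spec.axis < 8957.0)]).std()
        assert hi > 5.0 * mid

    def test_grid_is_2074_points(self):
        spec = ps.synth_nir_spectrum({})
        assert len(spec) == 2074
        assert spec.axis[0] == 4000.0 and spec.axis[-1] == 12000.0


class TestCampaign:
    def test_same_seed_reproduces_bundle(self):
        sched = [(0.0, {"aniline": 3.68, "LiHMDS": 6.89, "oFNB": 5.60})]
        b1 = ps.run_campaign(sched, seed=11, duration=900.0)
        b2 = ps.run_campaign(sched, seed=11, duration=900.0)
        assert b1.ground_truth.equals(b2.ground_truth)
        np.testing.assert_array_equal(b1.nmr_spectra[5].intensity,
                                      b2.nmr_spectra[5].intensity)
        np.testing.assert_array_equal(b1.nir_spectra[2].intensity,
                                      b2.nir_spectra[2].intensity)

    def test_constant_setpoints_reach_steady_state(self):
        sched = [(0.0, {"aniline": 3.68, "LiHMDS": 6.89, "oFNB": 5.60})]
        b = ps.run_campaign(sched, seed=1, duration=1200.0)
        gt = b.ground_truth
        series = ConcentrationSeries(
            gt["timestamp"].to_numpy(), gt[["aniline", "oFNB", "LiNDPA"]])
        flags = classify_steady(series)
        # ground truth is noiseless: everything past spin-up is steady
        assert flags[10:-5].all()

    def test_step_change_is_flagged_transient(self):
        sched = [(0.0, {"aniline": 3.68, "LiHMDS": 6.89, "oFNB": 5.60}),
                 (900.0, {"aniline": 2.5, "LiHMDS": 6.89, "oFNB": 5.60})]
        b = ps.run_campaign(sched, seed=1, duration=1800.0)
        gt = b.ground_truth
        series = ConcentrationSeries(
            gt["timestamp"].to_numpy(), gt[["aniline", "oFNB", "LiNDPA"]])
        flags = classify_steady(series)
        i_step = int(np.argmin(np.abs(gt["timestamp"].to_numpy() - 930.0)))
        assert not flags[i_step]
        assert flags[-10]  # re-settled by the end

    def test_sensor_delay_offset_between_streams(self):
        sched = [(0.0, {"aniline": 3.68, "LiHMDS": 6.89, "oFNB": 5.60}),
                 (800.0, {"aniline": 2.0, "LiHMDS": 6.89, "oFNB": 5.60})]
        b = ps.run_campaign(sched, seed=1, duration=1600.0)
        p = ps.TRUE_PLANT_PARAMS
        assert p.delay_nir - p.delay_nmr == 120.0
        # NIR ground truth at time t equals NMR ground truth at t-120
        t_nir = b.nir_times[-1]
        row_nir = b.nir_truth[b.nir_truth["timestamp"] == t_nir]
        i = int(np.argmin(np.abs(b.nmr_times - (t_nir - 120.0))))
        row_nmr = b.ground_truth.iloc[i]
        assert abs(row_nir["aniline"].iloc[0] - row_nmr["aniline"]) < 1e-9

    def test_bundle_save_layout(self, tmp_path):
        sched = [(0.0, {"aniline": 3.68, "LiHMDS": 6.89, "oFNB": 5.60})]
        b = ps.run_campaign(sched, seed=1, duration=400.0)
        b.save(tmp_path / "run")
        assert (tmp_path / "run" / "ground_truth.csv").exists()
        assert (tmp_path / "run" / "manifest.json").exists()
        assert len(list((tmp_path / "run" / "nmr").glob("*.csv"))) \
            == len(b.nmr_spectra)

    def test_end_to_end_steady_fraction_in_final_hold_minutes(
            self, model_library):
        """Quantified (noisy) series: at least 80% of the last 5 min of
        a constant hold classify steady under default noise."""
        from flownmr import ihm, pipeline
        sched = [(0.0, {"aniline": 3.68, "LiHMDS": 6.89, "oFNB": 5.60})]
        b = ps.run_campaign(sched, seed=5, duration=900.0)
        series = pipeline.quantify_campaign(
            b, model_library, ihm.CalibrationFactor(ps.XI_TRUE))
        flags = classify_steady(series)
        last5 = flags[(series.timestamps > 600.0 - 1)
                      & (series.timestamps <= 900.0 - 5 * 15.0)]
        assert last5.mean() >= 0.8
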