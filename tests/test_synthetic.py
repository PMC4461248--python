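"""Forward simulator: conservation, closure, binning, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

import pmrflux as pm
from pmrflux.quantify import bin_durations, bin_midpoints
from pmrflux.synthetic_data import SimParams, simulate_bout, simulate_group
from tests.conftest import NOISELESS, stim_integral


class TestGroundTruthInvariants:
    def test_atp_balance_exact_at_every_step(self, deep_bout):
        f = deep_bout.fine
        np.testing.assert_allclose(f["d"] + f["q"] + f["l"], f["u"], atol=1e-12)

    def test_ledger_closure_exact_at_every_step(self, deep_bout):
        f = deep_bout.fine
        np.testing.assert_allclose(
            f["h_gly"], f["h_ck"] + f["h_beta"] + f["h_efflux"] - f["h_ox"],
            atol=1e-12)

    def test_fine_grid_physics_matches_module_formulas(self, deep_bout):
        # the hot loop inlines the CK equilibrium, hyperbola and buffer
        # formulas; spot-check rows against the public functions
        f = deep_bout.fine.iloc[::97]
        p = deep_bout.params
        np.testing.assert_allclose(
            f["adp"], pm.adp_from_ck(f["pcr"].to_numpy(), p.atp_rest,
                                     f["ph"].to_numpy(), p.ck), rtol=1e-12)
        np.testing.assert_allclose(
            f["q"], pm.ox_flux(f["adp"].to_numpy(), pm.OxParams(p.qmax, p.km)),
            rtol=1e-12)
        np.testing.assert_allclose(
            f["h_ck"], pm.phi_stoich(f["ph"].to_numpy()) * f["d"], rtol=1e-9)
        np.testing.assert_allclose(
            f["h_ox"], pm.m_stoich(f["ph"].to_numpy()) * f["q"], rtol=1e-9)

    def test_basal_demand_is_resting_fixed_point(self):
        p = SimParams(noise_sd=dict(NOISELESS))
        flat = simulate_bout(SimParams(u_start=p.u_basal, u_ss=p.u_basal,
                                       g_early=0.0, g_late=0.0,
                                       noise_sd=dict(NOISELESS)))
        assert np.abs(flat.fine["pcr"] - p.pcr_rest).max() < 1e-9
        assert np.abs(flat.fine["ph"] - p.ph_rest).max() < 1e-9

    def test_pcr_stays_positive_and_monotone_decline_during_stim(self, deep_bout):
        stim = deep_bout.fine[deep_bout.fine["phase"] == "stim"]
        assert (stim["pcr"] > 0).all()
        assert (np.diff(stim["pcr"]) <= 1e-9).all()

    def test_infeasible_demand_warns_and_floors_pcr(self):
        with pytest.warns(RuntimeWarning):
            sim = simulate_bout(SimParams(u_start=400.0, u_ss=300.0,
                                          noise_sd=dict(NOISELESS)))
        assert (sim.fine["pcr"] >= 0).all()


class TestBinningAndNoise:
    def test_binned_series_is_within_bin_mean(self, deep_bout, protocol):
        f = deep_bout.fine
        edges = np.concatenate([[0.0], np.cumsum(bin_durations(protocol))])
        idx = np.searchsorted(edges, f["t_s"].to_numpy(), side="right") - 1
        for col in ("pcr", "pi", "ph"):
            means = f.groupby(idx)[col].mean().to_numpy()
            np.testing.assert_allclose(deep_bout.series[col], means, rtol=1e-12)

    def test_bin_midpoints_on_protocol_clock(self, deep_bout, protocol):
        np.testing.assert_allclose(deep_bout.series["t_s"],
                                   bin_midpoints(protocol))

    def test_same_seed_is_bit_identical(self):
        a = simulate_bout(SimParams(seed=11))
        b = simulate_bout(SimParams(seed=11))
        pd.testing.assert_frame_equal(a.series, b.series)
        np.testing.assert_array_equal(a.force.force, b.force.force)
        assert a.tti == b.tti

    def test_different_seeds_differ(self):
        a = simulate_bout(SimParams(seed=1))
        b = simulate_bout(SimParams(seed=2))
        assert not a.series["pcr"].equals(b.series["pcr"])

    def test_step_halving_changes_binned_output_by_under_point1_percent(self):
        coarse = simulate_bout(SimParams(dt_s=1.0, noise_sd=dict(NOISELESS)))
        fine = simulate_bout(SimParams(dt_s=0.5, noise_sd=dict(NOISELESS)))
        for col in ("pcr", "ph"):
            rel = np.abs(fine.series[col].to_numpy()
                         - coarse.series[col].to_numpy())
            scale = np.abs(fine.series[col].to_numpy()).max()
            assert (rel / scale).max() < 1e-3

    def test_noise_sd_scales_residuals(self):
        p = SimParams(noise_sd={"pcr": 1.0, "pi": 0.0, "atp": 0.0, "ph": 0.0})
        clean = simulate_bout(SimParams(noise_sd=dict(NOISELESS)))
        resid = []
        for seed in range(25):
            noisy = simulate_bout(SimParams(seed=seed, noise_sd=p.noise_sd))
            resid.extend(noisy.series["pcr"] - clean.series["pcr"])
        assert np.std(resid) == pytest.approx(1.0, rel=0.25)


class TestSelfConsistency:
    def test_recovery_fit_matches_fine_grid_rate_within_2pct(self, mild_bout):
        # ground-truth recovery rate: the same mono-exponential model
        # estimated on the dense noise-free trajectory; the binned fit may
        # differ only through time-discretisation
        from lmfit import Model

        rec = mild_bout.fine[mild_bout.fine["phase"] == "recovery"]
        t_min = (rec["t_s"].to_numpy() - 1440.0 + 960.0) / 60.0
        t_min = t_min - t_min[0]

        def f(t, rest, cons, k):
            return rest - cons * np.exp(-k * t)

        model = Model(f)
        pars = model.make_params(rest=32.0, cons=10.0, k={"value": 1.0, "min": 1e-6})
        dense = model.fit(rec["pcr"].to_numpy(), pars, t=t_min)
        fit = pm.fit_recovery(mild_bout.series)
        assert fit.k_rec == pytest.approx(dense.params["k"].value, rel=0.02)

    def test_monte_carlo_qmax_recovery(self, protocol_10s):
        # 20 noisy bouts (1 umol/g PCr noise, 10 s bins so the resynthesis
        # decay is resolved): the recovery-based capacity estimate must
        # average within 10% of the generating Qmax
        ests = []
        for seed in range(20):
            sim = simulate_bout(SimParams.validation(seed=seed), protocol_10s)
            rec = pm.fit_recovery(sim.series)
            adp_end = pm.adp_end_of_stim(sim.series)
            ests.append(pm.compute_qmax(rec.vpcr_rec, adp_end, 50.0))
        assert np.mean(ests) == pytest.approx(26.0, rel=0.10)


class TestSimulateGroup:
    def test_deterministic_under_seed(self):
        a = simulate_group(SimParams(), SimParams(), 2, 2, seed=3)
        b = simulate_group(SimParams(), SimParams(), 2, 2, seed=3)
        for (la, ia, sa), (lb, ib, sb) in zip(a, b):
            assert (la, ia) == (lb, ib)
            pd.testing.assert_frame_equal(sa.series, sb.series)

    def test_jitter_spreads_parameters_with_stated_cv(self):
        subs = simulate_group(SimParams(), SimParams(), 30, 2, seed=0, cv=0.10)
        qmaxes = [s.params.qmax for l, i, s in subs if l == "A"]
        assert np.std(qmaxes) / np.mean(qmaxes) == pytest.approx(0.10, abs=0.04)
        assert np.mean(qmaxes) == pytest.approx(26.0, rel=0.06)

    def test_minimum_group_size_enforced(self):
        with pytest.raises(ValueError):
            simulate_group(SimParams(), SimParams(), 1, 4, seed=0)

    def test_capacity_deficit_detected_downstream(self, protocol_10s):
        # scaled-down power check: a 30% Qmax deficit in group B should be
        # flagged by the t-test on per-subject estimates in >= 80% of
        # replicates (8 vs 10 subjects, 10% between-subject CV, 10 s bins)
        from pmrflux.stats_report import ttest_unpaired

        a_params = SimParams.validation()
        b_params = SimParams.validation(qmax=0.7 * 26.0)
        hits = 0
        n_rep = 25
        for rep in range(n_rep):
            subs = simulate_group(a_params, b_params, 8, 10, seed=rep,
                                  protocol=protocol_10s)
            est = {"A": [], "B": []}
            for label, _, sim in subs:
                rec = pm.fit_recovery(sim.series)
                adp_end = pm.adp_end_of_stim(sim.series)
                est[label].append(pm.compute_qmax(rec.vpcr_rec, adp_end, 50.0))
            if ttest_unpaired(est["A"], est["B"]).significant:
                hits += 1
        assert hits >= 0.8 * n_rep
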