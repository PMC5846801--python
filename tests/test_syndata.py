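"""Generator correctness: closed-form limits, independent oracles,
reproducibility and round-trip identities."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from chaperonekit import binding, saxs, syndata


class TestExchangeModel:
    def test_effective_rate_is_intrinsic_over_pf(self):
        m = syndata.ExchangeModel(residue_index=500, k_int=2.0, PF=40.0)
        assert m.k_ex == pytest.approx(0.05)

    def test_saturation_reaches_buffer_deuterium_fraction(self):
        m = syndata.ExchangeModel(residue_index=1, k_int=1.0, PF=3.0, f_D2O=0.754)
        assert m.deuterium_fraction(1e9) == pytest.approx(0.754)

    def test_half_life_gives_half_plateau(self):
        m = syndata.ExchangeModel(residue_index=1, k_int=1.0, PF=10.0)
        t_half = np.log(2) / m.k_ex
        assert m.deuterium_fraction(t_half) == pytest.approx(m.f_D2O / 2)

    @pytest.mark.parametrize("kwargs", [dict(k_int=0.0), dict(PF=0.5), dict(f_D2O=0.0)])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            syndata.ExchangeModel(residue_index=1, **kwargs)


class TestSimulateHdxPair:
    def test_saturation_plateau_is_100_percent(self):
        profiles = {r: (5.0, 5.0) for r in range(455, 470)}
        free, _ = syndata.simulate_hdx_pair(
            profiles, [(455, 464, "A" * 10)], timepoints=(1e7,), replicates=1,
            noise_sd=0.0)
        assert free["deuteration_pct"].iloc[0] == pytest.approx(100.0)

    def test_uniform_peptide_matches_direct_summation_oracle(self):
        # 20-residue peptide, prolines at positions 5 and 12 (after the
        # first residue), uniform PF: package value vs direct evaluation.
        seq = list("ACDEFGHIKLMNQRSTVWYA")
        seq[4] = "P"
        seq[11] = "P"
        seq = "".join(seq)
        pf = 80.0
        profiles = {r: (pf, pf) for r in range(500, 520)}
        t = 30.0
        free, _ = syndata.simulate_hdx_pair(
            profiles, [(500, 519, seq)], timepoints=(t,), replicates=1, noise_sd=0.0)
        # oracle: iterate residues explicitly
        vals = []
        for i, aa in enumerate(seq):
            if i == 0 or aa == "P":
                continue
            vals.append(1.0 - np.exp(-(1.0 / pf) * t))
        expected = 100.0 * np.mean(vals)
        assert free["deuteration_pct"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_uptake_monotone_in_time_noiseless(self, truth, peptide_map):
        free, bound = syndata.simulate_hdx_pair(
            truth.hdx, peptide_map, replicates=1, noise_sd=0.0)
        for df in (free, bound):
            for _, g in df.groupby("peptide_id"):
                d = g.sort_values("timepoint_s")["deuteration_pct"].to_numpy()
                assert np.all(np.diff(d) >= -1e-9)

    def test_seed_reproducibility(self, truth, peptide_map):
        a = syndata.simulate_hdx_pair(truth.hdx, peptide_map, seed=7)
        b = syndata.simulate_hdx_pair(truth.hdx, peptide_map, seed=7)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_empty_map_and_unexchangeable_peptide(self):
        profiles = {r: (5.0, 5.0) for r in range(455, 470)}
        with pytest.raises(ValueError):
            syndata.simulate_hdx_pair(profiles, [])
        with pytest.warns(UserWarning, match="no exchangeable"):
            free, _ = syndata.simulate_hdx_pair(
                profiles, [(455, 456, "AP"), (457, 466, "A" * 10)])
        assert free["peptide_id"].nunique() == 1


class TestSimulateItc:
    def test_stoichiometric_limit_is_step_function(self):
        # Kd -> 0: constant molar heat until the equivalence point, then ~0.
        tg = syndata.simulate_itc((1.0, 1e-12, -10.0))
        per_mol = tg.heats_ucal / (tg.syringe_conc * tg.injection_volumes_ul * 1e-6 * 1e9)
        ratios = tg.molar_ratios
        pre = per_mol[(ratios < 0.9)]
        post = per_mol[(ratios > 1.15)]
        assert np.allclose(pre, -10.0, rtol=5e-3)
        assert np.all(np.abs(post) < 0.05)

    def test_zero_enthalpy_gives_noise_only(self):
        tg = syndata.simulate_itc((1.0, 1.8e-6, 0.0), noise_sd_ucal=0.5, seed=1)
        assert np.all(np.abs(tg.heats_ucal) < 3.0)

    def test_paper_geometry_matches_equilibrium_solver_oracle(self):
        """Quadratic-root bookkeeping vs brute-force mass-balance solution."""
        n, kd, dh = 1.0, 1.8e-6, -9.2
        tg = syndata.simulate_itc((n, kd, dh))
        v0 = tg.cell_volume_ml * 1e-3
        inj = tg.injection_volumes_ul * 1e-6
        dv = np.cumsum(inj)
        mt = tg.cell_conc * (1 - dv / (2 * v0)) / (1 + dv / (2 * v0))
        xt = tg.syringe_conc * (dv / v0) * (1 - dv / (2 * v0))
        bound = []
        for M, X in zip(n * mt, xt):
            free = brentq(lambda x: x + M * x / (kd + x) - X, 0.0, X + 1e-12)
            bound.append(M * free / (kd + free))
        q = np.asarray(bound) * dh * v0 * 1e9
        q_prev = np.concatenate([[0.0], q[:-1]])
        dq = q + (inj / v0) * (q + q_prev) / 2 - q_prev
        assert np.max(np.abs((tg.heats_ucal - dq) / dq)) < 1e-3

    def test_overfilled_cell_rejected(self):
        with pytest.raises(ValueError, match="exceeds cell volume"):
            syndata.simulate_itc(injection_volumes_ul=(500.0,) * 4)


class TestSimulateMelt:
    def test_noiseless_inflection_equals_tm(self):
        mc = syndata.simulate_melt_curve((55.0, 2.0, 0.0, 0.0))
        res = binding.tm_estimate(mc)
        assert res.Tm == pytest.approx(55.0, abs=0.5)

    def test_flat_curve_refused_downstream(self):
        mc = syndata.simulate_melt_curve((55.0, 2.0, 0.0, 0.0), amplitude=0.0)
        with pytest.raises(ValueError, match="no transition|dynamic range"):
            binding.tm_estimate(mc)

    def test_derivative_estimate_unbiased_over_seeds(self):
        tms = [
            binding.tm_estimate(
                syndata.simulate_melt_curve((55.0, 2.0, 0.0, 0.0), noise_sd=0.01,
                                            seed=s)).Tm
            for s in range(100)
        ]
        assert abs(np.mean(tms) - 55.0) < 0.2

    def test_malformed_grid_rejected(self):
        with pytest.raises(ValueError):
            syndata.simulate_melt_curve(T_grid=np.array([10.0, 9.0, 8.0]))


class TestSimulateSaxs:
    def test_forward_scattering_limit(self):
        s = np.concatenate([[1e-9], np.arange(0.025, 1.0, 0.01)])
        c = syndata.simulate_saxs("sphere", (3.0,), I0=2.5, s_grid=s)[0]
        assert c.I[0] == pytest.approx(2.5, rel=1e-9)

    def test_sphere_guinier_radius_closed_form(self):
        c = syndata.simulate_saxs("sphere", (3.0,), 1.0)[0]
        rg = saxs.guinier_fit(c).Rg
        assert rg == pytest.approx(np.sqrt(3.0 / 5.0) * 3.0, rel=0.01)

    def test_sphere_pr_support_ends_at_diameter(self):
        c = syndata.simulate_saxs("sphere", (3.0,), 1.0)[0]
        pr = saxs.ift_pr(c, 12.0, reg_weight=1e-4)
        beyond = pr.pr[pr.r > 6.5]
        assert np.max(np.abs(beyond)) < 0.05 * np.max(pr.pr)

    def test_descending_grid_rejected(self):
        with pytest.raises(ValueError):
            syndata.simulate_saxs(s_grid=np.array([0.5, 0.4, 0.3]))


class TestSecSaxsFrames:
    def test_identity_mixing_returns_components(self):
        comps = syndata.simulate_saxs("sphere", (3.0,), 1.0)
        comps += syndata.simulate_saxs("sphere", (2.0,), 0.5)
        frames, _ = syndata.simulate_secsaxs_frames(comps, np.eye(2))
        assert np.allclose(frames[0], comps[0].I)
        assert np.allclose(frames[1], comps[1].I)

    def test_negative_mixing_rejected(self):
        comps = syndata.simulate_saxs("sphere", (3.0,), 1.0)
        with pytest.raises(ValueError):
            syndata.simulate_secsaxs_frames(comps, -np.ones((3, 1)))


class TestTitrationPeaklists:
    def test_ratio_zero_is_identity(self, truth, sequence):
        base = syndata.make_base_peaklist(sequence, sharp_residues=truth.sharp_residues)
        out = syndata.simulate_titration_peaklists(base, truth, ratios=(0.0,))[0]
        pd.testing.assert_frame_equal(out, base)

    @pytest.mark.parametrize("ratio,expected", [(0.25, 0.75), (0.5, 0.50)])
    def test_stoichiometric_residual_intensity(self, sequence, ratio, expected):
        """Sub-stoichiometric co-chaperone leaves ~75 %/50 % of the free-state
        peak intensity for unbroadened residues."""
        t = syndata.GroundTruth()  # no broadening, no CSPs
        base = syndata.make_base_peaklist(sequence)
        out = syndata.simulate_titration_peaklists(base, t, ratios=(ratio,))[0]
        frac = (out["height"] / base["height"]).to_numpy()
        assert np.allclose(frac, frac[0])
        assert frac[0] == pytest.approx(expected, abs=0.02)

    def test_broadening_zero_erases_peaks(self, sequence):
        t = syndata.GroundTruth(broadening={r: 0.0 for r in range(495, 516)})
        base = syndata.make_base_peaklist(sequence)
        out = syndata.simulate_titration_peaklists(base, t, ratios=(0.5,))[0]
        res = out["assignment"].str.extract(r"(\d+)$")[0].astype(int)
        assert np.all(out.loc[res.between(495, 515), "height"] == 0.0)
        assert np.all(out.loc[~res.between(495, 515), "height"] > 0.0)

    def test_sharp_peaks_intensify_monotonically(self, truth, sequence):
        base = syndata.make_base_peaklist(sequence, sharp_residues=truth.sharp_residues)
        lists = syndata.simulate_titration_peaklists(base, truth,
                                                     ratios=(0.0, 0.25, 0.5))
        res = base["assignment"].str.extract(r"(\d+)$")[0].astype(int)
        mask = res.isin(truth.sharp_residues)
        h = np.stack([pl.loc[mask, "height"].to_numpy() for pl in lists])
        assert np.all(np.diff(h, axis=0) > 0)


class TestLaneTable:
    def test_equal_fractions_give_fifty_percent(self):
        lanes = syndata.simulate_lane_table({"complex": 0.5, "free": 0.5})
        assert binding.complex_occupancy(lanes) == pytest.approx(50.0)

    def test_exposure_invariance_and_round_trip(self):
        a = syndata.simulate_lane_table({"complex": 0.145, "free": 0.855},
                                        exposure_scale=1.0)
        b = syndata.simulate_lane_table({"complex": 0.145, "free": 0.855},
                                        exposure_scale=2.0)
        assert binding.complex_occupancy(a) == pytest.approx(14.5)
        assert binding.complex_occupancy(b) == pytest.approx(14.5)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            syndata.simulate_lane_table({"complex": 0.6, "free": 0.6})
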