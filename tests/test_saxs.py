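"""Primary SAXS analysis: Guinier, IFT/P(r), Dmax, Porod, molecular
mass, dilution-series extrapolation, NMF extraction and restraints."""

import numpy as np
import pytest

from chaperonekit import saxs, syndata

RG_SPHERE3 = np.sqrt(3.0 / 5.0) * 3.0  # ~2.3238 nm


@pytest.fixture(scope="module")
def sphere3():
    return syndata.simulate_saxs("sphere", (3.0,), 1.0)[0]


class TestGuinier:
    def test_exact_on_pure_gaussian(self):
        s = np.arange(0.025, 1.0, 0.005)
        I = 5.0 * np.exp(-(s * 2.0) ** 2 / 3.0)
        g = saxs.guinier_fit(saxs.SAXSCurve(s, I, np.full_like(s, 1e-3)))
        assert g.Rg == pytest.approx(2.0, abs=1e-6)
        assert g.I0 == pytest.approx(5.0, rel=1e-6)

    def test_sphere_radius_within_one_percent(self, sphere3):
        g = saxs.guinier_fit(sphere3)
        assert g.Rg == pytest.approx(RG_SPHERE3, rel=0.01)
        assert g.window[1] * g.Rg <= 1.3 * 1.001

    def test_noisy_rg_scatter_below_two_percent(self):
        rgs = []
        for seed in range(50):
            c = syndata.simulate_saxs("sphere", (3.0,), 1.0, noise_scale=0.01,
                                      seed=seed)[0]
            rgs.append(saxs.guinier_fit(c).Rg)
        assert np.std(rgs) / np.mean(rgs) < 0.02

    def test_aggregation_upturn_rejected(self):
        s = np.arange(0.025, 1.0, 0.005)
        I = np.exp(+(s * 2.0) ** 2 / 3.0)
        with pytest.raises(ValueError, match="aggregation|slope"):
            saxs.guinier_fit(saxs.SAXSCurve(s, I, np.full_like(s, 1e-3)))


class TestIftPr:
    def test_sphere_pr_matches_analytic_shape(self, sphere3):
        res = saxs.ift_pr(sphere3, 6.0)
        oracle = saxs.sphere_pr(res.r, 3.0)
        a = res.pr / np.max(res.pr)
        b = oracle / np.max(oracle)
        assert np.max(np.abs(a - b)) < 0.05
        assert res.Rg_real == pytest.approx(RG_SPHERE3, rel=0.02)

    def test_real_space_consistency_with_guinier(self, sphere3):
        g = saxs.guinier_fit(sphere3)
        res = saxs.ift_pr(sphere3, 6.0)
        assert res.Rg_real == pytest.approx(g.Rg, rel=0.03)
        # conservation: I0 from P(r) moments equals forward scattering
        assert res.I0_real == pytest.approx(g.I0, rel=0.01)

    def test_endpoints_and_near_nonnegativity(self, sphere3):
        res = saxs.ift_pr(sphere3, 6.0)
        assert res.pr[0] == 0.0 and res.pr[-1] == 0.0
        assert res.pr.min() > -0.02 * res.pr.max()

    def test_oversized_dmax_leaves_tail_empty(self, sphere3):
        res = saxs.ift_pr(sphere3, 12.0, reg_weight=1e-4)
        tail = res.pr[res.r > 6.5]
        assert np.max(np.abs(tail)) < 0.05 * res.pr.max()

    def test_undersized_dmax_flags_poor_fit(self):
        c = syndata.simulate_saxs("sphere", (3.0,), 1.0, noise_scale=0.005, seed=0)[0]
        good = saxs.ift_pr(c, 6.0)
        bad = saxs.ift_pr(c, 3.0)
        assert bad.chi2 > 10 * good.chi2
        assert bad.poor_fit

    def test_requires_sigma(self, sphere3):
        naked = saxs.SAXSCurve(sphere3.s, sphere3.I)
        with pytest.raises(ValueError, match="sigma"):
            saxs.ift_pr(naked, 6.0)


class TestEstimateDmax:
    def test_sphere_diameter_recovered(self, sphere3):
        dmax, _ = saxs.estimate_dmax(sphere3, np.arange(4.0, 9.01, 0.25))
        assert dmax == pytest.approx(6.0, abs=0.25)

    def test_dumbbell_geometry_oracle(self):
        c = syndata.simulate_saxs("two_sphere", (2.0, 2.0, 8.0), 1.0)[0]
        dmax, _ = saxs.estimate_dmax(c, np.arange(8.0, 16.01, 0.5))
        assert dmax == pytest.approx(12.0, abs=0.5)

    def test_candidates_below_true_support_score_worse(self, sphere3):
        grid = np.arange(3.0, 9.01, 0.5)
        _, scores = saxs.estimate_dmax(sphere3, grid)
        below = scores[grid < 5.5]
        at = scores[np.isclose(grid, 6.0)][0]
        assert np.all(below > at)


class TestPorod:
    def test_sphere_volume_within_ten_percent(self, sphere3):
        g = saxs.guinier_fit(sphere3)
        res = saxs.porod_volume(sphere3, g.I0, g.Rg)
        assert res.V_porod == pytest.approx(4 / 3 * np.pi * 27.0, rel=0.10)

    def test_intensity_rescaling_leaves_volume_unchanged(self, sphere3):
        g = saxs.guinier_fit(sphere3)
        v1 = saxs.porod_volume(sphere3, g.I0, g.Rg).V_porod
        scaled = saxs.SAXSCurve(sphere3.s, 7.0 * sphere3.I, 7.0 * sphere3.sigma)
        v2 = saxs.porod_volume(scaled, 7.0 * g.I0, g.Rg).V_porod
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_truncation_inflates_volume_without_tail(self, sphere3):
        g = saxs.guinier_fit(sphere3)
        vols = []
        for s_max in (4.0, 2.0, 1.0):
            c = sphere3.crop(s_max=s_max)
            vols.append(saxs.porod_volume(c, g.I0, g.Rg,
                                          tail_correction=False).V_porod)
        assert vols[0] < vols[1] < vols[2]


class TestMolecularMass:
    def test_self_reference_returns_reference_mass(self):
        assert saxs.mm_from_reference(1.0, 1.0, 1.0, 1.0) == pytest.approx(66.0)

    @pytest.mark.parametrize("i0,c,expected", [(1.0, 0.5, 132.0), (2.0, 1.0, 132.0)])
    def test_linear_scaling(self, i0, c, expected):
        assert saxs.mm_from_reference(i0, c, 1.0, 1.0) == pytest.approx(expected)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            saxs.mm_from_reference(1.0, 0.0, 1.0, 1.0)


class TestZeroConcentration:
    def test_structure_factor_removed(self):
        curves = syndata.simulate_saxs(
            "sphere", (3.0,), 1.0, concentrations=(4.2, 2.1, 1.1),
            noise_scale=1e-3, structure_factor_b=0.02, seed=0)
        ideal = syndata.simulate_saxs("sphere", (3.0,), 1.0)[0]
        ex = saxs.extrapolate_zero_concentration(curves)
        low_s = ex.s < 1.0
        assert np.max(np.abs(ex.I[low_s] - ideal.I[low_s])) < 0.02
        g = saxs.guinier_fit(ex)
        assert g.Rg == pytest.approx(RG_SPHERE3, rel=0.02)

    def test_no_concentration_dependence_gives_weighted_mean(self):
        curves = syndata.simulate_saxs("sphere", (3.0,), 1.0,
                                       concentrations=(4.0, 2.0), noise_scale=0.0)
        ex = saxs.extrapolate_zero_concentration(curves)
        ideal = syndata.simulate_saxs("sphere", (3.0,), 1.0)[0]
        assert np.allclose(ex.I, ideal.I, rtol=1e-6)

    def test_single_concentration_rejected(self):
        curves = syndata.simulate_saxs("sphere", (3.0,), 1.0, concentrations=(2.0,))
        with pytest.raises(ValueError, match=">= 2"):
            saxs.extrapolate_zero_concentration(curves)


def make_secsaxs(seed=0, noise=2e-3, n_frames=200):
    s = np.arange(0.025, 5.0, 0.01)
    comps = [syndata.simulate_saxs("sphere", (r,), i0, s_grid=s)[0]
             for r, i0 in ((2.0, 0.8), (3.0, 1.0), (4.0, 1.3))]
    buffer = saxs.SAXSCurve(s, np.full_like(s, 0.05), np.full_like(s, 1e-3))
    t = np.arange(n_frames)
    mix = np.stack([np.exp(-0.5 * ((t - c) / w) ** 2) * a
                    for c, w, a in ((60, 12, 1.0), (100, 15, 1.4), (140, 12, 0.9))],
                   axis=1)
    mix = np.hstack([mix, np.full((n_frames, 1), 0.8)])
    frames, sig = syndata.simulate_secsaxs_frames(comps + [buffer], mix,
                                                  noise_scale=noise, seed=seed)
    return s, comps, frames, sig


class TestNmfExtract:
    def test_known_mixture_with_buffer_recovered(self):
        s, comps, frames, sig = make_secsaxs()
        sel, all_c, rep = saxs.nmf_extract(frames, sig, s, k=4,
                                           expected_Rg=RG_SPHERE3, seed=0)
        truth = comps[1].I
        cos = np.dot(sel.I, truth) / np.linalg.norm(sel.I) / np.linalg.norm(truth)
        assert cos > 0.999
        assert saxs.guinier_fit(sel).Rg == pytest.approx(RG_SPHERE3, rel=0.03)
        assert len(all_c) == 4

    def test_pure_single_component_recovered(self):
        s = np.arange(0.025, 5.0, 0.01)
        comp = syndata.simulate_saxs("sphere", (3.0,), 1.0, s_grid=s)[0]
        frames = np.outer(np.linspace(0.5, 2.0, 30), comp.I)
        sig = np.full_like(frames, 1e-3)
        sel, _, _ = saxs.nmf_extract(frames, sig, s, k=2, expected_Rg=RG_SPHERE3,
                                     seed=0)
        cos = np.dot(sel.I, comp.I) / np.linalg.norm(sel.I) / np.linalg.norm(comp.I)
        assert cos > 0.999

    def test_residual_decreases_with_more_iterations(self):
        from sklearn.decomposition import NMF

        s, comps, frames, sig = make_secsaxs()
        X = frames / np.median(sig, axis=0)
        errs = []
        for iters in (5, 20, 200):
            m = NMF(n_components=4, init="nndsvda", max_iter=iters, random_state=0,
                    tol=1e-12)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m.fit(X)
            errs.append(m.reconstruction_err_)
        assert errs[0] >= errs[1] >= errs[2]

    def test_rank_deficient_mixing_flags_ambiguity(self):
        s = np.arange(0.025, 5.0, 0.01)
        comp = syndata.simulate_saxs("sphere", (3.0,), 1.0, s_grid=s)[0]
        other = syndata.simulate_saxs("sphere", (2.0,), 0.7, s_grid=s)[0]
        buffer = saxs.SAXSCurve(s, np.full_like(s, 0.05), np.full_like(s, 1e-3))
        t = np.arange(60)
        prof = np.exp(-0.5 * ((t - 30) / 8) ** 2)
        mix = np.stack([prof, prof, 0.3 * np.ones(60)], axis=1)  # shared profile
        frames, sig = syndata.simulate_secsaxs_frames([comp, other, buffer], mix,
                                                      noise_scale=1e-3, seed=0)
        with pytest.warns(UserWarning, match="ambiguous"):
            saxs.nmf_extract(frames, sig, s, k=3, expected_Rg=2.3, seed=0)

    def test_negative_frames_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            saxs.nmf_extract(-np.ones((4, 5)), np.ones((4, 5)),
                             np.linspace(0.1, 0.5, 5))


class TestContactRestraints:
    KINASE = [(607, 624), (667, 680), (728, 748)]
    COCHAP = [(4, 28), (270, 293), (309, 316), (317, 341)]

    def test_reciprocal_scheme(self):
        rs = saxs.build_contact_restraints(self.KINASE, self.COCHAP,
                                           name_a="FGFR3", name_b="Cdc37")
        assert len(rs.restraints) == 7
        a = [r for r in rs.restraints if r[0] == "FGFR3"]
        b = [r for r in rs.restraints if r[0] == "Cdc37"]
        assert len(a) == 3 and all(t == "contact Cdc37" for _, _, t in a)
        assert len(b) == 4 and all("contact FGFR3 or other-domain-of-Cdc37" == t
                                   for _, _, t in b)

    def test_one_sided_input_warns(self):
        with pytest.warns(UserWarning, match="only one molecule"):
            rs = saxs.build_contact_restraints([], self.COCHAP)
        assert len(rs.restraints) == 4

    def test_text_round_trip_layout(self):
        rs = saxs.build_contact_restraints(self.KINASE, self.COCHAP)
        text = rs.to_text()
        lines = [l for l in text.splitlines() if not l.startswith("#")]
        assert len(lines) == 7
        first = lines[0].split()
        assert first[0] == "kinase" and first[1] == "607" and first[2] == "624"

    def test_empty_both_sides_rejected(self):
        with pytest.raises(ValueError):
            saxs.build_contact_restraints([], [])
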