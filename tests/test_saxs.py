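"""Scattering theory and model-free analyses."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from kapflex import saxs
from kapflex import structures as st
from .conftest import sphere_beads
from .test_structures import toy_model


def sphere_profile(R=50.0, n=2000, n_q=200, width=0.0, seed=2):
    m = toy_model(sphere_beads(n, R, seed=seed))
    q = np.geomspace(0.002, 0.35, n_q)
    return m, saxs.debye_profile(m, q, bead_form_factor_width=width)


class TestDebye:
    def test_single_bead_unit_form_factor_is_flat(self):
        m = toy_model([[1.0, 2.0, 3.0]])
        prof = saxs.debye_profile(m, np.linspace(0.01, 0.5, 20),
                                  bead_form_factor_width=0.0)
        assert np.allclose(prof.I, 1.0)

    def test_two_beads_coherent_low_q_limit(self):
        m = toy_model([[0, 0, 0], [5.0, 0, 0]])
        prof = saxs.debye_profile(m, np.array([1e-4]),
                                  bead_form_factor_width=0.0)
        assert prof.I[0] == pytest.approx(4.0, rel=1e-4)

    def test_guinier_rg_matches_coordinate_rg_on_sphere(self):
        m, prof = sphere_profile()
        rg_coord = st.radius_of_gyration(m)
        rg_guinier = saxs.guinier_fit(prof).Rg
        assert rg_guinier == pytest.approx(rg_coord, rel=0.02)

    def test_rotation_translation_invariance_and_order_symmetry(self, rng):
        coords = rng.normal(size=(100, 3)) * 20
        q = np.geomspace(0.01, 0.5, 40)
        a = saxs.debye_profile(toy_model(coords), q)
        from scipy.spatial.transform import Rotation
        R = Rotation.random(rng=rng).as_matrix()
        b = saxs.debye_profile(toy_model(coords @ R.T + 50.0), q)
        c = saxs.debye_profile(toy_model(coords[rng.permutation(100)]), q)
        assert np.allclose(a.I, b.I, rtol=1e-6)
        assert np.allclose(a.I, c.I, rtol=1e-6)

    def test_weighted_beads_scale_intensity(self):
        coords = [[0, 0, 0], [10.0, 0, 0]]
        m = toy_model(coords)
        m.masses = np.array([2.0, 2.0])
        prof = saxs.debye_profile(m, np.array([1e-4]),
                                  bead_form_factor_width=0.0)
        assert prof.I[0] == pytest.approx(16.0, rel=1e-4)


class TestGuinier:
    def test_exact_guinier_curve_recovered(self):
        q = np.geomspace(0.002, 0.05, 60)
        prof = saxs.ScatteringProfile(q, 7.0 * np.exp(-q**2 * 50.0**2 / 3.0))
        res = saxs.guinier_fit(prof)
        assert res.Rg == pytest.approx(50.0, rel=1e-3)
        assert res.I0 == pytest.approx(7.0, rel=1e-3)
        assert res.qmax_Rg <= 1.3

    def test_window_constraint_enforced(self):
        q = np.geomspace(0.002, 0.6, 200)
        prof = saxs.ScatteringProfile(q, 7.0 * np.exp(-q**2 * 50.0**2 / 3.0))
        assert saxs.guinier_fit(prof).qmax_Rg <= 1.3

    def test_too_few_points_raises(self):
        q = np.linspace(0.01, 0.02, 4)
        prof = saxs.ScatteringProfile(q, np.exp(-q**2))
        with pytest.raises(saxs.AnalysisError):
            saxs.guinier_fit(prof)


class TestRodGuinier:
    def test_closed_form_cross_section(self):
        q = np.geomspace(0.002, 0.2, 300)
        I = (1.0 / q) * np.exp(-q**2 * 20.0**2 / 2.0)
        prof = saxs.ScatteringProfile(q, I)
        res = saxs.rod_guinier_fit(prof, Rg_hint=100.0)
        assert res.Rgc == pytest.approx(20.0, rel=1e-3)

    def test_bead_cylinder_cross_section_oracle(self, rng):
        # cross-section second-moment oracle: solid cylinder Rgc = R/sqrt(2)
        R, L, n = 15.0, 400.0, 3000
        r = R * np.sqrt(rng.uniform(size=n))
        phi = rng.uniform(0, 2 * np.pi, n)
        z = rng.uniform(-L / 2, L / 2, n)
        coords = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
        prof = saxs.debye_profile(toy_model(coords),
                                  np.geomspace(0.002, 0.3, 300),
                                  bead_form_factor_width=0.0)
        res = saxs.rod_guinier_fit(prof, Rg_hint=L / np.sqrt(12))
        assert res.Rgc == pytest.approx(R / np.sqrt(2), rel=0.05)


class TestKratky:
    def test_guinier_exact_profile_peaks_at_sqrt3(self):
        q = np.linspace(1e-4, 0.2, 20000)
        Rg = 40.0
        prof = saxs.ScatteringProfile(q, 5.0 * np.exp(-q**2 * Rg**2 / 3.0))
        g = saxs.guinier_fit(prof)
        x, y, globular = saxs.dimensionless_kratky(prof, g)
        k = np.argmax(y[x <= 4.0])
        assert x[k] == pytest.approx(np.sqrt(3.0), abs=1e-3)
        assert y[k] == pytest.approx(3.0 / np.e, abs=1e-3)
        assert globular

    def test_flexible_chain_profile_keeps_rising(self):
        # Debye-chain closed form: I/I0 = 2(exp(-x)-1+x)/x^2, x=(qRg)^2
        q = np.linspace(1e-4, 0.3, 3000)
        Rg = 40.0
        x2 = (q * Rg) ** 2
        I = np.where(x2 > 0, 2 * (np.exp(-x2) - 1 + x2) / np.maximum(x2, 1e-12) ** 2, 1.0)
        prof = saxs.ScatteringProfile(q, I)
        g = saxs.GuinierResult(Rg=Rg, I0=1.0, qmin=q[0], qmax=q[-1],
                               qmax_Rg=0, residual_rms=0, n_points=0)
        x, y, globular = saxs.dimensionless_kratky(prof, g)
        sel = x <= 4.0
        assert not globular
        assert np.all(np.diff(y[sel])[x[sel][:-1] > 1.0] > -1e-9)
        assert y[sel].max() <= 1.2 * 2.0  # plateau at 2, no sharp peak

    def test_scale_invariance(self):
        q = np.linspace(1e-3, 0.2, 500)
        I = np.exp(-q**2 * 30.0**2 / 3.0)
        p1 = saxs.ScatteringProfile(q, I)
        p2 = saxs.ScatteringProfile(q, 77.0 * I)
        g1, g2 = saxs.guinier_fit(p1), saxs.guinier_fit(p2)
        y1 = saxs.dimensionless_kratky(p1, g1)[1]
        y2 = saxs.dimensionless_kratky(p2, g2)[1]
        assert np.allclose(y1, y2, rtol=1e-6)


class TestPofR:
    def test_sphere_pofr_peak_position(self):
        # closed-form solid-sphere p(r) peaks at r/Dmax ~ 0.525
        _, prof = sphere_profile(R=50.0, n=3000)
        prof = saxs.ScatteringProfile(prof.q, prof.I,
                                      sigma=prof.I * 0.001 + prof.I[0] * 1e-6)
        pr = saxs.pofr_invert(prof, Dmax=100.0)
        peak_r = pr.r[np.argmax(pr.p)]
        # solid-sphere p(r) ∝ u²(1 − 3u/4 + u³/16), u = r/R, support 2R
        u = np.linspace(0, 2, 2001)[1:]
        closed = u**2 * (1 - 0.75 * u + u**3 / 16)
        assert peak_r / 100.0 == pytest.approx(u[np.argmax(closed)] / 2,
                                               abs=0.05)

    def test_back_transform_self_consistency(self):
        _, prof = sphere_profile(R=40.0, n=2000)
        sig = prof.I * 0.01 + prof.I[0] * 1e-5
        noisy = saxs.ScatteringProfile(prof.q, prof.I, sigma=sig)
        pr = saxs.pofr_invert(noisy, Dmax=85.0)
        I_back = pr.back_transform(prof.q)
        chi = saxs.chi2_fit(saxs.ScatteringProfile(prof.q, I_back), noisy)
        assert chi.chi2 <= 1.5

    def test_derived_quantities_consistent(self):
        m, prof = sphere_profile(R=50.0, n=3000)
        sig = prof.I * 0.005 + prof.I[0] * 1e-6
        pr = saxs.pofr_invert(
            saxs.ScatteringProfile(prof.q, prof.I, sigma=sig), Dmax=105.0)
        assert pr.Rg == pytest.approx(st.radius_of_gyration(m), rel=0.03)
        assert pr.I0 == pytest.approx(pr.back_transform(np.array([1e-5]))[0],
                                      rel=0.01)

    def test_select_dmax_on_sphere(self):
        _, prof = sphere_profile(R=50.0, n=3000)
        sig = prof.I * 0.005 + prof.I[0] * 1e-6
        noisy = saxs.ScatteringProfile(prof.q, prof.I, sigma=sig)
        d = saxs.select_dmax(noisy, d_grid=np.arange(60.0, 160.0, 5.0))
        assert d == pytest.approx(100.0, abs=10.0)


class TestPofRFromModel:
    def test_two_beads_single_peak(self):
        m = toy_model([[0, 0, 0], [100.0, 0, 0]])
        pr = saxs.pofr_from_model(m)
        assert pr.r[np.argmax(pr.p)] == pytest.approx(100.0, abs=2.0)

    def test_dumbbell_intermodule_peak(self, rbcc_model):
        pr = saxs.pofr_from_model(rbcc_model)
        # brute-force pair histogram oracle: bimodal with a peak at the
        # planted 160 Å module separation
        sel = (pr.r > 120) & (pr.r < 200)
        peak = pr.r[sel][np.argmax(pr.p[sel])]
        assert peak == pytest.approx(160.0, abs=10.0)

    def test_rg_matches_coordinates_within_smearing(self, rbcc_model):
        pr = saxs.pofr_from_model(rbcc_model)
        rg = st.radius_of_gyration(rbcc_model)
        assert pr.Rg == pytest.approx(rg, rel=0.02)


class TestChi2:
    def _pair(self, seed=0):
        rng = np.random.default_rng(seed)
        q = np.geomspace(0.01, 0.5, 80)
        I = 100.0 * np.exp(-q**2 * 30.0**2 / 3.0) + 1.0
        return q, I, rng

    def test_identity(self):
        q, I, _ = self._pair()
        calc = saxs.ScatteringProfile(q, I)
        exp = saxs.ScatteringProfile(q, I, sigma=0.01 * I)
        fq = saxs.chi2_fit(calc, exp)
        assert fq.chi2 == pytest.approx(0.0, abs=1e-12)
        assert fq.scale == pytest.approx(1.0)
        assert fq.offset == pytest.approx(0.0, abs=1e-9)

    def test_affine_recovery(self):
        q, I, _ = self._pair()
        calc = saxs.ScatteringProfile(q, I)
        exp = saxs.ScatteringProfile(q, 3.0 * I + 10.0, sigma=0.01 * I)
        fq = saxs.chi2_fit(calc, exp)
        assert fq.scale == pytest.approx(3.0)
        assert fq.offset == pytest.approx(10.0, rel=1e-6)
        assert fq.chi2 == pytest.approx(0.0, abs=1e-10)

    def test_gaussian_noise_gives_unit_chi2(self):
        q, I, rng = self._pair(3)
        chis = []
        for _ in range(20):
            sig = 0.02 * I
            exp = saxs.ScatteringProfile(q, I + rng.normal(scale=sig), sigma=sig)
            chis.append(saxs.chi2_fit(saxs.ScatteringProfile(q, I), exp).chi2)
        assert np.mean(chis) == pytest.approx(1.0, abs=0.2)

    def test_resampling_interpolates(self):
        q, I, _ = self._pair()
        calc = saxs.ScatteringProfile(q, I)
        q2 = q[5:-5] * 1.01
        exp = saxs.ScatteringProfile(q2, np.interp(q2, q, I),
                                     sigma=0.01 * np.interp(q2, q, I))
        assert saxs.chi2_fit(calc, exp).chi2 < 0.1

    def test_missing_sigma_raises(self):
        q, I, _ = self._pair()
        with pytest.raises(saxs.ProfileError):
            saxs.chi2_fit(saxs.ScatteringProfile(q, I),
                          saxs.ScatteringProfile(q, I))


class TestIO:
    def test_dat_round_trip(self, tmp_path, rbcc_model):
        q = np.geomspace(0.01, 0.3, 30)
        prof = saxs.debye_profile(rbcc_model, q)
        prof = saxs.ScatteringProfile(prof.q, prof.I, sigma=0.01 * prof.I,
                                      metadata={"construct": "RBCC"})
        path = tmp_path / "p.dat"
        saxs.write_dat(prof, path)
        back = saxs.read_dat(path)
        assert np.allclose(back.q, prof.q, rtol=1e-5)
        assert np.allclose(back.I, prof.I, rtol=1e-5)
        assert np.allclose(back.sigma, prof.sigma, rtol=1e-5)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.dat"
        path.write_text("# nothing here\n")
        with pytest.raises(saxs.ProfileError):
            saxs.read_dat(path)

    def test_invalid_profile_rejected(self):
        with pytest.raises(saxs.ProfileError):
            saxs.ScatteringProfile(np.array([0.2, 0.1]), np.array([1.0, 1.0]))
        with pytest.raises(saxs.ProfileError):
            saxs.ScatteringProfile(np.array([0.1, 0.2]), np.array([1.0, 1.0]),
                                   sigma=np.array([0.0, 1.0]))
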