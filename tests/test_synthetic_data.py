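"""Synthetic generators: geometry, noise models, determinism."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from kapflex import saxs, smtirf
from kapflex import structures as st
from kapflex import synthetic_data as syn


class TestDumbbell:
    def test_module_com_separation(self, default_template):
        m = syn.build_dumbbell_dimer(default_template, np.random.default_rng(0))
        a = st.center_of_mass(m, domain="RB1B2-A")
        b = st.center_of_mass(m, domain="RB1B2-B")
        assert np.linalg.norm(a - b) == pytest.approx(160.0, abs=1.0)

    def test_topologically_valid(self, planted_dimer):
        assert planted_dimer.is_topologically_valid()

    def test_max_intra_distance_matches_pair_oracle(self, rbcc_model,
                                                    default_template):
        # brute-force pairwise-distance oracle on the same coordinates:
        # rod length plus both module diameters bound the extent
        dmax = pdist(rbcc_model.coords).max()
        expected = default_template.cc_length + 2 * default_template.module_radius
        assert dmax == pytest.approx(expected, rel=0.10)

    def test_zero_module_radius_degenerates_to_rod(self):
        t = syn.DimerTemplate(module_radius=0.0, module_beads=5)
        m = syn.build_rbcc_dumbbell(t)
        # module beads collapse onto the rod ends: cross-section extent
        # is only the strand offset, so the rod-Guinier Rgc is at the
        # bead-smearing scale
        prof = saxs.debye_profile(m, np.geomspace(0.005, 0.5, 200))
        rgc = saxs.rod_guinier_fit(prof, Rg_hint=st.radius_of_gyration(m)).Rgc
        assert rgc < 3.0 * saxs._DEFAULT_BEAD_WIDTH

    def test_planted_displacements_are_exact(self, planted_dimer):
        from kapflex.ensemble import compute_cvs
        cv = compute_cvs(planted_dimer)
        assert cv.dA == pytest.approx(60.0, abs=1.0)
        assert cv.dB == pytest.approx(120.0, abs=1.0)

    def test_impossible_template_raises(self):
        with pytest.raises(syn.ConstructionError):
            syn.DimerTemplate(cc_length=-5.0)
        with pytest.raises(syn.ConstructionError):
            syn.DimerTemplate(d_planted=(60.0, 200.0))


class TestRandomizeTermini:
    def test_displacements_bounded_and_fill_the_ball(self, small_template):
        model = syn.build_dumbbell_dimer(small_template, np.random.default_rng(0))
        rng = np.random.default_rng(42)
        D = 140.0
        disps = []
        for _ in range(500):
            out = syn.randomize_termini(model, small_template, D=D, rng=rng)
            for chain in "AB":
                idx = model.select(domain=f"PHDBR-{chain}")
                anchor = model.coords[model.select(domain=f"CC-{chain}")[-1]]
                disps.append(np.linalg.norm(out.coords[idx].mean(0) - anchor))
        disps = np.asarray(disps)
        assert disps.max() <= D + 1e-6
        assert disps.max() > 130.0

    def test_zero_D_only_rotates_about_com(self, small_template):
        model = syn.build_dumbbell_dimer(small_template, np.random.default_rng(0))
        out = syn.randomize_termini(model, small_template, D=0.0,
                                    rng=np.random.default_rng(1))
        for chain in "AB":
            idx = model.select(domain=f"PHDBR-{chain}")
            assert np.allclose(out.coords[idx].mean(0),
                               model.coords[idx].mean(0), atol=1e-9)

    def test_seed_determinism(self, small_template):
        model = syn.build_dumbbell_dimer(small_template, np.random.default_rng(0))
        a = syn.randomize_termini(model, small_template, D=100.0,
                                  rng=np.random.default_rng(9))
        b = syn.randomize_termini(model, small_template, D=100.0,
                                  rng=np.random.default_rng(9))
        assert np.array_equal(a.coords, b.coords)

    def test_too_small_D_raises(self, small_template):
        model = syn.build_dumbbell_dimer(small_template, np.random.default_rng(0))
        with pytest.raises(syn.ConstructionError):
            syn.randomize_termini(model, small_template, D=2.0,
                                  rng=np.random.default_rng(0))


class TestGrowLinker:
    def test_bridges_distant_anchors_with_valid_bonds(self, rng):
        a0, a1 = np.zeros(3), np.array([60.0, 0, 0])
        chain = syn.grow_linker(a0, a1, 200, rng)
        steps = np.linalg.norm(np.diff(chain, axis=0), axis=1)
        assert np.all(np.abs(steps - 3.8) < 0.05)
        assert np.linalg.norm(chain[0] - a0) <= 3.8 + 1e-9
        assert np.linalg.norm(chain[-1] - a1) <= 3.8 + 1e-9
        d = pdist(chain)
        n = len(chain)
        # exclude consecutive pairs from the clash check
        mask = np.ones(len(d), dtype=bool)
        k = 0
        for i in range(n - 1):
            mask[k] = False  # pair (i, i+1) leads each row
            k += n - 1 - i
        assert d[mask].min() >= 2.0 - 1e-9

    def test_two_residue_bridge_is_straight(self, rng):
        a0, a1 = np.zeros(3), np.array([7.6, 0, 0])
        chain = syn.grow_linker(a0, a1, 2, rng)
        # forced geometry: both beads close to the line between anchors
        assert np.abs(chain[:, 1:]).max() < 3.8

    def test_free_chain_end_to_end_follows_ideal_statistics(self):
        # ideal-chain simulation oracle: mean end-to-end ~ b sqrt(N)
        rng = np.random.default_rng(11)
        r = [np.linalg.norm(c[-1] - c[0])
             for c in (syn.grow_linker(np.zeros(3), None, 100, rng)
                       for _ in range(150))]
        assert np.mean(r) == pytest.approx(3.8 * 10.0, rel=0.15)

    def test_unreachable_anchors_raise(self, rng):
        with pytest.raises(syn.InfeasibleLinkerError):
            syn.grow_linker(np.zeros(3), np.array([100.0, 0, 0]), 10, rng)


class TestSimulateSaxs:
    def test_zero_noise_equals_debye(self, rbcc_model):
        q = np.geomspace(0.0025, 0.6, 80)
        prof = syn.simulate_saxs(rbcc_model, q,
                                 syn.NoiseSpec(saxs_rel_sigma=0.0))
        truth = saxs.debye_profile(rbcc_model, q)
        assert np.allclose(prof.I, truth.I)

    def test_noise_calibrated_to_unit_chi2(self, rbcc_model):
        q = np.geomspace(0.0025, 0.6, 120)
        truth = saxs.debye_profile(rbcc_model, q)
        chis = []
        for seed in range(10):
            prof = syn.simulate_saxs(rbcc_model, q,
                                     syn.NoiseSpec(saxs_rel_sigma=0.01,
                                                   seed=seed))
            chis.append(saxs.chi2_fit(truth, prof).chi2)
        assert np.mean(chis) == pytest.approx(1.0, abs=0.2)

    def test_seed_determinism(self, rbcc_model):
        q = np.geomspace(0.0025, 0.6, 50)
        a = syn.simulate_saxs(rbcc_model, q, syn.NoiseSpec(seed=5))
        b = syn.simulate_saxs(rbcc_model, q, syn.NoiseSpec(seed=5))
        assert np.array_equal(a.I, b.I)


class TestSimulateTraces:
    KM = smtirf.KineticModel(tau_off_1=0.25, A1=87.0, tau_off_2=2.26,
                             A2=13.0, k_on=3.64e6, concentration=3e-9)

    def test_mixture_mean_bright_time(self):
        # mixture-mean oracle: E[T] = (A1 tau1 + A2 tau2)/100
        rng = np.random.default_rng(0)
        t = syn.draw_bright_times(self.KM, 20000, rng)
        assert t.mean() == pytest.approx(self.KM.mean_bright_s, rel=0.05)

    def test_all_monomers_full_labeling_plateau_at_one(self):
        km = smtirf.KineticModel(tau_off_1=1.0, A1=100.0, tau_off_2=1.0,
                                 A2=0.0, k_on=1e7, concentration=10e-9)
        traces, truth = syn.simulate_smtirf_traces(
            km, n_traces=3, n_frames=2000, label_efficiency=1.0,
            dimer_fraction=0.0, noise=syn.NoiseSpec(trace_snr=50.0, seed=2))
        for tr in traces:
            bright = tr.intensity[tr.intensity > 0.5]
            if len(bright):
                assert np.abs(bright - 1.0).max() < 0.5

    def test_single_exponential_degenerate_mixture(self):
        km = smtirf.KineticModel(tau_off_1=0.5, A1=100.0, tau_off_2=0.5,
                                 A2=0.0, k_on=1e7, concentration=10e-9)
        rng = np.random.default_rng(3)
        t = syn.draw_bright_times(km, 20000, rng)
        assert t.mean() == pytest.approx(0.5, rel=0.05)
        assert t.std() == pytest.approx(0.5, rel=0.05)

    def test_ground_truth_returned(self):
        traces, truth = syn.simulate_smtirf_traces(
            self.KM, n_traces=2, n_frames=1000,
            noise=syn.NoiseSpec(seed=4))
        assert len(traces) == len(truth) == 2
        assert all("bright_s" in t for t in truth)


class TestSimulateItc:
    def test_zero_dH_gives_zero_heats(self):
        exp = syn.simulate_itc(N=1.0, Kd=1e-7, dH=0.0,
                               noise=syn.NoiseSpec(itc_heat_frac=0.0))
        assert np.allclose(exp.heats_ucal, 0.0)

    def test_zero_noise_matches_model(self):
        from kapflex import itc
        exp = syn.simulate_itc(N=0.98, Kd=176e-9, dH=-1e4,
                               noise=syn.NoiseSpec(itc_heat_frac=0.0))
        model = itc.one_set_of_sites_heat(exp, 0.98, 176e-9, -1e4)
        assert np.allclose(exp.heats_ucal, model)

    def test_stoichiometric_limit(self):
        # numerical stoichiometric-titration oracle: heats constant until
        # the cumulative molar ratio reaches N, then drop to ~0
        exp = syn.simulate_itc(N=1.0, Kd=1e-12, dH=-1e4,
                               noise=syn.NoiseSpec(itc_heat_frac=0.0))
        ratios = exp.molar_ratios()
        h = exp.heats_ucal
        pre = h[ratios < 0.9]
        post = h[ratios > 1.1]
        assert np.allclose(pre, pre[0], rtol=0.02)
        assert np.all(np.abs(post) < 0.05 * np.abs(pre[0]))
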