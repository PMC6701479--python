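"""Single-molecule trace analysis: detection, survival statistics, kinetics."""

import numpy as np
import pytest

from kapflex import smtirf
from kapflex import synthetic_data as syn

KM_0NM = smtirf.KineticModel(tau_off_1=0.25, A1=87.0, tau_off_2=2.26,
                             A2=13.0, k_on=3.64e6, concentration=3e-9)
DT = 0.05


def square_trace(n_frames=1000, period=50, pulse=10, level=5.0):
    y = np.zeros(n_frames)
    for s in range(20, n_frames - pulse, period):
        y[s:s + pulse] = level
    t = np.arange(n_frames) * DT
    return smtirf.FluorescenceTrace(t, y)


def discretized_bright(km, n, seed):
    rng = np.random.default_rng(seed)
    t = syn.draw_bright_times(km, n, rng)
    t = np.floor(t / DT) * DT
    return t[t >= DT]


class TestDetectEvents:
    def test_noiseless_square_wave_exact(self):
        tr = square_trace()
        ev = smtirf.detect_events(tr)
        keep = ev.bright_s[~ev.bright_truncated]
        assert np.allclose(keep, 10 * DT)

    def test_known_events_recovered_at_snr5(self):
        km = smtirf.KineticModel(tau_off_1=0.5, A1=100.0, tau_off_2=0.5,
                                 A2=0.0, k_on=5e6, concentration=20e-9)
        traces, truth = syn.simulate_smtirf_traces(
            km, n_traces=12, n_frames=4000, label_efficiency=1.0,
            noise=syn.NoiseSpec(trace_snr=5.0, seed=21))
        hits = total = 0
        for tr, gt in zip(traces, truth):
            # a 5-frame running median keeps step edges exact while
            # bridging the 2-frame noise dropouts long events suffer
            ev = smtirf.detect_events(tr, smooth=5)
            found = np.sort(ev.bright_s)
            for dur in gt["bright_s"]:
                frames = int(np.floor(dur / DT))
                if frames < 3:
                    continue
                total += 1
                if np.any(np.abs(found - frames * DT) <= DT + 1e-9):
                    hits += 1
        assert total > 50
        assert hits / total >= 0.95

    def test_pure_noise_rarely_fires(self):
        rng = np.random.default_rng(0)
        n_events = 0
        for k in range(100):
            y = rng.normal(size=1000)
            tr = smtirf.FluorescenceTrace(np.arange(1000) * DT, y)
            ev = smtirf.detect_events(tr, k_mad=3.0, min_frames=2)
            n_events += int(len(ev.bright_s) > 0)
        assert n_events <= 1  # >= 99% of replicates silent

    def test_constant_trace_warns_no_events(self):
        tr = smtirf.FluorescenceTrace(np.arange(200) * DT, np.ones(200))
        with pytest.warns(RuntimeWarning):
            ev = smtirf.detect_events(tr)
        assert len(ev.bright_s) == 0

    def test_stuck_traces_flagged_as_bleach_suspects(self):
        km = smtirf.KineticModel(tau_off_1=0.5, A1=100.0, tau_off_2=0.5,
                                 A2=0.0, k_on=5e6, concentration=20e-9)
        traces, truth = syn.simulate_smtirf_traces(
            km, n_traces=20, n_frames=2000, stuck_fraction=0.5,
            bleach_time_s=8.0, noise=syn.NoiseSpec(trace_snr=10.0, seed=4))
        for tr, gt in zip(traces, truth):
            ev = smtirf.detect_events(tr)
            if gt["stuck"] and 1.0 < gt["bleach_s"] < 80.0:
                assert ev.bleach_suspect
            elif not gt["stuck"] and len(ev.bright_s) >= 2:
                assert not ev.bleach_suspect

    def test_threshold_monotone_in_k_mad(self):
        km = smtirf.KineticModel(tau_off_1=0.4, A1=100.0, tau_off_2=0.4,
                                 A2=0.0, k_on=5e6, concentration=20e-9)
        traces, _ = syn.simulate_smtirf_traces(
            km, n_traces=4, n_frames=3000,
            noise=syn.NoiseSpec(trace_snr=8.0, seed=3))
        for tr in traces:
            counts = [len(smtirf.detect_events(tr, k_mad=k).bright_s)
                      for k in (2.0, 3.0, 5.0, 8.0)]
            assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSurvival:
    def test_counting_example(self):
        c = smtirf.SurvivalCurve.from_durations(np.array([1.0, 2.0, 3.0]))
        assert c.at(np.array([1e-9]))[0] == pytest.approx(1.0)
        assert c.at(np.array([2.5]))[0] == pytest.approx(1.0 / 3.0)

    def test_survival_is_proper(self):
        rng = np.random.default_rng(2)
        c = smtirf.SurvivalCurve.from_durations(rng.exponential(1.0, 500))
        assert c.S[0] == 1.0
        assert np.all(np.diff(c.S) <= 0)
        assert c.S[-1] >= 0.0

    def test_exponential_sample_log_linear(self):
        rng = np.random.default_rng(3)
        d = rng.exponential(2.0, 1000)
        c = smtirf.SurvivalCurve.from_durations(d)
        t = np.linspace(0.1, 6.0, 50)
        S = c.at(t)
        keep = S > 0.01
        slope, intercept = np.polyfit(t[keep], np.log(S[keep]), 1)
        pred = slope * t[keep] + intercept
        ss_res = np.sum((np.log(S[keep]) - pred) ** 2)
        ss_tot = np.sum((np.log(S[keep]) - np.log(S[keep]).mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.95

    def test_truncated_intervals_excluded(self):
        tr = square_trace()
        bright, dark = smtirf.dwell_histograms([smtirf.detect_events(tr)])
        assert np.all(bright.durations == 10 * DT)


class TestFitDissociation:
    def test_mono_exponential_degenerate(self):
        rng = np.random.default_rng(5)
        d = np.floor(rng.exponential(0.25, 3000) / DT) * DT
        d = d[d >= DT]
        fit = smtirf.fit_dissociation(
            smtirf.SurvivalCurve.from_durations(d), n_bootstrap=60, seed=0)
        assert fit.mono
        assert fit.tau_off_1 == pytest.approx(0.25, rel=0.10)

    def test_mixture_recovery_within_bootstrap_ci(self):
        d = discretized_bright(KM_0NM, 5000, seed=7)
        fit = smtirf.fit_dissociation(
            smtirf.SurvivalCurve.from_durations(d), n_bootstrap=100, seed=1)
        assert not fit.mono
        assert fit.ci_tau_1[0] <= 0.25 <= fit.ci_tau_1[1]
        assert fit.ci_tau_2[0] <= 2.26 <= fit.ci_tau_2[1]
        assert fit.ci_A2[0] <= 13.0 <= fit.ci_A2[1]

    def test_mle_agrees_with_survival_fit(self):
        d = discretized_bright(KM_0NM, 5000, seed=7)
        curve = smtirf.SurvivalCurve.from_durations(d)
        lsq = smtirf.fit_dissociation(curve, n_bootstrap=0, seed=1)
        mle = smtirf.fit_dissociation(curve, n_bootstrap=0, seed=1,
                                      method="mle")
        assert mle.tau_off_1 == pytest.approx(lsq.tau_off_1, rel=0.10)
        assert mle.tau_off_2 == pytest.approx(lsq.tau_off_2, rel=0.15)
        assert mle.tau_off_1 == pytest.approx(0.25, rel=0.10)
        assert mle.tau_off_2 == pytest.approx(2.26, rel=0.15)

    def test_discretization_bias_controlled(self):
        # 50 ms binning at tau1 = 0.25 s: recovered within 10%
        taus = []
        for seed in range(3):
            d = discretized_bright(KM_0NM, 5000, seed=30 + seed)
            fit = smtirf.fit_dissociation(
                smtirf.SurvivalCurve.from_durations(d), n_bootstrap=0, seed=0)
            taus.append(fit.tau_off_1)
        assert np.median(taus) == pytest.approx(0.25, rel=0.10)


class TestFitAssociation:
    def test_arithmetic_inversion(self):
        # tau_dark = 91.6 s at 3 nM -> k_on = 3.64e6 /M/s
        rng = np.random.default_rng(11)
        d = np.floor(rng.exponential(91.6, 4000) / DT) * DT
        d = d[d >= DT]
        k_on, tau, r2 = smtirf.fit_association(
            smtirf.SurvivalCurve.from_durations(d), concentration=3e-9)
        assert k_on == pytest.approx(3.64e6, rel=0.15)
        assert r2 > 0.99

    def test_rate_law_concentration_scaling(self):
        km2 = smtirf.KineticModel(tau_off_1=0.25, A1=87.0, tau_off_2=2.26,
                                  A2=13.0, k_on=3.64e6, concentration=6e-9)
        rng = np.random.default_rng(12)
        d1 = syn.draw_dark_times(KM_0NM, 4000, rng)
        d2 = syn.draw_dark_times(km2, 4000, rng)
        assert d1.mean() / d2.mean() == pytest.approx(2.0, rel=0.1)

    def test_invalid_concentration(self):
        c = smtirf.SurvivalCurve.from_durations(np.ones(50))
        with pytest.raises(ValueError):
            smtirf.fit_association(c, concentration=0.0)


class TestIntensityOligomers:
    def _events(self, dimer_fraction, p, seed, n_traces=60):
        km = smtirf.KineticModel(tau_off_1=1.0, A1=100.0, tau_off_2=1.0,
                                 A2=0.0, k_on=4e6, concentration=20e-9)
        traces, _ = syn.simulate_smtirf_traces(
            km, n_traces=n_traces, n_frames=2000, label_efficiency=p,
            dimer_fraction=dimer_fraction,
            noise=syn.NoiseSpec(trace_snr=12.0, seed=seed))
        return [smtirf.detect_events(tr) for tr in traces]

    def test_all_monomers_no_two_dye_observations(self):
        ev = self._events(0.0, 1.0, seed=1)
        out = smtirf.intensity_oligomers(ev, label_efficiency=1.0)
        assert out["two_dye_fraction_observed"] < 0.05

    def test_round_trip_dimer_fraction(self):
        ev = self._events(0.4, 0.6, seed=2, n_traces=120)
        out = smtirf.intensity_oligomers(ev, label_efficiency=0.6)
        assert out["resolved"]
        assert out["dimer_fraction_inferred"] == pytest.approx(0.4, abs=0.07)

    def test_binomial_inversion_formula(self):
        # direct formula check: f2 = f p / (1 + f (1-p))
        f, p = 0.4, 0.6
        f2 = f * p / (1 + f * (1 - p))
        assert smtirf.infer_dimer_fraction(f2, p) == pytest.approx(f, rel=1e-9)

    def test_more_dimers_more_two_dye_observations(self):
        lo = smtirf.infer_dimer_fraction(0.08, 0.6)
        hi = smtirf.infer_dimer_fraction(0.28, 0.6)
        assert hi > lo > 0
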