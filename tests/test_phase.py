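"""Fourier phase extraction, delay cancellation, and the correlation fit."""

import dataclasses

import numpy as np
import pytest

from retmap import phase as ph
from retmap import synth, wrap_phase
from retmap.types import ParameterError, RunTimeSeries, StimulusParams
from tests.conftest import route_phases


def _run_from(series_1d, stim=None, coord="eccentricity", direction="forward"):
    stim = stim or StimulusParams()
    return RunTimeSeries(
        series=np.atleast_2d(series_1d), coordinate=coord, direction=direction,
        params=stim,
    )


class TestDetrend:
    def test_stimulation_frequency_passes_unchanged(self):
        stim = StimulusParams()
        t = stim.times_s
        s = np.cos(2 * np.pi * t / stim.period_s - 0.7)
        out = ph.detrend_series(_run_from(s))
        assert np.allclose(out.series[0], s, atol=1e-9)

    def test_constant_series_zeroed(self):
        out = ph.detrend_series(_run_from(np.full(224, 5.0)))
        assert np.allclose(out.series, 0.0, atol=1e-9)

    def test_low_frequency_removed_high_kept(self):
        # oracle: DFT amplitudes before/after
        stim = StimulusParams()
        t = stim.times_s
        low = np.cos(2 * np.pi * t / stim.run_duration_s)  # 1 cycle/run
        high = np.cos(2 * np.pi * 14 * t / stim.run_duration_s)
        out = ph.detrend_series(_run_from(low + high), cutoff_cycles_per_run=2.0)
        spec = np.abs(np.fft.rfft(out.series[0])) * 2 / 224
        assert spec[1] < 1e-9
        assert spec[14] == pytest.approx(1.0, abs=1e-9)

    def test_cutoff_at_stimulation_frequency_rejected(self):
        with pytest.raises(ParameterError):
            ph.detrend_series(_run_from(np.zeros(224)), cutoff_cycles_per_run=14.0)


class TestDftPhaseSnr:
    def test_pure_cosine_phase_and_amplitude(self):
        stim = StimulusParams()
        s = 2.0 * np.cos(2 * np.pi * stim.times_s / 32.0 - 1.0)
        m = ph.dft_phase_snr(_run_from(s))
        assert m.phase[0] == pytest.approx(-1.0, abs=1e-9)
        assert m.amplitude[0] == pytest.approx(2.0, abs=1e-9)

    def test_zero_series_undefined(self):
        m = ph.dft_phase_snr(_run_from(np.zeros(224)))
        assert m.amplitude[0] == 0.0
        assert m.snr[0] == 0.0
        assert not m.defined[0]
        assert np.isnan(m.phase[0])

    def test_white_noise_snr_near_one(self):
        # Monte-Carlo oracle: the ratio's expectation is ~1 for pure noise
        rng = np.random.default_rng(42)
        series = rng.normal(size=(1000, 224))
        m = ph.dft_phase_snr(_run_from(series))
        se = m.snr.std(ddof=1) / np.sqrt(m.snr.size)
        assert abs(m.snr.mean() - 1.0) < max(3 * se, 0.02)

    def test_too_few_cycles_rejected(self):
        stim = StimulusParams(period_s=32.0, tr_s=2.0, n_volumes=64)
        with pytest.raises(ParameterError):
            ph.dft_phase_snr(_run_from(np.zeros(64), stim), stim_frequency_hz=1 / 120.0)


class TestCombineOppositeDirections:
    def _maps(self, phi_f, phi_b):
        stim = StimulusParams()
        t = stim.times_s
        mf = ph.dft_phase_snr(_run_from(np.cos(2 * np.pi * t / 32 + phi_f)))
        mb = ph.dft_phase_snr(
            _run_from(np.cos(2 * np.pi * t / 32 + phi_b), direction="backward")
        )
        return mf, mb

    def test_worked_example(self):
        mf, mb = self._maps(-1.5, 0.5)  # forward phase -1.5, backward 0.5
        combined, delay = ph.combine_opposite_directions(mf, mb, 32.0)
        assert combined.phase[0] == pytest.approx(1.0, abs=1e-9)
        assert delay[0] == pytest.approx(0.5 * 32 / (2 * np.pi), abs=1e-9)

    def test_equal_phases_give_zero_stimulus_phase(self):
        mf, mb = self._maps(-0.6, -0.6)
        combined, delay = ph.combine_opposite_directions(mf, mb, 32.0)
        assert combined.phase[0] == pytest.approx(0.0, abs=1e-9)
        assert delay[0] == pytest.approx(0.6 * 32 / (2 * np.pi), abs=1e-9)

    def test_branch_choice_matches_brute_force(self):
        # oracle: enumerate both half-angle branches directly
        rng = np.random.default_rng(0)
        stim = StimulusParams()
        for _ in range(200):
            pf, pb = rng.uniform(-np.pi, np.pi, 2)
            mf, mb = self._maps(pf, pb)
            combined, delay = ph.combine_opposite_directions(mf, mb, 32.0)
            best = None
            for k in (0, 1):
                s = wrap_phase((pb - pf) / 2 + k * np.pi)
                d = np.mod(-(pf + pb) / 2 + k * np.pi, 2 * np.pi) * 32 / (2 * np.pi)
                if 0 - 1e-12 <= d <= 16 + 1e-12 and (best is None or d < best[1]):
                    best = (s, d)
            assert best is not None
            assert combined.phase[0] == pytest.approx(best[0], abs=1e-6)
            assert delay[0] == pytest.approx(best[1], abs=1e-6)

    def test_out_of_window_flagged_unresolved(self):
        mf, mb = self._maps(-0.6, -0.6)  # delay phase 0.6
        combined, delay = ph.combine_opposite_directions(
            mf, mb, 32.0, delay_range_s=(4.0, 5.0)
        )
        assert not combined.defined[0]
        assert np.isnan(delay[0])


class TestReverseAverage:
    def test_constant_passthrough(self):
        run = _run_from(np.full(224, 3.5))
        out, _ = ph.reverse_average_combine(run, _run_from(np.full(224, 3.5),
                                                           direction="backward"))
        assert np.allclose(out.series, 3.5)

    def test_length_mismatch_rejected(self):
        stim_a = StimulusParams(n_volumes=224)
        stim_b = StimulusParams(n_volumes=256)
        with pytest.raises(ParameterError):
            ph.reverse_average_combine(
                _run_from(np.zeros(224), stim_a),
                _run_from(np.zeros(256), stim_b, direction="backward"),
            )

    @pytest.mark.parametrize("delay_s", [5.0, 8.0])
    def test_noiseless_phase_matches_closed_form(self, ground_truth, delay_s):
        """Oracle: closed-form phase of the averaged cosines.

        The averaged pair is cos(D) * cos(w t - (phi + C/2)) with
        D = phi_h - C/2; its measured phase is -(phi + C/2), plus pi
        when the attenuation factor cos(D) is negative.
        """
        vf, _ = ground_truth
        stim = StimulusParams(hemo_delay_s=delay_s)
        runs = synth.simulate_runs(vf, stim, seed=1)
        fwd, bwd = runs[("eccentricity", "forward")], runs[("eccentricity", "backward")]
        combined, offset = ph.reverse_average_combine(fwd, bwd)
        m = ph.dft_phase_snr(combined)
        from retmap import coding

        phi = coding.eccentricity_to_phase(vf.eccentricity, stim)
        phi_h = 2 * np.pi * delay_s / 32.0
        atten = np.cos(phi_h - wrap_phase(offset))
        expected = wrap_phase(-(phi + offset) + (np.pi if atten < 0 else 0.0))
        ok = vf.valid
        assert np.nanmax(np.abs(wrap_phase(m.phase[ok] - expected[ok]))) < 1e-6

    def test_combined_phase_delay_independent_within_attenuation_regime(
        self, ground_truth
    ):
        """Delays with the same attenuation sign yield identical combined
        phases; crossing a zero of cos(phi_h - C/2) flips them by pi."""
        vf, _ = ground_truth

        def combined_phase(delay):
            stim = StimulusParams(hemo_delay_s=delay)
            runs = synth.simulate_runs(vf, stim, seed=1)
            c, off = ph.reverse_average_combine(
                runs[("polar", "forward")], runs[("polar", "backward")]
            )
            return ph.stimulus_phase_from_reverse_average(ph.dft_phase_snr(c), off)

        p5, p6 = combined_phase(5.0), combined_phase(6.0)
        ok = vf.valid
        assert np.nanmax(np.abs(wrap_phase(p5[ok] - p6[ok]))) < 1e-6


class TestCorrelationFit:
    def test_exact_grid_hit(self):
        stim = StimulusParams()
        s = np.cos(2 * np.pi * stim.times_s / 32.0 - 0.4)
        fit = ph.correlation_phase_fit(_run_from(s))
        assert fit.phase[0] == pytest.approx(0.4, abs=1e-9)
        assert fit.r[0] == pytest.approx(1.0, abs=1e-6)

    def test_midway_phase_snaps_to_bracketing_grid_point(self):
        stim = StimulusParams()
        s = np.cos(2 * np.pi * stim.times_s / 32.0 - 0.5)  # between 0.4 and 0.6
        fit = ph.correlation_phase_fit(_run_from(s))
        assert fit.phase[0] in (pytest.approx(0.4), pytest.approx(0.6))

    def test_constant_series_undefined(self):
        fit = ph.correlation_phase_fit(_run_from(np.full(224, 1.0)))
        assert not fit.defined[0]

    def test_noise_threshold_fraction_matches_direct_simulation(self):
        # oracle: independent max-over-grid Monte-Carlo on the same draws
        stim = StimulusParams()
        rng = np.random.default_rng(7)
        series = rng.normal(size=(500, stim.n_volumes))
        fit = ph.correlation_phase_fit(_run_from(series))
        frac = np.mean(fit.r >= 0.2)

        t = stim.times_s
        grid = np.arange(16) * 0.2
        count = 0
        for row in series:
            rs = [
                np.corrcoef(row, np.cos(2 * np.pi * t / 32.0 - g))[0, 1]
                for g in grid
            ]
            count += max(rs) >= 0.2
        assert frac == pytest.approx(count / 500, abs=1e-12)


class TestInvariants:
    def test_phase_recovery_at_arbitrary_delay(self, ground_truth, stim):
        from retmap import coding

        vf, _ = ground_truth
        for delay in (0.0, 3.3, 11.7, 15.9):
            st = StimulusParams(hemo_delay_s=delay)
            runs = synth.simulate_runs(vf, st, seed=1)
            m1, _ = route_phases(runs, "eccentricity", st)
            truth_phi = wrap_phase(coding.eccentricity_to_phase(vf.eccentricity, st))
            ok = vf.valid & m1.defined
            assert np.nanmax(np.abs(wrap_phase(m1.phase[ok] - truth_phi[ok]))) < 1e-6

    def test_snr_invariant_to_constant_offset_after_detrend(self):
        stim = StimulusParams()
        rng = np.random.default_rng(3)
        s = np.cos(2 * np.pi * stim.times_s / 32.0) + rng.normal(0, 0.5, 224)
        m1 = ph.dft_phase_snr(ph.detrend_series(_run_from(s)))
        m2 = ph.dft_phase_snr(ph.detrend_series(_run_from(s + 100.0)))
        assert m1.snr[0] == pytest.approx(m2.snr[0], rel=1e-9)

    def test_mean_phase_error_nondecreasing_in_noise(self, ground_truth, stim):
        from retmap import coding

        vf, _ = ground_truth
        truth_phi = wrap_phase(coding.eccentricity_to_phase(vf.eccentricity, stim))
        errs = []
        for sd in (0.0, 2.0, 8.0):
            reps = []
            for seed in range(20):
                runs = synth.simulate_runs(vf, stim, noise_sd=sd, seed=500 + seed)
                m1, _ = route_phases(runs, "eccentricity", stim)
                ok = vf.valid & m1.defined
                reps.append(
                    np.mean(np.abs(wrap_phase(m1.phase[ok] - truth_phi[ok])))
                )
            errs.append(np.mean(reps))
        assert errs[0] <= errs[1] <= errs[2]
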