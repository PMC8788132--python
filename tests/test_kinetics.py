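import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramplux import kinetics, preprocess, synth
from ramplux.preprocess import CycleResponse
from ramplux.stimulus import Phase, RampStimulus

from .oracles import all_grid_signals, circular_peaks_oracle


def make_cr(z, rate_hz=1.0):
    z = np.asarray(z, float)
    return CycleResponse(
        z=z, rate_hz=rate_hz, period_s=z.size / rate_hz, n_cycles_averaged=1
    )


def impl_peaks(z, min_prom):
    """(index, height, prominence) triples from the implementation."""
    cr = make_cr(z)
    return sorted(
        (int(round(p.t_peak)), p.height, p.prominence)
        for p in kinetics.find_peaks(cr, min_prominence=min_prom)
    )


class TestFindPeaks:
    def test_single_triangle_peak(self):
        z = [0.0, 1.0, 2.0, 1.0, 0.0, 0.0]
        peaks = kinetics.find_peaks(make_cr(z), min_prominence=0.75)
        assert len(peaks) == 1
        assert peaks[0].t_peak == pytest.approx(2.0)
        assert peaks[0].prominence == pytest.approx(2.0)

    def test_two_bumps_with_saddle(self):
        # heights 2 and 1 over a saddle at 0: prominences 2 and 1
        z = [0.0, 2.0, 0.0, 1.0, 0.0, 0.0]
        peaks = kinetics.find_peaks(make_cr(z), min_prominence=0.75)
        assert [p.prominence for p in peaks] == pytest.approx([2.0, 1.0])

    def test_subthreshold_bump_rejected(self):
        z = [0.0, 0.5, 0.0, 0.0, 0.0, 0.0]
        assert kinetics.find_peaks(make_cr(z), min_prominence=0.75) == []

    def test_peak_at_cycle_seam_found_once(self):
        z = [2.0, 0.5, 0.0, 0.0, 0.0, 0.5]
        peaks = kinetics.find_peaks(make_cr(z), min_prominence=0.75)
        assert len(peaks) == 1
        assert peaks[0].t_peak == pytest.approx(0.0)

    def test_exhaustive_grid_matches_oracle(self):
        """Exact agreement with the brute-force circular-prominence oracle."""
        cases = 0
        for length, values in [
            (3, (0, 1, 2, 3)),
            (4, (0, 1, 2, 3)),
            (5, (0, 1, 2, 3)),
            (6, (0, 1, 2, 3)),
            (7, (0, 1, 2)),
            (8, (0, 1, 2)),
        ]:
            for z in all_grid_signals(length, values):
                for thr in (0.0, 0.75, 1.5):
                    assert impl_peaks(z, thr) == circular_peaks_oracle(z, thr), (
                        f"mismatch for {z.tolist()} at threshold {thr}"
                    )
                cases += 1
        assert cases == 5440 + 2187 + 6561

    @given(st.lists(st.sampled_from([0.0, 0.3, 0.8, 1.0, 1.7, 2.5]),
                    min_size=3, max_size=12))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_random_signals_match_oracle(self, z):
        assert impl_peaks(np.array(z), 0.75) == circular_peaks_oracle(z, 0.75)

    def test_rotation_equivariance(self, rng):
        """Peak sets follow circular rotation of the cycle response."""
        z = np.zeros(20)
        z[4:9] = [0.5, 1.5, 2.5, 1.5, 0.5]
        base = kinetics.find_peaks(make_cr(z), min_prominence=0.75)
        for shift in (3, 9, 15):
            rolled = kinetics.find_peaks(make_cr(np.roll(z, shift)), 0.75)
            assert len(rolled) == len(base)
            assert rolled[0].t_peak == pytest.approx((base[0].t_peak + shift) % 20)
            assert rolled[0].prominence == pytest.approx(base[0].prominence)
            assert rolled[0].width == pytest.approx(base[0].width)


class TestHalfMaxStatistics:
    def test_symmetric_triangle_width_is_half_base(self):
        # triangular bump rising from zero over a 10 s base: the
        # half-height crossings span exactly half the base, 5 s
        z = np.zeros(16)
        z[2:11] = [0.5, 1.0, 1.5, 2.0, 2.5, 2.0, 1.5, 1.0, 0.5]
        peaks = kinetics.find_peaks(make_cr(z), min_prominence=0.75)
        assert kinetics.width_at_half_max(peaks, make_cr(z)) == pytest.approx(5.0)

    def test_multi_peak_width_is_mean(self):
        cr = make_cr(np.zeros(8))
        mk = lambda w: kinetics.Peak(0, 1, 1, 0.0, w, 0.5)
        assert kinetics.width_at_half_max([mk(4.0), mk(6.0)], cr) == pytest.approx(5.0)

    def test_lux_at_half_max_tracks_ground_truth(self, noiseless):
        """Noiseless synthetic traces recover the generator's half-max LUX
        within one-sample interpolation error."""
        for label in ("ON", "OFF", "DUAL"):
            for ramp_s, n_cyc in ((10.0, 6), (30.0, 4)):
                stim = RampStimulus(ramp_s=ramp_s, n_cycles=n_cyc)
                tr = synth.gen_trace(stim, synth.default_kernel(label, stim),
                                     noiseless, rng=np.random.default_rng(0))
                _, _, cr = preprocess.preprocess_trace(tr, stim)
                s = kinetics.analyze(cr, stim)
                lux_per_sample = (stim.max_lux - stim.min_lux) / (
                    stim.ramp_s * noiseless.rate_hz
                )
                assert s.lux_at_half_max == pytest.approx(
                    tr.meta["true_lux_half_max"], abs=lux_per_sample
                ), f"{label} at {ramp_s}s ramp"

    def test_lux_within_stimulus_bounds(self, ramp10, noiseless):
        for label in ("ON", "OFF", "DUAL"):
            tr = synth.gen_trace(ramp10, synth.default_kernel(label, ramp10),
                                 noiseless, rng=np.random.default_rng(1))
            _, _, cr = preprocess.preprocess_trace(tr, ramp10)
            s = kinetics.analyze(cr, ramp10)
            assert ramp10.min_lux <= s.lux_at_half_max <= ramp10.max_lux

    def test_dual_uses_more_prominent_falling_peak(self, ramp10, noiseless):
        """The DUAL falling-phase (OFF) peak decides LUX-at-half-max."""
        tr = synth.gen_trace(ramp10, synth.default_kernel("DUAL", ramp10),
                             noiseless, rng=np.random.default_rng(2))
        _, _, cr = preprocess.preprocess_trace(tr, ramp10)
        peaks = kinetics.find_peaks(cr)
        assert len(peaks) == 2
        chosen = kinetics.select_offpeak(peaks, ramp10)
        assert kinetics.peak_phase(chosen, ramp10) is Phase.FALLING
        assert chosen.prominence == max(p.prominence for p in peaks)

    def test_width_triples_between_ramp_durations(self):
        """The same luminance-domain kernel played on 30 s vs 10 s ramps
        triples its temporal width (fast-indicator limit)."""
        ind = synth.IndicatorSpec(tau_rise=0.02, tau_decay=0.1,
                                  noise_sd=0.0, rate_hz=10.0)
        ref = RampStimulus(ramp_s=10.0)
        for label in ("ON", "OFF", "DUAL"):
            kernel = synth.default_kernel(label, ref)
            widths = {}
            for ramp_s in (10.0, 30.0):
                stim = RampStimulus(ramp_s=ramp_s, n_cycles=4)
                tr = synth.gen_trace(stim, kernel, ind,
                                     rng=np.random.default_rng(0))
                _, _, cr = preprocess.preprocess_trace(tr, stim)
                widths[ramp_s] = kinetics.analyze(cr, stim).width_at_half_max
            assert widths[30.0] / widths[10.0] == pytest.approx(3.0, rel=0.02)

    def test_no_significant_peak_yields_undefined_kinetics(self):
        s = kinetics.analyze(make_cr(np.zeros(10)), RampStimulus(ramp_s=5.0))
        assert s.peaks == []
        assert s.lux_at_half_max is None
        assert s.width_at_half_max is None
        assert s.class_hint == "none"
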