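"""Biomarker extraction and abnormality-detector behavior on analytically
constructed traces."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repolpop.biomarkers import (AbnormalityReport, BiomarkerSet,
                                 DetectorConfig, NoActionPotentialError,
                                 classify_susceptibility, compute_biomarkers,
                                 detect_abnormality)
from repolpop.synthetic_data import SyntheticApSpec, gen_ap_trace


def trapezoid_ap(dt=1.0):
    """Rest -85 mV, instant rise to +35 mV at t=50, linear fall to -85 over
    300 ms.  The X% repolarization level is crossed at an exactly known
    time."""
    t = np.arange(0.0, 500.0 + dt / 2, dt)
    vm = np.full_like(t, -85.0)
    rise = (t >= 50.0) & (t <= 350.0)
    vm[rise] = 35.0 - (35.0 - (-85.0)) * (t[rise] - 50.0) / 300.0
    return t, vm


class TestComputeBiomarkers:
    def test_trapezoid_apd90_matches_closed_form(self):
        t, vm = trapezoid_ap()
        bm = compute_biomarkers(t, vm, stimulus_onset=49.0)
        # APD90 level: 35 - 0.9*120 = -73 mV, crossed 270 ms after the rise
        assert bm.apd90 == pytest.approx(270.0, abs=1.0)
        assert bm.apd40 == pytest.approx(120.0, abs=1.0)
        assert bm.vm_peak == pytest.approx(35.0)
        assert bm.rmp == pytest.approx(-85.0)

    def test_flat_trace_raises_no_ap(self):
        t = np.arange(0, 500.0, 1.0)
        with pytest.raises(NoActionPotentialError):
            compute_biomarkers(t, np.full_like(t, -88.0), 50.0)

    def test_triangulation_is_apd90_minus_apd40(self):
        t, vm = trapezoid_ap()
        bm = compute_biomarkers(t, vm, 49.0)
        assert bm.triangulation == pytest.approx(bm.apd90 - bm.apd40)
        bm50 = compute_biomarkers(t, vm, 49.0, triangulation_lower="apd50")
        assert bm50.triangulation == pytest.approx(bm50.apd90 - bm50.apd50)

    def test_unrepolarized_beat_flagged(self):
        t = np.arange(0.0, 400.0, 1.0)
        vm = np.where(t < 50.0, -85.0, 30.0)  # depolarizes, never returns
        bm = compute_biomarkers(t, vm, 49.0)
        assert bm.unrepolarized
        assert np.isnan(bm.apd90)

    @pytest.mark.parametrize("apd40, apd50, apd90",
                             [(180.0, 200.0, 250.0), (120.0, 160.0, 220.0),
                              (220.0, 260.0, 340.0)])
    def test_round_trip_with_generator(self, apd40, apd50, apd90):
        spec = SyntheticApSpec(apd40=apd40, apd50=apd50, apd90=apd90)
        tr = gen_ap_trace(spec)
        bm = compute_biomarkers(tr.time, tr.vm, tr.stimulus_onset)
        assert bm.apd40 == pytest.approx(apd40, abs=spec.dt)
        assert bm.apd50 == pytest.approx(apd50, abs=spec.dt)
        assert bm.apd90 == pytest.approx(apd90, abs=spec.dt)
        assert bm.vm_peak == pytest.approx(spec.peak, abs=0.1)
        assert bm.rmp == pytest.approx(spec.rmp, abs=0.1)


def _flat_tail_spec(**kw):
    """AP that is fully repolarized well before the cycle ends, so a bump in
    the tail produces a clean gradient signature."""
    return SyntheticApSpec(apd40=180.0, apd50=200.0, apd90=250.0, tail=30.0,
                           **kw)


class TestDetector:
    def test_monotone_repolarization_is_normal(self):
        tr = gen_ap_trace(_flat_tail_spec())
        rep = detect_abnormality(tr.time, tr.vm, tr.beat_starts,
                                 DetectorConfig(n_cycles=1))
        assert not rep.abnormal and rep.subtype == "none"

    def test_late_bump_above_threshold_is_ead(self):
        # Gaussian bump with peak upward gradient 0.03 mV/ms, onset 320 ms
        # after the upstroke (well past the 100 ms delay)
        amp = 0.03 * 40.0 * np.sqrt(np.e)
        tr = gen_ap_trace(_flat_tail_spec(ead_onset=320.0, ead_amplitude=amp,
                                          ead_width=40.0))
        rep = detect_abnormality(tr.time, tr.vm, tr.beat_starts,
                                 DetectorConfig(n_cycles=1))
        assert rep.abnormal and rep.subtype == "EAD"
        assert rep.first_event_time > tr.stimulus_onset + 100.0

    def test_spike_and_dome_before_delay_is_normal(self):
        # strong positive gradient 50 ms post-upstroke only: inside the
        # 100 ms dead time, so it must not be called an afterdepolarization
        tr = gen_ap_trace(_flat_tail_spec(ead_onset=50.0, ead_amplitude=6.0,
                                          ead_width=9.0))
        rep = detect_abnormality(tr.time, tr.vm, tr.beat_starts,
                                 DetectorConfig(n_cycles=1))
        assert not rep.abnormal

    def test_gradient_exactly_at_threshold_is_normal(self):
        # a sustained ramp whose gradient equals the threshold exactly must
        # not trigger: the rule is a strict inequality
        t = np.arange(0.0, 1000.0, 1.0)
        vm = np.full_like(t, -85.0)
        sel = (t >= 50) & (t < 250)
        vm[sel] = 30.0 - 0.5 * (t[sel] - 50)
        tail = (t >= 250) & (t < 650)
        vm[tail] = -70.0 + 0.02 * (t[tail] - 250.0)
        vm[t >= 650] = -85.0
        # use the trace's own maximal late gradient as the threshold so the
        # comparison is exact in floating point
        g = np.gradient(vm, t)
        thr = float(g[(t > 260) & (t < 640)].max())
        rep = detect_abnormality(t, vm, [50.0],
                                 DetectorConfig(gradient_threshold=thr,
                                                n_cycles=1))
        assert not rep.abnormal
        # an infinitesimally lower threshold does trigger
        rep2 = detect_abnormality(t, vm, [50.0],
                                  DetectorConfig(gradient_threshold=thr * 0.999,
                                                 n_cycles=1))
        assert rep2.abnormal

    def test_repolarization_failure_subtype(self):
        t = np.arange(0.0, 1000.0, 1.0)
        vm = np.where(t < 50, -85.0, 10.0)  # never repolarizes
        rep = detect_abnormality(t, vm, [50.0], DetectorConfig(n_cycles=1))
        assert rep.abnormal and rep.subtype == "repolarization_failure"

    def test_time_shift_invariance(self):
        amp = 0.05 * 40.0 * np.sqrt(np.e)
        tr = gen_ap_trace(_flat_tail_spec(ead_onset=320.0, ead_amplitude=amp,
                                          ead_width=40.0))
        for shift in (250.0, 1713.0):
            rep = detect_abnormality(tr.time + shift, tr.vm,
                                     tr.beat_starts + shift,
                                     DetectorConfig(n_cycles=1))
            assert rep.abnormal
            assert rep.first_event_time == pytest.approx(
                detect_abnormality(tr.time, tr.vm, tr.beat_starts,
                                   DetectorConfig(n_cycles=1)
                                   ).first_event_time + shift, abs=1e-6)

    @given(st.floats(0.001, 0.2))
    @settings(max_examples=25, deadline=None)
    def test_threshold_monotonicity(self, peak_gradient):
        """Lowering the gradient threshold never converts abnormal to
        normal."""
        amp = peak_gradient * 40.0 * np.sqrt(np.e)
        tr = gen_ap_trace(_flat_tail_spec(ead_onset=320.0, ead_amplitude=amp,
                                          ead_width=40.0))
        flags = []
        for thr in (0.08, 0.04, 0.02, 0.01, 0.005):
            cfg = DetectorConfig(gradient_threshold=thr, n_cycles=1)
            flags.append(detect_abnormality(tr.time, tr.vm, tr.beat_starts,
                                            cfg).abnormal)
        # once abnormal at some threshold, abnormal at all lower thresholds
        assert flags == sorted(flags)

    def test_too_few_cycles_rejected(self):
        tr = gen_ap_trace(_flat_tail_spec())
        with pytest.raises(ValueError):
            detect_abnormality(tr.time, tr.vm, tr.beat_starts,
                               DetectorConfig(n_cycles=2))


class TestClassification:
    @pytest.mark.parametrize("count, expected", [
        (0, "NS"), (1, "MS"), (9, "MS"), (10, "HS"), (96, "HS")])
    def test_thresholds(self, count, expected):
        assert classify_susceptibility(count) == expected

    @given(st.integers(0, 95))
    @settings(max_examples=50, deadline=None)
    def test_total_monotone_step(self, count):
        order = {"NS": 0, "MS": 1, "HS": 2}
        assert order[classify_susceptibility(count + 1)] >= \
            order[classify_susceptibility(count)]

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            classify_susceptibility(-1)

    def test_report_consistency_enforced(self):
        with pytest.raises(ValueError):
            AbnormalityReport(True, "none")
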