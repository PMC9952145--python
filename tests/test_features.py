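"""Feature formulas, algebraic identities and subject-level aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgscreen.errors import MalformedBeatError, SubjectExcludedError
from ppgscreen.features import (
    FEATURE_NAMES,
    aggregate_subject,
    amplitude_and_width,
    apg_features,
    areas,
    compute_beat_features,
    extract_subject,
    indices,
    timing_features,
)
from ppgscreen.fiducials import APGWave, FiducialSet
from ppgscreen.preprocess import Beat
from ppgscreen.synthgen import SubjectProfile


def fset(t_onset=0.0, t_sys=0.2, t_notch=0.45, t_end=1.0, amp_sys=1.0,
         amp_notch=0.4):
    return FiducialSet(
        t_onset=t_onset,
        t_sys=t_sys,
        amp_sys=amp_sys,
        t_end=t_end,
        t_notch=t_notch,
        amp_notch=amp_notch,
        notch_source="derivative-minimum" if t_notch is not None else "absent",
    )


def beat_from(samples, fs=120.0):
    return Beat("t", 0, 0, len(samples), np.asarray(samples, dtype=float), fs)


def profile(**kw):
    base = dict(
        subject_id="t", age=40.0, height=1.70, weight=72.0, bmi=24.9,
        gender="M", smoking=False, respiratory_problem=False,
        blood_pressure=False, physical_activity=True, others=False,
        spo2=98.0, pulse_rate=70.0, label="Healthy",
    )
    base.update(kw)
    return SubjectProfile(**base)


class TestTiming:
    def test_interval_definitions_by_substitution(self):
        nxt = fset(t_onset=1.0, t_sys=1.2, t_notch=1.45, t_end=2.0)
        out = timing_features(fset(), nxt)
        assert out["pulse_interval"] == pytest.approx(1.0)
        assert out["CT"] == pytest.approx(0.2)
        assert out["PTT"] == pytest.approx(0.25)
        assert out["systolic_time"] == pytest.approx(0.45)
        assert out["diastolic_time"] == pytest.approx(0.55)
        assert out["dT"] == pytest.approx(1.0)

    def test_notch_absent_leaves_dependent_intervals_missing(self):
        out = timing_features(fset(t_notch=None, amp_notch=None))
        assert math.isnan(out["PTT"])
        assert math.isnan(out["systolic_time"])
        assert math.isnan(out["diastolic_time"])
        assert not math.isnan(out["CT"])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        ct=st.floats(0.05, 0.4),
        ptt=st.floats(0.05, 0.4),
        dia=st.floats(0.05, 0.6),
    )
    def test_interval_telescoping_identities(self, ct, ptt, dia):
        """systolic_time = CT + PTT and pulse_interval = systolic + diastolic."""
        f = fset(t_sys=ct, t_notch=ct + ptt, t_end=ct + ptt + dia)
        out = timing_features(f, None)
        assert out["systolic_time"] == pytest.approx(out["CT"] + out["PTT"])
        assert out["pulse_interval"] == pytest.approx(
            out["systolic_time"] + out["diastolic_time"]
        )


class TestAmplitudeWidth:
    def test_gaussian_half_height_width_matches_fwhm(self):
        fs, sigma, c = 120.0, 0.06, 0.4
        t = np.arange(int(1.0 * fs)) / fs
        beat = beat_from(np.exp(-0.5 * ((t - c) / sigma) ** 2))
        fid = fset(t_sys=c, amp_sys=1.0, t_notch=None, amp_notch=None)
        out = amplitude_and_width(beat, fid)
        fwhm = 2 * sigma * math.sqrt(2 * math.log(2))
        assert abs(out["PW"] - fwhm) <= 2 / fs
        assert out["SA"] == pytest.approx(1.0, abs=1e-6)

    def test_width_is_scale_invariant(self):
        fs = 120.0
        t = np.arange(int(1.0 * fs)) / fs
        x = np.exp(-0.5 * ((t - 0.4) / 0.06) ** 2)
        fid1 = fset(t_sys=0.4, amp_sys=1.0, t_notch=None, amp_notch=None)
        fid5 = fset(t_sys=0.4, amp_sys=5.0, t_notch=None, amp_notch=None)
        w1 = amplitude_and_width(beat_from(x), fid1)["PW"]
        w5 = amplitude_and_width(beat_from(5 * x), fid5)["PW"]
        assert w1 == pytest.approx(w5)

    def test_degenerate_flat_beat_rejected(self):
        beat = beat_from(np.full(60, 2.0))
        with pytest.raises(MalformedBeatError):
            amplitude_and_width(beat, fset(amp_sys=2.0))


class TestAreas:
    def test_step_fixture_split_by_hand(self):
        # fs = 1 Hz step fixture; trapezoid values computed by hand
        beat = beat_from([0.0, 1.0, 1.0, 1.0, 1.0, 0.0], fs=1.0)
        fid = fset(t_sys=1.0, t_notch=2.0, t_end=6.0, amp_notch=1.0)
        out = areas(beat, fid)
        assert out["systolic_area"] == pytest.approx(1.5)   # 0.5 + 1.0
        assert out["diastolic_area"] == pytest.approx(2.5)  # 1.0 + 1.0 + 0.5
        assert out["total_area"] == pytest.approx(4.0)
        assert out["IPA"] == pytest.approx(2.5 / 1.5)

    def test_symmetric_beat_has_unit_ipa(self):
        fs = 120.0
        t = np.arange(int(1.0 * fs)) / fs
        x = np.exp(-0.5 * ((t - 0.5) / 0.1) ** 2)
        fid = fset(t_sys=0.5, t_notch=0.5, t_end=1.0)
        out = areas(beat_from(x), fid)
        assert out["IPA"] == pytest.approx(1.0, abs=0.02)

    def test_total_area_is_exactly_additive(self, healthy_beats):
        from ppgscreen.fiducials import extract_fiducials

        for beat in healthy_beats[:5]:
            fid = extract_fiducials(beat)
            out = areas(beat, fid.shifted(-fid.t_onset))
            assert out["total_area"] == pytest.approx(
                out["systolic_area"] + out["diastolic_area"], abs=1e-12
            )


class TestIndices:
    def test_table_formulas_by_substitution(self):
        feats = {
            "SA": 2.0, "notch_amp": 1.0, "PTT": 0.25, "pulse_interval": 1.0,
            "CT": 0.2, "systolic_time": 0.45, "dT": 0.9,
        }
        out = indices(feats, height_m=1.70)
        assert out["AI_amp"] == pytest.approx(0.5)
        assert out["RI"] == pytest.approx(0.5)
        assert out["AI_time"] == pytest.approx(0.25)
        assert out["SI"] == pytest.approx(1.70 / 0.25)  # 6.8 m/s
        assert out["T1"] == pytest.approx(0.2 / 0.9)
        assert out["T2"] == pytest.approx(0.45 / 0.9)
        assert out["T3"] == pytest.approx(0.25 / 0.9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        sa=st.floats(0.5, 3.0),
        frac=st.floats(0.05, 0.95),
        ct=st.floats(0.05, 0.4),
        ptt=st.floats(0.05, 0.4),
        dt=st.floats(0.5, 1.5),
    )
    def test_augmentation_identity_and_t2_decomposition(self, sa, frac, ct, ptt, dt):
        """AI_amp + RI = 1, and T2 = T1 + T3 given systolic = CT + PTT."""
        feats = {
            "SA": sa, "notch_amp": frac * sa, "PTT": ptt,
            "pulse_interval": ct + ptt + 0.3, "CT": ct,
            "systolic_time": ct + ptt, "dT": dt,
        }
        out = indices(feats, height_m=1.65)
        assert out["AI_amp"] + out["RI"] == pytest.approx(1.0)
        assert out["T2"] == pytest.approx(out["T1"] + out["T3"])

    def test_missing_inputs_propagate(self):
        feats = {
            "SA": 2.0, "notch_amp": math.nan, "PTT": math.nan,
            "pulse_interval": 1.0, "CT": 0.2, "systolic_time": math.nan,
            "dT": math.nan,
        }
        out = indices(feats, 1.70)
        assert all(math.isnan(v) for v in out.values())


class TestAPGFeatures:
    def test_ratio_arithmetic(self):
        out = apg_features(APGWave(0.05, 2.0), APGWave(0.08, -1.0), APGWave(0.3, 0.5))
        assert out["b_over_a"] == pytest.approx(-0.5)
        assert out["e_over_a"] == pytest.approx(0.25)
        assert out["b_minus_e_over_a"] == pytest.approx(-0.75)

    def test_ratios_are_scale_free(self):
        r1 = apg_features(APGWave(0.05, 2.0), APGWave(0.08, -1.0), APGWave(0.3, 0.5))
        r2 = apg_features(APGWave(0.05, 6.0), APGWave(0.08, -3.0), APGWave(0.3, 1.5))
        for k in ("b_over_a", "e_over_a", "b_minus_e_over_a"):
            assert r1[k] == pytest.approx(r2[k])

    def test_zero_a_wave_rejected(self):
        with pytest.raises(MalformedBeatError):
            apg_features(APGWave(0.05, 0.0), APGWave(0.08, -1.0), None)


class TestCatalogue:
    def test_exactly_24_features(self):
        assert len(FEATURE_NAMES) == 24
        assert len(set(FEATURE_NAMES)) == 24


class TestAggregate:
    def make_beat_rows(self, sa_values):
        rows = []
        for sa in sa_values:
            row = {name: 1.0 for name in FEATURE_NAMES}
            row["SA"] = sa
            rows.append(row)
        return rows

    def test_mean_and_sample_variance(self):
        rows = self.make_beat_rows([1.0, 3.0, 2.0, 2.0, 2.0])
        out = aggregate_subject(rows, profile())
        assert out.means["SA"] == pytest.approx(2.0)
        assert out.variances["SA"] == pytest.approx(0.5)  # ddof=1
        two = aggregate_subject(self.make_beat_rows([1.0, 3.0] * 3), profile())
        assert two.variances["SA"] == pytest.approx(np.var([1, 3, 1, 3, 1, 3], ddof=1))

    def test_identical_beats_have_zero_variance(self):
        out = aggregate_subject(self.make_beat_rows([2.0] * 6), profile())
        assert all(v == 0.0 for v in out.variances.values())

    def test_order_invariance(self):
        rows = self.make_beat_rows([1.0, 2.0, 3.0, 4.0, 5.0])
        a = aggregate_subject(rows, profile())
        b = aggregate_subject(list(reversed(rows)), profile())
        assert a.means == b.means and a.variances == b.variances

    def test_too_few_beats_excludes_subject(self):
        with pytest.raises(SubjectExcludedError):
            aggregate_subject(self.make_beat_rows([1.0, 2.0]), profile())


class TestRecovery:
    def test_features_recover_ground_truth_on_noise_free_subject(self, small_cohort):
        """Extracted timing/amplitude features match the generator's analytic
        values: peak-anchored intervals to 2 samples, onset-anchored ones to
        the ~8-sample foot resolution, amplitudes and areas to 2%."""
        subject = small_cohort.subjects[0]
        fs = subject.record.fs
        sf = extract_subject(subject.record, subject.profile)
        gts = subject.ground_truth
        gt_dt = np.mean(np.diff([g.t_sys for g in gts]))
        gt_ptt = np.mean([g.t_notch - g.t_sys for g in gts if g.t_notch])
        gt_pi = np.mean([g.t_end - g.t_onset for g in gts])
        gt_ct = np.mean([g.t_sys - g.t_onset for g in gts])
        raw = subject.record.samples
        gt_sa = np.mean(
            [g.amp_sys - raw[int(round(g.t_onset * fs))] for g in gts]
        )
        assert abs(sf.means["dT"] - gt_dt) <= 2 / fs
        assert abs(sf.means["PTT"] - gt_ptt) <= 2 / fs
        assert abs(sf.means["pulse_interval"] - gt_pi) <= 8 / fs
        assert abs(sf.means["CT"] - gt_ct) <= 8 / fs
        # SA is measured above the onset baseline after band-passing; the
        # pass-band shaping of the 0.6-15 Hz filter trims a few percent
        assert sf.means["SA"] == pytest.approx(gt_sa, rel=0.05)
        assert sf.n_beats_used >= 30
        assert sf.notch_fraction >= 0.95

    def test_units_sanity_on_cohort(self, small_cohort):
        for subject in small_cohort.subjects[:4]:
            sf = extract_subject(subject.record, subject.profile)
            assert 0 < sf.means["SI"] < 50  # m/s
            for key in ("CT", "PW", "PTT", "diastolic_time"):
                if not math.isnan(sf.means[key]):
                    assert sf.means[key] < sf.means["pulse_interval"]


class TestComputeBeatFeatures:
    def test_full_vector_on_synthetic_beat(self, healthy_beats):
        from ppgscreen.fiducials import extract_fiducials

        beat = healthy_beats[1]
        fid = extract_fiducials(beat)
        nxt = extract_fiducials(healthy_beats[2])
        feats = compute_beat_features(beat, fid, height_m=1.70, next_fid=nxt)
        assert set(feats) == set(FEATURE_NAMES)
        defined = [k for k, v in feats.items() if not math.isnan(v)]
        assert set(defined) == set(FEATURE_NAMES)  # healthy beat: all defined
        assert feats["AI_amp"] + feats["RI"] == pytest.approx(1.0)
        assert feats["T2"] == pytest.approx(feats["T1"] + feats["T3"])
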