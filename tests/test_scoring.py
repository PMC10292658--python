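"""Trial normalization, CR classification, exclusion rule and peak times."""
import numpy as np
import pytest

from blinkscore.scoring import (
    animal_peak_time,
    classify_cs_only,
    classify_paired,
    normalization_anchors,
    normalize_cs_only,
    normalize_paired,
    score_session,
    score_trial,
    trial_peak_time,
)
from blinkscore.synthetic import BlinkKinematicsParams, generate_trace
from blinkscore.types import CR, CS_ONLY, EXCLUDED, NO_CR, PAIRED, EyelidTrace

from oracles import brute_force_classify_cs_only, brute_force_classify_paired


def trace_from(t, v, rate=200.0):
    return EyelidTrace(time_ms=np.asarray(t, float), value_px=np.asarray(v, float),
                       frame_rate_hz=rate)


def ramp_trace(targets: dict, rate=200.0, span=(-500.0, 1750.0), base=0.0):
    """Piecewise-linear trace through (time -> value) anchor points."""
    t = np.arange(span[0], span[1], 1000.0 / rate)
    xs = sorted(targets)
    v = np.interp(t, xs, [targets[x] for x in xs], left=base, right=targets[xs[-1]])
    return trace_from(t, v, rate)


class TestNormalizationPaired:
    def test_affine_map_example(self):
        # cs_min 10 at some post-CS sample, us_max 110 after US onset
        tr = ramp_trace({100.0: 10.0, 200.0: 60.0, 300.0: 110.0}, base=10.0)
        cs_min, us_max = normalization_anchors(tr, 250.0)
        assert (cs_min, us_max) == (10.0, 110.0)
        norm, t, _ = normalize_paired(tr, 250.0)
        i = np.argmin(np.abs(t - 200.0))
        assert norm[i] == pytest.approx(0.5)

    def test_affine_invariance_of_normalization(self):
        tr = ramp_trace({0.0: 10.0, 150.0: 40.0, 280.0: 120.0}, base=10.0)
        norm0, _, _ = normalize_paired(tr, 250.0)
        tr2 = trace_from(tr.time_ms, 3.0 * tr.value_px + 7.0)
        norm1, _, _ = normalize_paired(tr2, 250.0)
        assert np.allclose(norm0, norm1)

    def test_noiseless_paired_ur_peak_is_one(self, paired_spec, noiseless_no_cr_params):
        tr = generate_trace(paired_spec, noiseless_no_cr_params, 200.0, seed=0)
        norm, t, _ = normalize_paired(tr, paired_spec.us_onset_ms)
        us_win = (t > paired_spec.us_onset_ms) & (t <= paired_spec.us_onset_ms + 500.0)
        assert norm[us_win].max() == pytest.approx(1.0)

    def test_window_restricted_to_1500ms_of_us(self):
        tr = ramp_trace({0.0: 0.0, 300.0: 100.0}, span=(-2500.0, 3000.0))
        _, t, _ = normalize_paired(tr, 250.0)
        assert t.min() >= -1250.0 and t.max() <= 1750.0

    def test_flat_trace_marked_degenerate(self):
        tr = trace_from(np.arange(-500.0, 1750.0, 5.0), np.full(450, 42.0))
        rec = score_trial(PAIRED, tr, us_onset_ms=250.0)
        assert rec.classification == EXCLUDED
        assert rec.exclusion_reason == "degenerate_normalization"


class TestClassifyPaired:
    T = np.arange(-500.0, 1750.0, 5.0)

    def _norm(self, targets, base=0.0):
        return np.interp(
            self.T, sorted(targets), [targets[k] for k in sorted(targets)],
            left=base, right=0.0,
        )

    def test_flat_zero_with_late_ur_is_no_cr(self):
        norm = self._norm({250.0: 0.0, 300.0: 1.0, 500.0: 1.0})
        assert classify_paired(norm, self.T) == NO_CR

    def test_crossing_in_window_is_cr(self):
        norm = self._norm({120.0: 0.0, 150.0: 0.2, 180.0: 0.0})
        assert classify_paired(norm, self.T) == CR

    def test_early_crossing_excluded_regardless_of_later_cr(self):
        norm = self._norm({30.0: 0.0, 50.0: 0.2, 70.0: 0.0, 150.0: 0.3, 200.0: 0.0})
        assert classify_paired(norm, self.T) == EXCLUDED

    def test_threshold_not_exceeded_at_exact_value(self):
        norm = self._norm({120.0: 0.0, 150.0: 0.15, 180.0: 0.0})
        assert classify_paired(norm, self.T) == NO_CR

    def test_no_samples_in_window_raises(self):
        t = np.array([300.0, 400.0])
        with pytest.raises(ValueError):
            classify_paired(np.zeros(2), t)


class TestCsOnly:
    T = np.arange(-500.0, 1780.0, 5.0)

    def _norm(self, targets, base=0.0):
        return np.interp(
            self.T, sorted(targets), [targets[k] for k in sorted(targets)],
            left=base, right=0.0,
        )

    def test_flat_zero_is_no_cr(self):
        assert classify_cs_only(np.zeros_like(self.T), self.T) == NO_CR

    def test_late_ramp_with_quiet_baseline_is_cr(self):
        norm = self._norm({99.0: 0.0, 300.0: 0.3, 500.0: 0.0})
        assert classify_cs_only(norm, self.T) == CR

    def test_noisy_baseline_defeats_cr(self):
        norm = self._norm({40.0: 0.0, 50.0: 0.06, 60.0: 0.06, 99.0: 0.0, 300.0: 0.3})
        assert classify_cs_only(norm, self.T) == NO_CR

    def test_normalized_by_mean_of_previous_urs(self):
        tr = trace_from(self.T, np.where(self.T > 0, 50.0, 0.0))
        norm = normalize_cs_only(tr, prev_ur_amplitudes=[90.0, 110.0])
        assert np.max(norm) == pytest.approx(0.5)

    def test_uses_at_most_last_nine_urs(self):
        tr = trace_from(self.T, np.where(self.T > 0, 50.0, 0.0))
        amps = [1000.0] + [100.0] * 9  # the old outlier must be ignored
        norm = normalize_cs_only(tr, prev_ur_amplitudes=amps)
        assert np.max(norm) == pytest.approx(0.5)

    def test_no_preceding_paired_trials_excluded(self):
        tr = trace_from(self.T, np.zeros_like(self.T))
        rec = score_trial(CS_ONLY, tr, prev_ur_amplitudes=[])
        assert rec.classification == EXCLUDED
        assert rec.exclusion_reason == "no_preceding_paired"


class TestOracleEquivalence:
    def test_production_classifier_matches_literal_rule_scan(self, paired_spec, cs_only_spec):
        """Vectorized classifier must agree with a per-sample scan of the
        rule text on randomized synthetic trials."""
        rng = np.random.default_rng(202)
        n_match = 0
        n = 1500
        for i in range(n):
            noisy = BlinkKinematicsParams(
                cr_probability=0.5,
                cr_onset_mean_ms=float(rng.uniform(60.0, 260.0)),
                cr_onset_sd_ms=40.0,
                cr_amplitude_frac=float(rng.uniform(0.05, 0.9)),
                noise_sd_px=float(rng.uniform(0.0, 12.0)),
                spontaneous_blink_rate_hz=0.4,
            )
            if i % 2 == 0:
                tr = generate_trace(paired_spec, noisy, 200.0, rng=rng)
                norm, t, _ = normalize_paired(tr, paired_spec.us_onset_ms)
                if norm is None:
                    continue
                assert classify_paired(norm, t) == brute_force_classify_paired(norm, t)
            else:
                tr = generate_trace(cs_only_spec, noisy, 200.0, rng=rng)
                norm = normalize_cs_only(tr, prev_ur_amplitudes=[100.0])
                assert classify_cs_only(norm, tr.time_ms) == brute_force_classify_cs_only(
                    norm, tr.time_ms
                )
            n_match += 1
        assert n_match > n * 0.9


class TestAffineInvariance:
    def test_paired_classification_invariant_to_gain_and_offset(self, paired_spec):
        rng = np.random.default_rng(77)
        params = BlinkKinematicsParams(cr_probability=0.5, spontaneous_blink_rate_hz=0.3)
        for _ in range(200):
            tr = generate_trace(paired_spec, params, 200.0, rng=rng)
            rec = score_trial(PAIRED, tr)
            a = float(rng.uniform(0.2, 5.0))
            b = float(rng.uniform(0.0, 200.0))
            tr2 = trace_from(tr.time_ms, a * tr.value_px + b)
            rec2 = score_trial(PAIRED, tr2)
            assert rec.classification == rec2.classification


class TestPeakTime:
    def test_noiseless_peak_recovered_within_one_frame(self):
        t = np.arange(-500.0, 1780.0, 5.0)
        v = np.interp(t, [100.0, 250.0, 600.0], [0.0, 1.0, 0.0])
        assert trial_peak_time(v, t) == pytest.approx(250.0, abs=5.0)

    def test_animal_peak_time_is_mean_of_trials(self):
        assert animal_peak_time([200.0, 300.0]) == pytest.approx(250.0)

    def test_absent_when_no_qualifying_trials(self):
        assert animal_peak_time([]) is None

    def test_jittered_cohort_peak_time_recovery(self, cs_only_spec):
        """Generator peak times (mean 260, sd 30 ms) recovered from scored
        CS-only CR trials to within 3 SEs."""
        params = BlinkKinematicsParams(
            cr_probability=1.0,
            cr_onset_mean_ms=160.0,
            cr_onset_sd_ms=30.0,
            cr_rise_ms=100.0,
            noise_sd_px=1.0,
            spontaneous_blink_rate_hz=0.0,
        )
        rng = np.random.default_rng(31)
        peaks = []
        for _ in range(30):
            tr = generate_trace(cs_only_spec, params, 200.0, rng=rng)
            rec = score_trial(CS_ONLY, tr, prev_ur_amplitudes=[params.ur_amplitude_px])
            if rec.peak_time_ms is not None:
                peaks.append(rec.peak_time_ms)
        assert len(peaks) >= 20
        se = 30.0 / np.sqrt(len(peaks))
        assert abs(np.mean(peaks) - 260.0) < 3 * se + 5.0  # + one frame interval


class TestScoreSession:
    def test_ur_history_feeds_cs_only_normalization(self, paired_spec, cs_only_spec,
                                                    clean_params):
        rng = np.random.default_rng(5)
        trials = []
        for _ in range(3):
            trials.append(
                (PAIRED, generate_trace(paired_spec, clean_params, 200.0, rng=rng))
            )
        trials.append(
            (CS_ONLY, generate_trace(cs_only_spec, clean_params, 200.0, rng=rng))
        )
        records = score_session(trials)
        assert records[-1].classification in (CR, NO_CR)
        assert all(r.classification == CR for r in records[:3])

    def test_first_trial_cs_only_is_excluded(self, cs_only_spec, clean_params):
        tr = generate_trace(cs_only_spec, clean_params, 200.0, seed=0)
        records = score_session([(CS_ONLY, tr)])
        assert records[0].classification == EXCLUDED

    def test_no_trial_both_excluded_and_cr(self, paired_spec):
        rng = np.random.default_rng(8)
        params = BlinkKinematicsParams(cr_probability=0.7, spontaneous_blink_rate_hz=0.5)
        trials = [
            (PAIRED, generate_trace(paired_spec, params, 200.0, rng=rng))
            for _ in range(50)
        ]
        for rec in score_session(trials):
            assert rec.classification in (CR, NO_CR, EXCLUDED)
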