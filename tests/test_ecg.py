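"""Extractor checks against generator ground truth and brute-force oracles."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from triagesim.ecg import (
    extract_features,
    locate_qs,
    locate_r,
    qrs_width,
    split_cycles,
    st_elevation,
)
from triagesim.waveform import (
    ECGMorphologyParams,
    PROFILE_NAMES,
    WaveComponent,
    WaveformRecord,
    class_profile,
    synthesize_ecg,
)


def _flat_record(duration=60.0, fs=250.0):
    n = round(duration * fs)
    return WaveformRecord("flat", fs, duration, np.zeros(n))


class TestSplitCycles:
    def test_flat_record_has_no_cycles(self):
        assert split_cycles(_flat_record()) == []

    @pytest.mark.parametrize("n_beats,duration", [(6, 6.0), (60, 60.0)])
    def test_cycle_count_and_boundaries_match_ground_truth(
        self, basic_params, n_beats, duration
    ):
        rec = synthesize_ecg(basic_params, duration=duration, fs=250.0)
        cycles = split_cycles(rec)
        assert len(cycles) == n_beats
        # each true R time falls inside exactly one cycle
        for rt in rec.ground_truth["r_times"]:
            hits = [c for c in cycles if c.t[0] <= rt <= c.t[-1]]
            assert len(hits) == 1

    def test_cycles_tile_the_record(self, basic_params):
        rec = synthesize_ecg(basic_params, duration=6.0, fs=250.0)
        cycles = split_cycles(rec)
        assert sum(c.t.size for c in cycles) == rec.n_samples
        for a, b in zip(cycles[:-1], cycles[1:]):
            assert a.t[-1] < b.t[0]

    def test_up_and_down_halves_partition_each_cycle(self, basic_params):
        rec = synthesize_ecg(basic_params, duration=6.0, fs=250.0)
        for cyc in split_cycles(rec):
            up, down = cyc.up_half, cyc.down_half
            assert len(set(up) & set(down)) == 0
            assert len(up) + len(down) == cyc.t.size


class TestFiducialOracles:
    """locate_r / locate_qs vs exhaustive scans on randomized morphologies."""

    @staticmethod
    def _random_record(rng):
        width = rng.uniform(0.03, 0.25)
        params = ECGMorphologyParams(
            heart_rate=rng.uniform(50, 90),
            p=WaveComponent(rng.uniform(0.0, 0.15), -(width / 2 + 0.15), 0.02),
            q=WaveComponent(-rng.uniform(0.1, 0.5), -width / 2, max(width / 10, 0.006)),
            r=WaveComponent(rng.uniform(0.8, 2.0), 0.0, max(width / 8, 0.009)),
            s=WaveComponent(-rng.uniform(0.1, 0.5), width / 2, max(width / 10, 0.006)),
            t=WaveComponent(rng.uniform(0.1, 0.3), width / 2 + 0.2, 0.025),
            st_offset=rng.choice([0.0, 0.2]),
        )
        return synthesize_ecg(params, duration=4.0, fs=250.0)

    def test_r_and_qs_match_brute_force_on_100_random_cycles(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 100:
            rec = self._random_record(rng)
            for cyc in split_cycles(rec):
                r = locate_r(cyc)
                # oracle: exhaustive argmax over samples at/above baseline
                above = cyc.v - cyc.baseline >= 0
                i_best = min(
                    (i for i in range(cyc.t.size) if above[i]),
                    key=lambda i: (-cyc.v[i], cyc.t[i]),
                )
                assert r == (cyc.t[i_best], cyc.v[i_best])

                q, s = locate_qs(cyc, r)
                for point, lo, hi in (
                    (q, r[0] - 0.3, r[0]),
                    (s, r[0], r[0] + 0.3),
                ):
                    window = [
                        i
                        for i in range(cyc.t.size)
                        if lo <= cyc.t[i] and cyc.t[i] <= hi and cyc.t[i] != r[0]
                        and (cyc.t[i] < r[0]) == (point is q)
                    ]
                    j_best = min(window, key=lambda i: (cyc.v[i], cyc.t[i]))
                    assert point == (cyc.t[j_best], cyc.v[j_best])
                checked += 1

    def test_r_matches_generator_ground_truth_within_one_sample(self, basic_params):
        rec = synthesize_ecg(basic_params, duration=6.0, fs=250.0)
        cycles = split_cycles(rec)
        for cyc, rt in zip(cycles, rec.ground_truth["r_times"]):
            r = locate_r(cyc)
            assert abs(r[0] - rt) <= 1.0 / rec.fs + 1e-9

    def test_qs_troughs_match_ground_truth_within_one_sample(self, basic_params):
        rec = synthesize_ecg(basic_params, duration=6.0, fs=250.0)
        cycles = split_cycles(rec)
        gt = rec.ground_truth
        for cyc, qt, stt in zip(cycles, gt["q_times"], gt["s_times"]):
            r = locate_r(cyc)
            q, s = locate_qs(cyc, r)
            assert abs(q[0] - qt) <= 1.0 / rec.fs + 1e-9
            assert abs(s[0] - stt) <= 1.0 / rec.fs + 1e-9

    def test_symmetric_qrs_gives_equidistant_troughs(self, basic_params):
        rec = synthesize_ecg(basic_params, duration=6.0, fs=250.0)
        cyc = split_cycles(rec)[2]
        r = locate_r(cyc)
        q, s = locate_qs(cyc, r)
        assert abs((r[0] - q[0]) - (s[0] - r[0])) <= 1.0 / rec.fs + 1e-9

    def test_all_negative_cycle_has_no_r(self):
        t = np.arange(100) / 100.0
        from triagesim.ecg import CycleSegment

        cyc = CycleSegment(t=t, v=np.full(100, -1.0), baseline=0.0)
        with pytest.raises(ValueError, match="no R wave"):
            locate_r(cyc)


class TestQRSWidthAndST:
    def test_degenerate_zero_width(self):
        assert qrs_width((1.0, -0.2), (1.0, -0.2)) == 0.0

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            qrs_width((2.0, -0.2), (1.0, -0.2))

    def test_flat_baseline_after_s_is_not_elevated(self, basic_params):
        params = dataclasses.replace(basic_params, st_offset=0.0)
        rec = synthesize_ecg(params, duration=6.0, fs=250.0)
        cyc = split_cycles(rec)[1]
        r = locate_r(cyc)
        _, s = locate_qs(cyc, r)
        mag, flag = st_elevation(cyc, s)
        assert abs(mag) < 0.05
        assert flag is False

    def test_generated_st_offset_recovered(self, basic_params):
        rec = synthesize_ecg(basic_params, duration=6.0, fs=250.0)  # st_offset 0.2
        cyc = split_cycles(rec)[1]
        r = locate_r(cyc)
        _, s = locate_qs(cyc, r)
        mag, flag = st_elevation(cyc, s)
        assert mag == pytest.approx(0.2, abs=0.05)
        assert flag is True


class TestExtractFeatures:
    def test_constant_rr_is_regular(self, make_spike_train):
        rec = make_spike_train(np.arange(0.5, 9.5, 1.0))
        fv = extract_features(rec)
        assert fv.pp_label == "Regular"
        assert fv.pp_interval == pytest.approx(1.0, abs=0.01)

    def test_alternating_rr_is_irregular(self, make_spike_train):
        times, t = [], 0.5
        for i in range(10):
            times.append(t)
            t += 0.5 if i % 2 == 0 else 1.0
        fv = extract_features(make_spike_train(times, duration=10.0))
        assert fv.pp_label == "Irregular"

    def test_single_peak_has_undefined_interval_and_regular_label(self, make_spike_train):
        fv = extract_features(make_spike_train([2.0], duration=4.0))
        assert fv.peaks == 1
        assert fv.pp_interval is None
        assert fv.pp_label == "Regular"

    def test_flat_record_yields_zero_peaks(self):
        fv = extract_features(_flat_record(10.0))
        assert fv.peaks == 0
        assert fv.qrs_width is None
        assert fv.heart_rate == 0.0

    @pytest.mark.parametrize("name", PROFILE_NAMES)
    def test_profile_round_trip(self, name):
        """Noise-free synthesis of each class reproduces its printed targets."""
        prof, params = class_profile(name)
        rec = synthesize_ecg(params, duration=prof.excerpt_duration, fs=250.0)
        fv = extract_features(rec)
        if prof.target_peaks is not None:
            assert fv.peaks == prof.target_peaks
        if prof.target_qrs_width is not None:
            assert fv.qrs_width == pytest.approx(
                prof.target_qrs_width, abs=1.0 / rec.fs + 1e-9
            )
        if prof.target_st_elevated is not None:
            assert fv.st_elevated is prof.target_st_elevated
        assert fv.pp_label == prof.target_pp_label
        if prof.target_heart_rate is not None:
            assert fv.heart_rate == pytest.approx(prof.target_heart_rate)

    def test_determinism(self, basic_params):
        rec = synthesize_ecg(basic_params, duration=6.0, fs=250.0)
        assert extract_features(rec) == extract_features(rec)


class TestInvariances:
    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(scale=st.floats(min_value=0.05, max_value=20.0))
    def test_amplitude_scale_invariance(self, scale):
        prof, params = class_profile("sleep_apnea")
        rec = synthesize_ecg(params, duration=prof.excerpt_duration, fs=250.0)
        scaled = WaveformRecord("scaled", rec.fs, rec.duration, rec.v * scale)
        base, new = extract_features(rec), extract_features(scaled)
        assert new.peaks == base.peaks
        assert new.pp_label == base.pp_label
        assert new.qrs_width == pytest.approx(base.qrs_width, abs=1e-12)

    @pytest.mark.parametrize("name", ["sleep_apnea", "heart_failure", "normal_hr110"])
    def test_doubling_fs_preserves_peak_count(self, name):
        prof, params = class_profile(name)
        lo = extract_features(synthesize_ecg(params, prof.excerpt_duration, fs=250.0))
        hi = extract_features(synthesize_ecg(params, prof.excerpt_duration, fs=500.0))
        assert lo.peaks == hi.peaks
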