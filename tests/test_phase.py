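"""Detection-stage contracts: filters, TSEng, extrema, association, cycles."""
import itertools
import re

import numpy as np
import pytest

from dsp_spiro import (AudioRecording, DataError, DetectionParams, Envelope,
                       ImuRecording, ParameterError, RespiratoryEvent,
                       SimulationConfig, associate_extrema, detect_extrema,
                       detect_phases, extract_cycles, filter_valid_sessions,
                       simulate_session, simulate_subject_profiles)
from dsp_spiro.metrics import event_recall_precision
from dsp_spiro.phase import (compute_tseng, compute_tseng_raw,
                             preprocess_audio, preprocess_imu)

PARAMS = DetectionParams()


def _imu_from_z(z, rate=100.0):
    t = np.arange(len(z)) / rate
    zero = np.zeros(len(z))
    return ImuRecording(rate=rate, t=t, ax=zero, ay=zero, az=np.asarray(z))


class TestImuConditioning:
    def test_slow_sine_phase_preserved(self):
        rate, f = 100.0, 0.2
        t = np.arange(0, 30, 1 / rate)
        env = preprocess_imu(_imu_from_z(np.sin(2 * np.pi * f * t)), PARAMS)
        # peaks of the 0.2 Hz sine at 1.25, 6.25, ... must survive in place
        for peak_t in np.arange(1.25, 29, 5.0):
            win = (env.times > peak_t - 1) & (env.times < peak_t + 1)
            t_max = env.times[win][np.argmax(env.values[win])]
            assert abs(t_max - peak_t) <= 1.5 / env.rate

    def test_fast_sine_attenuated(self):
        rate = 100.0
        t = np.arange(0, 20, 1 / rate)
        env = preprocess_imu(_imu_from_z(np.sin(2 * np.pi * 10.0 * t)), PARAMS)
        interior = env.values[5:-5]
        assert (interior.max() - interior.min()) / 2 < 0.1

    def test_constant_passthrough(self):
        env = preprocess_imu(_imu_from_z(np.full(500, 0.37)), PARAMS)
        assert np.allclose(env.values, 0.37, atol=1e-9)

    def test_short_recording_rejected(self):
        with pytest.raises(DataError):
            preprocess_imu(_imu_from_z(np.zeros(30)), PARAMS)


class TestAudioConditioning:
    def test_dc_rejected(self):
        audio = AudioRecording(rate=8000.0, samples=np.full(8000, 0.5))
        out = preprocess_audio(audio, PARAMS)
        assert np.max(np.abs(out[500:-500])) < 1e-6 * 0.5

    def test_passband_tone_near_unity(self):
        rate = 8000.0
        t = np.arange(0, 2, 1 / rate)
        audio = AudioRecording(rate=rate, samples=np.sin(2 * np.pi * 400 * t))
        out = preprocess_audio(audio, PARAMS)[2000:-2000]
        gain = np.sqrt(np.mean(out ** 2)) * np.sqrt(2)
        assert 0.9 <= gain <= 1.0 + 1e-6

    def test_stopband_tone_attenuated(self):
        rate = 8000.0
        t = np.arange(0, 2, 1 / rate)
        audio = AudioRecording(rate=rate, samples=np.sin(2 * np.pi * 2000 * t))
        out = preprocess_audio(audio, PARAMS)[2000:-2000]
        assert np.sqrt(np.mean(out ** 2)) * np.sqrt(2) < 0.1

    def test_zero_phase_time_reversal(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(4000)
        fwd = preprocess_audio(AudioRecording(rate=8000.0, samples=x), PARAMS)
        rev = preprocess_audio(AudioRecording(rate=8000.0, samples=x[::-1]),
                               PARAMS)
        assert np.max(np.abs(fwd - rev[::-1])) < 1e-9

    def test_infeasible_band_rejected(self):
        audio = AudioRecording(rate=8000.0, samples=np.zeros(8000))
        with pytest.raises(ParameterError):
            preprocess_audio(audio, DetectionParams(audio_band=(50.0, 5000.0)))
        with pytest.raises(ParameterError):
            preprocess_audio(AudioRecording(rate=1500.0, samples=np.zeros(1500)),
                             PARAMS)


class TestTseng:
    def test_all_zero_input_floored(self):
        raw = compute_tseng_raw(np.zeros(5000), 8000.0, PARAMS)
        assert np.allclose(raw, np.log(PARAMS.log_floor))

    def test_iid_noise_matches_log_variance(self):
        """Interior mean of the raw TSEng of iid noise equals ln(sigma^2)."""
        rng = np.random.default_rng(7)
        sigma = 0.3
        x = sigma * rng.standard_normal(200_000)
        raw = compute_tseng_raw(x, 8000.0, PARAMS)
        w = int(round(PARAMS.tseng_window * 8000))
        assert abs(raw[w:-w].mean() - np.log(sigma ** 2)) < 0.05

    def test_gain_shifts_log_variance(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(4000)
        g = 3.0
        a = compute_tseng_raw(x, 8000.0, PARAMS)
        b = compute_tseng_raw(g * x, 8000.0, PARAMS)
        unfloored = a > np.log(PARAMS.log_floor) + 1e-9
        assert np.allclose(b[unfloored] - a[unfloored], 2 * np.log(g),
                           atol=1e-9)

    def test_envelope_rate_and_finiteness(self):
        rng = np.random.default_rng(9)
        env = compute_tseng(rng.standard_normal(80_000), 8000.0, PARAMS)
        assert env.rate == PARAMS.envelope_rate
        assert np.all(np.isfinite(env.values))


def brute_force_prominences(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Independent prominence computation by definition: for each strict
    local maximum, walk each side to the nearest higher sample, track the
    minimum along the way; prominence = peak - the higher of the two minima."""
    peaks, proms = [], []
    n = len(v)
    for i in range(1, n - 1):
        if not (v[i] > v[i - 1] and v[i] > v[i + 1]):
            continue
        left_min = v[i]
        j = i - 1
        while j >= 0 and v[j] <= v[i]:
            left_min = min(left_min, v[j])
            j -= 1
        right_min = v[i]
        j = i + 1
        while j < n and v[j] <= v[i]:
            right_min = min(right_min, v[j])
            j += 1
        peaks.append(i)
        proms.append(v[i] - max(left_min, right_min))
    return np.array(peaks, dtype=int), np.array(proms)


def oracle_extrema(values: np.ndarray, rate: float, params: DetectionParams
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force reimplementation of the prominence/spacing selection."""
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        return np.array([]), np.array([])
    thr = params.prominence_frac_iqr * iqr
    dist = params.min_peak_distance * rate

    def run(sig):
        idx, proms = brute_force_prominences(sig)
        keep = proms >= thr
        idx, proms = idx[keep], proms[keep]
        order = sorted(range(len(idx)), key=lambda k: (-proms[k], idx[k]))
        chosen = []
        for k in order:
            if all(abs(idx[k] - c) >= dist for c in chosen):
                chosen.append(idx[k])
        return np.sort(np.array(chosen)) / rate

    return run(values), run(-values)


class TestDetectExtrema:
    def test_pure_sine_extrema(self):
        t = np.arange(0, 60, 1 / 20.0)
        env = Envelope(rate=20.0, values=np.sin(2 * np.pi * t / 4.0),
                       kind="imu_z")
        maxima, minima = detect_extrema(env, PARAMS)
        expected = np.arange(1.0, 58.0, 4.0)
        assert len(maxima) == 15
        assert np.max(np.abs(maxima - expected)) <= 1 / 20.0 + 1e-9
        assert len(minima) == 15

    def test_min_distance_keeps_one_of_close_pair(self):
        rate = 20.0
        t = np.arange(0, 60, 1 / rate)
        v = 0.1 * np.sin(2 * np.pi * t / 10.0)
        v[(t > 28) & (t < 34)] = 0.0  # flat floor so the bumps tie exactly
        for peak_t in (30.0, 31.0):  # two equal peaks 1.0 s apart
            v += 2.0 * np.clip(1 - np.abs(t - peak_t) / 0.25, 0, None)
        maxima, _ = detect_extrema(Envelope(rate=rate, values=v, kind="tseng"),
                                   PARAMS)
        close = maxima[(maxima > 29) & (maxima < 32)]
        assert len(close) == 1
        assert abs(close[0] - 30.0) < 0.1  # tie broken to the earlier peak

    def test_prominence_threshold_gates_bumps(self):
        rate = 20.0
        t = np.arange(0, 120, 1 / rate)
        base = np.sin(2 * np.pi * t / 8.0)  # IQR approx 1.41
        q75, q25 = np.percentile(base, [75, 25])
        iqr = q75 - q25
        v = base.copy()
        descending = 30.0  # mid-descent of a sine cycle
        v += 0.1 * iqr * np.clip(1 - np.abs(t - descending) / 0.2, 0, None)
        v += 0.3 * iqr * np.clip(1 - np.abs(t - descending - 40) / 0.2, 0, None)
        maxima, _ = detect_extrema(Envelope(rate=rate, values=v, kind="tseng"),
                                   PARAMS)
        assert not np.any(np.abs(maxima - descending) < 0.3)
        assert np.any(np.abs(maxima - (descending + 40)) < 0.3)

    def test_matches_brute_force_oracle(self):
        """Exhaustive prominence/spacing oracle agreement on 30 random
        smooth signals of <= 200 samples."""
        rng = np.random.default_rng(11)
        for trial in range(30):
            n = int(rng.integers(60, 201))
            v = np.cumsum(rng.standard_normal(n))
            v = np.convolve(v, np.ones(5) / 5, mode="same")
            v += 1e-9 * rng.standard_normal(n)  # break exact ties
            env = Envelope(rate=20.0, values=v, kind="imu_z")
            got_max, got_min = detect_extrema(env, PARAMS)
            exp_max, exp_min = oracle_extrema(v, 20.0, PARAMS)
            assert np.allclose(got_max, exp_max), f"trial {trial}"
            assert np.allclose(got_min, exp_min), f"trial {trial}"

    def test_constant_envelope_empty(self):
        env = Envelope(rate=20.0, values=np.full(200, 1.0), kind="imu_z")
        maxima, minima = detect_extrema(env, PARAMS)
        assert len(maxima) == 0 and len(minima) == 0


class TestAssociation:
    def test_within_window_pairing(self):
        ev = associate_extrema([10.0], [], [10.4], PARAMS)
        assert len(ev) == 1
        assert ev[0].label == "inspiration_start" and ev[0].time == 10.0
        assert ev[0].tseng_minimum_time == 10.4

    def test_window_exceeded_drops_event(self):
        assert associate_extrema([10.0], [], [11.5], PARAMS) == []

    def test_nearest_first_greedy(self):
        ev = associate_extrema([9.8, 10.3], [], [10.2], PARAMS)
        assert [e.time for e in ev] == [10.3]

    def test_greedy_matches_enumeration_oracle(self):
        """Independent nearest-first assignment on random configurations."""
        rng = np.random.default_rng(13)
        for _ in range(50):
            imu_min = np.sort(rng.uniform(0, 30, rng.integers(1, 6)))
            tseng_min = np.sort(rng.uniform(0, 30, rng.integers(1, 6)))
            got = {e.time for e in associate_extrema(imu_min, [], tseng_min,
                                                     PARAMS)}
            # oracle: repeatedly take the globally closest unused pair
            pool = [(abs(a - b), a, b) for a in imu_min for b in tseng_min
                    if abs(a - b) <= PARAMS.association_window]
            expected, used_a, used_b = set(), set(), set()
            for d, a, b in sorted(pool):
                if a not in used_a and b not in used_b:
                    used_a.add(a)
                    used_b.add(b)
                    expected.add(a)
            assert got == expected

    def test_maxima_become_expirations(self):
        ev = associate_extrema([10.0], [12.0], [10.1], PARAMS)
        assert [e.label for e in ev] == ["inspiration_start",
                                        "expiration_start"]
        strict = DetectionParams(strict_expiration=True)
        ev2 = associate_extrema([10.0], [20.0], [10.1], strict)
        assert [e.label for e in ev2] == ["inspiration_start"]


def _events(pattern: str) -> list:
    return [RespiratoryEvent(time=float(i),
                             label=("inspiration_start" if c == "I"
                                    else "expiration_start"),
                             imu_extremum_time=float(i))
            for i, c in enumerate(pattern)]


class TestExtractCycles:
    def test_minimal_valid_pattern(self):
        ev = [RespiratoryEvent(0.0, "inspiration_start", 0.0),
              RespiratoryEvent(2.0, "expiration_start", 2.0),
              RespiratoryEvent(5.0, "inspiration_start", 5.0)]
        (cyc,) = extract_cycles(ev)
        assert cyc.insp == (0.0, 2.0) and cyc.exp == (2.0, 5.0)

    def test_repeated_inspiration_invalidates_first(self):
        cycles = extract_cycles(_events("IIEI"))
        assert len(cycles) == 1
        assert cycles[0].insp == (1.0, 2.0)

    def test_exhaustive_pattern_oracle(self):
        """All inspiration/expiration strings up to length 12 agree with a
        regex scan for overlapping I-E-I triplets."""
        for n in range(0, 13):
            for combo in itertools.product("IE", repeat=n):
                s = "".join(combo)
                got = extract_cycles(_events(s))
                starts = [m.start() for m in re.finditer(r"(?=IEI)", s)]
                assert len(got) == len(starts), s
                for cyc, i in zip(got, starts):
                    assert cyc.insp == (float(i), float(i + 1))
                    assert cyc.exp == (float(i + 1), float(i + 2))

    def test_output_ordered_nonoverlapping(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            s = "".join(rng.choice(list("IE"), size=rng.integers(0, 15)))
            cycles = extract_cycles(_events(s))
            for a, b in zip(cycles, cycles[1:]):
                assert a.insp[0] < b.insp[0]
                assert a.exp[1] <= b.insp[1]


class TestEndToEnd:
    def test_clean_session_recovers_annotation(self, clean_session,
                                               clean_detection):
        cycles, events, _ = clean_detection
        assert len(cycles) == 5
        ann_i, ann_e = clean_session.annotation.event_times()
        det_i = [e.time for e in events if e.label == "inspiration_start"]
        det_e = [e.time for e in events if e.label == "expiration_start"]
        recall, precision = event_recall_precision(det_i, det_e, ann_i, ann_e)
        assert recall >= 0.95 and precision >= 0.95
        for cyc, (t0, t1, _) in zip(cycles, clean_session.annotation.cycles):
            assert abs(cyc.insp[0] - t0) <= 0.5
            assert abs(cyc.insp[1] - t1) <= 0.5

    def test_flat_session_yields_no_cycles(self):
        cfg = SimulationConfig(seed=1, snr_db=np.inf, audio_amp=0.0,
                               imu_amp_g=0.0, imu_drift_g=0.0)
        prof = simulate_subject_profiles(cfg)[0]
        sess = simulate_session(prof, "forceful", 3, cfg, seed=5)
        cycles, events, _ = detect_phases(sess, PARAMS)
        assert cycles == [] and events == []

    def test_deterministic(self, clean_session):
        c1, e1, _ = detect_phases(clean_session, PARAMS)
        c2, e2, _ = detect_phases(clean_session, PARAMS)
        assert c1 == c2 and e1 == e2


class TestFilterValidSessions:
    def test_threshold_and_partition(self):
        mk = lambda n: extract_cycles(_events("IE" * n + "I"))
        results = {"a": mk(2), "b": mk(3), "c": mk(0), "d": mk(5)}
        retained, rejected = filter_valid_sessions(results, PARAMS)
        assert set(retained) == {"b", "d"}
        assert set(rejected) == {"a", "c"}
        assert set(retained) | set(rejected) == set(results)
        assert not set(retained) & set(rejected)
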