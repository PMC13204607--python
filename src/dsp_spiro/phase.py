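"""Respiratory phase detection from tracheal sound energy and chest motion.

Pipeline: the IMU Z-axis is zero-phase low-pass filtered at 5 Hz
(second-order Butterworth), smoothed with moving median and mean windows,
and resampled to a 20 Hz envelope. The audio is zero-phase band-pass
filtered to 50-1000 Hz; tracheal sound energy (TSEng) is the log of the
moving variance over a 20 ms sliding window, low-pass filtered at 2 Hz and
conditioned onto the same 20 Hz grid. Local extrema of both envelopes are
found by prominence (20% of the envelope's interquartile range) and spacing
(>= 1.5 s) criteria. IMU minima that align with a TSEng minimum within
+-1 s are labeled inspiration onsets; IMU maxima are expiration onsets. A
valid breath cycle is an inspiration onset followed by an expiration onset
followed by the next inspiration onset, with no intervening events.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.ndimage import median_filter, uniform_filter1d

from .errors import DataError, ParameterError
from .types import (AudioRecording, BreathCycle, Envelope, ImuRecording,
                    RespiratoryEvent, Session)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionParams:
    audio_band: tuple[float, float] = (50.0, 1000.0)
    tseng_window: float = 0.020       # s, moving-variance window
    tseng_lowpass: float = 2.0        # Hz
    imu_lowpass: float = 5.0          # Hz
    butter_order: int = 2
    envelope_rate: float = 20.0       # Hz
    min_peak_distance: float = 1.5    # s
    prominence_frac_iqr: float = 0.20
    association_window: float = 1.0   # s
    median_window: float = 0.5        # s
    mean_window: float = 0.5          # s
    min_valid_cycles: int = 3
    log_floor: float = 1e-12
    strict_expiration: bool = False   # require TSEng confirmation for maxima too
    imu_polarity: int = 1             # -1 flips min/max labeling convention

    def __post_init__(self) -> None:
        if not (0 < self.audio_band[0] < self.audio_band[1]):
            raise ParameterError("audio_band must satisfy 0 < low < high")
        for name in ("tseng_window", "tseng_lowpass", "imu_lowpass",
                     "envelope_rate", "min_peak_distance",
                     "prominence_frac_iqr", "association_window",
                     "median_window", "mean_window", "log_floor"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


def _zero_phase(b: np.ndarray, a: np.ndarray, x: np.ndarray,
                rate: float, lowest_pole_hz: float) -> np.ndarray:
    """Forward-backward filtering with Gustafsson initial conditions, which
    make the result exactly symmetric under time reversal (padding-based
    edge handling is not, for lightly damped low-frequency poles)."""
    n = len(x)
    irlen = int(6.0 * rate / lowest_pole_hz)
    if n <= 3 * max(len(a), len(b)) + 1:
        raise DataError("signal too short for zero-phase filtering")
    if irlen >= n - 1:
        irlen = None  # exact solve; cheap for short signals
    return sps.filtfilt(b, a, x, method="gust", irlen=irlen)


def _odd_window(duration_s: float, rate: float) -> int:
    w = max(1, int(round(duration_s * rate)))
    return w if w % 2 == 1 else w + 1


def _smooth(values: np.ndarray, rate: float, params: DetectionParams) -> np.ndarray:
    """Moving median then moving average, edge-replicated."""
    med_w = _odd_window(params.median_window, rate)
    mean_w = max(1, int(round(params.mean_window * rate)))
    out = median_filter(values, size=med_w, mode="nearest")
    return uniform_filter1d(out, size=mean_w, mode="nearest")


def _resample_uniform(values: np.ndarray, rate: float, t0: float,
                      target_rate: float) -> tuple[np.ndarray, float]:
    """Linear interpolation onto a uniform target-rate grid starting at t0."""
    t_src = t0 + np.arange(len(values)) / rate
    n_out = max(2, int(np.floor((t_src[-1] - t0) * target_rate)) + 1)
    t_out = t0 + np.arange(n_out) / target_rate
    return np.interp(t_out, t_src, values), t0


def preprocess_imu(imu: ImuRecording, params: DetectionParams | None = None) -> Envelope:
    """Condition the Z-axis into a 20 Hz respiration envelope."""
    params = params or DetectionParams()
    if imu.rate <= 2 * params.imu_lowpass:
        raise ParameterError("IMU rate must exceed twice the low-pass cutoff")
    settle = 1.0 / params.imu_lowpass
    if (imu.t_end - imu.t0) < 3 * settle:
        raise DataError("IMU recording shorter than 3x the filter settling length")
    b, a = sps.butter(params.butter_order, params.imu_lowpass, btype="lowpass",
                      fs=imu.rate)
    z = _zero_phase(b, a, params.imu_polarity * imu.az, imu.rate,
                    params.imu_lowpass)
    z = _smooth(z, imu.rate, params)
    values, t0 = _resample_uniform(z, imu.rate, imu.t0, params.envelope_rate)
    return Envelope(rate=params.envelope_rate, values=values, kind="imu_z", t0=t0)


def preprocess_audio(audio: AudioRecording,
                     params: DetectionParams | None = None) -> np.ndarray:
    """Zero-phase band-pass (DC-rejecting) filtering of the raw audio."""
    params = params or DetectionParams()
    lo, hi = params.audio_band
    if audio.rate <= 2000:
        raise ParameterError("audio rate must exceed 2000 Hz")
    if hi >= audio.rate / 2:
        raise ParameterError("audio_band high edge must be below Nyquist")
    b, a = sps.butter(params.butter_order, [lo, hi], btype="bandpass",
                      fs=audio.rate)
    return _zero_phase(b, a, audio.samples, audio.rate, lo)


def compute_tseng_raw(filtered_audio: np.ndarray, rate: float,
                      params: DetectionParams | None = None) -> np.ndarray:
    """Log moving variance at audio rate: centered window, shrinking at edges,
    variance floored before the log."""
    params = params or DetectionParams()
    x = np.asarray(filtered_audio, dtype=float)
    w = int(round(params.tseng_window * rate))
    if w < 2:
        raise ParameterError("variance window must span at least 2 samples")
    n = len(x)
    half = w // 2
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    i = np.arange(n)
    start = np.maximum(0, i - half)
    end = np.minimum(n, i - half + w)
    cnt = (end - start).astype(float)
    mean = (c1[end] - c1[start]) / cnt
    var = (c2[end] - c2[start]) / cnt - mean ** 2
    var = np.maximum(var, 0.0)
    return np.log(np.maximum(var, params.log_floor))


def compute_tseng(filtered_audio: np.ndarray, rate: float,
                  params: DetectionParams | None = None,
                  t0: float = 0.0) -> Envelope:
    """Full TSEng envelope: log moving variance, 2 Hz zero-phase low-pass,
    resampled to the 20 Hz grid and median/mean smoothed."""
    params = params or DetectionParams()
    raw = compute_tseng_raw(filtered_audio, rate, params)
    # block-average decimation to ~200 Hz before the 2 Hz low-pass: its
    # impulse response spans seconds, which is intractable to solve exactly
    # at audio rate and invisible at the 20 Hz envelope stage
    m = max(1, int(round(rate / 200.0)))
    n_blocks = len(raw) // m
    if n_blocks < 10:
        raise DataError("audio too short for envelope estimation")
    dec = raw[: n_blocks * m].reshape(n_blocks, m).mean(axis=1)
    rate_d = rate / m
    t_src = t0 + (np.arange(n_blocks) * m + (m - 1) / 2.0) / rate
    b, a = sps.butter(params.butter_order, params.tseng_lowpass,
                      btype="lowpass", fs=rate_d)
    smooth = _zero_phase(b, a, dec, rate_d, params.tseng_lowpass)
    n_out = max(2, int(np.floor((t_src[-1] - t0) * params.envelope_rate)) + 1)
    t_out = t0 + np.arange(n_out) / params.envelope_rate
    values = np.interp(t_out, t_src, smooth)
    values = _smooth(values, params.envelope_rate, params)
    return Envelope(rate=params.envelope_rate, values=values, kind="tseng", t0=t0)


def _candidate_peaks(values: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    idx, props = sps.find_peaks(values, prominence=max(threshold, 0.0))
    return idx, props["prominences"]


def detect_extrema(env: Envelope, params: DetectionParams | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(maxima times, minima times) by prominence and minimum-spacing rules.

    Candidates must have prominence >= prominence_frac_iqr * IQR(envelope);
    the spacing rule keeps the higher-prominence peak (ties: the earlier
    one). A constant envelope (zero IQR) yields no extrema.
    """
    params = params or DetectionParams()
    v = env.values
    if len(v) <= params.min_peak_distance * env.rate:
        raise DataError("envelope shorter than the minimum peak distance")
    q75, q25 = np.percentile(v, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        logger.warning("constant envelope (IQR=0): no extrema detected")
        return np.array([]), np.array([])
    threshold = params.prominence_frac_iqr * iqr
    min_dist = params.min_peak_distance * env.rate

    def select(sig: np.ndarray) -> np.ndarray:
        idx, prom = _candidate_peaks(sig, threshold)
        order = np.lexsort((idx, -prom))  # prominence desc, then earlier
        chosen: list[int] = []
        for j in order:
            if all(abs(idx[j] - c) >= min_dist for c in chosen):
                chosen.append(idx[j])
        return np.sort(np.array(chosen, dtype=int))

    maxima = select(v)
    minima = select(-v)
    return env.t0 + maxima / env.rate, env.t0 + minima / env.rate


def associate_extrema(imu_min: np.ndarray, imu_max: np.ndarray,
                      tseng_min: np.ndarray,
                      params: DetectionParams | None = None
                      ) -> list[RespiratoryEvent]:
    """Label events from already-detected extremum times.

    Pairing is nearest-first greedy within the +-association_window, each
    TSEng minimum used at most once; ties go to the earlier IMU minimum.
    Unpaired IMU minima are dropped. With ``strict_expiration``, maxima also
    require a TSEng minimum within the window (the expiratory turnaround).
    """
    params = params or DetectionParams()
    imu_min = np.asarray(imu_min, dtype=float)
    imu_max = np.asarray(imu_max, dtype=float)
    tseng_min = np.asarray(tseng_min, dtype=float)
    events: list[RespiratoryEvent] = []
    pairs = []
    for i, tm in enumerate(imu_min):
        for j, ts in enumerate(tseng_min):
            dt = abs(tm - ts)
            if dt <= params.association_window:
                pairs.append((dt, tm, i, j))
    pairs.sort(key=lambda p: (p[0], p[1]))
    used_imu: set[int] = set()
    used_tseng: set[int] = set()
    for dt, tm, i, j in pairs:
        if i in used_imu or j in used_tseng:
            continue
        used_imu.add(i)
        used_tseng.add(j)
        events.append(RespiratoryEvent(time=float(tm), label="inspiration_start",
                                       imu_extremum_time=float(tm),
                                       tseng_minimum_time=float(tseng_min[j])))
    for tm in imu_max:
        if params.strict_expiration:
            if not (len(tseng_min) and
                    np.min(np.abs(tseng_min - tm)) <= params.association_window):
                continue
        events.append(RespiratoryEvent(time=float(tm), label="expiration_start",
                                       imu_extremum_time=float(tm)))
    events.sort(key=lambda e: e.time)
    return events


def associate_events(imu_env: Envelope, tseng_env: Envelope,
                     params: DetectionParams | None = None
                     ) -> list[RespiratoryEvent]:
    """Detect extrema on both envelopes and label respiratory events:
    IMU minima aligned with a TSEng minimum become inspiration onsets, IMU
    maxima expiration onsets."""
    params = params or DetectionParams()
    imu_max, imu_min = detect_extrema(imu_env, params)
    _, tseng_min = detect_extrema(tseng_env, params)
    return associate_extrema(imu_min, imu_max, tseng_min, params)


def extract_cycles(events: Sequence[RespiratoryEvent]) -> list[BreathCycle]:
    """Valid cycles: consecutive inspiration -> expiration -> inspiration
    triplets; the closing inspiration may open the next cycle."""
    labels = [e.label for e in events]
    times = [e.time for e in events]
    cycles: list[BreathCycle] = []
    for i in range(len(events) - 2):
        if (labels[i] == "inspiration_start"
                and labels[i + 1] == "expiration_start"
                and labels[i + 2] == "inspiration_start"):
            cycles.append(BreathCycle(insp=(times[i], times[i + 1]),
                                      exp=(times[i + 1], times[i + 2])))
    return cycles


def detect_phases(session: Session, params: DetectionParams | None = None
                  ) -> tuple[list[BreathCycle], list[RespiratoryEvent],
                             dict[str, object]]:
    """Full detection on one session; intermediates returned for QC plots."""
    params = params or DetectionParams()
    imu_env = preprocess_imu(session.imu, params)
    filtered = preprocess_audio(session.audio, params)
    tseng = compute_tseng(filtered, session.audio.rate, params,
                          t0=session.audio.t0)
    events = associate_events(imu_env, tseng, params)
    cycles = extract_cycles(events)
    envelopes = {"imu_z": imu_env, "tseng": tseng, "audio_filtered": filtered}
    return cycles, events, envelopes


def filter_valid_sessions(results: Mapping[object, Sequence[BreathCycle]],
                          params: DetectionParams | None = None
                          ) -> tuple[dict, dict]:
    """Partition sessions by the minimum-valid-cycle rule (default >= 3)."""
    params = params or DetectionParams()
    retained, rejected = {}, {}
    for key, cycles in results.items():
        (retained if len(cycles) >= params.min_valid_cycles else rejected)[key] = cycles
    logger.info("retained %d / %d sessions with >= %d valid cycles",
                len(retained), len(results), params.min_valid_cycles)
    return retained, rejected
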