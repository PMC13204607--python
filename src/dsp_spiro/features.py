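"""Per-breath feature extraction: MFCC summaries, IMU ranges, envelope timing.

Each valid breath cycle yields exactly 185 named features:

* 78 acoustic features per phase x 2 phases = 156
  (13 MFCCs x 3 orders {static, d1, d2} x 2 stats {mean, std})
* 6 IMU range features per phase x 2 phases = 12
  (3 axes x {peak-to-peak, P95-P5})
* 17 envelope/timing features
  (per phase: duration, TSEng mean/std/max/area, audio RMS, audio
  zero-crossing rate; cycle level: total duration, inspiratory duty
  fraction, TSEng area ratio expiration/inspiration)

MFCCs follow the common recipe: Hamming window, power spectrum, HTK-mel
triangular filterbank, log with floor, orthonormal type-II DCT, coefficients
c0..c12. Deltas are regression derivatives with replicated edge frames.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.fft import dct, rfft

from .errors import DataError, ParameterError
from .types import BreathCycle, Envelope, ImuRecording, Session

logger = logging.getLogger(__name__)

PHASES = ("insp", "exp")
MFCC_ORDERS = ("static", "d1", "d2")
AXES = ("x", "y", "z")

#: acoustic per-phase base names (78)
_MFCC_BASE = [
    f"mfcc_{order}_c{k:02d}_{stat}"
    for order in MFCC_ORDERS
    for k in range(13)
    for stat in ("mean", "std")
]
#: IMU per-phase base names (6)
_IMU_BASE = [f"acc_{ax}_{meas}" for ax in AXES for meas in ("p2p", "rng90")]
#: cycle-level timing/envelope names (17)
_TIMING_NAMES = (
    [f"{ph}_{b}" for ph in PHASES for b in (
        "duration_s", "tseng_mean", "tseng_std", "tseng_max", "tseng_area",
        "audio_rms", "audio_zcr")]
    + ["cycle_duration_s", "insp_duty_frac", "tseng_area_ratio"]
)

#: canonical, ordered 185-feature inventory
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{ph}_{b}" for ph in PHASES for b in _MFCC_BASE]
    + [f"{ph}_{b}" for ph in PHASES for b in _IMU_BASE]
    + _TIMING_NAMES
)
assert len(FEATURE_NAMES) == 185
assert len(set(FEATURE_NAMES)) == 185

COVARIATE_COLUMNS = ("age", "sex_male", "bmi", "eth_asian", "eth_southeast_asian", "eth_other")
TARGET_COLUMNS = ("fvc_ref", "fev1_ref", "pef_ref")
INDEX_TO_TARGET = {"fvc": "fvc_ref", "fev1": "fev1_ref", "pef": "pef_ref"}

#: chest-motion modality: accelerometer ranges plus phase timing (timing is
#: derived from the motion-defined segmentation); everything else is
#: tracheal-sound derived.
IMU_GROUP: tuple[str, ...] = tuple(
    n for n in FEATURE_NAMES
    if "acc_" in n or n in ("insp_duration_s", "exp_duration_s",
                            "cycle_duration_s", "insp_duty_frac")
)
ACOUSTIC_GROUP: tuple[str, ...] = tuple(n for n in FEATURE_NAMES if n not in IMU_GROUP)
assert len(IMU_GROUP) + len(ACOUSTIC_GROUP) == 185


@dataclass(frozen=True)
class MfccParams:
    n_coeffs: int = 13
    frame_len: float = 0.025   # s
    hop: float = 0.010         # s
    n_mels: int = 26
    fft_size: Optional[int] = None   # next power of two >= frame if None
    mel_fmin: float = 0.0
    mel_fmax: Optional[float] = None  # rate/2 if None
    log_floor: float = 1e-10
    window: str = "hamming"
    delta_halfwidth: int = 2
    include_c0: bool = True    # False -> keep c1..c13 instead

    def __post_init__(self) -> None:
        if self.n_coeffs > self.n_mels:
            raise ParameterError("n_coeffs must be <= n_mels")
        if not (self.frame_len > self.hop > 0):
            raise ParameterError("require frame_len > hop > 0")


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, rate: float,
                   fmin: float, fmax: float) -> np.ndarray:
    """Triangular HTK-mel filterbank as an (n_mels, n_fft//2+1) weight matrix."""
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = np.asarray(_mel_to_hz(mel_pts))
    bin_freqs = np.arange(n_fft // 2 + 1) * rate / n_fft
    fb = np.zeros((n_mels, len(bin_freqs)))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (bin_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - bin_freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _frame_signal(x: np.ndarray, frame: int, hop: int) -> np.ndarray:
    n_frames = (len(x) - frame) // hop + 1
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def compute_mfcc(segment: np.ndarray, rate: float, params: MfccParams | None = None) -> np.ndarray:
    """Static MFCC matrix (frames x n_coeffs) for one audio segment."""
    params = params or MfccParams()
    x = np.asarray(segment, dtype=float)
    frame = int(round(params.frame_len * rate))
    hop = int(round(params.hop * rate))
    if len(x) < frame:
        raise DataError(f"segment of {len(x)} samples shorter than one {frame}-sample frame")
    n_fft = params.fft_size or int(2 ** np.ceil(np.log2(frame)))
    fmax = params.mel_fmax if params.mel_fmax is not None else rate / 2.0
    frames = _frame_signal(x, frame, hop)
    if params.window == "hamming":
        win = np.hamming(frame)
    else:
        raise ParameterError(f"unsupported window {params.window!r}")
    spectrum = np.abs(rfft(frames * win, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(params.n_mels, n_fft, rate, params.mel_fmin, fmax)
    mel_energy = spectrum @ fb.T
    log_mel = np.log(np.maximum(mel_energy, params.log_floor))
    cep = dct(log_mel, type=2, norm="ortho", axis=1)
    if params.include_c0:
        return cep[:, : params.n_coeffs]
    return cep[:, 1 : params.n_coeffs + 1]


def compute_delta(m: np.ndarray, params: MfccParams | None = None) -> np.ndarray:
    """Regression delta of a (frames x coeffs) matrix; edges replicated."""
    params = params or MfccParams()
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ParameterError("expected a 2-D frame matrix")
    n = m.shape[0]
    if n == 1:
        return np.zeros_like(m)
    K = params.delta_halfwidth
    padded = np.pad(m, ((K, K), (0, 0)), mode="edge")
    denom = 2.0 * sum(k * k for k in range(1, K + 1))
    out = np.zeros_like(m)
    for k in range(1, K + 1):
        out += k * (padded[K + k : K + k + n] - padded[K - k : K - k + n])
    return out / denom


def summarize_mfcc(segment: np.ndarray, rate: float,
                   params: MfccParams | None = None) -> dict[str, float]:
    """78 features: mean and SD per coefficient for static, delta, delta-delta."""
    params = params or MfccParams()
    static = compute_mfcc(segment, rate, params)
    mats = {"static": static,
            "d1": compute_delta(static, params)}
    mats["d2"] = compute_delta(mats["d1"], params)
    out: dict[str, float] = {}
    for order in MFCC_ORDERS:
        mat = mats[order]
        means = mat.mean(axis=0)
        sds = mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros(mat.shape[1])
        for k in range(params.n_coeffs):
            out[f"mfcc_{order}_c{k:02d}_mean"] = float(means[k])
            out[f"mfcc_{order}_c{k:02d}_std"] = float(sds[k])
    return out


def imu_range_features(imu: ImuRecording, interval: tuple[float, float]) -> dict[str, float]:
    """Peak-to-peak and robust (P95-P5) range per axis over [t0, t1)."""
    t0, t1 = interval
    mask = (imu.t >= t0) & (imu.t < t1)
    if not mask.any():
        raise DataError(f"no IMU samples in [{t0}, {t1})")
    out: dict[str, float] = {}
    for ax_name, series in zip(AXES, (imu.ax, imu.ay, imu.az)):
        seg = series[mask]
        out[f"acc_{ax_name}_p2p"] = float(seg.max() - seg.min())
        p5, p95 = np.percentile(seg, [5, 95])  # linear-interpolation quantiles
        out[f"acc_{ax_name}_rng90"] = float(p95 - p5)
    return out


def _zcr_per_second(x: np.ndarray, rate: float) -> float:
    if len(x) < 2:
        return 0.0
    crossings = int(np.count_nonzero(np.diff(np.signbit(x))))
    return crossings * rate / len(x)


def envelope_timing_features(cycle: BreathCycle, tseng: Envelope,
                             audio_filtered: np.ndarray, audio_rate: float,
                             audio_t0: float = 0.0) -> dict[str, float]:
    """17 envelope/timing features for one cycle."""
    out: dict[str, float] = {}
    areas: dict[str, float] = {}
    env_end = tseng.t0 + len(tseng.values) / tseng.rate
    if cycle.exp[1] > env_end + 1.0 / tseng.rate:
        raise DataError("cycle extends past the envelope")
    for ph, (a, b) in zip(PHASES, (cycle.insp, cycle.exp)):
        tt = tseng.times
        seg = tseng.values[(tt >= a) & (tt < b)]
        if len(seg) == 0:
            raise DataError(f"no envelope samples in {ph} phase [{a}, {b})")
        i0 = max(0, int(round((a - audio_t0) * audio_rate)))
        i1 = max(i0 + 1, int(round((b - audio_t0) * audio_rate)))
        aud = audio_filtered[i0:i1]
        out[f"{ph}_duration_s"] = b - a
        out[f"{ph}_tseng_mean"] = float(seg.mean())
        out[f"{ph}_tseng_std"] = float(seg.std(ddof=1)) if len(seg) > 1 else 0.0
        out[f"{ph}_tseng_max"] = float(seg.max())
        areas[ph] = float(np.trapezoid(seg, dx=1.0 / tseng.rate))
        out[f"{ph}_tseng_area"] = areas[ph]
        out[f"{ph}_audio_rms"] = float(np.sqrt(np.mean(aud ** 2))) if len(aud) else 0.0
        out[f"{ph}_audio_zcr"] = _zcr_per_second(aud, audio_rate)
    out["cycle_duration_s"] = cycle.duration
    out["insp_duty_frac"] = cycle.insp_duration / cycle.duration
    out["tseng_area_ratio"] = areas["exp"] / areas["insp"] if areas["insp"] != 0 else 0.0
    return out


def assemble_feature_vector(cycle: BreathCycle, session: Session,
                            tseng: Envelope, audio_filtered: np.ndarray,
                            params: MfccParams | None = None) -> dict[str, float]:
    """Concatenate the full 185-feature vector for one cycle, in canonical order."""
    params = params or MfccParams()
    rate = session.audio.rate
    vec: dict[str, float] = {}
    for ph, (a, b) in zip(PHASES, (cycle.insp, cycle.exp)):
        i0 = max(0, int(round((a - session.audio.t0) * rate)))
        i1 = max(i0 + 1, int(round((b - session.audio.t0) * rate)))
        seg = audio_filtered[i0:i1]
        for name, val in summarize_mfcc(seg, rate, params).items():
            vec[f"{ph}_{name}"] = val
    for ph, (a, b) in zip(PHASES, (cycle.insp, cycle.exp)):
        for name, val in imu_range_features(session.imu, (a, b)).items():
            vec[f"{ph}_{name}"] = val
    vec.update(envelope_timing_features(cycle, tseng, audio_filtered,
                                        rate, session.audio.t0))
    ordered = {name: vec[name] for name in FEATURE_NAMES}
    if len(ordered) != 185:
        raise DataError("feature vector does not match the 185-name inventory")
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise DataError(f"non-finite features: {bad[:5]}")
    return ordered


def covariate_row(profile) -> dict[str, float]:
    """Model covariates: age, sex (male=1), BMI, ethnicity one-hot (ref Caucasian)."""
    return {
        "age": float(profile.age),
        "sex_male": 1.0 if profile.sex == "male" else 0.0,
        "bmi": float(profile.bmi),
        "eth_asian": 1.0 if profile.ethnicity == "Asian" else 0.0,
        "eth_southeast_asian": 1.0 if profile.ethnicity == "Southeast Asian" else 0.0,
        "eth_other": 1.0 if profile.ethnicity == "Other" else 0.0,
    }


def build_feature_table(items: Sequence[tuple[Session, tuple]],
                        params: MfccParams | None = None,
                        min_valid_cycles: int = 3) -> pd.DataFrame:
    """One row per valid cycle across sessions; subjects below the cycle
    minimum are excluded entirely.

    ``items`` pairs each Session with its detection result
    (cycles, events, envelopes) as returned by ``phase.detect_phases``.
    """
    params = params or MfccParams()
    rows = []
    for session, (cycles, _events, envs) in items:
        if len(cycles) < min_valid_cycles:
            logger.info("session %s/%s excluded: %d < %d valid cycles",
                        session.subject_id, session.mode, len(cycles), min_valid_cycles)
            continue
        prof = session.profile
        for field in ("age", "sex", "bmi", "ethnicity", "fvc_ref", "fev1_ref", "pef_ref"):
            if getattr(prof, field, None) is None:
                raise DataError(f"subject {session.subject_id}: missing profile field {field}")
        cov = covariate_row(prof)
        kept = []
        for i, cyc in enumerate(cycles):
            try:
                vec = assemble_feature_vector(cyc, session, envs["tseng"],
                                              envs["audio_filtered"], params)
            except DataError as exc:
                logger.warning("dropping cycle %d of %s: %s", i, session.subject_id, exc)
                continue
            row = {"subject_id": session.subject_id,
                   "cycle_id": f"{session.subject_id}_{session.mode}_{i}",
                   "mode": session.mode}
            row.update(vec)
            row.update(cov)
            row.update({"fvc_ref": prof.fvc_ref, "fev1_ref": prof.fev1_ref,
                        "pef_ref": prof.pef_ref})
            kept.append(row)
        if len(kept) >= min_valid_cycles:
            rows.extend(kept)
    columns = (["subject_id", "cycle_id", "mode"] + list(FEATURE_NAMES)
               + list(COVARIATE_COLUMNS) + list(TARGET_COLUMNS))
    return pd.DataFrame(rows, columns=columns)
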