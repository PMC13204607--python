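"""Synthetic multimodal recordings and cohorts with known ground truth.

The generator emulates the study conditions end to end: a healthy-adult
cohort whose demographic and spirometric moments match the published
participant table; breath timelines for the two maneuver types (low-effort:
slow deep inhalation with gentle nasal exhalation; forceful: deep inhalation
with a sharp, rapid mouth exhalation); tracheal audio as band-limited
(50-1000 Hz, extra energy 800-1000 Hz) noise amplitude-modulated by a smooth
airflow envelope; and quasi-periodic chest-wall Z-acceleration whose minima
sit at inspiration onsets and maxima at expiration onsets, with drift,
broadband noise, and optional motion-artifact spikes.

Cohort draws use truncated normals whose underlying location/scale are
moment-matched so the *truncated* distribution reproduces the configured
mean/SD (naive truncation would bias, e.g., mean age upward by ~0.5 y).
Every generator is a pure function of its configuration and seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .errors import ParameterError
from .features import (COVARIATE_COLUMNS, FEATURE_NAMES, INDEX_TO_TARGET,
                       TARGET_COLUMNS, covariate_row)
from .types import (AudioRecording, BreathTimeline, ImuRecording, MODES,
                    Session, SubjectProfile)

#: published cohort moments (mean, SD) and category frequencies
DEFAULT_COHORT_PARAMS: dict = {
    "age": (30.3, 6.7),
    "bmi": (23.9, 3.3),
    "fvc": (4.0, 1.1),
    "fev1": (3.2, 0.7),
    "pef": (6.9, 1.7),
    "male_prop": 8 / 18,
    "ethnicity_probs": {"Asian": 6 / 18, "Caucasian": 8 / 18,
                        "Southeast Asian": 1 / 18, "Other": 3 / 18},
}

#: physical lower bounds for cohort draws
TRUNCATION_BOUNDS = {"age": 18.0, "bmi": 15.0, "fvc": 0.5, "fev1": 0.5, "pef": 0.5}

#: maneuver timing defaults (seconds): mean, SD, lower clip, upper clip
TIMELINE_DEFAULTS = {
    "low_effort": {"insp": (2.4, 0.3, 1.8, 3.5), "exp": (3.5, 0.5, 2.2, 5.5),
                   "pause": (0.7, 0.2, 0.3, 1.0)},
    "forceful": {"insp": (2.0, 0.25, 1.7, 3.0), "exp": (1.2, 0.2, 0.7, 2.0),
                 "pause": (0.8, 0.2, 0.3, 1.0)},
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for the simulators; defaults are the study conditions."""

    n_subjects: int = 18
    mode: str = "low_effort"
    seed: int = 0
    audio_rate: float = 8000.0
    imu_rate: float = 100.0
    snr_db: float = 30.0
    cohort_params: Mapping = field(default_factory=lambda: dict(DEFAULT_COHORT_PARAMS))
    true_coefficients: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.25          # outcome units (L or L/s)
    # audio signal model
    audio_amp: float = 0.1          # peak envelope amplitude, full scale 1
    exp_insp_amp_ratio: float = 1.5
    forceful_amp_factor: float = 4.0
    high_band_mix: float = 0.8      # extra 800-1000 Hz energy fraction
    # IMU signal model
    imu_amp_g: float = 0.02
    imu_low_effort_factor: float = 0.5
    imu_drift_g: float = 0.005
    imu_xy_coupling: float = 0.3
    artifact_rate_hz: float = 0.0
    artifact_amp_g: float = 0.1
    # feature-cohort model
    n_rows_per_subject: int = 3
    feature_between_sd: float = 1.0
    feature_within_sd: float = 0.3
    subject_effect_sd: float = 0.0
    intercept: float = 4.0
    target_index: str = "fvc"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if self.audio_rate <= 0 or self.imu_rate <= 0:
            raise ParameterError("sampling rates must be positive")
        if self.mode not in MODES:
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.n_rows_per_subject < 3:
            raise ParameterError("n_rows_per_subject must be >= 3")


def _truncnorm_moment_matched(rng: np.random.Generator, n: int, mean: float,
                              sd: float, lower: float) -> np.ndarray:
    """Sample a lower-truncated normal whose mean/SD equal the targets."""
    if sd < 0:
        raise ParameterError("SD must be nonnegative")
    if sd == 0:
        if mean < lower:
            raise ParameterError("degenerate mean below truncation bound")
        return np.full(n, float(mean))
    a0 = (lower - mean) / sd
    if a0 < -8:  # truncation mass negligible; no adjustment needed
        mu, sigma = mean, sd
    else:
        def moments(x):
            mu_, lsig = x
            sig = math.exp(lsig)
            a = (lower - mu_) / sig
            lam = stats.norm.pdf(a) / stats.norm.sf(a)
            m = mu_ + sig * lam
            v = sig ** 2 * (1 + a * lam - lam ** 2)
            return [m - mean, math.sqrt(max(v, 1e-300)) - sd]

        sol = optimize.root(moments, x0=[mean, math.log(sd)], method="hybr")
        if not sol.success:
            raise ParameterError(f"could not match truncated-normal moments "
                                 f"(mean={mean}, sd={sd}, lower={lower})")
        mu, sigma = sol.x[0], math.exp(sol.x[1])
    a = (lower - mu) / sigma
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n,
                               random_state=rng)


def simulate_subject_profiles(config: SimulationConfig) -> list[SubjectProfile]:
    """Draw a reproducible cohort from the configured moments.

    FEV1 draws exceeding the same subject's FVC are clipped to FVC.
    """
    cp = config.cohort_params
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    draws = {}
    for key in ("age", "bmi", "fvc", "fev1", "pef"):
        mean, sd = cp[key]
        draws[key] = _truncnorm_moment_matched(rng, n, mean, sd,
                                               TRUNCATION_BOUNDS[key])
    fev1 = np.minimum(draws["fev1"], draws["fvc"])
    male = rng.random(n) < cp["male_prop"]
    eth_names = list(cp["ethnicity_probs"].keys())
    eth_p = np.array(list(cp["ethnicity_probs"].values()), dtype=float)
    eth_p = eth_p / eth_p.sum()
    eth = rng.choice(eth_names, size=n, p=eth_p)
    return [
        SubjectProfile(
            subject_id=f"S{i + 1:04d}",
            age=float(draws["age"][i]),
            sex="male" if male[i] else "female",
            bmi=float(draws["bmi"][i]),
            ethnicity=str(eth[i]),
            fvc_ref=float(draws["fvc"][i]),
            fev1_ref=float(fev1[i]),
            pef_ref=float(draws["pef"][i]),
        )
        for i in range(n)
    ]


def simulate_breath_timeline(mode: str, n_cycles: int, seed: int,
                             timing: Optional[Mapping] = None) -> BreathTimeline:
    """Ordered non-overlapping breath cycles with inter-cycle pauses.

    Low-effort expirations are long (default mean 3.5 s); forceful
    expirations are short and sharp (default mean 1.2 s). A closing
    inhalation onset is annotated after the final expiration.
    """
    if mode not in MODES:
        raise ParameterError(f"unknown mode {mode!r}")
    if n_cycles < 1:
        raise ParameterError("n_cycles must be >= 1")
    timing = timing or TIMELINE_DEFAULTS[mode]
    rng = np.random.default_rng(seed)

    def draw(key: str) -> float:
        mean, sd, lo, hi = timing[key]
        return float(np.clip(rng.normal(mean, sd), lo, hi))

    lead_in = 0.6 + float(rng.uniform(0.0, 0.2))
    cycles = []
    t = lead_in
    for _ in range(n_cycles):
        insp_start = t
        exp_start = insp_start + draw("insp")
        cycle_end = exp_start + draw("exp")
        cycles.append((insp_start, exp_start, cycle_end))
        t = cycle_end + draw("pause")
    closing = t
    duration = closing + timing["insp"][0] * 0.6 + 1.0
    return BreathTimeline(cycles=tuple(cycles), mode=mode, duration=duration,
                          closing_insp_start=closing)


def _hann_bump(t: np.ndarray, a: float, b: float) -> np.ndarray:
    """Smooth bump rising from 0 at t=a to 1 mid-phase and back to 0 at t=b."""
    out = np.zeros_like(t)
    mask = (t >= a) & (t < b)
    s = (t[mask] - a) / (b - a)
    out[mask] = 0.5 * (1.0 - np.cos(2.0 * np.pi * s))
    return out


def airflow_envelope(timeline: BreathTimeline, t: np.ndarray,
                     config: SimulationConfig) -> np.ndarray:
    """Smooth airflow-intensity envelope: per-phase bumps, near-zero pauses."""
    mode_factor = (config.forceful_amp_factor
                   if timeline.mode == "forceful" else 1.0)
    a_insp = config.audio_amp * mode_factor
    a_exp = a_insp * config.exp_insp_amp_ratio
    env = np.zeros_like(t)
    if timeline.cycles:
        # tail of the expiration that preceded recording start: the subject
        # was already breathing, so airflow decays into the first inspiration
        lead = timeline.cycles[0][0]
        if lead > 0:
            pre = t < lead
            env[pre] += a_exp * 0.5 * (1.0 + np.cos(np.pi * t[pre] / lead))
    for (t0, t1, t2) in timeline.cycles:
        env += a_insp * _hann_bump(t, t0, t1)
        env += a_exp * _hann_bump(t, t1, t2)
    if timeline.closing_insp_start is not None:
        c0 = timeline.closing_insp_start
        c1 = min(c0 + TIMELINE_DEFAULTS[timeline.mode]["insp"][0],
                 timeline.duration)
        env += a_insp * _hann_bump(t, c0, c1)
    return env


def synthesize_tracheal_audio(timeline: BreathTimeline, config: SimulationConfig,
                              seed: Optional[int] = None) -> AudioRecording:
    """Band-limited noise carrier modulated by the airflow envelope.

    The carrier is 50-1000 Hz Gaussian noise with extra 800-1000 Hz energy
    (the band where tracheal coupling is strongest). Additive white sensor
    noise is scaled to ``snr_db`` relative to the nominal peak envelope.
    """
    rate = config.audio_rate
    if rate < 2000:
        raise ParameterError("audio_rate must be >= 2000 Hz to represent the "
                             "50-1000 Hz tracheal band")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = int(round(timeline.duration * rate))
    t = np.arange(n) / rate
    white = rng.standard_normal(n)
    sos_wide = signal.butter(4, [50.0, 1000.0], btype="bandpass", fs=rate,
                             output="sos")
    sos_high = signal.butter(4, [800.0, 1000.0], btype="bandpass", fs=rate,
                             output="sos")
    carrier = signal.sosfiltfilt(sos_wide, white)
    carrier = carrier + config.high_band_mix * signal.sosfiltfilt(
        sos_high, rng.standard_normal(n))
    carrier /= np.sqrt(np.mean(carrier ** 2))
    env = airflow_envelope(timeline, t, config)
    samples = carrier * env
    if np.isfinite(config.snr_db):
        mode_factor = (config.forceful_amp_factor
                       if timeline.mode == "forceful" else 1.0)
        noise_sd = config.audio_amp * mode_factor * 10 ** (-config.snr_db / 20)
        samples = samples + noise_sd * rng.standard_normal(n)
    return AudioRecording(rate=rate, samples=samples, t0=0.0)


def _respiration_waveform(timeline: BreathTimeline, t: np.ndarray,
                          amp: float) -> np.ndarray:
    """Piecewise-cosine chest motion: minima at inspiration onsets, maxima at
    expiration onsets, monotone in between (so those are the only extrema)."""
    z = np.zeros_like(t)
    events: list[tuple[float, float, float, float]] = []  # (a, b, z_a, z_b)
    cyc = timeline.cycles
    first_t0 = cyc[0][0]
    events.append((0.0, first_t0, 0.0, -amp))
    for i, (t0, t1, _t2) in enumerate(cyc):
        events.append((t0, t1, -amp, amp))
        nxt = (cyc[i + 1][0] if i + 1 < len(cyc)
               else (timeline.closing_insp_start or timeline.duration))
        events.append((t1, nxt, amp, -amp))
    if timeline.closing_insp_start is not None:
        events.append((timeline.closing_insp_start, timeline.duration, -amp, 0.0))
    for (a, b, za, zb) in events:
        if b <= a:
            continue
        mask = (t >= a) & (t < b)
        s = (t[mask] - a) / (b - a)
        z[mask] = za + (zb - za) * 0.5 * (1.0 - np.cos(np.pi * s))
    z[t >= timeline.duration] = events[-1][3] if events else 0.0
    return z


def synthesize_imu(timeline: BreathTimeline, config: SimulationConfig,
                   seed: Optional[int] = None) -> ImuRecording:
    """Tri-axial accelerometer track with respiration on Z plus drift, noise,
    and optional artifact spikes; X/Y carry attenuated copies."""
    rate = config.imu_rate
    if rate < 20:
        raise ParameterError("imu_rate must be >= 20 Hz for the 5 Hz low-pass "
                             "and 20 Hz envelope stage")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = int(round(timeline.duration * rate))
    t = np.arange(n) / rate
    amp = config.imu_amp_g * (config.imu_low_effort_factor
                              if timeline.mode == "low_effort" else 1.0)
    resp = _respiration_waveform(timeline, t, amp)
    drift_freq = rng.uniform(0.01, 0.03)
    drift = config.imu_drift_g * np.sin(2 * np.pi * drift_freq * t
                                        + rng.uniform(0, 2 * np.pi))
    noise_sd = (amp * 10 ** (-config.snr_db / 20)
                if np.isfinite(config.snr_db) else 0.0)
    artifacts = np.zeros(n)
    if config.artifact_rate_hz > 0:
        n_art = rng.poisson(config.artifact_rate_hz * timeline.duration)
        for _ in range(n_art):
            i0 = rng.integers(0, n)
            length = int(0.1 * rate)
            seg = np.exp(-np.arange(length) / (0.03 * rate))
            sign = rng.choice([-1.0, 1.0])
            end = min(n, i0 + length)
            artifacts[i0:end] += sign * config.artifact_amp_g * seg[: end - i0]
    az = resp + drift + artifacts + noise_sd * rng.standard_normal(n)
    ax = config.imu_xy_coupling * resp + noise_sd * rng.standard_normal(n)
    ay = config.imu_xy_coupling * resp + noise_sd * rng.standard_normal(n)
    return ImuRecording(rate=rate, t=t, ax=ax, ay=ay, az=az)


def simulate_session(profile: SubjectProfile, mode: str, n_cycles: int,
                     config: SimulationConfig,
                     seed: Optional[int] = None) -> Session:
    """Bundle one subject's audio + IMU from a single timeline, with the
    ground-truth timeline attached as annotation. Audio and IMU share t=0."""
    base = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    s_tl, s_audio, s_imu = [int(s.generate_state(1)[0] % (2 ** 31))
                            for s in ss.spawn(3)]
    timeline = simulate_breath_timeline(mode, n_cycles, seed=s_tl)
    audio = synthesize_tracheal_audio(timeline, config, seed=s_audio)
    imu = synthesize_imu(timeline, config, seed=s_imu)
    return Session(subject_id=profile.subject_id, mode=mode, audio=audio,
                   imu=imu, profile=profile, annotation=timeline)


def simulate_feature_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Feature table with a known sparse linear link to one spirometric index.

    Each subject carries a latent feature state (between-subject SD
    ``feature_between_sd``); rows scatter around it with within-subject SD
    ``feature_within_sd``. The planted outcome is
    ``intercept + sum(coef * latent) + subject_effect + noise`` and is stored
    as the subject's reference value for ``target_index``; the other two
    targets come from the simulated profiles.
    """
    bad = set(config.true_coefficients) - set(FEATURE_NAMES)
    if bad:
        raise ParameterError(f"unknown feature names in true_coefficients: {sorted(bad)[:3]}")
    if config.target_index not in INDEX_TO_TARGET:
        raise ParameterError(f"unknown target_index {config.target_index!r}")
    profiles = simulate_subject_profiles(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 917]))
    p = len(FEATURE_NAMES)
    coef = np.array([config.true_coefficients.get(name, 0.0)
                     for name in FEATURE_NAMES])
    target_col = INDEX_TO_TARGET[config.target_index]
    rows = []
    for prof in profiles:
        latent = config.feature_between_sd * rng.standard_normal(p)
        y = (config.intercept + float(latent @ coef)
             + config.subject_effect_sd * rng.standard_normal()
             + config.noise_sd * rng.standard_normal())
        targets = {"fvc_ref": prof.fvc_ref, "fev1_ref": prof.fev1_ref,
                   "pef_ref": prof.pef_ref}
        targets[target_col] = y
        cov = covariate_row(prof)
        for j in range(config.n_rows_per_subject):
            x = latent + config.feature_within_sd * rng.standard_normal(p)
            row = {"subject_id": prof.subject_id,
                   "cycle_id": f"{prof.subject_id}_{config.mode}_{j}",
                   "mode": config.mode}
            row.update(dict(zip(FEATURE_NAMES, x)))
            row.update(cov)
            row.update(targets)
            rows.append(row)
    columns = (["subject_id", "cycle_id", "mode"] + list(FEATURE_NAMES)
               + list(COVARIATE_COLUMNS) + list(TARGET_COLUMNS))
    return pd.DataFrame(rows, columns=columns)
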