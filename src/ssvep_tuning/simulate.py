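"""Trial-level EEG synthesis with a planted 12 Hz tuning structure.

The driven component is a stationary 12 Hz sinusoid starting at stimulus
onset (100 ms cosine on-ramp against edge ringing), scaled per trial by the
condition amplitude and by a smooth occipital spatial profile.  Background
activity is 1/f^alpha noise, independent across channels; artifact trials
(saturated channels, high-gradient spikes) can be injected at a configured
rate.  A fast table-level generator produces pooled-SNR tables directly for
statistics testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contrasts import ContrastWeights
from .design import CONDITIONS, ExperimentSchedule
from .epochs import EpochSet
from .montage import SensorMontage
from .subjects import SubjectProfile

RATING_SCALES = ("valence", "arousal", "us_expectancy")
RATING_BOUNDS = {"valence": (1.0, 9.0), "arousal": (1.0, 9.0), "us_expectancy": (0.0, 100.0)}


@dataclass
class SignalParams:
    fs: float = 250.0
    pre_ms: float = 600.0
    post_ms: float = 3000.0
    drive_freq: float = 12.0
    ramp_ms: float = 100.0
    baseline_uv: float = 1.0          # driven amplitude common to all conditions
    acq_delta_uv: float = 0.35        # extra CS+ amplitude during acquisition
    spatial_sigma: float = 0.8        # rad; width of the occipital profile
    noise_sd: float = 1.0             # time-domain SD of 1/f noise, microvolts
    noise_alpha: float = 1.0
    artifact_rate: float = 0.0        # fraction of trials receiving artifacts
    artifact_channels: int = 25
    artifact_amp_uv: float = 500.0

    @property
    def n_samples(self) -> int:
        return int(round((self.pre_ms + self.post_ms) / 1000.0 * self.fs))


def condition_amplitudes(
    profile: SubjectProfile,
    pattern: ContrastWeights | None,
    baseline: float,
) -> np.ndarray:
    """Six 12 Hz amplitudes in canonical condition order.

    amplitude(c) = max(0, baseline + accentuation * w(c) / ||w||); a ``None``
    pattern yields flat tuning at ``baseline``.
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    if pattern is None:
        return np.full(len(CONDITIONS), float(baseline))
    u = pattern.unit()
    if u.shape != (len(CONDITIONS),):
        raise ValueError(f"pattern must have {len(CONDITIONS)} weights")
    return np.maximum(0.0, baseline + profile.accentuation * u)


def occipital_profile(montage: SensorMontage, sigma: float) -> np.ndarray:
    """Gaussian-in-angle gain peaking at the montage's occipital cluster centroid."""
    cluster = montage.cluster_indices()
    centroid = montage.positions[cluster].mean(axis=0)
    centroid = centroid / np.linalg.norm(centroid)
    cosang = np.clip(montage.positions @ centroid, -1.0, 1.0)
    ang = np.arccos(cosang)
    return np.exp(-0.5 * (ang / sigma) ** 2)


def pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
               alpha: float = 1.0, sd: float = 1.0) -> np.ndarray:
    """1/f^alpha noise along the last axis, scaled to the requested SD."""
    if sd == 0:
        return np.zeros(shape + (n_samples,))
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-alpha / 2.0)
    shaped = np.fft.irfft(spec * gain, n=n_samples, axis=-1)
    scale = shaped.std(axis=-1, keepdims=True)
    scale[scale == 0] = 1.0
    return shaped / scale * sd


def synthesize_epochs(
    profile: SubjectProfile,
    schedule: ExperimentSchedule,
    montage: SensorMontage,
    params: SignalParams | None = None,
    pattern: ContrastWeights | None = None,
    seed: int = 0,
) -> EpochSet:
    """Generate one subject's epoched EEG for every trial in the schedule."""
    params = params or SignalParams()
    if params.noise_sd < 0 or params.artifact_rate < 0:
        raise ValueError("noise parameters must be non-negative")
    rng = np.random.default_rng(seed)
    meta = schedule.to_frame()
    n_trials = len(meta)
    n_ch = montage.n_channels
    n_samp = params.n_samples
    t = -params.pre_ms / 1000.0 + np.arange(n_samp) / params.fs

    # driven waveform: 12 Hz from onset with cosine on-ramp
    drive = np.sin(2 * np.pi * params.drive_freq * t)
    ramp = np.clip(t / (params.ramp_ms / 1000.0), 0.0, 1.0)
    envelope = np.where(t < 0, 0.0, 0.5 - 0.5 * np.cos(np.pi * ramp))
    drive = drive * envelope

    amps6 = condition_amplitudes(profile, pattern, params.baseline_uv)
    amp_by_cond = dict(zip(CONDITIONS, amps6))

    def trial_amplitude(phase: str, condition: str) -> float:
        if phase == "habituation":
            return params.baseline_uv
        if phase == "acquisition":
            return params.baseline_uv + (params.acq_delta_uv if condition == "CS+" else 0.0)
        return float(amp_by_cond[condition])

    spatial = occipital_profile(montage, params.spatial_sigma)
    amps = np.array([trial_amplitude(p, c) for p, c in zip(meta["phase"], meta["condition"])])

    data = pink_noise(rng, (n_trials, n_ch), n_samp, params.noise_alpha, params.noise_sd)
    data += amps[:, None, None] * spatial[None, :, None] * drive[None, None, :]

    if params.artifact_rate > 0:
        bad_trials = np.flatnonzero(rng.random(n_trials) < params.artifact_rate)
        for tr in bad_trials:
            chans = rng.choice(n_ch, size=min(params.artifact_channels, n_ch), replace=False)
            half = len(chans) // 2
            # saturated channels: railed at +/- full scale
            data[tr, chans[:half], :] = params.artifact_amp_uv * np.sign(
                rng.standard_normal(half)
            )[:, None]
            # spike channels: single-sample excursions (huge temporal gradient)
            for ch in chans[half:]:
                pos = rng.integers(1, n_samp - 1)
                data[tr, ch, pos] += params.artifact_amp_uv

    return EpochSet(data, params.fs, -params.pre_ms, meta, list(montage.labels))


@dataclass
class RatingParams:
    """Linear generalization gradients for the three rating scales.

    Expected rating decreases linearly from CS+ to CS- (positions 0..5 along
    the morph continuum); values are clipped to the scale bounds.
    """

    cs_plus_mean: dict = field(default_factory=lambda: {
        "valence": 6.5, "arousal": 6.5, "us_expectancy": 72.0})
    slope: dict = field(default_factory=lambda: {
        "valence": 0.5, "arousal": 0.6, "us_expectancy": 13.0})
    noise_sd: dict = field(default_factory=lambda: {
        "valence": 1.0, "arousal": 1.2, "us_expectancy": 15.0})
    habituation_flat: bool = True


def synthesize_ratings(
    profiles: list[SubjectProfile],
    params: RatingParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Long table (subject_id, phase, condition, scale, value).

    Valence and arousal are rated after every phase; expectancy of the
    aversive outcome only after acquisition and generalization.  Habituation
    means are flat (no learning yet) unless configured otherwise.
    """
    params = params or RatingParams()
    for scale in RATING_SCALES:
        for d in (params.cs_plus_mean, params.slope, params.noise_sd):
            if not np.isfinite(d[scale]):
                raise ValueError("gradient parameters must be finite")
    rng = np.random.default_rng(seed)
    phase_plan = [
        ("habituation", ("CS+", "CS-"), ("valence", "arousal")),
        ("acquisition", ("CS+", "CS-"), RATING_SCALES),
        ("generalization", CONDITIONS, RATING_SCALES),
    ]
    rows = []
    for prof in profiles:
        for phase, conds, scales in phase_plan:
            for scale in scales:
                lo, hi = RATING_BOUNDS[scale]
                for cond in conds:
                    pos = CONDITIONS.index(cond)
                    slope = params.slope[scale]
                    if phase == "habituation" and params.habituation_flat:
                        slope = 0.0
                    mean = params.cs_plus_mean[scale] - slope * pos
                    val = mean + rng.normal(0.0, params.noise_sd[scale])
                    rows.append(
                        (prof.subject_id, phase, cond, scale,
                         float(np.clip(val, lo, hi)), prof.spai)
                    )
    return pd.DataFrame(
        rows, columns=["subject_id", "phase", "condition", "scale", "value", "spai"]
    )


def simulate_snr_table(
    profiles: list[SubjectProfile],
    pattern: ContrastWeights | None = None,
    baseline: float = 3.4,
    noise_sd: float = 0.8,
    acq_delta: float = 0.35,
    subject_sd: float = 0.6,
    include_phases: tuple[str, ...] = ("habituation", "acquisition", "generalization"),
    seed: int = 0,
) -> pd.DataFrame:
    """Pooled-SNR table generated directly at the subject x condition level.

    Mirrors the epoch-level ground truth (flat habituation, CS+ boost in
    acquisition, pattern x accentuation in generalization) plus a Gaussian
    subject offset and cell noise, skipping the EEG stage entirely.  SNRs are
    floored at a small positive value.
    """
    rng = np.random.default_rng(seed)
    u = pattern.unit() if pattern is not None else np.zeros(len(CONDITIONS))
    rows = []
    for prof in profiles:
        offset = rng.normal(0.0, subject_sd)
        for phase in include_phases:
            conds = CONDITIONS if phase == "generalization" else ("CS+", "CS-")
            for cond in conds:
                mean = baseline + offset
                if phase == "acquisition" and cond == "CS+":
                    mean += acq_delta
                if phase == "generalization":
                    mean += prof.accentuation * u[CONDITIONS.index(cond)]
                snr = max(0.05, mean + rng.normal(0.0, noise_sd))
                rows.append((prof.subject_id, phase, cond, float(snr), prof.spai))
    return pd.DataFrame(rows, columns=["subject_id", "phase", "condition", "snr", "spai"])
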