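"""Epoch preprocessing: low-pass filtering, statistical artifact control,
spherical-spline channel repair, and condition averaging.

Artifact control follows the statistical-control-of-artifacts logic: three
per-trial, per-channel statistics (absolute maximum, standard deviation,
maximum absolute first difference) are compared against distribution-based
cutoffs (median + k * IQR over all trials and channels); a channel exceeding
any cutoff is flagged, flagged channels are interpolated from the remaining
set, and a trial is rejected outright when more than ``max_bad`` of its
channels are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .epochs import AveragedEpochs, EpochSet
from .montage import SensorMontage
from .spline import check_positions, cosine_distances, kernel_matrix, solve_spline


def lowpass_filter(epochs: EpochSet, cutoff: float = 40.0, order: int = 4) -> EpochSet:
    """Zero-phase (forward-backward) Butterworth low pass per channel."""
    nyq = epochs.fs / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(order, cutoff, btype="low", fs=epochs.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return EpochSet(filtered, epochs.fs, epochs.t0_ms, epochs.trial_meta.copy(),
                    list(epochs.channels))


@dataclass
class ArtifactReport:
    flags: np.ndarray            # (n_trials, n_channels) bool
    rejected: np.ndarray         # (n_trials,) bool
    stats: dict = field(default_factory=dict)       # name -> (trials, channels)
    thresholds: dict = field(default_factory=dict)  # name -> float
    k_iqr: float = 3.0
    max_bad: int = 20

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())

    def rejection_rate(self) -> float:
        return float(self.rejected.mean()) if len(self.rejected) else 0.0


def detect_artifacts(epochs: EpochSet, k_iqr: float = 3.0, max_bad: int = 20) -> ArtifactReport:
    """Flag outlying channels per trial; reject trials with > ``max_bad`` flags.

    The decision depends only on the voltage statistics, never on the trial's
    condition labels.
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials for distribution-based thresholds")
    data = epochs.data
    stats = {
        "abs_max": np.abs(data).max(axis=-1),
        "sd": data.std(axis=-1),
        "max_gradient": np.abs(np.diff(data, axis=-1)).max(axis=-1),
    }
    flags = np.zeros(data.shape[:2], dtype=bool)
    thresholds = {}
    for name, s in stats.items():
        q1, med, q3 = np.percentile(s, [25, 50, 75])
        cutoff = med + k_iqr * (q3 - q1)
        thresholds[name] = float(cutoff)
        flags |= s > cutoff  # strict: all-constant data yields no flags
    rejected = flags.sum(axis=1) > max_bad
    return ArtifactReport(flags, rejected, stats, thresholds, k_iqr, max_bad)


def interpolate_channels(
    epochs: EpochSet,
    report: ArtifactReport,
    montage: SensorMontage,
    m: int = 4,
    legendre_terms: int = 50,
    lam: float = 1e-5,
) -> EpochSet:
    """Replace flagged channels by spherical-spline interpolation.

    Unflagged channels are passed through bit-identically; rejected trials are
    left untouched (they are dropped at averaging).  Raises when a retained
    trial would keep fewer than 4 good channels.
    """
    if list(montage.labels) != list(epochs.channels):
        raise ValueError("montage channels do not match epochs")
    positions = check_positions(montage.positions)
    data = epochs.data.copy()
    flags = report.flags
    # group trials by identical flag patterns so each spline system is solved once
    patterns: dict[bytes, list[int]] = {}
    for tr in range(epochs.n_trials):
        if report.rejected[tr] or not flags[tr].any():
            continue
        patterns.setdefault(flags[tr].tobytes(), []).append(tr)
    for key, trial_idx in patterns.items():
        bad = np.frombuffer(key, dtype=bool)
        good = ~bad
        if good.sum() < 4:
            raise ValueError(
                f"trial {trial_idx[0]}: only {int(good.sum())} good channels; "
                "spline interpolation underdetermined"
            )
        cos_gg = cosine_distances(positions[good], positions[good])
        g_gg = kernel_matrix(cos_gg, m, legendre_terms)
        scale = np.trace(g_gg) / g_gg.shape[0]
        cos_bg = cosine_distances(positions[bad], positions[good])
        g_bg = kernel_matrix(cos_bg, m, legendre_terms) / scale
        y = data[trial_idx][:, good, :]                    # (t, good, samples)
        y2 = np.moveaxis(y, 1, 0).reshape(good.sum(), -1)  # (good, t*samples)
        c, d = solve_spline(g_gg, y2, lam)
        interp = g_bg @ c + d                              # (bad, t*samples)
        interp = np.moveaxis(interp.reshape(bad.sum(), len(trial_idx), -1), 0, 1)
        for j, tr in enumerate(trial_idx):
            data[tr, bad, :] = interp[j]
    return EpochSet(data, epochs.fs, epochs.t0_ms, epochs.trial_meta.copy(),
                    list(epochs.channels))


def average_conditions(
    epochs: EpochSet,
    report: ArtifactReport | None = None,
    exclude_reinforced: bool = False,
    subject_id: str = "",
) -> AveragedEpochs:
    """Arithmetic mean over retained trials per (phase, condition) cell.

    Raises listing the empty cells when any scheduled cell retains no trials.
    """
    meta = epochs.trial_meta
    keep = np.ones(epochs.n_trials, dtype=bool)
    if report is not None:
        keep &= ~report.rejected
    if exclude_reinforced:
        keep &= ~meta["reinforced"].to_numpy(dtype=bool)
    cells = list(dict.fromkeys(zip(meta["phase"], meta["condition"])))
    out = np.empty((len(cells), epochs.n_channels, epochs.n_samples))
    n_avg = np.zeros(len(cells), dtype=int)
    empty = []
    for i, (phase, cond) in enumerate(cells):
        sel = keep & (meta["phase"] == phase).to_numpy() & (meta["condition"] == cond).to_numpy()
        n_avg[i] = sel.sum()
        if n_avg[i] == 0:
            empty.append((phase, cond))
            continue
        out[i] = epochs.data[sel].mean(axis=0)
    if empty:
        raise ValueError(f"no retained trials for cells: {empty}")
    return AveragedEpochs(cells, out, n_avg, epochs.fs, epochs.t0_ms,
                          list(epochs.channels), subject_id=subject_id)
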