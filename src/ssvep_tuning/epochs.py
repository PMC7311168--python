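"""Epoched EEG containers flowing through filtering, artifact control and CSD."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EpochSet:
    """Trial x channel x sample voltages with sampling metadata.

    ``t0_ms`` is the time of the first sample relative to stimulus onset
    (negative = pre-stimulus).  ``trial_meta`` has one row per trial with at
    least columns ``phase``, ``condition``, ``reinforced``.
    """

    data: np.ndarray  # (n_trials, n_channels, n_samples), microvolts
    fs: float
    t0_ms: float
    trial_meta: pd.DataFrame
    channels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if len(self.trial_meta) != self.data.shape[0]:
            raise ValueError("trial_meta length must equal trial count")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel list length must equal channel count")
        self.trial_meta = self.trial_meta.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times_ms(self) -> np.ndarray:
        return self.t0_ms + 1000.0 * np.arange(self.n_samples) / self.fs

    def onset_index(self) -> int:
        """Sample index of stimulus onset (t = 0)."""
        idx = int(round(-self.t0_ms / 1000.0 * self.fs))
        if not 0 <= idx < self.n_samples:
            raise ValueError("stimulus onset outside the epoch")
        return idx


@dataclass
class AveragedEpochs:
    """Per (phase, condition) mean voltage traces for one subject."""

    cells: list[tuple[str, str]]  # (phase, condition)
    data: np.ndarray  # (n_cells, n_channels, n_samples)
    n_trials_averaged: np.ndarray  # (n_cells,)
    fs: float
    t0_ms: float
    channels: list[str]
    units: str = "uV"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.n_trials_averaged = np.asarray(self.n_trials_averaged, dtype=int)
        if self.data.shape[0] != len(self.cells):
            raise ValueError("data rows must match cells")
        if self.n_trials_averaged.shape != (len(self.cells),):
            raise ValueError("n_trials_averaged must have one entry per cell")

    def cell_index(self, phase: str, condition: str) -> int:
        return self.cells.index((phase, condition))

    def onset_index(self) -> int:
        idx = int(round(-self.t0_ms / 1000.0 * self.fs))
        if not 0 <= idx < self.data.shape[2]:
            raise ValueError("stimulus onset outside the epoch")
        return idx
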