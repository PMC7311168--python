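"""Frequency-domain endpoint: FFT power spectra and the 12 Hz SNR.

The analysis window (default 500-3000 ms post-onset, dropping the initial
non-stationary response) spans an integer number of 12 Hz cycles at 250 Hz,
so the driving frequency falls exactly on a 0.4 Hz bin and no taper is
needed.  The SNR divides the power at the driving frequency by the mean
power of six neighbor bins (three per side), skipping the two immediate
neighbors; channel SNRs are then averaged over the occipital cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sig

from .epochs import AveragedEpochs
from .montage import SensorMontage


@dataclass
class SpectrumTable:
    """Power per cell x channel x frequency bin for one subject."""

    cells: list[tuple[str, str]]
    freqs: np.ndarray          # (n_bins,), Hz
    power: np.ndarray          # (n_cells, n_channels, n_bins)
    channels: list[str]
    window_ms: tuple[float, float]
    subject_id: str = ""

    @property
    def resolution(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def bin_index(self, f: float, tol: float = 1e-9) -> int:
        idx = int(round(f / self.resolution))
        if idx >= len(self.freqs) or abs(self.freqs[idx] - f) > tol:
            raise ValueError(f"{f} Hz does not fall on a frequency bin "
                             f"(resolution {self.resolution} Hz)")
        return idx


def compute_spectrum(
    avg: AveragedEpochs,
    window_ms: tuple[float, float] = (500.0, 3000.0),
    detrend: bool = True,
    amplitude: bool = False,
) -> SpectrumTable:
    """Power spectrum of the linearly detrended, untapered analysis window.

    ``amplitude=True`` returns amplitude (not squared) spectra for
    sensitivity checks; the default is power.
    """
    lo, hi = window_ms
    onset = avg.onset_index()
    i0 = onset + lo / 1000.0 * avg.fs
    i1 = onset + hi / 1000.0 * avg.fs
    if abs(i0 - round(i0)) > 1e-6 or abs(i1 - round(i1)) > 1e-6:
        raise ValueError("window length x sampling rate must be an integer sample count")
    i0, i1 = int(round(i0)), int(round(i1))
    if i0 < 0 or i1 > avg.data.shape[2] or i1 <= i0:
        raise ValueError("analysis window outside the epoch")
    seg = avg.data[:, :, i0:i1]
    if detrend:
        seg = sig.detrend(seg, axis=-1, type="linear")
    n = seg.shape[-1]
    spec = np.fft.rfft(seg, axis=-1)
    amp = np.abs(spec) / n
    amp[..., 1:] *= 2.0  # one-sided amplitude of a real sinusoid
    freqs = np.fft.rfftfreq(n, d=1.0 / avg.fs)
    power = amp if amplitude else amp**2
    return SpectrumTable(list(avg.cells), freqs, power, list(avg.channels),
                         (lo, hi), avg.subject_id)


def snr_at(
    spectrum: SpectrumTable,
    f: float = 12.0,
    n_side: int = 3,
    skip: int = 1,
) -> np.ndarray:
    """Per cell x channel SNR: P(f) / mean of 2*n_side neighbor bins.

    Neighbors are at +/- (skip+1 .. skip+n_side) bins; with the defaults that
    is +/-2, +/-3, +/-4 bins, i.e. six noise bins excluding the two immediate
    neighbors.  Raises if any noise bin is exactly zero.
    """
    idx = spectrum.bin_index(f)
    offsets = np.concatenate([-(np.arange(skip + 1, skip + n_side + 1)),
                              np.arange(skip + 1, skip + n_side + 1)])
    neighbor_idx = idx + offsets
    if neighbor_idx.min() < 0 or neighbor_idx.max() >= len(spectrum.freqs):
        raise ValueError("not enough frequency bins around the driving frequency")
    noise = spectrum.power[:, :, neighbor_idx]
    if np.any(noise.mean(axis=-1) == 0):
        raise ValueError("zero noise power in neighbor bins (degenerate noiseless input); "
                         "add a small epsilon to the spectrum if intended")
    return spectrum.power[:, :, idx] / noise.mean(axis=-1)


def pool_occipital(channel_snr: np.ndarray, spectrum_channels: list[str],
                   montage: SensorMontage) -> np.ndarray:
    """Arithmetic mean of the occipital-cluster channel SNRs, per cell."""
    missing = [c for c in montage.occipital_cluster if c not in spectrum_channels]
    if missing:
        raise ValueError(f"missing occipital cluster channels: {missing}")
    idx = [spectrum_channels.index(c) for c in montage.occipital_cluster]
    return channel_snr[:, idx].mean(axis=1)


def snr_rows(
    avg: AveragedEpochs,
    montage: SensorMontage,
    spai: float,
    window_ms: tuple[float, float] = (500.0, 3000.0),
    f: float = 12.0,
) -> pd.DataFrame:
    """Pooled-SNR long-table rows for one subject's averaged epochs."""
    spectrum = compute_spectrum(avg, window_ms)
    pooled = pool_occipital(snr_at(spectrum, f), spectrum.channels, montage)
    return pd.DataFrame(
        {
            "subject_id": avg.subject_id,
            "phase": [p for p, _ in avg.cells],
            "condition": [c for _, c in avg.cells],
            "snr": pooled,
            "spai": spai,
        }
    )
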