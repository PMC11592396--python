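"""EEG preprocessing and Morlet time-frequency decomposition.

The decomposition follows the classic complex Morlet family with a constant
centre-frequency-to-bandwidth ratio f0 / sigma_f = 7:

    w(t, f0) = (sigma_t * sqrt(pi))^(-1/2)
               * exp(-t^2 / (2 sigma_t^2)) * exp(2 i pi f0 t),

with sigma_f = f0 / 7 and sigma_t = 1 / (2 pi sigma_f). The time-varying
energy is E(t, f0) = |(w * s)(t)|^2, evaluated on an integer frequency grid
1..45 Hz and averaged over the canonical EEG bands (delta 1-3, theta 4-7,
alpha 8-13, beta 14-30, gamma 31-45 Hz) and 1-s time bins.

Preprocessing is a zero-phase 1-60 Hz bandpass, a 50 Hz notch, and
re-referencing to the common average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import scipy.fft
import scipy.signal

from .synthetic import BAND_EDGES_HZ, FRONTAL_ROI, EEGRecording

__all__ = [
    "TimeFrequencyEnergy",
    "BandPowerSeries",
    "morlet_wavelet",
    "preprocess",
    "morlet_energy",
    "band_power",
    "roi_average",
]

DEFAULT_FREQS_HZ = np.arange(1, 46)
WAVELET_RATIO = 7.0
_TRUNC_SD = 4.0  # wavelet support: +/- 4 sigma_t


@dataclass
class TimeFrequencyEnergy:
    """|wavelet * signal|^2 on a (channels, frequencies, samples) grid."""

    frequencies_hz: np.ndarray
    energy: np.ndarray
    fs: float
    channel_names: List[str]
    piece_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.energy.ndim != 3:
            raise ValueError("energy must be channels x frequencies x time")
        if self.energy.shape[1] != len(self.frequencies_hz):
            raise ValueError("frequency axis mismatch")

    def edge_seconds(self, f0: float) -> float:
        """Width of the edge-contaminated margin at frequency ``f0``."""
        sigma_t = WAVELET_RATIO / (2 * np.pi * f0)
        return _TRUNC_SD * sigma_t


@dataclass
class BandPowerSeries:
    """Per-1-s-bin mean power for one named band, single channel or ROI."""

    band: str
    values: np.ndarray
    scope: str  # channel name or "ROI"
    piece_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and self.values.min() < 0:
            raise ValueError("band power must be non-negative")

    @property
    def bin_edges_s(self) -> np.ndarray:
        return np.arange(self.values.size + 1, dtype=float)


def preprocess(
    rec: EEGRecording,
    band: Tuple[float, float] = (1.0, 60.0),
    notch_hz: float = 50.0,
    notch_width_hz: float = 2.0,
) -> EEGRecording:
    """Zero-phase bandpass + notch, then common-average re-reference."""
    lo, hi = band
    if rec.fs <= 2 * hi:
        raise ValueError(
            f"fs = {rec.fs} too low for a {lo}-{hi} Hz bandpass (need > {2 * hi})"
        )
    sos = scipy.signal.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    data = scipy.signal.sosfiltfilt(sos, rec.data, axis=1)
    if notch_hz and notch_hz < rec.fs / 2:
        b, a = scipy.signal.iirnotch(notch_hz, notch_hz / notch_width_hz, fs=rec.fs)
        data = scipy.signal.filtfilt(b, a, data, axis=1)
    data = data - data.mean(axis=0, keepdims=True)  # average reference
    return EEGRecording(
        list(rec.channel_names), rec.fs, data,
        piece_id=rec.piece_id, subject_id=rec.subject_id,
    )


def morlet_wavelet(f0: float, fs: float, ratio: float = WAVELET_RATIO) -> np.ndarray:
    """Sampled complex Morlet wavelet at centre frequency ``f0``.

    Truncated at +/- 4 sigma_t; the returned array has odd length and is
    scaled by the sample interval so that discrete convolution approximates
    the continuous integral.
    """
    sigma_f = f0 / ratio
    sigma_t = 1.0 / (2 * np.pi * sigma_f)
    half = int(np.ceil(_TRUNC_SD * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = (
        (sigma_t * np.sqrt(np.pi)) ** (-0.5)
        * np.exp(-(t**2) / (2 * sigma_t**2))
        * np.exp(2j * np.pi * f0 * t)
    )
    return w / fs


def morlet_energy(
    rec: EEGRecording,
    f0_list: Sequence[float] = DEFAULT_FREQS_HZ,
    ratio: float = WAVELET_RATIO,
    method: str = "fft",
) -> TimeFrequencyEnergy:
    """Time-varying energy E(t, f0) = |w(., f0) * s|^2 per channel.

    The signal is reflection-padded by the longest wavelet's half-length so
    the output has the input's length; the first/last ``edge_seconds(f0)``
    of each frequency row remain edge-contaminated and can be trimmed by
    the caller. ``method`` selects FFT-based or direct time-domain
    convolution; both compute the same linear convolution.
    """
    f0_list = np.asarray(f0_list, dtype=float)
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    if f0_list.max() >= rec.fs / 2:
        raise ValueError("max frequency must be below Nyquist")
    n = rec.n_samples
    halves = np.ceil(_TRUNC_SD * (ratio / (2 * np.pi * f0_list)) * rec.fs).astype(int)
    pad = int(halves.max())
    if n <= pad:
        raise ValueError(
            f"recording too short for the longest wavelet: need > "
            f"{pad / rec.fs:.2f} s, got {n / rec.fs:.2f} s"
        )
    padded = np.pad(rec.data, ((0, 0), (pad, pad)), mode="reflect")

    energy = np.empty((rec.data.shape[0], f0_list.size, n))
    if method == "fft":
        nfft = scipy.fft.next_fast_len(padded.shape[1] + 2 * pad + 1)
        sig_f = scipy.fft.fft(padded, n=nfft, axis=1)
        for i, f0 in enumerate(f0_list):
            w = morlet_wavelet(f0, rec.fs, ratio)
            w_f = scipy.fft.fft(w, n=nfft)
            conv = scipy.fft.ifft(sig_f * w_f[None, :], axis=1)
            half = len(w) // 2
            centre = conv[:, pad + half : pad + half + n]
            energy[:, i, :] = np.abs(centre) ** 2
    elif method == "direct":
        for i, f0 in enumerate(f0_list):
            w = morlet_wavelet(f0, rec.fs, ratio)
            half = len(w) // 2
            for c in range(padded.shape[0]):
                conv = np.convolve(padded[c], w, mode="full")
                energy[c, i, :] = np.abs(conv[pad + half : pad + half + n]) ** 2
    else:
        raise ValueError(f"unknown method {method!r}")
    return TimeFrequencyEnergy(
        f0_list, energy, rec.fs, list(rec.channel_names),
        piece_id=rec.piece_id, subject_id=rec.subject_id,
    )


def band_power(
    tfe: TimeFrequencyEnergy,
    bands: Dict[str, Tuple[float, float]] = BAND_EDGES_HZ,
    log_transform: bool = False,
) -> Dict[str, List[BandPowerSeries]]:
    """Mean energy per band, then per 1-s bin, per channel.

    Bins are half-open [k, k+1) seconds anchored at the recording start;
    the trailing partial bin is dropped. Power is raw by default
    (``log_transform`` applies log10 after binning).
    """
    freqs = tfe.frequencies_hz
    n_bins = int(tfe.energy.shape[2] // tfe.fs)
    samples_per_bin = int(tfe.fs)
    out: Dict[str, List[BandPowerSeries]] = {}
    for band_name, (lo, hi) in bands.items():
        rows = (freqs >= lo) & (freqs <= hi)
        if not rows.any():
            raise ValueError(f"band {band_name!r} has no computed frequencies")
        band_energy = tfe.energy[:, rows, :].mean(axis=1)  # channels x time
        trimmed = band_energy[:, : n_bins * samples_per_bin]
        binned = trimmed.reshape(band_energy.shape[0], n_bins, samples_per_bin).mean(
            axis=2
        )
        if log_transform:
            binned = np.log10(binned)
        out[band_name] = [
            BandPowerSeries(band_name, binned[c], scope=tfe.channel_names[c],
                            piece_id=tfe.piece_id, subject_id=tfe.subject_id)
            for c in range(binned.shape[0])
        ]
    return out


def roi_average(
    series: Sequence[BandPowerSeries],
    roi: Sequence[str] = FRONTAL_ROI,
) -> BandPowerSeries:
    """Element-wise mean of the per-channel series over the ROI channels."""
    by_name = {s.scope: s for s in series}
    missing = [ch for ch in roi if ch not in by_name]
    if missing:
        raise ValueError(f"ROI channels missing from series: {missing}")
    bands = {by_name[ch].band for ch in roi}
    if len(bands) != 1:
        raise ValueError(f"mixed bands in ROI average: {sorted(bands)}")
    stacked = np.stack([by_name[ch].values for ch in roi])
    first = by_name[roi[0]]
    return BandPowerSeries(
        first.band, stacked.mean(axis=0), scope="ROI",
        piece_id=first.piece_id, subject_id=first.subject_id,
    )
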