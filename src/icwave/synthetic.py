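"""Synthetic study generator: music, ratings, and regressor-coupled EEG.

Emulates the study design end-to-end so every downstream stage can be tested
with known ground truth: note sequences are drawn from a stationary
low-order Markov source (so each event's true information content is
-log2 of the generating probability), continuous 1-4 pleasure ratings are a
lagged, smoothed threshold response to surprisal, and EEG is pink + white
noise with a band-limited oscillation at frontal channels whose amplitude
envelope is linearly coupled to a chosen regressor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Sequence, Tuple

import numpy as np

from .surprisal import SurpriseSeries, SymbolSequence

__all__ = [
    "MarkovSource",
    "CouplingSpec",
    "StudyConfig",
    "SyntheticStudy",
    "RatingSeries",
    "EEGRecording",
    "MONTAGE_30",
    "FRONTAL_ROI",
    "random_markov_source",
    "generate_markov_pieces",
    "generate_ratings",
    "generate_eeg",
    "generate_study",
]

# 30-channel 10-20/10-10 montage (8 frontal ROI channels first).
FRONTAL_ROI: Tuple[str, ...] = ("Fp1", "Fp2", "F3", "Fz", "F4", "FC3", "FCz", "FC4")
MONTAGE_30: Tuple[str, ...] = FRONTAL_ROI + (
    "F7", "F8", "FT7", "FT8", "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8", "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

BAND_EDGES_HZ: Dict[str, Tuple[float, float]] = {
    "delta": (1, 3),
    "theta": (4, 7),
    "alpha": (8, 13),
    "beta": (14, 30),
    "gamma": (31, 45),
}


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is channels x samples at rate ``fs``."""

    channel_names: List[str]
    fs: float
    data: np.ndarray
    piece_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be channels x samples")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class RatingSeries:
    """Integer 1-4 pleasure per consecutive 1-s bin [k, k+1)."""

    piece_id: str
    subject_id: str
    values: np.ndarray
    flagged_constant: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.size and not np.all((self.values >= 1) & (self.values <= 4)):
            raise ValueError("rating values must be in {1, 2, 3, 4}")

    @property
    def bin_edges_s(self) -> np.ndarray:
        return np.arange(self.values.size + 1, dtype=float)


@dataclass(frozen=True)
class MarkovSource:
    """A stationary Markov source over a finite alphabet.

    ``transition_probabilities`` maps context tuples (length <= ``order``) to
    a distribution over the alphabet; the empty context must be present so
    generation can start. Shorter-context distributions are also the
    fallback while fewer than ``order`` symbols have been emitted.
    """

    order: int
    alphabet: Tuple[Hashable, ...]
    transition_probabilities: Dict[Tuple[Hashable, ...], Dict[Hashable, float]]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")
        if () not in self.transition_probabilities:
            raise ValueError("the empty context () must have a distribution")
        for ctx, dist in self.transition_probabilities.items():
            if len(ctx) > self.order:
                raise ValueError(f"context {ctx!r} longer than order {self.order}")
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(
                    f"distribution for context {ctx!r} sums to {total!r}, not 1"
                )
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"negative probability in context {ctx!r}")

    def distribution_for(self, history: Sequence[Hashable]) -> Dict[Hashable, float]:
        """Longest-suffix lookup, backing off to shorter contexts."""
        ctx = tuple(history)[-self.order :] if self.order else ()
        for k in range(len(ctx), -1, -1):
            dist = self.transition_probabilities.get(ctx[len(ctx) - k :])
            if dist is not None:
                return dist
        raise KeyError("no distribution found (empty context missing)")


def random_markov_source(
    order: int,
    alphabet: Sequence[Hashable],
    seed: int,
    concentration: float = 1.0,
) -> MarkovSource:
    """Dirichlet-random transition table over all contexts up to ``order``."""
    rng = np.random.default_rng(seed)
    alphabet = tuple(alphabet)
    table: Dict[Tuple[Hashable, ...], Dict[Hashable, float]] = {}

    def fill(ctx: Tuple[Hashable, ...]) -> None:
        probs = rng.dirichlet([concentration] * len(alphabet))
        table[ctx] = dict(zip(alphabet, probs.tolist()))
        if len(ctx) < order:
            for sym in alphabet:
                fill(ctx + (sym,))

    fill(())
    return MarkovSource(order, alphabet, table, seed=seed)


def generate_markov_pieces(
    source: MarkovSource,
    n_pieces: int,
    length_events: int,
    tempo_events_per_s: float = 2.0,
    seed: int = 0,
    stream: str = "melody",
    piece_prefix: str = "piece",
) -> List[Tuple[SymbolSequence, SurpriseSeries]]:
    """Sample token sequences with their true per-event information content.

    Events are spaced ``1 / tempo_events_per_s`` seconds apart starting at
    t = 0; the true IC of each emitted symbol is -log2 of its generating
    probability under the source's context distribution.
    """
    if length_events < source.order + 1:
        raise ValueError("length_events must be >= order + 1")
    if tempo_events_per_s <= 0:
        raise ValueError("tempo_events_per_s must be > 0")
    rng = np.random.default_rng(seed)
    dt = 1.0 / tempo_events_per_s
    out: List[Tuple[SymbolSequence, SurpriseSeries]] = []
    for p in range(n_pieces):
        tokens: List[Hashable] = []
        ic: List[float] = []
        for _ in range(length_events):
            dist = source.distribution_for(tokens)
            symbols = list(dist)
            probs = np.array([dist[s] for s in symbols], dtype=float)
            idx = rng.choice(len(symbols), p=probs / probs.sum())
            tokens.append(symbols[idx])
            ic.append(-math.log2(probs[idx]) if probs[idx] < 1.0 else 0.0)
        times = [i * dt for i in range(length_events)]
        pid = f"{piece_prefix}{p:02d}"
        out.append(
            (
                SymbolSequence(pid, stream, tokens, times),
                SurpriseSeries(pid, stream, ic, times),
            )
        )
    return out


def _ic_per_second(ic: SurpriseSeries, n_bins: int) -> np.ndarray:
    """Per-1-s-bin mean IC, forward-filled over empty bins (0 before onset)."""
    values = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for t, x in zip(ic.timestamps_s, ic.ic_bits):
        b = int(t)
        if 0 <= b < n_bins:
            values[b] += x
            counts[b] += 1
    out = np.zeros(n_bins)
    last = 0.0
    started = False
    for b in range(n_bins):
        if counts[b] > 0:
            last = values[b] / counts[b]
            started = True
        out[b] = last if started else 0.0
    return out


def generate_ratings(
    ic: SurpriseSeries,
    lag_s: float = 2.0,
    thresholds: Sequence[float] = (1.8, 2.6, 3.4),
    piece_duration_s: float = 60.0,
    seed: int = 0,
    smooth_window_s: int = 3,
    noise_sd: float = 0.0,
) -> RatingSeries:
    """Piecewise-constant 1-4 rating derived from lagged, smoothed surprisal.

    The per-second IC is smoothed with a centred moving average
    (``smooth_window_s`` bins, guards against 1-bin flicker), delayed by
    ``lag_s`` (the behavioural response lag), optionally perturbed with
    Gaussian noise (per-subject variability), and thresholded: the rating is
    1 plus the number of ``thresholds`` strictly below the value. Bins
    before the first note are 1 (neutral).
    """
    t1, t2, t3 = thresholds
    if not (t1 < t2 < t3):
        raise ValueError("thresholds must be strictly ascending")
    if lag_s < 0:
        raise ValueError("lag_s must be >= 0")
    n_bins = int(piece_duration_s)
    rng = np.random.default_rng(seed)
    if len(ic) == 0:
        return RatingSeries(ic.piece_id, "", np.ones(n_bins, dtype=int),
                            flagged_constant=True)

    per_s = _ic_per_second(ic, n_bins)
    if smooth_window_s > 1:
        kernel = np.ones(smooth_window_s) / smooth_window_s
        pad = smooth_window_s // 2
        padded = np.pad(per_s, pad, mode="edge")
        smoothed = np.convolve(padded, kernel, mode="valid")[:n_bins]
    else:
        smoothed = per_s
    lag_bins = int(round(lag_s))
    lagged = np.roll(smoothed, lag_bins)
    lagged[:lag_bins] = 0.0  # before the (lagged) first note: neutral
    if noise_sd > 0:
        lagged = lagged + rng.normal(0.0, noise_sd, size=n_bins)

    values = 1 + (lagged[:, None] > np.array(thresholds)[None, :]).sum(axis=1)
    first_bin = int(ic.timestamps_s[0]) + lag_bins
    values[: min(first_bin, n_bins)] = 1
    return RatingSeries(ic.piece_id, "", values,
                        flagged_constant=bool(np.all(values == values[0])))


@dataclass(frozen=True)
class CouplingSpec:
    """How a ground-truth regressor drives ROI oscillatory amplitude.

    ``gain`` is in signal-amplitude units per regressor unit; the coupled
    oscillation's envelope is ``baseline + gain * regressor`` (floored at 0)
    carried at ``carrier_hz`` (default: the band's midpoint, which keeps the
    energy inside the band after wavelet smearing).
    """

    band: str = "beta"
    roi_channels: Tuple[str, ...] = FRONTAL_ROI
    gain: float = 0.0
    regressor: str = "ic_melody"  # ic_melody | ic_harmony | pleasure | none
    lag_s: float = 0.0
    baseline: float = 1.0
    carrier_hz: float | None = None

    def __post_init__(self) -> None:
        if self.band not in BAND_EDGES_HZ:
            raise ValueError(f"unknown band {self.band!r}")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")
        if self.lag_s < 0:
            raise ValueError("lag_s must be >= 0")

    @property
    def effective_carrier_hz(self) -> float:
        if self.carrier_hz is not None:
            return self.carrier_hz
        lo, hi = BAND_EDGES_HZ[self.band]
        return (lo + hi) / 2.0


def _pink_noise(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise with standard deviation ``scale``."""
    if scale == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.zeros_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    return x * (scale / sd) if sd > 0 else x


def generate_eeg(
    piece_duration_s: float,
    fs: float,
    montage: Sequence[str],
    coupling: CouplingSpec,
    noise: Dict[str, float] | None = None,
    regressor_series: np.ndarray | None = None,
    seed: int = 0,
    piece_id: str = "",
    subject_id: str = "",
) -> EEGRecording:
    """Simulate one recording: pink + white noise, plus a coupled oscillation.

    Every channel receives independent pink and white noise. Channels in
    ``coupling.roi_channels`` additionally carry a sinusoid at the coupled
    band's carrier frequency whose envelope follows the lagged regressor
    (linearly interpolated from its per-second samples at bin centres).
    """
    noise = {"pink_scale": 1.0, "white_scale": 0.5} if noise is None else noise
    unknown = set(coupling.roi_channels) - set(montage)
    if unknown:
        raise ValueError(f"roi_channels not in montage: {sorted(unknown)}")
    lo, hi = BAND_EDGES_HZ[coupling.band]
    if fs < 2 * hi:
        raise ValueError(f"fs = {fs} too low for the {coupling.band} band (<= {hi} Hz)")

    n = int(round(piece_duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    needs_drive = coupling.regressor != "none" and coupling.gain > 0
    if needs_drive or coupling.baseline > 0:
        if regressor_series is not None:
            reg = np.asarray(regressor_series, dtype=float)
            if reg.size < int(piece_duration_s):
                raise ValueError("regressor_series does not cover the piece duration")
            bin_centres = np.arange(reg.size) + 0.5
            drive = np.interp(t - coupling.lag_s, bin_centres, reg)
        elif needs_drive:
            raise ValueError("coupling requires a regressor_series")
        else:
            drive = np.zeros(n)
        envelope = np.clip(coupling.baseline + coupling.gain * drive, 0.0, None)
    else:
        envelope = None

    data = np.empty((len(montage), n))
    for c, name in enumerate(montage):
        x = _pink_noise(rng, n, noise.get("pink_scale", 1.0))
        x = x + rng.normal(0.0, noise.get("white_scale", 0.5), size=n)
        if envelope is not None and name in coupling.roi_channels:
            phase = rng.uniform(0, 2 * np.pi)
            x = x + envelope * np.sin(
                2 * np.pi * coupling.effective_carrier_hz * t + phase
            )
        data[c] = x
    return EEGRecording(list(montage), fs, data, piece_id=piece_id,
                        subject_id=subject_id)


# -- whole-study assembly ----------------------------------------------------


@dataclass
class Piece:
    piece_id: str
    melody: SymbolSequence
    harmony: SymbolSequence
    ic_melody: SurpriseSeries
    ic_harmony: SurpriseSeries
    duration_s: float


@dataclass
class SubjectData:
    subject_id: str
    eeg: Dict[str, EEGRecording]  # piece_id -> recording
    ratings: Dict[str, RatingSeries]  # piece_id -> rating series


@dataclass
class StudyConfig:
    """All knobs of a synthetic study; defaults mirror the study design
    (8 pieces x 15 subjects, 30 channels at 512 Hz)."""

    n_pieces: int = 8
    n_subjects: int = 15
    piece_duration_s: float = 60.0
    fs: float = 512.0
    montage: Tuple[str, ...] = MONTAGE_30
    melody_alphabet_size: int = 8
    harmony_alphabet_size: int = 6
    markov_order: int = 1
    tempo_events_per_s: float = 2.0
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    noise: Dict[str, float] = field(
        default_factory=lambda: {"pink_scale": 1.0, "white_scale": 0.5}
    )
    rating_lag_s: float = 2.0
    rating_thresholds: Tuple[float, float, float] = (1.8, 2.6, 3.4)
    rating_noise_sd: float = 0.3
    seed: int = 0


@dataclass
class SyntheticStudy:
    pieces: List[Piece]
    subjects: List[SubjectData]
    config: StudyConfig

    def recording(self, subject_id: str, piece_id: str) -> EEGRecording:
        subj = next(s for s in self.subjects if s.subject_id == subject_id)
        return subj.eeg[piece_id]


_MELODY_PITCHES = tuple(range(60, 60 + 12))  # C4 upward
# small chord vocabulary: common pitch-class triads/tetrads
_CHORD_SYMBOLS = (
    (0, 4, 7), (2, 5, 9), (4, 7, 11), (5, 9, 0), (7, 11, 2),
    (9, 0, 4), (0, 4, 7, 10), (5, 9, 0, 3),
)


def generate_study(config: StudyConfig | None = None) -> SyntheticStudy:
    """Build a full synthetic study: pieces, per-subject ratings and EEG.

    Deterministic given ``config`` (including its seed): all randomness is
    drawn from child streams of one SeedSequence.
    """
    cfg = config or StudyConfig()
    root = np.random.SeedSequence(cfg.seed)
    s_mel, s_har, s_pieces, s_subj = root.spawn(4)

    mel_source = random_markov_source(
        cfg.markov_order, _MELODY_PITCHES[: cfg.melody_alphabet_size],
        seed=s_mel.generate_state(1)[0] % (2**31),
    )
    har_source = random_markov_source(
        cfg.markov_order, _CHORD_SYMBOLS[: cfg.harmony_alphabet_size],
        seed=s_har.generate_state(1)[0] % (2**31),
    )
    length = int(cfg.piece_duration_s * cfg.tempo_events_per_s)
    mel = generate_markov_pieces(
        mel_source, cfg.n_pieces, length, cfg.tempo_events_per_s,
        seed=s_pieces.generate_state(1)[0] % (2**31), stream="melody",
    )
    har = generate_markov_pieces(
        har_source, cfg.n_pieces, length // 2, cfg.tempo_events_per_s / 2,
        seed=(s_pieces.generate_state(2)[1]) % (2**31), stream="harmony",
    )
    pieces = []
    for (m_seq, m_ic), (h_seq, h_ic) in zip(mel, har):
        h_seq.piece_id = m_seq.piece_id
        h_ic.piece_id = m_seq.piece_id
        pieces.append(
            Piece(m_seq.piece_id, m_seq, h_seq, m_ic, h_ic, cfg.piece_duration_s)
        )

    n_bins = int(cfg.piece_duration_s)
    subjects: List[SubjectData] = []
    subj_seeds = s_subj.spawn(cfg.n_subjects)
    for j in range(cfg.n_subjects):
        sid = f"sub{j:02d}"
        per_piece_seeds = subj_seeds[j].spawn(len(pieces))
        eeg: Dict[str, EEGRecording] = {}
        ratings: Dict[str, RatingSeries] = {}
        for p, piece in enumerate(pieces):
            st = per_piece_seeds[p].generate_state(2) % (2**31)
            rating = generate_ratings(
                piece.ic_melody,
                lag_s=cfg.rating_lag_s,
                thresholds=cfg.rating_thresholds,
                piece_duration_s=cfg.piece_duration_s,
                seed=int(st[0]),
                noise_sd=cfg.rating_noise_sd,
            )
            rating.subject_id = sid
            ratings[piece.piece_id] = rating
            reg = _regressor_values(cfg.coupling.regressor, piece, rating, n_bins)
            eeg[piece.piece_id] = generate_eeg(
                cfg.piece_duration_s, cfg.fs, cfg.montage, cfg.coupling,
                noise=cfg.noise, regressor_series=reg, seed=int(st[1]),
                piece_id=piece.piece_id, subject_id=sid,
            )
        subjects.append(SubjectData(sid, eeg, ratings))
    return SyntheticStudy(pieces, subjects, cfg)


def _regressor_values(
    kind: str, piece: Piece, rating: RatingSeries, n_bins: int
) -> np.ndarray:
    if kind == "ic_melody":
        return _ic_per_second(piece.ic_melody, n_bins)
    if kind == "ic_harmony":
        return _ic_per_second(piece.ic_harmony, n_bins)
    if kind == "pleasure":
        return rating.values.astype(float)
    if kind == "none":
        return np.zeros(n_bins)
    raise ValueError(f"unknown regressor kind {kind!r}")
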