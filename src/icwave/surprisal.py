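"""Variable-order Markov (PPM) surprisal engine for symbolic music.

Melody and harmony are represented as discrete token streams; a
prediction-by-partial-matching (PPM) model assigns each event a conditional
probability ``p`` given its context, and the information content

    IC(p) = -log2(p)   [bits]

quantifies how surprising the event is. Two models are maintained: a
long-term model (``ltm``) trained on a background corpus and a short-term
model (``stm``) trained causally on the piece itself. In the ``both+``
configuration the ltm additionally keeps learning from the piece, and the
two predictive distributions are merged by an entropy-weighted geometric
mean before scoring each event.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, List, Sequence, Tuple

import numpy as np

Symbol = Hashable
Context = Tuple[Symbol, ...]

__all__ = [
    "NoteEvent",
    "SymbolSequence",
    "SurpriseSeries",
    "PredictiveDistribution",
    "PPMModel",
    "extract_melody",
    "chordify",
    "train",
    "predict",
    "combine",
    "sequence_ic",
]


@dataclass(frozen=True)
class NoteEvent:
    """A timed note: onset and duration in seconds, MIDI pitch 0-127."""

    onset_s: float
    duration_s: float
    pitch: int
    part_id: str = ""

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError(f"onset_s must be >= 0, got {self.onset_s}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if not (0 <= self.pitch <= 127):
            raise ValueError(f"pitch must be in [0, 127], got {self.pitch}")

    @property
    def pitch_class(self) -> int:
        return self.pitch % 12


@dataclass
class SymbolSequence:
    """An ordered discrete token stream with strictly increasing timestamps.

    ``stream`` is ``"melody"`` (tokens are MIDI pitches) or ``"harmony"``
    (tokens are sorted tuples of 3-5 distinct pitch classes).
    """

    piece_id: str
    stream: str
    tokens: List[Symbol]
    timestamps_s: List[float]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.timestamps_s):
            raise ValueError("tokens and timestamps_s must have equal length")
        ts = np.asarray(self.timestamps_s, dtype=float)
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps_s must be strictly increasing")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class SurpriseSeries:
    """Per-event information content (bits), aligned 1:1 with a SymbolSequence."""

    piece_id: str
    stream: str
    ic_bits: List[float]
    timestamps_s: List[float]

    def __post_init__(self) -> None:
        if len(self.ic_bits) != len(self.timestamps_s):
            raise ValueError("ic_bits and timestamps_s must have equal length")
        if any((not math.isfinite(x)) or x < 0 for x in self.ic_bits):
            raise ValueError("every IC value must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.ic_bits)


@dataclass
class PredictiveDistribution:
    """Next-symbol distribution over the model's current alphabet."""

    probabilities: Dict[Symbol, float]
    context_used: Context = ()

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1 (got {total!r})")
        if any(p < 0 for p in self.probabilities.values()):
            raise ValueError("probabilities must be non-negative")

    def __getitem__(self, symbol: Symbol) -> float:
        return self.probabilities[symbol]

    def entropy_bits(self) -> float:
        p = np.array(list(self.probabilities.values()), dtype=float)
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())


class PPMModel:
    """Interpolated PPM with escape method C.

    Counts are kept for every context of length 0..``max_order``. Prediction
    blends the maximum-likelihood estimate at the longest matching context
    with successively shorter contexts; at each level the escape mass
    ``d / (N + d)`` (``d`` distinct continuations, ``N`` total count) is
    passed down, terminating in a uniform order -1 distribution over the
    alphabet plus one reserved "unseen" slot. Every alphabet symbol therefore
    receives strictly positive probability.
    """

    def __init__(
        self,
        max_order: int = 2,
        alphabet: Iterable[Symbol] = (),
        escape: str = "C",
    ) -> None:
        if max_order < 0:
            raise ValueError("max_order must be >= 0")
        if escape != "C":
            raise ValueError(f"unknown escape method {escape!r}; available: 'C'")
        self.max_order = int(max_order)
        self.escape = escape
        self.alphabet: set = set(alphabet)
        self.counts: Dict[Context, Counter] = {}

    # -- training -----------------------------------------------------------

    def observe(self, context: Sequence[Symbol], symbol: Symbol) -> None:
        """Add one event: increment counts for every context suffix."""
        ctx = tuple(context)[-self.max_order :] if self.max_order else ()
        self.alphabet.add(symbol)
        for k in range(len(ctx) + 1):
            sub = ctx[len(ctx) - k :]
            self.counts.setdefault(sub, Counter())[symbol] += 1

    def train_sequence(self, tokens: Sequence[Symbol]) -> None:
        for i, sym in enumerate(tokens):
            self.observe(tokens[:i], sym)

    # -- prediction ---------------------------------------------------------

    def predict(
        self,
        context: Sequence[Symbol] = (),
        alphabet: Iterable[Symbol] | None = None,
    ) -> PredictiveDistribution:
        """Predictive distribution after PPM-C back-off smoothing.

        Contexts longer than ``max_order`` are truncated to their last
        ``max_order`` symbols. ``alphabet`` may widen the support (symbols
        without counts draw only on the uniform order -1 floor).
        """
        support = set(self.alphabet)
        if alphabet is not None:
            support |= set(alphabet)
        if not support:
            raise ValueError("cannot predict: model untrained and no alphabet declared")
        ctx = tuple(context)[-self.max_order :] if self.max_order else ()

        prob = dict.fromkeys(support, 0.0)
        escape_mass = 1.0
        for k in range(len(ctx), -1, -1):
            counter = self.counts.get(ctx[len(ctx) - k :])
            if not counter:
                continue
            n_total = sum(counter.values())
            d = len(counter)
            denom = n_total + d
            for sym, n in counter.items():
                if sym in prob:
                    prob[sym] += escape_mass * n / denom
            escape_mass *= d / denom
        # order -1: uniform over support plus one reserved unseen slot
        floor = escape_mass / (len(support) + 1)
        for sym in prob:
            prob[sym] += floor
        total = sum(prob.values())  # = 1 - floor left on the unseen slot
        return PredictiveDistribution(
            {sym: p / total for sym, p in prob.items()}, context_used=ctx
        )

    def copy(self) -> "PPMModel":
        new = PPMModel(self.max_order, self.alphabet, self.escape)
        new.counts = {ctx: Counter(c) for ctx, c in self.counts.items()}
        return new


# -- stream preparation ------------------------------------------------------


def extract_melody(notes: Sequence[NoteEvent], melody_part: str) -> SymbolSequence:
    """Melody token stream: pitches of one part in onset order.

    Simultaneous onsets within the part resolve to the highest pitch
    (top-voice heuristic).
    """
    if not notes:
        raise ValueError("notes must be non-empty")
    part_notes = [n for n in notes if n.part_id == melody_part]
    if not part_notes:
        available = sorted({n.part_id for n in notes})
        raise ValueError(
            f"part {melody_part!r} not found; available parts: {available}"
        )
    by_onset: Dict[float, int] = {}
    for n in sorted(part_notes, key=lambda n: (n.onset_s, -n.pitch)):
        by_onset.setdefault(n.onset_s, n.pitch)  # first seen = highest pitch
    onsets = sorted(by_onset)
    return SymbolSequence(
        piece_id="",
        stream="melody",
        tokens=[by_onset[t] for t in onsets],
        timestamps_s=list(onsets),
    )


def chordify(
    notes: Sequence[NoteEvent],
    onset_tolerance_s: float = 0.05,
    min_notes: int = 3,
    max_notes: int = 5,
) -> SymbolSequence:
    """Harmony token stream: near-simultaneous notes grouped into chords.

    Notes whose onsets fall within ``onset_tolerance_s`` of the window's
    first onset form a candidate chord; candidates with ``min_notes`` to
    ``max_notes`` distinct pitch classes become tokens (sorted pitch-class
    tuples, octave-invariant) stamped at the window's earliest onset. Other
    windows are dropped; an empty result is valid.
    """
    if onset_tolerance_s < 0:
        raise ValueError("onset_tolerance_s must be >= 0")
    ordered = sorted(notes, key=lambda n: n.onset_s)
    tokens: List[Symbol] = []
    timestamps: List[float] = []
    i = 0
    while i < len(ordered):
        start = ordered[i].onset_s
        window = [ordered[i]]
        i += 1
        while i < len(ordered) and ordered[i].onset_s <= start + onset_tolerance_s:
            window.append(ordered[i])
            i += 1
        pcs = tuple(sorted({n.pitch_class for n in window}))
        if min_notes <= len(pcs) <= max_notes:
            tokens.append(pcs)
            timestamps.append(start)
    return SymbolSequence(
        piece_id="", stream="harmony", tokens=tokens, timestamps_s=timestamps
    )


# -- functional wrappers -----------------------------------------------------


def train(model: PPMModel, corpus: Iterable[SymbolSequence]) -> PPMModel:
    """Train ``model`` in place on every sequence of ``corpus``; returns it.

    Training is additive: repeating a sequence doubles its counts.
    """
    for seq in corpus:
        model.train_sequence(seq.tokens)
    return model


def predict(model: PPMModel, context: Sequence[Symbol] = ()) -> PredictiveDistribution:
    return model.predict(context)


def combine(
    dist_ltm: PredictiveDistribution,
    dist_stm: PredictiveDistribution,
    bias: float = 1.0,
) -> PredictiveDistribution:
    """Merge ltm and stm predictions by an entropy-weighted geometric mean.

    Each distribution gets weight proportional to its normalized Shannon
    entropy raised to ``-bias``: confident (low-entropy) models dominate for
    positive bias, and ``bias = 0`` reduces to the plain geometric mean.
    """
    support = set(dist_ltm.probabilities)
    if support != set(dist_stm.probabilities):
        raise ValueError("distributions must share an identical support")
    n = len(support)
    log_n = math.log2(n) if n > 1 else 1.0
    eps = 1e-12
    weights = []
    for d in (dist_ltm, dist_stm):
        h_norm = d.entropy_bits() / log_n
        weights.append(max(h_norm, eps) ** (-bias))
    w_sum = weights[0] + weights[1]
    w_ltm, w_stm = weights[0] / w_sum, weights[1] / w_sum

    symbols = list(support)
    p1 = np.array([dist_ltm[s] for s in symbols], dtype=float)
    p2 = np.array([dist_stm[s] for s in symbols], dtype=float)
    log_p = w_ltm * np.log(np.maximum(p1, 1e-300)) + w_stm * np.log(
        np.maximum(p2, 1e-300)
    )
    p = np.exp(log_p - log_p.max())
    p /= p.sum()
    return PredictiveDistribution(dict(zip(symbols, p.tolist())))


@dataclass
class SurprisalConfig:
    max_order: int = 2
    bias: float = 1.0
    mode: str = "both_plus"


def sequence_ic(
    ltm_corpus: Iterable[SymbolSequence],
    target: SymbolSequence,
    config: SurprisalConfig | None = None,
) -> SurpriseSeries:
    """Per-event information content of ``target`` under the both+ scheme.

    Processing is strictly causal: for event ``i`` the stm has seen only
    ``target[:i]`` and the ltm has seen the corpus plus ``target[:i]``; both
    are updated with event ``i`` only after it has been scored. IC at event
    ``i`` therefore never depends on later events.
    """
    if len(target) == 0:
        raise ValueError("target must be non-empty")
    cfg = config or SurprisalConfig()

    ltm = PPMModel(max_order=cfg.max_order)
    for seq in ltm_corpus:
        ltm.train_sequence(seq.tokens)
    stm = PPMModel(max_order=cfg.max_order)

    alphabet = set(ltm.alphabet)
    ic: List[float] = []
    tokens = target.tokens
    for i, sym in enumerate(tokens):
        alphabet.add(sym)  # support fixed before scoring; uses no later event
        context = tokens[max(0, i - cfg.max_order) : i]
        if cfg.mode == "both_plus":
            d_ltm = ltm.predict(context, alphabet=alphabet)
            d_stm = stm.predict(context, alphabet=alphabet)
            dist = combine(d_ltm, d_stm, bias=cfg.bias)
        elif cfg.mode == "ltm":
            dist = ltm.predict(context, alphabet=alphabet)
        elif cfg.mode == "stm":
            dist = stm.predict(context, alphabet=alphabet)
        else:
            raise ValueError(f"unknown mode {cfg.mode!r}")
        ic.append(-math.log2(dist[sym]))
        stm.observe(context, sym)
        if cfg.mode != "stm":
            ltm.observe(context, sym)
    return SurpriseSeries(
        piece_id=target.piece_id,
        stream=target.stream,
        ic_bits=ic,
        timestamps_s=list(target.timestamps_s),
    )
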