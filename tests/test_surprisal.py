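"""Unit tests for the PPM surprisal engine and music-stream preparation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icwave.surprisal import (
    NoteEvent,
    PPMModel,
    PredictiveDistribution,
    SurprisalConfig,
    SymbolSequence,
    chordify,
    combine,
    extract_melody,
    sequence_ic,
)

# ---------------------------------------------------------------------------
# independent oracle: recursive PPM-C evaluator over raw count tables


def oracle_counts(tokens, max_order):
    """Hand enumeration of context counts for every order 0..max_order."""
    counts = {}
    for i, sym in enumerate(tokens):
        for k in range(max_order + 1):
            if i - k < 0:
                continue
            ctx = tuple(tokens[i - k : i])
            counts.setdefault(ctx, {}).setdefault(sym, 0)
            counts[ctx][sym] += 1
    return counts


def oracle_ppm_c(counts, context, alphabet, max_order):
    """Recursive PPM escape-method-C probability for every alphabet symbol.

    p(s | c) = n(c,s)/(N+d) + d/(N+d) * p(s | shorter c), bottoming out in a
    uniform distribution over |alphabet| + 1 slots; finally renormalized
    over the alphabet.
    """
    ctx = tuple(context)[-max_order:] if max_order else ()

    def p(sym, c):
        if len(c) < 0:
            raise AssertionError
        table = counts.get(c, {})
        total = sum(table.values())
        d = len(table)
        if c == ():
            base = 1.0 / (len(alphabet) + 1)
        else:
            base = p(sym, c[1:])
        if total == 0:
            return base
        return table.get(sym, 0) / (total + d) + (d / (total + d)) * base

    raw = {s: p(s, ctx) for s in alphabet}
    z = sum(raw.values())
    return {s: v / z for s, v in raw.items()}


def seq(tokens, stream="melody", piece="p"):
    return SymbolSequence(piece, stream, list(tokens), list(range(len(tokens))))


# ---------------------------------------------------------------------------
# stream preparation


class TestExtractMelody:
    def test_sequential_triad_maps_to_pitches(self):
        notes = [NoteEvent(0.0, 0.5, 60, "m"), NoteEvent(1.0, 0.5, 64, "m"),
                 NoteEvent(2.0, 0.5, 67, "m")]
        s = extract_melody(notes, "m")
        assert s.tokens == [60, 64, 67]
        assert s.timestamps_s == [0.0, 1.0, 2.0]

    def test_simultaneous_onset_keeps_highest_pitch(self):
        notes = [NoteEvent(0.0, 0.5, 60, "m"), NoteEvent(0.0, 0.5, 72, "m")]
        s = extract_melody(notes, "m")
        assert s.tokens == [72]

    def test_twenty_note_part_matches_hand_sorted_listing(self):
        rng = np.random.default_rng(42)
        onsets = rng.permutation(20) * 0.25
        pitches = rng.integers(48, 84, size=20)
        notes = [NoteEvent(float(t), 0.2, int(p), "m")
                 for t, p in zip(onsets, pitches)]
        expected = [int(p) for _, p in sorted(zip(onsets, pitches))]
        assert extract_melody(notes, "m").tokens == expected

    def test_missing_part_error_names_available_parts(self):
        notes = [NoteEvent(0.0, 0.5, 60, "bass")]
        with pytest.raises(ValueError, match="bass"):
            extract_melody(notes, "melody")


class TestChordify:
    def test_simultaneous_triad_is_one_pitch_class_token(self):
        notes = [NoteEvent(0.0, 1.0, 60, "h"), NoteEvent(0.0, 1.0, 64, "h"),
                 NoteEvent(0.0, 1.0, 67, "h")]
        s = chordify(notes)
        assert s.tokens == [(0, 4, 7)]
        assert s.timestamps_s == [0.0]

    def test_dyad_below_min_notes_is_dropped(self):
        notes = [NoteEvent(0.0, 1.0, 60, "h"), NoteEvent(0.0, 1.0, 67, "h")]
        assert chordify(notes).tokens == []

    def test_six_onset_clusters_match_window_grouping_oracle(self):
        rng = np.random.default_rng(7)
        notes = []
        for k in range(6):
            base = k * 1.0
            n_notes = int(rng.integers(2, 6))
            for j in range(n_notes):
                notes.append(
                    NoteEvent(base + float(rng.uniform(0, 0.04)), 0.5,
                              int(rng.integers(40, 90)), "h")
                )
        tol = 0.05
        # oracle: exhaustive greedy grouping on the sorted onsets
        ordered = sorted(notes, key=lambda n: n.onset_s)
        expected, i = [], 0
        while i < len(ordered):
            start = ordered[i].onset_s
            group = []
            while i < len(ordered) and ordered[i].onset_s <= start + tol:
                group.append(ordered[i])
                i += 1
            pcs = tuple(sorted({n.pitch % 12 for n in group}))
            if 3 <= len(pcs) <= 5:
                expected.append((start, pcs))
        got = chordify(notes, onset_tolerance_s=tol)
        assert list(zip(got.timestamps_s, got.tokens)) == expected


# ---------------------------------------------------------------------------
# training and prediction


class TestTrain:
    def test_empty_corpus_predicts_uniform_over_declared_alphabet(self):
        m = PPMModel(max_order=2, alphabet="ABCD")
        dist = m.predict(())
        assert dist.probabilities == pytest.approx(
            {s: 0.25 for s in "ABCD"}, abs=1e-12
        )

    def test_abab_counts_match_hand_enumeration(self):
        m = PPMModel(max_order=1)
        m.train_sequence(list("ABAB"))
        assert m.counts[("A",)]["B"] == 2
        assert m.counts[("B",)]["A"] == 1
        assert m.counts[()] == {"A": 2, "B": 2}

    def test_training_twice_doubles_every_count(self):
        a, b = PPMModel(max_order=2), PPMModel(max_order=2)
        tokens = list("ABACABA")
        a.train_sequence(tokens)
        b.train_sequence(tokens)
        b.train_sequence(tokens)
        for ctx, counter in a.counts.items():
            for sym, n in counter.items():
                assert b.counts[ctx][sym] == 2 * n


class TestPredict:
    def test_repeated_continuation_dominates(self):
        m = PPMModel(max_order=1)
        m.train_sequence(list("AB" * 50))
        dist = m.predict(("A",))
        assert dist["B"] > 0.95
        assert dist["A"] > 0  # escape floor keeps all symbols possible

    def test_abab_context_a_matches_recursive_oracle(self):
        tokens = list("ABAB")
        m = PPMModel(max_order=1)
        m.train_sequence(tokens)
        got = m.predict(("A",))
        expected = oracle_ppm_c(
            oracle_counts(tokens, 1), ("A",), sorted(m.alphabet), 1
        )
        for s in expected:
            assert got[s] == pytest.approx(expected[s], abs=1e-12)

    def test_long_context_is_truncated(self):
        m = PPMModel(max_order=1)
        m.train_sequence(list("ABAB"))
        assert (
            m.predict(("X", "Y", "A")).probabilities
            == m.predict(("A",)).probabilities
        )

    @given(st.lists(st.sampled_from("ABC"), min_size=1, max_size=12),
           st.lists(st.sampled_from("ABC"), max_size=3),
           st.integers(min_value=0, max_value=2))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_distribution_is_proper(self, tokens, context, max_order):
        m = PPMModel(max_order=max_order)
        m.train_sequence(tokens)
        dist = m.predict(tuple(context))
        assert sum(dist.probabilities.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(p > 0 for p in dist.probabilities.values())


class TestCombine:
    def d(self, probs):
        return PredictiveDistribution(dict(probs))

    def test_identical_inputs_are_idempotent(self):
        d = self.d({"A": 0.7, "B": 0.3})
        out = combine(d, d, bias=1.0)
        assert out.probabilities == pytest.approx(d.probabilities, abs=1e-12)

    def test_bias_zero_is_plain_geometric_mean(self):
        d1 = self.d({"A": 0.8, "B": 0.2})
        d2 = self.d({"A": 0.4, "B": 0.6})
        out = combine(d1, d2, bias=0.0)
        raw = {s: math.sqrt(d1[s] * d2[s]) for s in "AB"}
        z = sum(raw.values())
        for s in "AB":
            assert out[s] == pytest.approx(raw[s] / z, abs=1e-12)

    def test_bias_pulls_output_towards_confident_model(self):
        sharp = self.d({"A": 0.97, "B": 0.02, "C": 0.01})
        flat = self.d({"A": 0.34, "B": 0.33, "C": 0.33})
        out = combine(sharp, flat, bias=1.0)

        def kl(p, q):  # independent numerical divergence oracle
            return sum(p[s] * math.log2(p[s] / q[s]) for s in "ABC")

        assert kl(out.probabilities, sharp.probabilities) < kl(
            out.probabilities, flat.probabilities
        )

    def test_mismatched_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            combine(self.d({"A": 1.0}), self.d({"B": 1.0}))


# ---------------------------------------------------------------------------
# whole-sequence information content


class TestSequenceIC:
    def test_ic_nonnegative_and_finite(self):
        target = seq("ABCCABXA")
        out = sequence_ic([seq("ABCAB")], target)
        assert len(out) == len(target)
        assert all(np.isfinite(out.ic_bits)) and min(out.ic_bits) >= 0

    def test_short_term_model_learns_a_periodic_piece(self):
        target = seq("ABC" * 6)
        out = sequence_ic([], target)
        first, last = out.ic_bits[:3], out.ic_bits[-3:]
        assert np.mean(last) < np.mean(first)

    def test_ic_is_causal(self):
        """IC at event i never depends on later events."""
        corpus = [seq("ABCABCAB")]
        a = sequence_ic(corpus, seq("ABCABX"))
        b = sequence_ic(corpus, seq("ABCABA"))
        assert a.ic_bits[:5] == pytest.approx(b.ic_bits[:5], abs=1e-15)

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            sequence_ic([], seq(""))

    def test_stm_only_mode_ignores_corpus(self):
        cfg = SurprisalConfig(mode="stm")
        a = sequence_ic([seq("AAAA")], seq("ABAB"), cfg)
        b = sequence_ic([], seq("ABAB"), cfg)
        assert a.ic_bits == pytest.approx(b.ic_bits, abs=1e-15)
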