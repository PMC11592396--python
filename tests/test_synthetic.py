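"""Unit tests for the synthetic study generator (known-ground-truth inputs)."""

import math

import numpy as np
import pytest

from icwave.spectral import band_power, morlet_energy, roi_average
from icwave.surprisal import SurpriseSeries
from icwave.synthetic import (
    FRONTAL_ROI,
    MONTAGE_30,
    CouplingSpec,
    MarkovSource,
    StudyConfig,
    generate_eeg,
    generate_markov_pieces,
    generate_ratings,
    generate_study,
    random_markov_source,
)


class TestMarkovSource:
    def test_invalid_distribution_rejected_naming_context(self):
        with pytest.raises(ValueError, match=r"\('A',\)"):
            MarkovSource(1, ("A", "B"),
                         {(): {"A": 0.5, "B": 0.5}, ("A",): {"A": 0.7, "B": 0.7}})

    def test_context_longer_than_order_rejected(self):
        with pytest.raises(ValueError, match="order"):
            MarkovSource(0, ("A",), {(): {"A": 1.0}, ("A",): {"A": 1.0}})

    def test_random_source_distributions_are_proper(self):
        src = random_markov_source(2, "ABC", seed=1)
        assert len(src.transition_probabilities) == 1 + 3 + 9
        for dist in src.transition_probabilities.values():
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)


class TestGenerateMarkovPieces:
    def test_deterministic_source_has_zero_ic(self):
        src = MarkovSource(0, ("A",), {(): {"A": 1.0}})
        (_, ic), = generate_markov_pieces(src, 1, 10, seed=0)
        assert ic.ic_bits == [0.0] * 10

    def test_uniform_iid_source_has_two_bits_everywhere(self):
        src = MarkovSource(0, "ABCD", {(): {s: 0.25 for s in "ABCD"}})
        (_, ic), = generate_markov_pieces(src, 1, 64, seed=1)
        assert ic.ic_bits == pytest.approx([2.0] * 64, abs=1e-12)

    def test_order1_transition_ic_is_minus_log2_p(self):
        # direct evaluation of -log2 p for the emitted transition
        src = MarkovSource(
            1, ("A", "B"),
            {(): {"A": 1.0, "B": 0.0},
             ("A",): {"A": 0.9, "B": 0.1},
             ("B",): {"A": 1.0, "B": 0.0}},
        )
        (s, ic), = generate_markov_pieces(src, 1, 400, seed=3)
        expected = {"A": None, "B": -math.log2(0.1)}
        saw_b = False
        for i in range(1, 400):
            if s.tokens[i - 1] == "A" and s.tokens[i] == "B":
                assert ic.ic_bits[i] == pytest.approx(-math.log2(0.1), abs=1e-12)
                saw_b = True
        assert saw_b

    def test_timestamps_evenly_spaced_by_tempo(self):
        src = MarkovSource(0, "AB", {(): {"A": 0.5, "B": 0.5}})
        (s, _), = generate_markov_pieces(src, 1, 8, tempo_events_per_s=4.0, seed=0)
        assert np.allclose(np.diff(s.timestamps_s), 0.25)

    def test_length_shorter_than_order_rejected(self):
        src = random_markov_source(2, "AB", seed=0)
        with pytest.raises(ValueError):
            generate_markov_pieces(src, 1, 2, seed=0)


def ic_series(values, times=None, piece="p"):
    times = list(range(len(values))) if times is None else times
    return SurpriseSeries(piece, "melody", list(values), list(times))


class TestGenerateRatings:
    def test_low_ic_below_all_thresholds_is_all_neutral(self):
        ic = ic_series([0.1] * 30)
        r = generate_ratings(ic, lag_s=0, thresholds=(1, 2, 3),
                             piece_duration_s=30)
        assert np.all(r.values == 1)
        assert r.flagged_constant

    def test_ic_above_all_thresholds_is_all_chills(self):
        ic = ic_series([10.0] * 30)
        r = generate_ratings(ic, lag_s=0, thresholds=(1, 2, 3),
                             piece_duration_s=30, smooth_window_s=1)
        assert np.all(r.values == 4)

    def test_step_in_ic_steps_rating_after_lag(self):
        # step at t = 10 s, lag 2 s -> rating steps at bin 12; checked
        # against a brute-force re-evaluation of the thresholding rule
        vals = [0.0] * 10 + [5.0] * 20
        ic = ic_series(vals)
        r = generate_ratings(ic, lag_s=2.0, thresholds=(1, 2, 3),
                             piece_duration_s=30, smooth_window_s=1)
        lagged = np.roll(np.array(vals), 2)
        lagged[:2] = 0
        expected = 1 + (lagged[:, None] > np.array([1, 2, 3])).sum(axis=1)
        assert list(r.values) == list(expected)
        assert r.values[11] == 1 and r.values[12] == 4

    def test_empty_ic_gives_flagged_neutral_series(self):
        r = generate_ratings(ic_series([]), piece_duration_s=20)
        assert np.all(r.values == 1) and r.flagged_constant

    def test_thresholds_must_ascend(self):
        with pytest.raises(ValueError):
            generate_ratings(ic_series([1.0]), thresholds=(3, 2, 1),
                             piece_duration_s=10)

    def test_raising_ic_never_lowers_rating(self):
        base = ic_series(list(np.linspace(0, 4, 40)))
        up = ic_series(list(np.linspace(0, 4, 40) + 0.5))
        r0 = generate_ratings(base, lag_s=0, piece_duration_s=40)
        r1 = generate_ratings(up, lag_s=0, piece_duration_s=40)
        assert np.all(r1.values >= r0.values)


class TestGenerateEEG:
    def test_unknown_roi_channel_rejected(self):
        spec = CouplingSpec(roi_channels=("Nope",))
        with pytest.raises(ValueError, match="Nope"):
            generate_eeg(10, 128, MONTAGE_30, spec)

    def test_zero_everything_is_all_zero(self):
        spec = CouplingSpec(gain=0.0, regressor="none", baseline=0.0)
        rec = generate_eeg(10, 128, FRONTAL_ROI, spec,
                           noise={"pink_scale": 0, "white_scale": 0})
        assert np.all(rec.data == 0)
        tfe = morlet_energy(rec)
        assert np.all(tfe.energy == 0)

    def test_output_length_and_shape(self):
        spec = CouplingSpec(gain=0.0, regressor="none")
        rec = generate_eeg(7.5, 128, FRONTAL_ROI, spec, seed=1)
        assert rec.data.shape == (8, 960)

    def test_fs_below_band_nyquist_rejected(self):
        spec = CouplingSpec(band="gamma")
        with pytest.raises(ValueError, match="too low"):
            generate_eeg(10, 64, FRONTAL_ROI, spec)

    def test_strong_coupling_gives_high_power_regressor_correlation(self):
        # gain recorded with the recovery fixtures; envelope-coupled beta
        # power should track the regressor almost perfectly
        rng = np.random.default_rng(11)
        reg = rng.uniform(0, 4, size=40)
        spec = CouplingSpec(band="beta", gain=1.0, regressor="ic_melody")
        rec = generate_eeg(40, 128, FRONTAL_ROI, spec, regressor_series=reg,
                           seed=2)
        tfe = morlet_energy(rec)
        beta = roi_average(band_power(tfe)["beta"], roi=FRONTAL_ROI)
        r = np.corrcoef(beta.values, reg[: beta.values.size])[0, 1]
        assert r > 0.9

    def test_gain_zero_slope_is_null_across_seeds(self):
        # across many seeds the regression of binned beta power on the
        # regressor has mean slope ~ 0 (95% CI covers 0)
        import scipy.stats

        rng = np.random.default_rng(5)
        reg = rng.uniform(0, 4, size=20)
        spec = CouplingSpec(band="beta", gain=0.0, regressor="ic_melody")
        slopes = []
        for s in range(120):
            rec = generate_eeg(20, 128, FRONTAL_ROI, spec,
                               regressor_series=reg, seed=100 + s)
            tfe = morlet_energy(rec)
            beta = roi_average(band_power(tfe)["beta"], roi=FRONTAL_ROI)
            slopes.append(
                scipy.stats.linregress(reg[: beta.values.size], beta.values).slope
            )
        slopes = np.array(slopes)
        ci = 1.96 * slopes.std(ddof=1) / np.sqrt(slopes.size)
        assert abs(slopes.mean()) < ci


class TestGenerateStudy:
    def test_reproducible_bit_identical(self):
        cfg = StudyConfig(n_pieces=1, n_subjects=2, piece_duration_s=20,
                          fs=128, montage=FRONTAL_ROI)
        a, b = generate_study(cfg), generate_study(cfg)
        assert a.pieces[0].melody.tokens == b.pieces[0].melody.tokens
        for sa, sb in zip(a.subjects, b.subjects):
            for pid in sa.eeg:
                assert np.array_equal(sa.eeg[pid].data, sb.eeg[pid].data)
                assert np.array_equal(sa.ratings[pid].values,
                                      sb.ratings[pid].values)

    def test_true_ic_matches_minus_log2_of_generating_probability(self):
        cfg = StudyConfig(n_pieces=2, n_subjects=1, piece_duration_s=30,
                          fs=128, montage=FRONTAL_ROI, seed=3)
        study = generate_study(cfg)
        for piece in study.pieces:
            assert len(piece.ic_melody) == len(piece.melody)
            assert min(piece.ic_melody.ic_bits) >= 0
            assert len(piece.ic_harmony) == len(piece.harmony)

    def test_study_geometry_and_coverage(self):
        cfg = StudyConfig(n_pieces=2, n_subjects=3, piece_duration_s=25,
                          fs=128, montage=FRONTAL_ROI)
        study = generate_study(cfg)
        assert len(study.pieces) == 2 and len(study.subjects) == 3
        for subj in study.subjects:
            for piece in study.pieces:
                rec = subj.eeg[piece.piece_id]
                # EEG covers the piece; ratings cover every 1-s bin
                assert rec.duration_s >= piece.melody.timestamps_s[-1]
                assert subj.ratings[piece.piece_id].values.size == 25
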