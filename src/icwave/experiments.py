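"""Simulation experiments: null calibration, coupling recovery, convergence.

These are the package's own validation studies, shared by the test suite
and the acceptance script. Each runs the full chain (synthesis ->
preprocessing -> Morlet band power -> GLM -> group test) at a reduced desk
scale (default 60-s pieces, 128 Hz, the 8 frontal channels) chosen so the
statistics remain well-posed while whole ladders of replicate studies run
in minutes.

The experiments exclude wavelet edge-contaminated 1-s bins from the fits:
finite recordings inflate low-frequency energy near the boundaries, and the
regressors have onset-locked structure in exactly those bins (ratings start
neutral), so including edge bins injects a spurious association that has
nothing to do with regressor-coupled oscillations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import scipy.stats

from .surprisal import SurprisalConfig, sequence_ic
from .synthetic import (
    FRONTAL_ROI,
    CouplingSpec,
    StudyConfig,
    generate_markov_pieces,
    generate_study,
    random_markov_source,
)
from .stats import run_study

__all__ = [
    "reduced_config",
    "null_calibration",
    "coupling_recovery",
    "surprisal_convergence",
    "RECOVERY_GAIN",
]

# Coupling gain (amplitude units per bit of IC) used by the recovery
# experiments; calibrated once in a pilot so that binned ROI beta power
# correlates > 0.9 with the driving regressor at the default noise levels.
RECOVERY_GAIN = 1.0

# Pilot-recorded ceiling for the final rung of the convergence ladder
# (observed final MAE across pilot seeds: 0.69-0.77 bits; the floor is set
# by short-term-model contamination of the both+ mixture, not by the
# long-term model's estimation error).
PILOT_MAE_BOUND_BITS = 0.9


def reduced_config(
    seed: int,
    n_pieces: int = 2,
    n_subjects: int = 10,
    piece_duration_s: float = 60.0,
    fs: float = 128.0,
    coupling: CouplingSpec | None = None,
) -> StudyConfig:
    """Desk-scale study: 8 frontal channels, 60-s pieces at 128 Hz."""
    return StudyConfig(
        n_pieces=n_pieces,
        n_subjects=n_subjects,
        piece_duration_s=piece_duration_s,
        fs=fs,
        montage=FRONTAL_ROI,
        coupling=coupling or CouplingSpec(gain=0.0, regressor="none"),
        seed=seed,
    )


@dataclass
class NullCalibrationResult:
    z_scores: np.ndarray          # pooled per-fit z over all bands x regressors
    ks_distance: float            # KS distance of z to the standard normal
    n_group_tests: int
    n_group_rejections: int       # two-sided p < 0.05
    n_fits: int                   # piece x subject combinations simulated

    @property
    def rejection_rate(self) -> float:
        return self.n_group_rejections / self.n_group_tests


def null_calibration(
    seed: int,
    n_studies: int = 50,
    n_pieces: int = 2,
    n_subjects: int = 10,
    alpha: float = 0.05,
) -> NullCalibrationResult:
    """Run gain-0 studies and measure calibration of the whole chain.

    With no regressor-coupled oscillation injected, every per-fit z should
    be standard-normal-like and every group test should reject at about the
    nominal rate.
    """
    rng = np.random.SeedSequence(seed)
    z_all: List[float] = []
    n_tests = 0
    n_rej = 0
    n_fits = 0
    for child in rng.spawn(n_studies):
        cfg = reduced_config(
            seed=int(child.generate_state(1)[0] % (2**31)),
            n_pieces=n_pieces, n_subjects=n_subjects,
        )
        study = generate_study(cfg)
        n_fits += cfg.n_pieces * cfg.n_subjects
        res = run_study(study, drop_edge_bins=True)
        ok = res.fits[~res.fits.degenerate]
        z_all.extend(ok.z_score.tolist())
        n_tests += len(res.group)
        n_rej += int((res.group.p_value < alpha).sum())
    z = np.array(z_all)
    ks = scipy.stats.kstest(z, "norm").statistic
    return NullCalibrationResult(z, float(ks), n_tests, n_rej, n_fits)


@dataclass
class RecoveryResult:
    coupled_band: str
    regressor: str
    n_replicates: int
    coupled_significant_positive: int   # group p < 0.05 with mean z > 0
    theta_rejections: int               # group p < 0.05 in the theta band
    coupled_mean_z: np.ndarray
    theta_mean_z: np.ndarray

    @property
    def recovery_rate(self) -> float:
        return self.coupled_significant_positive / self.n_replicates

    @property
    def theta_rejection_rate(self) -> float:
        return self.theta_rejections / self.n_replicates


def coupling_recovery(
    seed: int,
    n_replicates: int = 20,
    gain: float = RECOVERY_GAIN,
    band: str = "beta",
    regressor: str = "ic_melody",
    n_pieces: int = 2,
    n_subjects: int = 10,
    alpha: float = 0.05,
) -> RecoveryResult:
    """Replicate coupled studies and measure band-specific recovery.

    Injects the oscillation in one band only; the coupled band's group test
    should come out significantly positive while an uncoupled control band
    (theta) stays at the nominal false-positive rate.
    """
    rng = np.random.SeedSequence(seed)
    hits = 0
    theta_rej = 0
    coupled_mz: List[float] = []
    theta_mz: List[float] = []
    for child in rng.spawn(n_replicates):
        coupling = CouplingSpec(band=band, gain=gain, regressor=regressor)
        cfg = reduced_config(
            seed=int(child.generate_state(1)[0] % (2**31)),
            n_pieces=n_pieces, n_subjects=n_subjects, coupling=coupling,
        )
        res = run_study(generate_study(cfg), drop_edge_bins=True)
        g = res.group_result(band, regressor)
        if g.p_value < alpha and g.mean_z > 0:
            hits += 1
        coupled_mz.append(g.mean_z)
        gt = res.group_result("theta", regressor)
        if gt.p_value < alpha:
            theta_rej += 1
        theta_mz.append(gt.mean_z)
    return RecoveryResult(
        band, regressor, n_replicates, hits, theta_rej,
        np.array(coupled_mz), np.array(theta_mz),
    )


@dataclass
class ConvergenceResult:
    corpus_sizes: Tuple[int, ...]
    mae_bits: Tuple[float, ...]   # mean |IC_est - IC_true| per ladder rung


def surprisal_convergence(
    seed: int,
    corpus_sizes: Sequence[int] = (5, 50, 500),
    n_targets: int = 40,
    sequence_length: int = 100,
    alphabet_size: int = 8,
    max_order: int = 2,
) -> ConvergenceResult:
    """Estimated vs true IC on order-1 Markov fixtures across a corpus ladder.

    Targets and corpora are drawn from the same known source; as the
    long-term corpus grows, the both+ estimate of each event's IC should
    approach the generating -log2 probability.
    """
    source = random_markov_source(1, tuple(range(alphabet_size)), seed=seed)
    targets = generate_markov_pieces(
        source, n_targets, sequence_length, seed=seed + 1, piece_prefix="target"
    )
    corpus_full = [
        seq for seq, _ in generate_markov_pieces(
            source, max(corpus_sizes), sequence_length, seed=seed + 2,
            piece_prefix="corpus",
        )
    ]
    cfg = SurprisalConfig(max_order=max_order)
    maes = []
    for size in corpus_sizes:
        errs: List[float] = []
        for target, true_ic in targets:
            est = sequence_ic(corpus_full[:size], target, cfg)
            errs.extend(
                abs(e - t) for e, t in zip(est.ic_bits, true_ic.ic_bits)
            )
        maes.append(float(np.mean(errs)))
    return ConvergenceResult(tuple(corpus_sizes), tuple(maes))
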