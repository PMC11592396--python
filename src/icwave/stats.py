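"""GLM fitting of band power on regressors and group-level inference.

Each (subject, piece, band, regressor) cell is an ordinary least-squares
fit of the 1-s-binned frontal band power on one regressor plus an
intercept; the slope's t-value is mapped to a df-free z-score through the
exact probability-integral transform z = Phi^-1(F_t(t; df)), so pieces of
different lengths contribute comparably. Group inference is a two-sided
one-sample t-test of the z-scores against zero, pooled over pieces and
subjects. Spearman rank correlation relates pleasure and surprisal at the
note-event level. Raw p-values are reported; no multiple-testing
correction is applied across bands or regressors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats

from .align import RegressorSeries, ic_to_regressor, rating_series_to_regressor
from .spectral import BandPowerSeries, band_power, morlet_energy, preprocess, roi_average
from .synthetic import BAND_EDGES_HZ, FRONTAL_ROI, EEGRecording, SyntheticStudy

__all__ = [
    "GLMFit",
    "GroupTestResult",
    "glm_fit",
    "t_to_z",
    "group_test",
    "spearman",
    "run_study",
    "StudyResults",
]


@dataclass
class GLMFit:
    piece_id: str
    subject_id: str
    band: str
    regressor: str
    beta0: float = np.nan
    beta1: float = np.nan
    t_value: float = np.nan
    df: int = 0
    z_score: float = np.nan
    n_valid_bins: int = 0
    degenerate: bool = False
    reason: str = ""


@dataclass
class GroupTestResult:
    band: str
    regressor: str
    mean_z: float
    t_statistic: float
    df: int
    p_value: float
    n: int


def glm_fit(
    power: BandPowerSeries,
    regressor: RegressorSeries,
    extra_valid: Optional[np.ndarray] = None,
) -> GLMFit:
    """OLS of band power on one regressor with intercept.

    Only bins valid in both series enter the fit (band power bins are all
    valid; the regressor's mask governs, optionally intersected with
    ``extra_valid``, e.g. an edge-bin mask). Zero-variance regressors (e.g.
    an all-neutral rating trace) and zero-residual fits are flagged
    degenerate and carry no t or z.
    """
    n = min(power.values.size, len(regressor))
    y = power.values[:n]
    x = regressor.values[:n]
    mask = regressor.valid[:n].copy()
    if extra_valid is not None:
        mask &= np.asarray(extra_valid, dtype=bool)[:n]
    fit = GLMFit(
        piece_id=power.piece_id or regressor.piece_id,
        subject_id=power.subject_id or regressor.subject_id,
        band=power.band,
        regressor=regressor.kind,
        n_valid_bins=int(mask.sum()),
    )
    if fit.n_valid_bins < 3:
        fit.degenerate, fit.reason = True, "fewer than 3 jointly valid bins"
        return fit
    x, y = x[mask], y[mask]
    if np.ptp(x) == 0:
        fit.degenerate, fit.reason = True, "zero-variance regressor"
        return fit
    res = scipy.stats.linregress(x, y)
    fit.beta0, fit.beta1 = float(res.intercept), float(res.slope)
    fit.df = fit.n_valid_bins - 2
    if res.stderr == 0 or not np.isfinite(res.stderr):
        fit.degenerate, fit.reason = True, "zero residual variance"
        return fit
    fit.t_value = float(res.slope / res.stderr)
    fit.z_score = t_to_z(fit.t_value, fit.df)
    return fit


def t_to_z(t: float, df: int) -> float:
    """Exact t -> z conversion via the probability-integral transform.

    z = Phi^-1(F_t(t; df)): sign-preserving, strictly increasing in t and
    antisymmetric. Computed through the survival function on the positive
    side so extreme t-values keep full tail precision.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if not np.isfinite(t):
        return float("nan")
    if t >= 0:
        return float(scipy.stats.norm.isf(scipy.stats.t.sf(t, df)))
    return -float(scipy.stats.norm.isf(scipy.stats.t.sf(-t, df)))


def group_test(fits: Sequence[GLMFit]) -> GroupTestResult:
    """Two-sided one-sample t-test of the non-degenerate z-scores against 0."""
    valid = [f for f in fits if not f.degenerate and np.isfinite(f.z_score)]
    if len(valid) < 2:
        raise ValueError("group test requires >= 2 non-degenerate fits")
    z = np.array([f.z_score for f in valid])
    if np.ptp(z) == 0:
        raise ValueError("group test undefined: all z-scores identical")
    res = scipy.stats.ttest_1samp(z, 0.0)
    bands = {f.band for f in valid}
    regs = {f.regressor for f in valid}
    return GroupTestResult(
        band=bands.pop() if len(bands) == 1 else "mixed",
        regressor=regs.pop() if len(regs) == 1 else "mixed",
        mean_z=float(z.mean()),
        t_statistic=float(res.statistic),
        df=len(z) - 1,
        p_value=float(res.pvalue),
        n=len(z),
    )


def spearman(pleasure: Sequence[float], ic: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    pleasure = np.asarray(pleasure, dtype=float)
    ic = np.asarray(ic, dtype=float)
    if pleasure.size != ic.size:
        raise ValueError("inputs must have equal length")
    if pleasure.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(pleasure) == 0 or np.ptp(ic) == 0:
        raise ValueError("rank correlation undefined for constant input")
    res = scipy.stats.spearmanr(pleasure, ic)
    return float(res.statistic), float(res.pvalue)


# -- whole-study orchestration ----------------------------------------------

REGRESSOR_KINDS = ("pleasure", "ic_melody", "ic_harmony")


@dataclass
class StudyResults:
    fits: pd.DataFrame          # one row per (subject, piece, band, regressor)
    group: pd.DataFrame         # one row per (band, regressor)
    spearman: Dict[str, Tuple[float, float]]
    exclusions: List[Dict]      # manifest of degenerate/failed combinations
    errors: List[Dict]

    def group_result(self, band: str, regressor: str) -> pd.Series:
        sel = self.group[(self.group.band == band) & (self.group.regressor == regressor)]
        if sel.empty:
            raise KeyError(f"no group result for ({band}, {regressor})")
        return sel.iloc[0]


def run_study(
    study: SyntheticStudy,
    bands: Iterable[str] = tuple(BAND_EDGES_HZ),
    roi: Sequence[str] = FRONTAL_ROI,
    drop_edge_bins: bool = False,
) -> StudyResults:
    """Run the full analysis chain on a (synthetic) study.

    For every subject x piece: preprocess the EEG, compute Morlet energy on
    the 1-45 Hz grid, reduce to frontal-ROI band power per 1-s bin, and fit
    each of the three regressors (pleasure, melody IC, harmony IC) per
    band. Degenerate fits and per-combination errors are recorded in the
    exclusion manifest and the run continues. Group tests pool one z per
    (piece x subject).
    """
    bands = tuple(bands)
    rows: List[GLMFit] = []
    exclusions: List[Dict] = []
    errors: List[Dict] = []
    pieces = {p.piece_id: p for p in study.pieces}

    for subj in study.subjects:
        for piece_id, rec in subj.eeg.items():
            piece = pieces[piece_id]
            try:
                clean = preprocess(rec)  # average reference uses all channels
                idx = [clean.channel_names.index(ch) for ch in roi]
                clean = EEGRecording(
                    list(roi), clean.fs, clean.data[idx],
                    piece_id=clean.piece_id, subject_id=clean.subject_id,
                )
                tfe = morlet_energy(clean)
                per_channel = band_power(tfe)
                regs = _piece_regressors(study, subj.subject_id, piece)
                for band_name in bands:
                    roi_power = roi_average(per_channel[band_name], roi=roi)
                    edge_mask = (
                        _edge_valid_mask(roi_power, tfe, band_name)
                        if drop_edge_bins else None
                    )
                    for reg in regs:
                        fit = glm_fit(roi_power, reg, extra_valid=edge_mask)
                        rows.append(fit)
                        if fit.degenerate:
                            exclusions.append(
                                {
                                    "subject_id": fit.subject_id,
                                    "piece_id": fit.piece_id,
                                    "band": fit.band,
                                    "regressor": fit.regressor,
                                    "reason": fit.reason,
                                }
                            )
            except Exception as exc:  # attribute failure, keep going
                errors.append(
                    {"subject_id": subj.subject_id, "piece_id": piece_id,
                     "error": str(exc)}
                )

    fits_df = pd.DataFrame([vars(f) for f in rows])
    group_rows = []
    for band_name in bands:
        for kind in REGRESSOR_KINDS:
            cell = [
                f for f in rows
                if f.band == band_name and f.regressor == kind and not f.degenerate
            ]
            if len(cell) < 2:
                continue
            g = group_test(cell)
            group_rows.append(vars(g))
    group_df = pd.DataFrame(group_rows)

    spearman_out: Dict[str, Tuple[float, float]] = {}
    for stream in ("melody", "harmony"):
        pl, icv = _event_aligned_pairs(study, stream)
        if len(pl) >= 3 and np.ptp(pl) > 0 and np.ptp(icv) > 0:
            spearman_out[f"ic_{stream}"] = spearman(pl, icv)

    return StudyResults(fits_df, group_df, spearman_out, exclusions, errors)


def _piece_regressors(study, subject_id, piece) -> List[RegressorSeries]:
    subj = next(s for s in study.subjects if s.subject_id == subject_id)
    regs = [rating_series_to_regressor(subj.ratings[piece.piece_id])]
    for stream, series in (("melody", piece.ic_melody), ("harmony", piece.ic_harmony)):
        r = ic_to_regressor(series, piece.duration_s)
        r.subject_id = subject_id
        regs.append(r)
    return regs


def _edge_valid_mask(roi_power: BandPowerSeries, tfe, band_name: str) -> np.ndarray:
    """False for 1-s bins inside the band's edge-contaminated margins."""
    lo, _ = BAND_EDGES_HZ[band_name]
    edge_bins = int(np.ceil(tfe.edge_seconds(lo)))
    n = roi_power.values.size
    keep = np.ones(n, dtype=bool)
    if edge_bins > 0:
        keep[:edge_bins] = False
        keep[n - edge_bins :] = False
    return keep


def _event_aligned_pairs(study: SyntheticStudy, stream: str):
    """Pleasure sampled at each note event's bin, pooled over pieces/subjects."""
    pl: List[float] = []
    icv: List[float] = []
    for piece in study.pieces:
        series = piece.ic_melody if stream == "melody" else piece.ic_harmony
        # average pleasure across subjects per bin, as in event-indexed plots
        ratings = np.stack(
            [s.ratings[piece.piece_id].values for s in study.subjects]
        ).mean(axis=0)
        for t, x in zip(series.timestamps_s, series.ic_bits):
            b = int(t)
            if b < ratings.size:
                pl.append(float(ratings[b]))
                icv.append(x)
    return np.array(pl), np.array(icv)
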