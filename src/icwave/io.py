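"""Plain-text (TSV/JSON) interchange and the on-disk study layout.

Every stage reads and writes tidy tab-separated tables so each step is
independently inspectable and replaceable; raw EEG arrays use .npy files
with a JSON sidecar carrying channel names and the sampling rate. A run
manifest (config echo, seeds, content hash) makes runs reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .surprisal import NoteEvent, SurpriseSeries, SymbolSequence
from .synthetic import (
    CouplingSpec,
    EEGRecording,
    Piece,
    RatingSeries,
    StudyConfig,
    SubjectData,
    SyntheticStudy,
)

NOTE_COLUMNS = ["piece_id", "part_id", "onset_s", "duration_s", "pitch"]
IC_COLUMNS = ["piece_id", "stream", "event_index", "timestamp_s", "ic_bits"]
RATING_COLUMNS = ["piece_id", "subject_id", "bin_start_s", "value"]


def write_notes_tsv(path, notes: Sequence[NoteEvent], piece_id: str) -> None:
    df = pd.DataFrame(
        [
            {"piece_id": piece_id, "part_id": n.part_id, "onset_s": n.onset_s,
             "duration_s": n.duration_s, "pitch": n.pitch}
            for n in notes
        ],
        columns=NOTE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_notes_tsv(path) -> Dict[str, List[NoteEvent]]:
    """Note-event tables keyed by piece_id."""
    df = pd.read_csv(path, sep="\t")
    missing = set(NOTE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"note table missing columns: {sorted(missing)}")
    out: Dict[str, List[NoteEvent]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.piece_id), []).append(
            NoteEvent(float(row.onset_s), float(row.duration_s), int(row.pitch),
                      str(row.part_id))
        )
    return out


def write_surprise_tsv(path, series_list: Sequence[SurpriseSeries]) -> None:
    rows = []
    for s in series_list:
        for i, (t, x) in enumerate(zip(s.timestamps_s, s.ic_bits)):
            rows.append(
                {"piece_id": s.piece_id, "stream": s.stream, "event_index": i,
                 "timestamp_s": t, "ic_bits": x}
            )
    pd.DataFrame(rows, columns=IC_COLUMNS).to_csv(path, sep="\t", index=False)


def read_surprise_tsv(path) -> List[SurpriseSeries]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (pid, stream), grp in df.groupby(["piece_id", "stream"], sort=False):
        grp = grp.sort_values("event_index")
        out.append(
            SurpriseSeries(str(pid), str(stream), grp.ic_bits.tolist(),
                           grp.timestamp_s.tolist())
        )
    return out


def write_eeg(directory, rec: EEGRecording, stem: str) -> None:
    directory = Path(directory)
    np.save(directory / f"{stem}.npy", rec.data)
    meta = {
        "channel_names": rec.channel_names,
        "fs": rec.fs,
        "piece_id": rec.piece_id,
        "subject_id": rec.subject_id,
    }
    (directory / f"{stem}.json").write_text(json.dumps(meta, indent=1))


def read_eeg(directory, stem: str) -> EEGRecording:
    directory = Path(directory)
    meta = json.loads((directory / f"{stem}.json").read_text())
    data = np.load(directory / f"{stem}.npy")
    return EEGRecording(meta["channel_names"], meta["fs"], data,
                        piece_id=meta["piece_id"], subject_id=meta["subject_id"])


def config_to_dict(cfg: StudyConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["coupling"]["roi_channels"] = list(d["coupling"]["roi_channels"])
    return d


def config_hash(cfg: StudyConfig) -> str:
    return hashlib.sha256(
        json.dumps(config_to_dict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_study(directory, study: SyntheticStudy, force: bool = False) -> None:
    """Serialize a full synthetic study (tables + EEG arrays + manifest)."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise FileExistsError(
            f"{directory} exists and is not empty (pass force=True to overwrite)"
        )
    directory.mkdir(parents=True, exist_ok=True)
    write_surprise_tsv(
        directory / "ic_true.tsv",
        [p.ic_melody for p in study.pieces] + [p.ic_harmony for p in study.pieces],
    )
    tok_rows = []
    for p in study.pieces:
        for seq in (p.melody, p.harmony):
            for i, (t, tok) in enumerate(zip(seq.timestamps_s, seq.tokens)):
                tok_rows.append(
                    {"piece_id": p.piece_id, "stream": seq.stream, "event_index": i,
                     "timestamp_s": t, "token": json.dumps(tok)}
                )
    pd.DataFrame(tok_rows).to_csv(directory / "tokens.tsv", sep="\t", index=False)

    rating_rows = []
    for subj in study.subjects:
        for pid, rating in subj.ratings.items():
            for b, v in enumerate(rating.values):
                rating_rows.append(
                    {"piece_id": pid, "subject_id": subj.subject_id,
                     "bin_start_s": float(b), "value": int(v)}
                )
    pd.DataFrame(rating_rows, columns=RATING_COLUMNS).to_csv(
        directory / "ratings.tsv", sep="\t", index=False
    )
    eeg_dir = directory / "eeg"
    eeg_dir.mkdir(exist_ok=True)
    for subj in study.subjects:
        for pid, rec in subj.eeg.items():
            write_eeg(eeg_dir, rec, f"{subj.subject_id}_{pid}")
    manifest = {
        "config": config_to_dict(study.config),
        "config_hash": config_hash(study.config),
        "n_pieces": len(study.pieces),
        "n_subjects": len(study.subjects),
        "piece_ids": [p.piece_id for p in study.pieces],
        "subject_ids": [s.subject_id for s in study.subjects],
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )


def read_study(directory) -> SyntheticStudy:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    cfg_d = dict(manifest["config"])
    coupling_d = dict(cfg_d.pop("coupling"))
    coupling_d["roi_channels"] = tuple(coupling_d["roi_channels"])
    cfg_d["montage"] = tuple(cfg_d["montage"])
    cfg_d["rating_thresholds"] = tuple(cfg_d["rating_thresholds"])
    cfg = StudyConfig(coupling=CouplingSpec(**coupling_d), **cfg_d)

    ic_all = {(s.piece_id, s.stream): s for s in read_surprise_tsv(directory / "ic_true.tsv")}
    tok_df = pd.read_csv(directory / "tokens.tsv", sep="\t")
    pieces: List[Piece] = []
    for pid in manifest["piece_ids"]:
        seqs = {}
        for stream in ("melody", "harmony"):
            grp = tok_df[(tok_df.piece_id == pid) & (tok_df.stream == stream)]
            grp = grp.sort_values("event_index")
            tokens = [json.loads(t) for t in grp.token]
            tokens = [tuple(t) if isinstance(t, list) else t for t in tokens]
            seqs[stream] = SymbolSequence(pid, stream, tokens,
                                          grp.timestamp_s.tolist())
        pieces.append(
            Piece(pid, seqs["melody"], seqs["harmony"],
                  ic_all[(pid, "melody")], ic_all[(pid, "harmony")],
                  cfg.piece_duration_s)
        )
    rating_df = pd.read_csv(directory / "ratings.tsv", sep="\t")
    subjects: List[SubjectData] = []
    for sid in manifest["subject_ids"]:
        eeg, ratings = {}, {}
        for pid in manifest["piece_ids"]:
            eeg[pid] = read_eeg(directory / "eeg", f"{sid}_{pid}")
            grp = rating_df[
                (rating_df.subject_id == sid) & (rating_df.piece_id == pid)
            ].sort_values("bin_start_s")
            ratings[pid] = RatingSeries(pid, sid, grp.value.to_numpy())
        subjects.append(SubjectData(sid, eeg, ratings))
    return SyntheticStudy(pieces, subjects, cfg)


def write_results(directory, results, force: bool = False) -> None:
    """Per-fit and group tables plus the exclusion manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    results.fits.to_csv(directory / "fits.tsv", sep="\t", index=False)
    results.group.to_csv(directory / "group.tsv", sep="\t", index=False)
    manifest = {
        "exclusions": results.exclusions,
        "errors": results.errors,
        "spearman": {k: {"rho": v[0], "p": v[1]} for k, v in results.spearman.items()},
    }
    (directory / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
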