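"""File formats and run configuration.

Canonical on-disk dialects:

* ECG — CSV with header ``time_s,<lead>,...``, microvolt samples,
  period decimal separator.
* RR — plain text, one interval in ms per line, ``#`` comments allowed.
* Beats — CSV of R-peak sample indices with the sampling rate recorded
  in a ``# fs=...`` comment.
* Features — one row per segment with the stable 21-column schema.
* Cohort — a directory holding a ``manifest.csv``, per-session RR
  files, and a ``behavior.csv``.

Every writer stamps the output with the hash of the
:class:`RunConfig` that produced it (a ``# config_hash=...`` comment),
and every reader tolerates comment lines.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import (
    BeatSeries,
    EcgRecord,
    InvalidSpecError,
    RRSeries,
    SessionRecord,
    TrialRecord,
)
from .hrv import FEATURE_NAMES

__all__ = [
    "RunConfig",
    "FormatError",
    "read_ecg",
    "write_ecg",
    "read_rr",
    "write_rr",
    "read_beats",
    "write_beats",
    "read_features",
    "write_features",
    "write_cohort",
    "read_cohort",
]


class FormatError(ValueError):
    """Malformed input file (carries the offending line when known)."""


@dataclass
class RunConfig:
    """End-to-end run options; defaults are the study-fidelity choices."""

    fs: float = 500.0
    lead: Optional[str] = None  # None -> II when present, else first lead
    dialect: str = "printed"  # printed | conventional feature formulas
    spectral_method: str = "welch"  # welch | lombscargle
    artifact_filter: bool = True
    alpha: float = 0.05
    correction: Optional[str] = None  # None | "bh"
    paired: bool = False
    seed: int = 0
    n_subjects: int = 10
    duration_s: float = 300.0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _hash_comment(config_hash: Optional[str]) -> str:
    return f"# config_hash={config_hash}\n" if config_hash else ""


# -- ECG --------------------------------------------------------------------


def write_ecg(path, ecg: EcgRecord, config_hash: Optional[str] = None) -> None:
    path = Path(path)
    t = ecg.times()
    with path.open("w") as fh:
        fh.write(_hash_comment(config_hash))
        fh.write("time_s," + ",".join(ecg.leads) + "\n")
        for i in range(ecg.n_samples):
            fh.write(f"{t[i]:.6f}," + ",".join(f"{v:.6f}" for v in ecg.samples[:, i]) + "\n")


def read_ecg(path) -> EcgRecord:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise FormatError(f"{path}: expected header 'time_s,<lead>,...'")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 2  # +1 for header, +1 for 1-based
        raise FormatError(f"{path}: non-monotone time at data row {bad}")
    leads = [c for c in df.columns if c != "time_s"]
    fs = 1.0 / float(np.median(dt))
    return EcgRecord(df[leads].to_numpy(dtype=float).T, fs=fs, leads=tuple(leads),
                     start_time=float(t[0]))


# -- RR ---------------------------------------------------------------------


def write_rr(path, rr: RRSeries, config_hash: Optional[str] = None) -> None:
    with Path(path).open("w") as fh:
        fh.write(_hash_comment(config_hash))
        if rr.label:
            fh.write(f"# label={rr.label}\n")
        for v in rr.intervals:
            fh.write(f"{v:.6f}\n")


def read_rr(path) -> RRSeries:
    path = Path(path)
    intervals: List[float] = []
    label = ""
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            if s.startswith("# label="):
                label = s.split("=", 1)[1]
            continue
        try:
            v = float(s)
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: not a number: {s!r}") from None
        if v <= 0:
            raise FormatError(f"{path}: line {lineno}: non-positive interval {v}")
        intervals.append(v)
    return RRSeries(np.asarray(intervals), label=label)


# -- Beats ------------------------------------------------------------------


def write_beats(path, beats: BeatSeries, config_hash: Optional[str] = None) -> None:
    with Path(path).open("w") as fh:
        fh.write(_hash_comment(config_hash))
        fh.write(f"# fs={beats.fs}\n")
        fh.write("sample_index\n")
        for i in beats.indices:
            fh.write(f"{int(i)}\n")


def read_beats(path) -> BeatSeries:
    path = Path(path)
    fs = None
    for line in path.read_text().splitlines():
        if line.startswith("# fs="):
            fs = float(line.split("=", 1)[1])
    if fs is None:
        raise FormatError(f"{path}: missing '# fs=' comment")
    df = pd.read_csv(path, comment="#")
    return BeatSeries(df["sample_index"].to_numpy(dtype=np.int64), fs=fs)


# -- Features ---------------------------------------------------------------

_ID_COLS = ["subject", "group", "state"]


def write_features(path, frame: pd.DataFrame, config_hash: Optional[str] = None) -> None:
    cols = [c for c in _ID_COLS if c in frame.columns] + list(FEATURE_NAMES)
    missing = [c for c in FEATURE_NAMES if c not in frame.columns]
    if missing:
        raise InvalidSpecError(f"feature frame missing columns: {missing}")
    with Path(path).open("w") as fh:
        fh.write(_hash_comment(config_hash))
        frame[cols].to_csv(fh, index=False)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing feature columns: {missing}")
    return df


# -- Cohort directories -----------------------------------------------------


def write_cohort(outdir, sessions: Sequence[SessionRecord],
                 config_hash: Optional[str] = None) -> None:
    """Write a cohort as manifest.csv + per-session RR files + behavior.csv."""
    from .stats import cohort_behavior_frame

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sessions:
        rr_file = f"rr_{s.group}_{s.subject}_{s.state.replace(' ', '_')}.txt"
        if s.rr is not None:
            write_rr(outdir / rr_file, s.rr, config_hash=config_hash)
        rows.append(
            {
                "subject": s.subject,
                "group": s.group,
                "state": s.state,
                "rr_file": rr_file if s.rr is not None else "",
                "sfs_items": ";".join(str(i) for i in s.sfs_items),
            }
        )
    with (outdir / "manifest.csv").open("w") as fh:
        fh.write(_hash_comment(config_hash))
        pd.DataFrame(rows).to_csv(fh, index=False)
    beh = cohort_behavior_frame(sessions)
    with (outdir / "behavior.csv").open("w") as fh:
        fh.write(_hash_comment(config_hash))
        beh.to_csv(fh, index=False)


def read_cohort(outdir) -> List[SessionRecord]:
    """Rebuild session records (RR + SFS items) from a cohort directory.

    Trial-level records are not persisted — behavior.csv stores the
    scored accuracy and mean RT — so the returned sessions carry empty
    trial lists.
    """
    outdir = Path(outdir)
    manifest = outdir / "manifest.csv"
    if not manifest.exists():
        raise FormatError(f"{manifest}: no such file")
    df = pd.read_csv(manifest, comment="#", dtype=str).fillna("")
    sessions = []
    for _, row in df.iterrows():
        rr = read_rr(outdir / row["rr_file"]) if row["rr_file"] else None
        items = [int(v) for v in row["sfs_items"].split(";")] if row["sfs_items"] else []
        sessions.append(
            SessionRecord(
                subject=row["subject"],
                group=row["group"],
                state=row["state"],
                sfs_items=items,
                trials=(),
                rr=rr,
            )
        )
    return sessions
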