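"""Reading and writing sensor recordings and cohort metadata.

Signals are stored one CSV per subject-location with the fixed header
``t_s,accel_ap_g,accel_ml_g,accel_si_g,gyro_roll_dps,gyro_pitch_dps,
gyro_yaw_dps``; cohort metadata is a TSV with one row per subject.  Channels
are mapped by header name, never by position.  The time column is
authoritative for the sample rate; nothing is resampled at read time.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import LOCATIONS, Cohort, SensorRecording, SubjectRecord

logger = logging.getLogger(__name__)

SIGNAL_COLUMNS = (
    "t_s",
    "accel_ap_g", "accel_ml_g", "accel_si_g",
    "gyro_roll_dps", "gyro_pitch_dps", "gyro_yaw_dps",
)

_ACCEL = ("accel_ap_g", "accel_ml_g", "accel_si_g")
_GYRO = ("gyro_roll_dps", "gyro_pitch_dps", "gyro_yaw_dps")

METADATA_COLUMNS = (
    "subject_id", "label", "tug_time_s", "four_stage_s", "chair_stands",
    "followup_fall", "age_years", "sex", "height_cm", "mass_kg",
)


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


def signal_filename(subject_id: str, location: str) -> str:
    return f"{subject_id}_{location}.csv"


def write_recording(recording: SensorRecording, path: str | Path) -> None:
    """Write one recording as CSV (UTF-8, ~12 significant digits)."""
    t = np.arange(recording.n_samples) / recording.sample_rate_hz
    df = pd.DataFrame({"t_s": t})
    for i, c in enumerate(_ACCEL):
        df[c] = recording.accel[:, i]
    for i, c in enumerate(_GYRO):
        df[c] = recording.gyro[:, i]
    df.to_csv(path, index=False, float_format="%.12g")


def read_recording(
    path: str | Path,
    expected_rate_hz: float | None = None,
    *,
    location: str | None = None,
    subject_id: str | None = None,
    max_jitter: float = 1e-3,
) -> SensorRecording:
    """Read one signal CSV, inferring the rate from the time column.

    The sample rate is the reciprocal of the median time step.  A relative
    deviation of any step from the median beyond ``max_jitter`` is a
    non-uniform-sampling error naming the first offending index; a mismatch
    with ``expected_rate_hz`` beyond 1% is an error.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise FormatError(f"{path}: time column not monotone at index {i + 1}")
    med = float(np.median(dt))
    bad = np.abs(dt - med) > max_jitter * med
    if np.any(bad):
        i = int(np.argmax(bad))
        raise FormatError(
            f"{path}: non-uniform sampling at index {i + 1} "
            f"(dt={dt[i]:.6g}, median={med:.6g})")
    rate = 1.0 / med
    if expected_rate_hz is not None and \
            abs(rate - expected_rate_hz) > 0.01 * expected_rate_hz:
        raise FormatError(
            f"{path}: inferred rate {rate:.3f} Hz differs from expected "
            f"{expected_rate_hz} Hz by more than 1%")
    if location is None or subject_id is None:
        stem = path.stem
        for loc in LOCATIONS:
            if stem.endswith(f"_{loc}"):
                location = location or loc
                subject_id = subject_id or stem[: -len(loc) - 1]
                break
        else:
            location = location or "neck"
            subject_id = subject_id or stem
    accel = df.loc[:, list(_ACCEL)].to_numpy(dtype=float)
    gyro = df.loc[:, list(_GYRO)].to_numpy(dtype=float)
    return SensorRecording(subject_id=subject_id, location=location,
                           sample_rate_hz=rate, accel=accel, gyro=gyro)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort: ``metadata.tsv`` plus one CSV per subject-location."""
    out_dir = Path(out_dir)
    signals = out_dir / "signals"
    signals.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        rows.append({c: getattr(s, c) for c in METADATA_COLUMNS})
    pd.DataFrame(rows).to_csv(out_dir / "metadata.tsv", sep="\t",
                              index=False, float_format="%.12g")
    for (sid, loc), rec in cohort.recordings.items():
        write_recording(rec, signals / signal_filename(sid, loc))
    return out_dir


def read_metadata(meta_path: str | Path) -> list[SubjectRecord]:
    """Parse the cohort metadata TSV into subject records."""
    df = pd.read_csv(meta_path, sep="\t")
    for c in ("subject_id", "label"):
        if c not in df.columns:
            raise FormatError(f"{meta_path}: missing column {c!r}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise FormatError(f"{meta_path}: duplicated subject_id {dup!r}")
    if not set(df["label"].unique()) <= {0, 1}:
        raise FormatError(f"{meta_path}: labels must be 0 or 1")
    subjects = []
    for _, row in df.iterrows():
        kw = {}
        for c in METADATA_COLUMNS:
            if c in df.columns and not pd.isna(row[c]):
                kw[c] = row[c]
        kw["subject_id"] = str(row["subject_id"])
        kw["label"] = int(row["label"])
        if "chair_stands" in kw:
            kw["chair_stands"] = int(kw["chair_stands"])
        subjects.append(SubjectRecord(**kw))
    return subjects


def read_cohort(
    meta_path: str | Path,
    signals_dir: str | Path,
    required_locations: tuple[str, ...] = LOCATIONS,
    expected_rate_hz: float | None = None,
) -> Cohort:
    """Load a cohort, excluding subjects missing a required location.

    Exclusions are logged as a warning listing the excluded ids and count.
    Raises if no usable subject remains.
    """
    signals_dir = Path(signals_dir)
    subjects = read_metadata(meta_path)
    usable, recordings, excluded = [], {}, []
    for s in subjects:
        paths = {loc: signals_dir / signal_filename(s.subject_id, loc)
                 for loc in required_locations}
        if not all(p.exists() for p in paths.values()):
            excluded.append(s.subject_id)
            continue
        for loc, p in paths.items():
            recordings[(s.subject_id, loc)] = read_recording(
                p, expected_rate_hz, location=loc, subject_id=s.subject_id)
        usable.append(s)
    if excluded:
        logger.warning(
            "excluded %d subject(s) missing a required sensor location: %s",
            len(excluded), ", ".join(excluded))
    if not usable:
        raise FormatError("no usable subjects after exclusions")
    return Cohort(subjects=usable, recordings=recordings)
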