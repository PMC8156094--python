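"""Synthetic Timed-Up-and-Go (TUG) IMU recordings.

The Timed-Up-and-Go test asks a subject to rise from a chair, walk three
metres at their usual pace, turn, walk back and sit down.  This module
generates labelled cohorts of tri-axial accelerometer + gyroscope recordings
of that manoeuvre at three body locations (back of the neck, right foot,
left foot), with the phase structure and faller-class gait effects that the
downstream screening analysis assumes: fallers take longer overall, step at
a slower cadence, show larger step-time variability and larger mediolateral
sway.

The waveforms are phase-concatenated templates — a biphasic pitch-rate pulse
for the sit-to-stand and stand-to-sit transfers, raised-cosine step impulses
at the drawn cadence during the walk phases, a half-sine yaw-rate lobe for
the turns, and a low-frequency mediolateral sway sinusoid — plus additive
Gaussian sensor noise, clipped to the sensor range.  They are class
discriminative, not biomechanically validated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

LOCATIONS = ("neck", "right_foot", "left_foot")

#: order of the five TUG phases
PHASES = ("sit_to_stand", "walk_out", "turn", "walk_back", "turn_and_sit")


@dataclass(frozen=True)
class ClassParams:
    """Per-class gait parameters (one set for fallers, one for non-fallers).

    Parameters
    ----------
    cadence_hz : (mean, sd) of the step frequency in Hz.
    phase_durations_s : five (mean, sd) pairs, one per TUG phase, seconds.
    step_time_cv : coefficient of variation of inter-step intervals.
    ml_sway_gain : multiplier on mediolateral sway amplitude.
    """

    cadence_hz: tuple[float, float] = (1.9, 0.12)
    phase_durations_s: tuple[tuple[float, float], ...] = (
        (1.2, 0.3), (3.2, 0.8), (1.3, 0.3), (3.2, 0.8), (1.8, 0.4))
    step_time_cv: float = 0.03
    ml_sway_gain: float = 1.0

    @property
    def mean_total_duration_s(self) -> float:
        return float(sum(m for m, _ in self.phase_durations_s))


#: default faller-class parameters: slower cadence, longer phases with larger
#: spread, noisier step timing, larger mediolateral sway.
FALLER_DEFAULTS = ClassParams(
    cadence_hz=(1.35, 0.12),
    phase_durations_s=(
        (2.2, 0.5), (5.5, 1.6), (2.0, 0.5), (5.5, 1.6), (2.8, 0.7)),
    step_time_cv=0.09,
    ml_sway_gain=2.0,
)


@dataclass(frozen=True)
class SimulationParams:
    """Acquisition and cohort-level simulation settings.

    Defaults mirror the acquisition set-up of the screening study this
    package models: 250 Hz sampling within +/-16 G and +/-2000 degree/s,
    a 3 m walkway, and a faller class whose mean total duration exceeds the
    non-faller mean.
    """

    sample_rate_hz: float = 250.0
    accel_range_g: float = 16.0
    gyro_range_dps: float = 2000.0
    walk_distance_m: float = 3.0
    non_faller: ClassParams = field(default_factory=ClassParams)
    faller: ClassParams = field(default_factory=lambda: FALLER_DEFAULTS)
    noise_sd_accel_g: float = 0.05
    noise_sd_gyro_dps: float = 4.0
    #: probability that a given sensor location is missing for a subject
    drop_location_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("sample_rate_hz", "accel_range_g", "gyro_range_dps",
                     "walk_distance_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.noise_sd_accel_g < 0 or self.noise_sd_gyro_dps < 0:
            raise ValueError("noise scales must be non-negative")
        if not 0 <= self.drop_location_prob < 1:
            raise ValueError("drop_location_prob must be in [0, 1)")
        if (self.faller.mean_total_duration_s
                < self.non_faller.mean_total_duration_s):
            raise ValueError(
                "faller mean total duration must be >= non-faller mean")

    def class_params(self, label: int) -> ClassParams:
        return self.faller if label else self.non_faller


@dataclass
class SensorRecording:
    """One subject x one sensor location: 6-channel kinematic time series.

    ``accel`` columns are (AP, ML, SI) in G; ``gyro`` columns are
    (roll, pitch, yaw) in degree/s.  Both arrays share ``n_samples`` rows.
    """

    subject_id: str
    location: str
    sample_rate_hz: float
    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self):
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.accel.shape != self.gyro.shape or self.accel.ndim != 2 \
                or self.accel.shape[1] != 3:
            raise ValueError("accel and gyro must both be (n_samples, 3)")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass
class SubjectRecord:
    """Cohort metadata for one subject."""

    subject_id: str
    label: int  # 1 = faller (high fall risk), 0 = non-faller
    tug_time_s: float
    four_stage_s: float = np.nan
    chair_stands: int = -1
    followup_fall: str | None = None  # "fell" | "no_fall" | None (missing)
    age_years: float = np.nan
    sex: str | None = None
    height_cm: float = np.nan
    mass_kg: float = np.nan

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (non-faller) or 1 (faller)")


@dataclass
class Cohort:
    """A simulated or loaded cohort: subject metadata plus recordings.

    ``recordings`` is keyed by ``(subject_id, location)``; a key may be
    absent when that sensor's data are missing for the subject.
    """

    subjects: list[SubjectRecord]
    recordings: dict[tuple[str, str], SensorRecording]
    params: SimulationParams | None = None

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects], dtype=int)

    @property
    def tug_times(self) -> np.ndarray:
        return np.array([s.tug_time_s for s in self.subjects], dtype=float)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def recording(self, subject_id: str, location: str) -> SensorRecording:
        return self.recordings[(subject_id, location)]

    def has_location(self, subject_id: str, location: str) -> bool:
        return (subject_id, location) in self.recordings


def _raised_cosine(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-height raised-cosine impulse of the given width, zero outside."""
    u = (t - center) / width
    out = np.zeros_like(t)
    m = np.abs(u) < 0.5
    out[m] = 0.5 * (1.0 + np.cos(2 * np.pi * u[m]))
    return out


def _draw_positive(rng: np.random.Generator, mean: float, sd: float,
                   what: str, max_attempts: int = 100) -> float:
    """Draw Normal(mean, sd) rejecting non-positive values."""
    for _ in range(max_attempts):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise RuntimeError(
        f"could not draw a positive {what} in {max_attempts} attempts "
        f"(mean={mean}, sd={sd})")


def _step_times(rng, start, stop, cadence, cv):
    """Step event times in [start, stop): intervals ~ N(1/f, cv/f), floored."""
    mean_dt = 1.0 / cadence
    times = []
    t = start + 0.4 * mean_dt
    while t < stop:
        times.append(t)
        dt = rng.normal(mean_dt, cv * mean_dt)
        t += max(dt, 0.3 * mean_dt)
    return np.asarray(times)


def simulate_subject(
    params: SimulationParams,
    label: int,
    subject_seed: int,
    subject_id: str | None = None,
) -> tuple[SubjectRecord, dict[str, SensorRecording]]:
    """Simulate one subject's TUG test at all three sensor locations.

    Deterministic given ``(params, label, subject_seed)``.  Returns the
    subject metadata and a dict ``location -> SensorRecording``; the three
    recordings share one total duration.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    rng = np.random.default_rng([int(params.seed), int(subject_seed),
                                 int(label)])
    cp = params.class_params(label)

    durations = np.array([
        _draw_positive(rng, m, sd, f"duration of phase {name}")
        for (m, sd), name in zip(cp.phase_durations_s, PHASES)])
    cadence = _draw_positive(rng, *cp.cadence_hz, "cadence")

    fs = params.sample_rate_hz
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    total = edges[-1]
    n = int(round(total * fs))
    if n < 2:
        raise RuntimeError("degenerate recording length")
    t = np.arange(n) / fs

    # step events in both walk phases, alternating feet (right first)
    steps, feet = [], []
    for phase in (1, 3):
        st = _step_times(rng, edges[phase], edges[phase + 1], cadence,
                         cp.step_time_cv)
        steps.append(st)
        feet.append((np.arange(len(st)) + (0 if phase == 1 else 1)) % 2)
    steps = np.concatenate(steps)
    feet = np.concatenate(feet)  # 0 = right, 1 = left
    step_w = 0.30 / cadence

    walk_mask = ((t >= edges[1]) & (t < edges[2])) | \
                ((t >= edges[3]) & (t < edges[4]))
    f_stride = cadence / 2.0
    sway_ml = 0.08 * cp.ml_sway_gain * np.sin(2 * np.pi * f_stride * t)
    sway_roll = 15.0 * cp.ml_sway_gain * np.sin(
        2 * np.pi * f_stride * t + 0.6)

    def transfer(accel, gyro, phase, sign, amp=1.0):
        """Sit-to-stand / stand-to-sit: biphasic pitch pulse + AP bump."""
        a, b = edges[phase], edges[phase + 1]
        m = (t >= a) & (t < b)
        gyro[m, 1] += sign * amp * 70.0 * np.sin(
            2 * np.pi * (t[m] - a) / (b - a))
        accel[:, 0] += sign * amp * 0.35 * _raised_cosine(
            t, (a + b) / 2, (b - a))

    def turn_lobe(gyro, a, b, sign, amp=1.0):
        m = (t >= a) & (t < b)
        gyro[m, 2] += sign * amp * 130.0 * np.sin(
            np.pi * (t[m] - a) / (b - a))

    out: dict[str, SensorRecording] = {}
    for location in LOCATIONS:
        accel = np.zeros((n, 3))
        gyro = np.zeros((n, 3))
        if location == "neck":
            step_amp, sway_amp, transfer_amp = 0.5, 1.0, 1.0
            sel = np.ones(len(steps), dtype=bool)
        else:
            step_amp, sway_amp, transfer_amp = 1.0, 0.3, 0.5
            sel = feet == (0 if location == "right_foot" else 1)
        for s in steps[sel]:
            imp = _raised_cosine(t, s, step_w)
            accel[:, 2] += step_amp * 0.55 * imp                    # SI
            accel[:, 0] += step_amp * 0.25 * _raised_cosine(        # AP
                t, s + 0.3 * step_w, step_w)
            gyro[:, 1] += step_amp * 50.0 * imp                     # pitch
        accel[walk_mask, 1] += sway_amp * sway_ml[walk_mask]
        gyro[walk_mask, 0] += sway_amp * sway_roll[walk_mask]
        transfer(accel, gyro, 0, +1, transfer_amp)
        transfer(accel, gyro, 4, -1, transfer_amp)
        turn_lobe(gyro, edges[2], edges[3], +1)
        turn_lobe(gyro, edges[4], 0.5 * (edges[4] + edges[5]), -1)
        accel += rng.normal(0.0, params.noise_sd_accel_g, (n, 3))
        gyro += rng.normal(0.0, params.noise_sd_gyro_dps, (n, 3))
        np.clip(accel, -params.accel_range_g, params.accel_range_g,
                out=accel)
        np.clip(gyro, -params.gyro_range_dps, params.gyro_range_dps,
                out=gyro)
        out[location] = SensorRecording(
            subject_id=subject_id or f"seed{subject_seed}",
            location=location, sample_rate_hz=fs, accel=accel, gyro=gyro)

    # clinical scores correlated with class, drawn after the signals so the
    # signal stream is unaffected by metadata choices
    if label:
        four_stage = float(np.clip(rng.normal(22.0, 8.0), 4.0, 40.0))
        stands = int(np.clip(round(rng.normal(7.0, 3.0)), 0, 25))
        age = float(np.clip(rng.normal(79.0, 7.0), 65, 99))
    else:
        four_stage = float(np.clip(rng.normal(35.0, 5.0), 4.0, 40.0))
        stands = int(np.clip(round(rng.normal(12.0, 3.0)), 0, 25))
        age = float(np.clip(rng.normal(74.0, 6.0), 65, 99))
    record = SubjectRecord(
        subject_id=subject_id or f"seed{subject_seed}",
        label=int(label), tug_time_s=n / fs, four_stage_s=four_stage,
        chair_stands=stands, age_years=age,
        sex="F" if rng.random() < 0.5 else "M",
        height_cm=float(rng.normal(166, 10)),
        mass_kg=float(rng.normal(78, 14)),
    )
    return record, out


def simulate_cohort(
    n_subjects: int,
    faller_fraction: float,
    params: SimulationParams | None = None,
) -> Cohort:
    """Simulate a labelled cohort.

    Exactly ``round(n_subjects * faller_fraction)`` subjects (round half up)
    are fallers.  Subject seeds are derived from ``params.seed`` via a
    ``numpy.random.SeedSequence`` so that distinct master seeds give
    independent streams.  Pure: writes nothing.
    """
    params = params or SimulationParams()
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if not 0 < faller_fraction < 1:
        raise ValueError("faller_fraction must be in (0, 1)")
    n_fallers = int(np.floor(n_subjects * faller_fraction + 0.5))
    if n_fallers == 0 or n_fallers == n_subjects:
        raise ValueError("rounding produced an empty class")
    seeds = np.random.SeedSequence(params.seed).generate_state(
        n_subjects + 1)
    drop_rng = np.random.default_rng(seeds[-1])
    width = len(str(n_subjects))
    subjects, recordings = [], {}
    for i in range(n_subjects):
        label = 1 if i < n_fallers else 0
        sid = f"S{i + 1:0{width}d}"
        rec, recs = simulate_subject(params, label, int(seeds[i]),
                                     subject_id=sid)
        for loc, r in recs.items():
            if params.drop_location_prob and \
                    drop_rng.random() < params.drop_location_prob:
                continue
            recordings[(sid, loc)] = r
        subjects.append(rec)
    return Cohort(subjects=subjects, recordings=recordings, params=params)


def replace(params: SimulationParams, **kw) -> SimulationParams:
    """Return a copy of ``params`` with the given fields replaced."""
    return dataclasses.replace(params, **kw)
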