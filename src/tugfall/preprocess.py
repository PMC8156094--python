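"""Signal curation: Fourier resampling, cohort min-max scaling, zero-padding.

The chain runs in a fixed order — resample to 100 Hz, min-max normalize each
modality to [0, 1] using extremes pooled across the cohort, then zero-pad
every subject to the longest recording — mirroring the acquisition pipeline
of the screening study this package models.

Normalization uses *signed* extremes (a magnitude range could not recover
sign when mapping onto [0, 1]) and by default pools minima/maxima over all
subjects; fitting on the training subjects only is available via
``scope="train_only"``, in which case out-of-range transformed values are
left unclipped and logged.
"""

from __future__ import annotations

import logging
from dataclasses import replace as _dc_replace

import numpy as np
from scipy.signal import resample as _fft_resample_1d
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import SensorRecording

logger = logging.getLogger(__name__)


def fft_resample(recording: SensorRecording,
                 target_rate_hz: float = 100.0) -> SensorRecording:
    """Fourier-domain resampling of every channel to ``target_rate_hz``.

    Output length is ``round(n_samples * target / rate)``; frequency content
    above the new Nyquist (50 Hz at the default) is removed, which is the
    implicit low-pass of FFT resampling.
    """
    rate = recording.sample_rate_hz
    if target_rate_hz >= rate:
        raise ValueError("target rate must be below the recording rate")
    n_out = int(round(recording.n_samples * target_rate_hz / rate))
    if n_out < 2:
        raise ValueError("resampled length would be < 2 samples")
    accel = _fft_resample_1d(recording.accel, n_out, axis=0)
    gyro = _fft_resample_1d(recording.gyro, n_out, axis=0)
    return SensorRecording(subject_id=recording.subject_id,
                           location=recording.location,
                           sample_rate_hz=target_rate_hz,
                           accel=accel, gyro=gyro)


class MinMaxNormalizer(BaseEstimator, TransformerMixin):
    """Cohort-wide per-modality min-max scaler to [0, 1].

    ``fit`` pools signed minima and maxima over every sample, channel,
    location and subject in the recordings it is given; ``transform`` maps
    acceleration and angular velocity separately onto [0, 1].  Values of
    out-of-scope recordings may leave [0, 1]; they are never clipped, only
    logged.

    Parameters
    ----------
    scope : {"all_subjects", "train_only"}
        Bookkeeping tag for which subjects the state was fitted on.  The
        study pooled extremes over all subjects (training and test alike);
        ``train_only`` is the leakage-free alternative.
    """

    def __init__(self, scope: str = "all_subjects"):
        self.scope = scope

    def fit(self, recordings, y=None):
        recordings = list(recordings)
        if not recordings:
            raise ValueError("need at least one recording to fit")
        if self.scope not in ("all_subjects", "train_only"):
            raise ValueError(f"unknown scope {self.scope!r}")
        self.accel_min_ = min(float(r.accel.min()) for r in recordings)
        self.accel_max_ = max(float(r.accel.max()) for r in recordings)
        self.gyro_min_ = min(float(r.gyro.min()) for r in recordings)
        self.gyro_max_ = max(float(r.gyro.max()) for r in recordings)
        if self.accel_max_ <= self.accel_min_ or \
                self.gyro_max_ <= self.gyro_min_:
            raise ValueError("degenerate modality range (max == min)")
        return self

    def transform(self, recording: SensorRecording) -> SensorRecording:
        if not hasattr(self, "accel_min_"):
            raise ValueError("normalizer has not been fitted")
        accel = (recording.accel - self.accel_min_) / \
            (self.accel_max_ - self.accel_min_)
        gyro = (recording.gyro - self.gyro_min_) / \
            (self.gyro_max_ - self.gyro_min_)
        for name, arr in (("accel", accel), ("gyro", gyro)):
            lo, hi = float(arr.min()), float(arr.max())
            if lo < 0 or hi > 1:
                logger.warning(
                    "subject %s/%s: normalized %s outside [0, 1] "
                    "(range %.4f..%.4f); values left unclipped",
                    recording.subject_id, recording.location, name, lo, hi)
        return SensorRecording(subject_id=recording.subject_id,
                               location=recording.location,
                               sample_rate_hz=recording.sample_rate_hz,
                               accel=accel, gyro=gyro)

    def transform_all(self, recordings) -> list[SensorRecording]:
        return [self.transform(r) for r in recordings]


def fit_normalization(recordings, scope: str = "all_subjects"
                      ) -> MinMaxNormalizer:
    """Fit cohort min/max state; thin wrapper over :class:`MinMaxNormalizer`."""
    return MinMaxNormalizer(scope=scope).fit(recordings)


def apply_normalization(recording: SensorRecording,
                        state: MinMaxNormalizer) -> SensorRecording:
    return state.transform(recording)


def zero_pad(recordings: list[SensorRecording]
             ) -> tuple[list[SensorRecording], np.ndarray]:
    """Pad every recording with trailing zeros to the longest length.

    All recordings must share one sample rate.  Returns the padded
    recordings and the original (true) lengths in samples, so downstream
    segmentation can identify windows that lie entirely in the padding.
    """
    if not recordings:
        return [], np.zeros(0, dtype=int)
    rates = {r.sample_rate_hz for r in recordings}
    if len(rates) != 1:
        raise ValueError("all recordings must share one sample rate")
    true_lengths = np.array([r.n_samples for r in recordings], dtype=int)
    n_max = int(true_lengths.max())
    out = []
    for r in recordings:
        pad = n_max - r.n_samples
        if pad == 0:
            out.append(r)
            continue
        out.append(_dc_replace(
            r,
            accel=np.vstack([r.accel, np.zeros((pad, 3))]),
            gyro=np.vstack([r.gyro, np.zeros((pad, 3))]),
        ))
    return out, true_lengths


def preprocess_recordings(
    recordings: list[SensorRecording],
    target_rate_hz: float = 100.0,
    normalizer: MinMaxNormalizer | None = None,
    scope: str = "all_subjects",
) -> tuple[list[SensorRecording], np.ndarray, MinMaxNormalizer]:
    """Run the full chain: resample -> normalize -> zero-pad.

    If ``normalizer`` is None one is fitted on the resampled recordings
    (default cohort-wide scope).  Returns padded recordings, true lengths in
    samples at the target rate, and the normalization state.
    """
    res = [fft_resample(r, target_rate_hz) for r in recordings]
    if normalizer is None:
        normalizer = fit_normalization(res, scope=scope)
    norm = normalizer.transform_all(res)
    padded, true_lengths = zero_pad(norm)
    return padded, true_lengths, normalizer
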