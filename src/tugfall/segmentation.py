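"""Sliding-window segmentation and per-subject summary statistics.

Preprocessed 3-channel signals are cut into fixed 3 s windows with a 1 s
stride (CNN inputs); windows lying entirely in the zero-padded tail are
flagged and, by default, dropped.  The SVM baseline instead consumes nine
summary statistics per subject: the mean, standard deviation and
coefficient of variation of each of the three channels, computed over the
unpadded extent only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class SegmentSet:
    """A stack of fixed-length 3-channel windows with provenance.

    ``segments`` has shape (n_segments, window_samples, 3).  Each segment
    maps to exactly one subject via ``subject_index``; ``labels`` are
    inherited from the subject (1 = faller).  ``is_padding_only`` marks
    windows that start at or beyond the subject's true (unpadded) length.
    """

    segments: np.ndarray
    subject_index: np.ndarray
    labels: np.ndarray
    starts_s: np.ndarray
    is_padding_only: np.ndarray
    modality: str = "accel"
    location: str = "neck"
    window_s: float = 3.0
    stride_s: float = 1.0
    rate_hz: float = 100.0

    def __len__(self) -> int:
        return self.segments.shape[0]

    @property
    def window_samples(self) -> int:
        return self.segments.shape[1]

    def drop_padding_only(self) -> "SegmentSet":
        keep = ~self.is_padding_only
        return replace(self, segments=self.segments[keep],
                       subject_index=self.subject_index[keep],
                       labels=self.labels[keep],
                       starts_s=self.starts_s[keep],
                       is_padding_only=self.is_padding_only[keep])

    def for_subjects(self, subject_idx) -> "SegmentSet":
        keep = np.isin(self.subject_index, np.asarray(subject_idx))
        return replace(self, segments=self.segments[keep],
                       subject_index=self.subject_index[keep],
                       labels=self.labels[keep],
                       starts_s=self.starts_s[keep],
                       is_padding_only=self.is_padding_only[keep])

    def per_subject_segments(self, n_subjects: int) -> list[np.ndarray]:
        """Segments grouped by subject index (0..n_subjects-1)."""
        return [self.segments[self.subject_index == i]
                for i in range(n_subjects)]


def _window_samples(window_s, stride_s, rate_hz):
    w = window_s * rate_hz
    s = stride_s * rate_hz
    if abs(w - round(w)) > 1e-9 or abs(s - round(s)) > 1e-9:
        raise ValueError(
            "window and stride must be integer multiples of the sample "
            "period")
    return int(round(w)), int(round(s))


def sliding_windows(
    data: np.ndarray,
    rate_hz: float = 100.0,
    window_s: float = 3.0,
    stride_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a (n_samples, 3) signal into overlapping fixed windows.

    Windows start at 0, stride, 2*stride, ...; the count is
    ``floor((L - W) / S) + 1``.  No partial trailing window is emitted
    (upstream zero-padding guarantees coverage).  Returns the window stack
    (n, W, 3) and the start times in seconds.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (n_samples, n_channels)")
    w, s = _window_samples(window_s, stride_s, rate_hz)
    n = data.shape[0]
    if n < w:
        raise ValueError(
            f"recording ({n} samples) shorter than window ({w} samples)")
    views = sliding_window_view(data, w, axis=0)[::s]  # (n_win, C, W)
    segments = np.ascontiguousarray(views.transpose(0, 2, 1))
    starts = np.arange(segments.shape[0]) * s / rate_hz
    return segments, starts


def segment_subjects(
    signals: list[np.ndarray],
    labels: np.ndarray,
    true_lengths: np.ndarray,
    rate_hz: float = 100.0,
    window_s: float = 3.0,
    stride_s: float = 1.0,
    modality: str = "accel",
    location: str = "neck",
) -> SegmentSet:
    """Segment a padded cohort (one (L, 3) array per subject) into windows."""
    labels = np.asarray(labels, dtype=int)
    all_seg, subj_idx, all_lab, all_starts = [], [], [], []
    for i, sig in enumerate(signals):
        seg, starts = sliding_windows(sig, rate_hz, window_s, stride_s)
        all_seg.append(seg)
        all_starts.append(starts)
        subj_idx.append(np.full(len(seg), i))
        all_lab.append(np.full(len(seg), labels[i]))
    segset = SegmentSet(
        segments=np.concatenate(all_seg),
        subject_index=np.concatenate(subj_idx),
        labels=np.concatenate(all_lab),
        starts_s=np.concatenate(all_starts),
        is_padding_only=np.zeros(sum(len(s) for s in all_seg), dtype=bool),
        modality=modality, location=location,
        window_s=window_s, stride_s=stride_s, rate_hz=rate_hz)
    return flag_padding_segments(segset, np.asarray(true_lengths))


def flag_padding_segments(segset: SegmentSet,
                          true_lengths: np.ndarray) -> SegmentSet:
    """Mark windows lying entirely within a subject's zero-padded tail.

    A window is padding-only iff its start sample is at or beyond the
    subject's true (unpadded) length in samples.
    """
    true_lengths = np.asarray(true_lengths)
    start_samples = np.round(segset.starts_s * segset.rate_hz).astype(int)
    flags = start_samples >= true_lengths[segset.subject_index]
    return replace(segset, is_padding_only=flags)


def summary_features(data: np.ndarray, true_length: int | None = None,
                     eps: float = 1e-8) -> np.ndarray:
    """Nine summary statistics of a 3-channel signal.

    Per channel: mean, population standard deviation (ddof=0) and
    coefficient of variation (sd/mean), over the unpadded extent
    ``data[:true_length]`` only.  Near-zero means (|mean| < eps) make the
    CV undefined; it is set to 0 with a warning.  Returned in channel-major
    order: (mean_1, sd_1, cv_1, mean_2, sd_2, cv_2, mean_3, sd_3, cv_3).
    """
    data = np.asarray(data, dtype=float)
    if true_length is not None:
        data = data[: int(true_length)]
    if data.shape[0] < 2:
        raise ValueError("need at least 2 samples within the true extent")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=0)
    cv = np.zeros_like(mean)
    small = np.abs(mean) < eps
    if small.any():
        warnings.warn("channel mean below epsilon; CV set to 0",
                      RuntimeWarning, stacklevel=2)
    cv[~small] = sd[~small] / mean[~small]
    return np.column_stack([mean, sd, cv]).reshape(-1)


def feature_table(signals: list[np.ndarray],
                  true_lengths: np.ndarray) -> np.ndarray:
    """Stack :func:`summary_features` over subjects -> (n_subjects, 9)."""
    return np.vstack([
        summary_features(sig, tl)
        for sig, tl in zip(signals, np.asarray(true_lengths))])
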