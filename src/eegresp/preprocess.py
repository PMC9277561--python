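"""Deterministic EEG signal conditioning.

The chain, applied in this fixed order, mirrors standard resting-state
practice: common-average re-referencing, per-channel baseline (mean) removal,
a zero-phase Butterworth band-pass (1-50 Hz by default) and extraction of a
fixed-length analysis segment.  All operations are pure: they return new
:class:`~eegresp.core.EEGRecording` objects with the step appended to
``provenance`` and never mutate their input.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core import ConfigError, DataValidationError, EEGRecording


def common_average_rereference(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous across-channel mean from every channel."""
    if rec.n_channels < 2:
        raise DataValidationError(
            "common-average re-referencing needs at least 2 channels"
        )
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.with_data(data, "common_average_rereference")


def remove_baseline(rec: EEGRecording) -> EEGRecording:
    """Subtract each channel's temporal mean (DC baseline)."""
    if rec.n_samples == 0:
        raise DataValidationError("empty recording")
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    return rec.with_data(data, "remove_baseline")


def bandpass_filter(
    rec: EEGRecording,
    f_low: float = 1.0,
    f_high: float = 50.0,
    order: int = 4,
) -> EEGRecording:
    """Zero-phase Butterworth band-pass (applied forward-backward).

    The effective magnitude response is the squared Butterworth response, so
    pass-band amplitudes are preserved and the -3 dB points sit slightly
    inside [f_low, f_high].
    """
    nyq = rec.fs / 2.0
    if not (0 < f_low < f_high < nyq):
        raise ConfigError(
            f"need 0 < f_low < f_high < fs/2; got ({f_low}, {f_high}) at fs={rec.fs}"
        )
    sos = signal.butter(order, [f_low, f_high], btype="bandpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.with_data(
        data, f"bandpass_butterworth(order={order}, band=[{f_low}, {f_high}] Hz, zero-phase)"
    )


def take_segment(
    rec: EEGRecording, length_s: float = 150.0, offset_s: float = 0.0
) -> EEGRecording:
    """Keep a contiguous ``length_s``-second window starting at ``offset_s``."""
    start = int(round(offset_s * rec.fs))
    n = int(round(length_s * rec.fs))
    if start < 0 or start + n > rec.n_samples:
        raise DataValidationError(
            f"recording {rec.subject_id}/{rec.session} has {rec.duration_s:.3f} s, "
            f"cannot take {length_s} s at offset {offset_s} s"
        )
    data = rec.data[:, start : start + n]
    return rec.with_data(data, f"segment(length={length_s} s, offset={offset_s} s)")


def preprocess(
    rec: EEGRecording,
    f_low: float = 1.0,
    f_high: float = 50.0,
    order: int = 4,
    segment_s: float | None = 150.0,
    segment_offset_s: float = 0.0,
) -> EEGRecording:
    """Full conditioning chain: re-reference -> demean -> band-pass -> segment."""
    out = common_average_rereference(rec)
    out = remove_baseline(out)
    out = bandpass_filter(out, f_low=f_low, f_high=f_high, order=order)
    if segment_s is not None:
        out = take_segment(out, length_s=segment_s, offset_s=segment_offset_s)
    return out
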