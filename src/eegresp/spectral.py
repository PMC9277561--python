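"""Welch power spectral density estimation and band-power features.

PSDs are estimated with Welch's method on 1-second Hamming-windowed segments
with 50% overlap (299 periodograms for a 150 s recording), one-sided density
scaling, no per-segment detrending (the conditioning chain already removes
the baseline).  "Band power" is the arithmetic mean of the PSD over the
half-open in-band frequency bins [f_low, f_high), so bands sharing an edge
never double-count a bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

from .core import (
    BandDefinition,
    BandPowerTable,
    ConfigError,
    DataValidationError,
    EEGRecording,
)


@dataclass
class PSDEstimate:
    """One-sided Welch PSD. ``psd`` is (n_channels, n_freqs) in µV²/Hz."""

    freqs: np.ndarray
    psd: np.ndarray
    seg_len_s: float
    overlap: float
    window: str

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.psd = np.atleast_2d(np.asarray(self.psd, float))
        if self.psd.shape[-1] != self.freqs.size:
            raise DataValidationError("psd and freqs lengths differ")
        if np.any(self.psd < 0):
            raise DataValidationError("PSD values must be non-negative")

    @property
    def df(self) -> float:
        """Frequency-grid spacing (1 / seg_len_s)."""
        return float(self.freqs[1] - self.freqs[0])

    def total_power(self) -> np.ndarray:
        """Rectangle-rule integral of the PSD over [0, fs/2], per channel."""
        return self.psd.sum(axis=-1) * self.df


def welch_psd(
    x: np.ndarray,
    fs: float,
    seg_len_s: float = 1.0,
    overlap: float = 0.5,
    window: str = "hamming",
) -> PSDEstimate:
    """Welch PSD of a single- or multi-channel series (last axis = time)."""
    x = np.asarray(x, float)
    nperseg = int(round(seg_len_s * fs))
    if x.shape[-1] < nperseg:
        raise DataValidationError(
            f"signal of {x.shape[-1]} samples shorter than one {seg_len_s} s segment"
        )
    if not 0 <= overlap < 1:
        raise ConfigError(f"overlap must be in [0, 1), got {overlap}")
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window=window,
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend=False,
        scaling="density",
        axis=-1,
    )
    return PSDEstimate(freqs, psd, seg_len_s, overlap, window)


def band_power(est: PSDEstimate, band: BandDefinition) -> np.ndarray:
    """Mean PSD over the half-open bin range f_low <= f < f_high, per channel."""
    mask = (est.freqs >= band.f_low) & (est.freqs < band.f_high)
    if not mask.any():
        raise ConfigError(
            f"band {band.name} [{band.f_low}, {band.f_high}) contains no frequency "
            f"bins on a grid with spacing {est.df} Hz"
        )
    return est.psd[:, mask].mean(axis=-1)


def band_powers_for_recording(
    rec: EEGRecording,
    bands: Sequence[BandDefinition],
    seg_len_s: float = 1.0,
    overlap: float = 0.5,
    window: str = "hamming",
) -> np.ndarray:
    """(n_channels, n_bands) mean-PSD matrix for one recording."""
    est = welch_psd(rec.data, rec.fs, seg_len_s=seg_len_s, overlap=overlap, window=window)
    return np.column_stack([band_power(est, b) for b in bands])


def build_band_power_table(
    recordings: Iterable[EEGRecording],
    bands: Sequence[BandDefinition],
    seg_len_s: float = 1.0,
    overlap: float = 0.5,
    window: str = "hamming",
) -> dict[str, BandPowerTable]:
    """One :class:`BandPowerTable` per session from preprocessed recordings.

    Subject order follows first appearance in the input; channel order is the
    (shared) channel order of the recordings.  All recordings must agree on
    sampling rate and channel set.
    """
    recordings = list(recordings)
    if not recordings:
        raise DataValidationError("no recordings given")
    fs = recordings[0].fs
    channels = recordings[0].channel_labels
    chan_key = tuple(c.upper() for c in channels)
    per_session: dict[str, dict[str, np.ndarray]] = {}
    subject_order: list[str] = []
    for rec in recordings:
        if rec.fs != fs:
            raise DataValidationError(
                f"sampling-rate mismatch: {rec.subject_id} has fs={rec.fs}, expected {fs}"
            )
        if tuple(c.upper() for c in rec.channel_labels) != chan_key:
            raise DataValidationError(
                f"channel set of {rec.subject_id}/{rec.session} differs from "
                f"{recordings[0].subject_id}"
            )
        sess = per_session.setdefault(rec.session, {})
        if rec.subject_id in sess:
            raise DataValidationError(
                f"duplicate recording for {rec.subject_id}/{rec.session}"
            )
        if rec.subject_id not in subject_order:
            subject_order.append(rec.subject_id)
        sess[rec.subject_id] = band_powers_for_recording(
            rec, bands, seg_len_s=seg_len_s, overlap=overlap, window=window
        )
    tables = {}
    band_names = tuple(b.name for b in bands)
    for session, by_subject in per_session.items():
        missing = [s for s in subject_order if s not in by_subject]
        if missing:
            raise DataValidationError(
                f"session {session!r} missing subjects {missing}"
            )
        values = np.stack([by_subject[s] for s in subject_order])
        tables[session] = BandPowerTable(
            session, tuple(subject_order), channels, band_names, values
        )
    return tables
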