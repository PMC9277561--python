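"""Shared domain containers for the EEG treatment-response pipeline.

The pipeline analyses resting-state EEG recorded before and after a course of
transcranial direct current stimulation (tDCS) in patients with PTSD.  The
objects defined here are passed between the stages:

* :class:`EEGRecording` — one subject-session multichannel time series,
* :class:`ClinicalRecord` — CAPS-5-like severity/symptom scores pre and post,
* :class:`BandDefinition` — a named frequency band,
* :class:`BandPowerTable` — subjects x channels x bands mean PSD for one
  session, the feature container consumed by the statistics and the
  classifier.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("eegresp")

SESSIONS = ("pre", "post")
GROUPS = ("responder", "nonresponder")


class ConfigError(ValueError):
    """A configuration value is invalid or internally inconsistent."""


class DataValidationError(ValueError):
    """Input data violate a structural contract (axes, labels, ranges)."""


# Extended 10-20 montage of a 62-electrode NeuroScan Quick-Cap
# (HEO/VEO/EKG excluded).  Order is the canonical montage order used for
# deterministic tie-breaking in channel selection.
CHANNELS_62: tuple[str, ...] = (
    "FP1", "FPZ", "FP2",
    "AF3", "AF4",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "CB1", "O1", "OZ", "O2", "CB2",
)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_low, f_high) in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ConfigError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got ({self.f_low}, {self.f_high})"
            )


#: The five canonical resting-state bands used throughout.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("low_alpha", 8.0, 10.0),
    BandDefinition("high_alpha", 10.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
)


def band_by_name(bands: Sequence[BandDefinition], name: str) -> BandDefinition:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}; have {[b.name for b in bands]}")


@dataclass
class EEGRecording:
    """One subject-session multichannel EEG time series.

    ``data`` is channels x samples in microvolts; row *i* corresponds to
    ``channel_labels[i]``.  ``provenance`` records the processing steps
    already applied, in order.
    """

    subject_id: str
    session: str
    channel_labels: tuple[str, ...]
    fs: float
    data: np.ndarray
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataValidationError("data must be a channels x samples matrix")
        if self.data.shape[0] != len(self.channel_labels):
            raise DataValidationError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if len(set(lbl.upper() for lbl in self.channel_labels)) != len(self.channel_labels):
            raise DataValidationError("channel labels must be unique (case-insensitive)")
        if not self.fs > 0:
            raise DataValidationError(f"fs must be positive, got {self.fs}")
        if self.session not in SESSIONS:
            raise DataValidationError(f"session must be one of {SESSIONS}, got {self.session!r}")
        if not np.all(np.isfinite(self.data)):
            raise DataValidationError("EEG samples must all be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, step: str) -> "EEGRecording":
        """Return a copy carrying new sample data and an appended provenance step."""
        return replace(self, data=np.asarray(data, float), provenance=self.provenance + (step,))


@dataclass
class ClinicalRecord:
    """Per-subject CAPS-5-like scores before and after treatment.

    ``sev`` is the total severity score, ``sx`` the total count of prevalent
    symptoms.  Optional DSM-5 subscale pairs (B intrusions, C avoidance,
    D negative affect, E arousal) may be attached; only the totals drive
    responder labeling.
    """

    subject_id: str
    sev_pre: int
    sev_post: int
    sx_pre: int
    sx_post: int
    group: str | None = None
    subscales: Mapping[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        for name in ("sev_pre", "sev_post", "sx_pre", "sx_post"):
            v = getattr(self, name)
            if v < 0:
                raise DataValidationError(f"{name} must be >= 0, got {v}")

    def improvement(self, scale: str) -> float:
        """Fractional improvement (pre - post) / pre on 'sev' or 'sx'."""
        pre = getattr(self, f"{scale}_pre")
        post = getattr(self, f"{scale}_post")
        if pre <= 0:
            raise ZeroDivisionError(f"{scale}_pre is zero for {self.subject_id}")
        return (pre - post) / pre

    @property
    def responder(self) -> bool:
        """True iff BOTH Sev and Sx improved by strictly more than 50%."""
        return self.improvement("sev") > 0.5 and self.improvement("sx") > 0.5


def clinical_to_csv(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "group": r.group if r.group is not None else "",
            "sev_pre": r.sev_pre,
            "sev_post": r.sev_post,
            "sx_pre": r.sx_pre,
            "sx_post": r.sx_post,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def clinical_from_csv(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path)
    required = {"subject_id", "sev_pre", "sev_post", "sx_pre", "sx_post"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"clinical table {path} missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        group = getattr(row, "group", None)
        if isinstance(group, float) and np.isnan(group):
            group = None
        out.append(
            ClinicalRecord(
                subject_id=str(row.subject_id),
                sev_pre=int(row.sev_pre),
                sev_post=int(row.sev_post),
                sx_pre=int(row.sx_pre),
                sx_post=int(row.sx_post),
                group=group if group else None,
            )
        )
    return out


@dataclass
class BandPowerTable:
    """Mean in-band PSD (µV²/Hz) per subject, channel and band for one session."""

    session: str
    subjects: tuple[str, ...]
    channels: tuple[str, ...]
    bands: tuple[str, ...]
    values: np.ndarray  # (n_subjects, n_channels, n_bands)

    def __post_init__(self) -> None:
        self.subjects = tuple(self.subjects)
        self.channels = tuple(self.channels)
        self.bands = tuple(self.bands)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.subjects), len(self.channels), len(self.bands))
        if self.values.shape != expected:
            raise DataValidationError(
                f"values shape {self.values.shape} != (subjects, channels, bands) {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError("band powers must be finite")
        if np.any(self.values < 0):
            raise DataValidationError("band powers must be non-negative")

    def get_band(self, band: str) -> np.ndarray:
        """Subjects x channels matrix for one band."""
        try:
            j = self.bands.index(band)
        except ValueError:
            raise KeyError(f"band {band!r} not in table bands {self.bands}") from None
        return self.values[:, :, j]

    @classmethod
    def single_band(
        cls,
        matrix: np.ndarray,
        band: str = "delta",
        session: str = "pre",
        subjects: Sequence[str] | None = None,
        channels: Sequence[str] | None = None,
    ) -> "BandPowerTable":
        """Wrap a subjects x channels matrix as a one-band table (test/fixture aid)."""
        matrix = np.asarray(matrix, float)
        n_subj, n_chan = matrix.shape
        subjects = tuple(subjects) if subjects is not None else tuple(
            f"sub{i:03d}" for i in range(n_subj)
        )
        channels = tuple(channels) if channels is not None else tuple(
            CHANNELS_62[:n_chan] if n_chan <= 62 else (f"CH{i}" for i in range(n_chan))
        )
        return cls(session, subjects, channels, (band,), matrix[:, :, None])

    def to_long_frame(self) -> pd.DataFrame:
        """Tidy long format: subject, channel, band, value."""
        idx = pd.MultiIndex.from_product(
            [self.subjects, self.channels, self.bands],
            names=["subject", "channel", "band"],
        )
        return pd.DataFrame({"value": self.values.ravel()}, index=idx).reset_index()

    def to_csv(self, path: str | Path) -> None:
        df = self.to_long_frame()
        df.insert(0, "session", self.session)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BandPowerTable":
        df = pd.read_csv(path)
        required = {"session", "subject", "channel", "band", "value"}
        if not required <= set(df.columns):
            raise DataValidationError(f"band-power table {path} needs columns {sorted(required)}")
        sessions = df["session"].unique()
        if len(sessions) != 1:
            raise DataValidationError("one band-power file must hold exactly one session")
        subjects = tuple(pd.unique(df["subject"]).astype(str))
        channels = tuple(pd.unique(df["channel"]).astype(str))
        bands = tuple(pd.unique(df["band"]).astype(str))
        pivot = df.set_index(["subject", "channel", "band"])["value"]
        values = pivot.reindex(
            pd.MultiIndex.from_product([subjects, channels, bands])
        ).to_numpy().reshape(len(subjects), len(channels), len(bands))
        if np.any(np.isnan(values)):
            raise DataValidationError(f"band-power table {path} is not a full grid")
        return cls(str(sessions[0]), subjects, channels, bands, values)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
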