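"""Synthetic pre/post EEG cohorts with controllable group structure.

No raw clinical EEG accompanies the study this pipeline targets, so every
downstream stage is exercised on simulated cohorts.  Each subject-session
recording is a stationary Gaussian process whose one-sided power spectral
density is piecewise constant over the analysis bands plus a 1/f background:

    S(f) = sum_b  P_b * e(group, session, channel, b) * u_subj * v_sess * w_chan
           + pink_noise_level^2 / f

where ``P_b`` is the per-band baseline density, ``e`` the configured
multiplicative effect factor and ``u, v, w`` lognormal variability factors
(between subjects, between sessions within subject, between channels).  The
realization is synthesized directly in the frequency domain (complex Gaussian
rFFT coefficients scaled to the target density), which is distributionally the
sum of independently band-pass-filtered white-noise components the model
describes, with an exactly calibrated expected Welch band power.

Clinical scores are generated so that the intended group always satisfies the
">50% improvement on both Sev and Sx" responder rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .core import (
    CHANNELS_62,
    DEFAULT_BANDS,
    GROUPS,
    SESSIONS,
    BandDefinition,
    ClinicalRecord,
    ConfigError,
    EEGRecording,
    clinical_to_csv,
)

logger = logging.getLogger("eegresp")

#: Width (Hz) of the constant-level spectral shoulder above the highest band,
#: so Hamming-window smearing does not bias the edge bins of that band.
SHOULDER_HZ = 4.0


@dataclass(frozen=True)
class EffectRule:
    """Multiplicative band-power factor for matching (group, session, channel, band).

    Each field is either a literal label, ``"*"`` (match anything), or a
    tuple of labels.  Factors of all matching rules multiply.
    """

    group: str = "*"
    session: str = "*"
    channel: str | tuple[str, ...] = "*"
    band: str | tuple[str, ...] = "*"
    factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ConfigError(f"effect factor must be > 0, got {self.factor}")

    @staticmethod
    def _match(pattern, value: str) -> bool:
        if pattern == "*":
            return True
        if isinstance(pattern, str):
            return pattern.upper() == value.upper()
        return value.upper() in {p.upper() for p in pattern}

    def matches(self, group: str, session: str, channel: str, band: str) -> bool:
        return (
            self._match(self.group, group)
            and self._match(self.session, session)
            and self._match(self.channel, channel)
            and self._match(self.band, band)
        )


def default_effect_map() -> tuple[EffectRule, ...]:
    """Study-condition effects: responders' theta/beta power falls after
    treatment while non-responders' rises, and a handful of channels carry
    pre-existing (both-session) between-group differences that make
    responder status predictable from pre-treatment powers alone."""
    return (
        # treatment-by-group effects on post-treatment power
        EffectRule("responder", "post", "*", ("theta", "beta"), 0.84),
        EffectRule("nonresponder", "post", "*", ("theta", "beta"), 1.12),
        # trait (session-independent) group differences in selected channels
        EffectRule("responder", "*", ("CZ", "O1", "FC2", "FC1", "F2"), "delta", 1.50),
        EffectRule("responder", "*", ("PZ", "CP5"), "beta", 0.65),
        EffectRule("responder", "*", ("FCZ", "POZ", "CPZ"), "theta", 1.35),
    )


_DEFAULT_BASE_POWER: Mapping[str, float] = {
    "delta": 1.2,
    "theta": 0.9,
    "low_alpha": 1.1,
    "high_alpha": 0.9,
    "beta": 0.45,
}


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic pre/post cohort.

    Defaults reproduce the study conditions: 17 responders + 31
    non-responders, 62-channel extended 10-20 montage, 1,000 Hz sampling,
    150 s eyes-closed segments and the five canonical bands.
    """

    n_responders: int = 17
    n_nonresponders: int = 31
    channel_labels: tuple[str, ...] = CHANNELS_62
    fs: float = 1000.0
    duration_s: float = 150.0
    band_defs: tuple[BandDefinition, ...] = DEFAULT_BANDS
    base_band_power: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASE_POWER)
    )
    effect_map: tuple[EffectRule, ...] = field(default_factory=default_effect_map)
    pink_noise_level: float = 0.2
    subject_sd: float = 0.30   # between-subject log-power SD (trait)
    session_sd: float = 0.15   # between-session within-subject log-power SD (state)
    channel_sd: float = 0.10   # per-channel log-power jitter
    improvement_responder: float = 0.70
    improvement_nonresponder: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.band_defs = tuple(self.band_defs)
        self.validate()

    def validate(self) -> None:
        if self.n_responders < 0 or self.n_nonresponders < 0:
            raise ConfigError("group sizes must be >= 0")
        if self.n_responders + self.n_nonresponders < 2:
            raise ConfigError("need at least 2 subjects in total")
        if len(set(c.upper() for c in self.channel_labels)) != len(self.channel_labels):
            raise ConfigError("channel_labels must be unique")
        highest = max(b.f_high for b in self.band_defs)
        if not self.fs > 2 * (highest + SHOULDER_HZ):
            raise ConfigError(
                f"fs={self.fs} too low for highest band edge {highest} Hz "
                f"(+{SHOULDER_HZ} Hz shoulder); need fs > {2 * (highest + SHOULDER_HZ)}"
            )
        for b in self.band_defs:
            if b.name not in self.base_band_power:
                raise ConfigError(f"base_band_power missing band {b.name!r}")
            if not self.base_band_power[b.name] > 0:
                raise ConfigError(f"base_band_power[{b.name!r}] must be > 0")
        for sd in (self.subject_sd, self.session_sd, self.channel_sd):
            if sd < 0:
                raise ConfigError("variability SDs must be >= 0")
        if self.pink_noise_level < 0:
            raise ConfigError("pink_noise_level must be >= 0")
        if not (0 < self.improvement_nonresponder < 0.5 < self.improvement_responder < 1):
            raise ConfigError(
                "need 0 < improvement_nonresponder < 0.5 < improvement_responder < 1"
            )

    @property
    def n_subjects(self) -> int:
        return self.n_responders + self.n_nonresponders

    def effect_factor(self, group: str, session: str, channel: str, band: str) -> float:
        f = 1.0
        for rule in self.effect_map:
            if rule.matches(group, session, channel, band):
                f *= rule.factor
        return f

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SyntheticConfig":
        raw = dict(raw)
        if "band_defs" in raw:
            raw["band_defs"] = tuple(
                BandDefinition(b["name"], float(b["f_low"]), float(b["f_high"]))
                for b in raw["band_defs"]
            )
        if "effect_map" in raw:
            raw["effect_map"] = tuple(
                EffectRule(
                    group=r.get("group", "*"),
                    session=r.get("session", "*"),
                    channel=_as_pattern(r.get("channel", "*")),
                    band=_as_pattern(r.get("band", "*")),
                    factor=float(r.get("factor", 1.0)),
                )
                for r in raw["effect_map"]
            )
        if "channel_labels" in raw:
            raw["channel_labels"] = tuple(raw["channel_labels"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "n_responders": self.n_responders,
            "n_nonresponders": self.n_nonresponders,
            "channel_labels": list(self.channel_labels),
            "fs": self.fs,
            "duration_s": self.duration_s,
            "band_defs": [
                {"name": b.name, "f_low": b.f_low, "f_high": b.f_high}
                for b in self.band_defs
            ],
            "base_band_power": dict(self.base_band_power),
            "effect_map": [
                {
                    "group": r.group,
                    "session": r.session,
                    "channel": list(r.channel) if isinstance(r.channel, tuple) else r.channel,
                    "band": list(r.band) if isinstance(r.band, tuple) else r.band,
                    "factor": r.factor,
                }
                for r in self.effect_map
            ],
            "pink_noise_level": self.pink_noise_level,
            "subject_sd": self.subject_sd,
            "session_sd": self.session_sd,
            "channel_sd": self.channel_sd,
            "improvement_responder": self.improvement_responder,
            "improvement_nonresponder": self.improvement_nonresponder,
            "seed": self.seed,
        }


def _as_pattern(value):
    return tuple(value) if isinstance(value, (list, tuple)) else value


# ----------------------------------------------------------------- recording


def _as_seedseq(rng_state) -> np.random.SeedSequence:
    if isinstance(rng_state, np.random.SeedSequence):
        return rng_state
    return np.random.SeedSequence(rng_state)


def _child(ss: np.random.SeedSequence, key: int) -> np.random.SeedSequence:
    """Stateless substream derivation (SeedSequence.spawn mutates its parent)."""
    return np.random.SeedSequence(entropy=ss.entropy, spawn_key=ss.spawn_key + (key,))


def _target_density(
    config: SyntheticConfig,
    freqs: np.ndarray,
    factors: np.ndarray,  # (n_channels, n_bands) total multiplicative factor
) -> np.ndarray:
    """One-sided target PSD (n_channels, n_freqs) on the synthesis grid."""
    bands = sorted(config.band_defs, key=lambda b: b.f_low)
    n_chan = factors.shape[0]
    S = np.zeros((n_chan, freqs.size))
    band_index = {b.name: j for j, b in enumerate(config.band_defs)}
    for k, b in enumerate(bands):
        lo, hi = b.f_low, b.f_high
        if k == 0:
            lo = 0.0            # extend lowest band level down to DC (shoulder)
        if k == len(bands) - 1:
            hi = hi + SHOULDER_HZ  # shoulder above the top band
        mask = (freqs >= lo) & (freqs < hi)
        level = config.base_band_power[b.name] * factors[:, band_index[b.name]]
        S[:, mask] += level[:, None]
    if config.pink_noise_level > 0:
        with np.errstate(divide="ignore"):
            pink = config.pink_noise_level**2 / np.maximum(freqs, 0.5)
        S += pink[None, :]
    S[:, 0] = 0.0  # no DC power
    return S


def generate_recording(
    config: SyntheticConfig,
    subject_id: str,
    group: str,
    session: str,
    rng_state: int | np.random.SeedSequence,
) -> EEGRecording:
    """Synthesize one subject-session recording.

    ``rng_state`` identifies the *subject* stream: calling with the same
    state for session 'pre' and 'post' yields consistent trait-level
    (session-independent) variability factors.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    if session not in SESSIONS:
        raise ValueError(f"session must be one of {SESSIONS}, got {session!r}")
    config.validate()

    ss = _as_seedseq(rng_state)
    trait_ss = _child(ss, 0)
    session_ss = _child(ss, 1 if session == "pre" else 2)
    trait_rng = np.random.default_rng(trait_ss)
    sess_rng = np.random.default_rng(session_ss)

    n_chan = len(config.channel_labels)
    n_band = len(config.band_defs)
    band_names = [b.name for b in config.band_defs]

    # lognormal variability: trait (subject x band, shared across sessions),
    # state (session x band) and per-channel jitter
    u_subj = np.exp(trait_rng.normal(0.0, config.subject_sd, size=n_band))
    v_sess = np.exp(sess_rng.normal(0.0, config.session_sd, size=n_band))
    w_chan = np.exp(sess_rng.normal(0.0, config.channel_sd, size=(n_chan, n_band)))

    effects = np.array(
        [
            [config.effect_factor(group, session, ch, b) for b in band_names]
            for ch in config.channel_labels
        ]
    )
    factors = effects * (u_subj * v_sess)[None, :] * w_chan

    n = int(round(config.duration_s * config.fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / config.fs)
    S = _target_density(config, freqs, factors)

    # complex Gaussian spectral synthesis: E|Z_k|^2 = S_k * fs * n / 2
    scale = np.sqrt(S * config.fs * n / 2.0)
    z = sess_rng.standard_normal((n_chan, freqs.size)) + 1j * sess_rng.standard_normal(
        (n_chan, freqs.size)
    )
    Z = scale * z / np.sqrt(2.0)
    Z[:, 0] = 0.0
    if n % 2 == 0:  # Nyquist bin must be real
        Z[:, -1] = scale[:, -1] * z[:, -1].real
    data = np.fft.irfft(Z, n=n, axis=1)

    return EEGRecording(
        subject_id=subject_id,
        session=session,
        channel_labels=config.channel_labels,
        fs=config.fs,
        data=data,
        provenance=(f"synthetic(group={group}, seed_entropy={ss.entropy})",),
    )


# ------------------------------------------------------------------ clinical

# Safety margin keeping realized improvements away from the 50% boundary so
# integer rounding of post scores can never flip a label (pre >= 20 means
# rounding moves the fraction by at most 0.025).
_MARGIN = 0.55, 0.45


def generate_clinical(
    group: str,
    rng_state: int | np.random.SeedSequence,
    improvement_responder: float = 0.70,
    improvement_nonresponder: float = 0.20,
    subject_id: str = "sub000",
) -> ClinicalRecord:
    """Draw CAPS-like pre/post scores consistent with the group's label.

    Pre-treatment totals are drawn on the scale of a moderate-to-severe PTSD
    cohort (Sev around 40, Sx up to 20); post scores apply a noisy
    group-specific fractional improvement, clipped away from the 50%
    boundary so the responder rule always matches ``group``.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    if not (0 < improvement_nonresponder < 0.5 < improvement_responder < 1):
        raise ValueError(
            "need 0 < improvement_nonresponder < 0.5 < improvement_responder < 1"
        )
    rng = np.random.default_rng(_as_seedseq(rng_state))
    sev_pre = int(np.clip(round(rng.normal(42.0, 8.0)), 20, 70))
    sx_pre = int(np.clip(round(rng.normal(14.0, 3.0)), 6, 20))

    center = improvement_responder if group == "responder" else improvement_nonresponder
    lo, hi = (_MARGIN[0], 0.95) if group == "responder" else (0.05, _MARGIN[1])
    post = {}
    for scale, pre in (("sev", sev_pre), ("sx", sx_pre)):
        imp = float(np.clip(rng.normal(center, 0.08), lo, hi))
        value = max(0, int(round(pre * (1.0 - imp))))
        # integer clamp so rounding can never move the improvement across 50%:
        # responders need post < pre/2 (strict), non-responders post >= pre/2
        half = int(np.ceil(pre / 2.0))
        value = min(value, half - 1) if group == "responder" else max(value, half)
        post[scale] = value

    rec = ClinicalRecord(
        subject_id=subject_id,
        sev_pre=sev_pre,
        sev_post=post["sev"],
        sx_pre=sx_pre,
        sx_post=post["sx"],
        group=group,
        subscales=_split_subscales(sev_pre, post["sev"], sx_pre, post["sx"]),
    )
    assert rec.responder == (group == "responder"), "label rule violated by construction"
    return rec


def _split_subscales(sev_pre, sev_post, sx_pre, sx_post):
    """Deterministically split totals into B/C/D/E with fixed proportions."""
    props = {"B": 0.25, "C": 0.20, "D": 0.35, "E": 0.20}
    out = {}
    for key, p in props.items():
        out[f"{key}_sev"] = (int(round(sev_pre * p)), int(round(sev_post * p)))
        out[f"{key}_sx"] = (int(round(sx_pre * p)), int(round(sx_post * p)))
    return out


# -------------------------------------------------------------------- cohort


def subject_plan(config: SyntheticConfig) -> list[tuple[str, str, np.random.SeedSequence]]:
    """Stable (subject_id, group, subject SeedSequence) triples.

    Substreams are keyed by subject index, so enlarging the cohort never
    reshuffles earlier subjects.
    """
    plan = []
    for i in range(config.n_subjects):
        group = "responder" if i < config.n_responders else "nonresponder"
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(i,))
        plan.append((f"sub{i:03d}", group, ss))
    return plan


def iter_cohort_recordings(config: SyntheticConfig):
    """Yield (pre, post) EEGRecording pairs one subject at a time.

    Streaming generation keeps peak memory at two recordings; at the default
    62 ch x 150 s x 1 kHz a single recording is ~74 MB.
    """
    for subject_id, group, ss in subject_plan(config):
        eeg_ss = _child(ss, 0)
        yield (
            generate_recording(config, subject_id, group, "pre", eeg_ss),
            generate_recording(config, subject_id, group, "post", eeg_ss),
        )


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[EEGRecording], list[ClinicalRecord]]:
    """Materialize the full cohort: 2 recordings per subject + clinical table.

    Fully reproducible from ``config.seed``.  For large configurations prefer
    :func:`iter_cohort_recordings` plus :func:`generate_clinical_cohort`.
    """
    recordings: list[EEGRecording] = []
    for pre, post in iter_cohort_recordings(config):
        recordings.extend((pre, post))
    return recordings, generate_clinical_cohort(config)


def generate_clinical_cohort(config: SyntheticConfig) -> list[ClinicalRecord]:
    out = []
    for subject_id, group, ss in subject_plan(config):
        clin_ss = _child(ss, 1)
        out.append(
            generate_clinical(
                group,
                clin_ss,
                improvement_responder=config.improvement_responder,
                improvement_nonresponder=config.improvement_nonresponder,
                subject_id=subject_id,
            )
        )
    return out


# ------------------------------------------------------------------- writers


def write_recording(rec: EEGRecording, directory: str | Path, fmt: str = "%.8g") -> Path:
    """Write one recording as a samples-in-columns CSV matrix + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{rec.subject_id}_{rec.session}"
    data_path = directory / f"{stem}.csv"
    np.savetxt(data_path, rec.data, delimiter=",", fmt=fmt)
    sidecar = {
        "subject": rec.subject_id,
        "session": rec.session,
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return data_path


def write_cohort(config: SyntheticConfig, directory: str | Path) -> Path:
    """Write a full synthetic cohort (EEG matrices + clinical.csv) to disk."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for pre, post in iter_cohort_recordings(config):
        write_recording(pre, directory)
        write_recording(post, directory)
    clinical_to_csv(generate_clinical_cohort(config), directory / "clinical.csv")
    return directory
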