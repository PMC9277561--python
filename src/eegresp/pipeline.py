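"""End-to-end orchestration: simulate/ingest -> preprocess -> band powers ->
group statistics -> classification, with stable on-disk schemas.

A run follows the two analysis paths: (a) pre/post change-rate statistics per
band with FDR-adjusted group comparisons, and (b) prediction of responder
status from pre-treatment band powers (single-channel screen, greedy forward
channel selection, permutation test of the best subset).  Every artifact is
traceable to the run's config and seed through ``manifest.json``, and
re-running with the same config produces byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from .preprocess import preprocess as preprocess_recording
from . import groupstats as gs
from . import spectral as sp
from . import synthetic as syn
from .core import (
    BandPowerTable,
    ClinicalRecord,
    ConfigError,
    DataValidationError,
    EEGRecording,
    clinical_from_csv,
    clinical_to_csv,
    write_json,
)

logger = logging.getLogger("eegresp")


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    synthetic: syn.SyntheticConfig | None = None
    input_dir: str | None = None
    # preprocessing
    f_low: float = 1.0
    f_high: float = 50.0
    filter_order: int = 4
    segment_s: float | None = 150.0
    segment_offset_s: float = 0.0
    # Welch
    seg_len_s: float = 1.0
    overlap: float = 0.5
    window: str = "hamming"
    # statistics
    responder_rule: str = "both"
    responder_threshold: float = 0.5
    # classification
    classifier: clf.ClassifierSpec = field(default_factory=clf.ClassifierSpec)
    selection_max_steps: int | None = None
    n_perm: int = 1000
    # bookkeeping
    out_dir: str = "results"
    seed: int = 0
    write_raw: bool = False

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_dir is None):
            raise ConfigError("exactly one of 'synthetic' or 'input_dir' must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        if raw.get("synthetic") is not None:
            syn_raw = dict(raw["synthetic"])
            syn_raw.setdefault("seed", raw.get("seed", 0))
            raw["synthetic"] = syn.SyntheticConfig.from_dict(syn_raw)
        if raw.get("classifier") is not None:
            cdict = dict(raw["classifier"])
            for key in ("c_grid", "gamma_grid"):
                if key in cdict:
                    cdict[key] = tuple(float(v) for v in cdict[key])
            raw["classifier"] = clf.ClassifierSpec(**cdict)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {
            "synthetic": self.synthetic.to_dict() if self.synthetic else None,
            "input_dir": self.input_dir,
            "f_low": self.f_low,
            "f_high": self.f_high,
            "filter_order": self.filter_order,
            "segment_s": self.segment_s,
            "segment_offset_s": self.segment_offset_s,
            "seg_len_s": self.seg_len_s,
            "overlap": self.overlap,
            "window": self.window,
            "responder_rule": self.responder_rule,
            "responder_threshold": self.responder_threshold,
            "classifier": {
                "kernel": self.classifier.kernel,
                "c_grid": list(self.classifier.c_grid),
                "gamma_grid": list(self.classifier.gamma_grid),
                "n_folds": self.classifier.n_folds,
                "inner_folds": self.classifier.inner_folds,
                "cv_seed": self.classifier.cv_seed,
                "scale_features": self.classifier.scale_features,
            },
            "selection_max_steps": self.selection_max_steps,
            "n_perm": self.n_perm,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "write_raw": self.write_raw,
        }
        return d


# ------------------------------------------------------------------- reading


def _read_matrix_recording(sidecar_path: Path) -> EEGRecording:
    meta = json.loads(sidecar_path.read_text())
    for key in ("subject", "session", "fs", "channel_labels"):
        if key not in meta:
            raise DataValidationError(f"sidecar {sidecar_path} missing key {key!r}")
    data_path = sidecar_path.with_suffix(".csv")
    if not data_path.exists():
        raise DataValidationError(f"no data matrix next to sidecar {sidecar_path}")
    data = np.loadtxt(data_path, delimiter=",", ndmin=2)
    return EEGRecording(
        subject_id=str(meta["subject"]),
        session=str(meta["session"]),
        channel_labels=tuple(meta["channel_labels"]),
        fs=float(meta["fs"]),
        data=data,
        provenance=(f"loaded({data_path.name})",),
    )


def _read_edf_recording(path: Path) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an optional extra
        raise DataValidationError(f"cannot read {path}: mne is not installed") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    stem = path.stem
    if "_" not in stem:
        raise DataValidationError(
            f"EDF filename {path.name} must be <subject>_<session>.edf"
        )
    subject, session = stem.rsplit("_", 1)
    return EEGRecording(
        subject_id=subject,
        session=session,
        channel_labels=tuple(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        data=raw.get_data() * 1e6,  # volts -> microvolts
        provenance=(f"loaded({path.name})",),
    )


def read_eeg_dataset(path: str | Path, expected_channels: int | None = None) -> list[EEGRecording]:
    """Load every EDF or CSV-matrix+JSON-sidecar recording in a directory.

    Mixed formats are allowed; all recordings must agree on sampling rate and
    channel count (and on ``expected_channels`` if given).
    """
    path = Path(path)
    if not path.is_dir():
        raise DataValidationError(f"{path} is not a directory")
    recs: list[EEGRecording] = []
    for sidecar in sorted(path.glob("*.json")):
        if sidecar.name in ("manifest.json",):
            continue
        recs.append(_read_matrix_recording(sidecar))
    for edf in sorted(path.glob("*.edf")):
        recs.append(_read_edf_recording(edf))
    if not recs:
        raise DataValidationError(f"no recordings found in {path}")
    fs = recs[0].fs
    n_chan = expected_channels or recs[0].n_channels
    for r in recs:
        if r.fs != fs:
            raise DataValidationError(
                f"sampling-rate mismatch: {r.subject_id}/{r.session} has fs={r.fs}, expected {fs}"
            )
        if r.n_channels != n_chan:
            raise DataValidationError(
                f"{r.subject_id}/{r.session} has {r.n_channels} channels, expected {n_chan}"
            )
    return recs


# ---------------------------------------------------------------- the stages


def compute_band_power_tables(config: RunConfig) -> tuple[dict[str, BandPowerTable], list[ClinicalRecord]]:
    """Acquire (synthesize or load) recordings, condition them and build the
    per-session band-power tables.  Synthetic cohorts are generated
    subject-by-subject so peak memory stays at two recordings."""
    if config.synthetic is not None:
        bands = config.synthetic.band_defs
        clinical = syn.generate_clinical_cohort(config.synthetic)
        rows: dict[str, dict[str, np.ndarray]] = {"pre": {}, "post": {}}
        subjects: list[str] = []
        channels = config.synthetic.channel_labels
        for pre_rec, post_rec in syn.iter_cohort_recordings(config.synthetic):
            subjects.append(pre_rec.subject_id)
            for rec in (pre_rec, post_rec):
                conditioned = preprocess_recording(
                    rec,
                    f_low=config.f_low,
                    f_high=config.f_high,
                    order=config.filter_order,
                    segment_s=(
                        min(config.segment_s, rec.duration_s)
                        if config.segment_s is not None
                        else None
                    ),
                    segment_offset_s=config.segment_offset_s,
                )
                rows[rec.session][rec.subject_id] = sp.band_powers_for_recording(
                    conditioned,
                    bands,
                    seg_len_s=config.seg_len_s,
                    overlap=config.overlap,
                    window=config.window,
                )
        band_names = tuple(b.name for b in bands)
        tables = {
            session: BandPowerTable(
                session,
                tuple(subjects),
                channels,
                band_names,
                np.stack([by_subj[s] for s in subjects]),
            )
            for session, by_subj in rows.items()
        }
        return tables, clinical

    data_dir = Path(config.input_dir)
    recordings = read_eeg_dataset(data_dir)
    clinical_path = data_dir / "clinical.csv"
    if not clinical_path.exists():
        raise DataValidationError(f"no clinical table at {clinical_path}")
    clinical = clinical_from_csv(clinical_path)
    from .core import DEFAULT_BANDS

    conditioned = [
        preprocess_recording(
            rec,
            f_low=config.f_low,
            f_high=config.f_high,
            order=config.filter_order,
            segment_s=(
                min(config.segment_s, rec.duration_s) if config.segment_s is not None else None
            ),
            segment_offset_s=config.segment_offset_s,
        )
        for rec in recordings
    ]
    tables = sp.build_band_power_table(
        conditioned,
        DEFAULT_BANDS,
        seg_len_s=config.seg_len_s,
        overlap=config.overlap,
        window=config.window,
    )
    return tables, clinical


def _check_subject_match(tables: dict[str, BandPowerTable], labels: Mapping[str, bool]) -> None:
    for session, table in tables.items():
        missing = [s for s in table.subjects if s not in labels]
        if missing:
            raise DataValidationError(
                f"clinical table missing subjects present in EEG ({session}): {missing}"
            )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all result tables + manifest.

    Returns the manifest (also written to ``<out_dir>/manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tables, clinical = compute_band_power_tables(config)
    if "pre" not in tables or "post" not in tables:
        raise DataValidationError(f"need both sessions, found {sorted(tables)}")
    labels = gs.label_responders(
        clinical, threshold=config.responder_threshold, rule=config.responder_rule
    )
    _check_subject_match(tables, labels)

    clinical_to_csv(clinical, out / "clinical.csv")
    tables["pre"].to_csv(out / "bandpower_pre.csv")
    tables["post"].to_csv(out / "bandpower_post.csv")

    # out_dir is a filesystem location, not part of the run's scientific
    # identity: dropping it keeps manifests of identical runs byte-identical
    config_echo = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    manifest: dict = {
        "config": config_echo,
        "files": {
            "clinical": "clinical.csv",
            "bandpower_pre": "bandpower_pre.csv",
            "bandpower_post": "bandpower_post.csv",
            "group_stats": {},
            "single_channel": {},
            "selection": {},
        },
        "summary": {"n_responders": int(sum(labels.values())), "n_subjects": len(labels)},
    }

    # upper path: change-rate statistics
    changes = gs.change_rate(tables["pre"], tables["post"])
    stats_summary = {}
    for band in changes.bands:
        result = gs.compare_groups(changes, labels, band)
        fname = f"group_stats_{band}.csv"
        result.to_frame().to_csv(out / fname, index=False)
        manifest["files"]["group_stats"][band] = fname
        valid_p = [t.p_adj for t in result.tests if t.valid]
        stats_summary[band] = {
            "n_significant_adj": int(sum(p < 0.05 for p in valid_p)),
            "min_p_adj": float(min(valid_p)) if valid_p else None,
        }
    manifest["summary"]["group_stats"] = stats_summary

    # lower path: prediction from pre-treatment powers
    seed_seq = np.random.SeedSequence(config.seed)
    perm_seeds = seed_seq.generate_state(len(tables["pre"].bands)) % (2**31)
    clf_summary = {}
    for b_idx, band in enumerate(tables["pre"].bands):
        screen = clf.single_channel_screen(tables["pre"], labels, band, config.classifier)
        screen_df = pd.DataFrame(
            [
                {
                    "band": band,
                    "channel": ch,
                    "auc": r.auc,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "balanced_accuracy": r.balanced_accuracy,
                }
                for ch, r in screen.items()
            ]
        )
        fname = f"single_channel_{band}.csv"
        screen_df.to_csv(out / fname, index=False)
        manifest["files"]["single_channel"][band] = fname

        trace = clf.forward_channel_selection(
            tables["pre"], labels, band, config.classifier, max_steps=config.selection_max_steps
        )
        perm = clf.permutation_test(
            tables["pre"],
            labels,
            trace.best_subset,
            band,
            spec=config.classifier,
            n_perm=config.n_perm,
            seed=int(perm_seeds[b_idx]),
        )
        trace_dict = trace.to_dict()
        trace_dict["permutation"] = {
            "observed_auc": perm.observed_auc,
            "p_value": perm.p_value,
            "n_perm": config.n_perm,
            "null_aucs": perm.null_aucs.tolist(),
        }
        fname = f"selection_{band}.json"
        write_json(trace_dict, out / fname)
        manifest["files"]["selection"][band] = fname

        best_single = max(screen.items(), key=lambda kv: kv[1].auc)
        clf_summary[band] = {
            "best_single_channel": best_single[0],
            "best_single_auc": best_single[1].auc,
            "best_subset": trace.best_subset,
            "best_auc": trace.best_auc,
            "best_balanced_accuracy": trace.best_result.balanced_accuracy,
            "permutation_p": perm.p_value,
        }
    manifest["summary"]["classification"] = clf_summary

    write_json(manifest, out / "manifest.json")
    logger.info("pipeline complete; manifest at %s", out / "manifest.json")
    return manifest
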