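"""Responder labeling, band-power change rates and group comparisons.

The treatment-effect statistic is the fractional change rate

    P_change = (P_pre - P_post) / P_pre

per subject, channel and band: positive values mean power *decreased* after
treatment.  Change rates are compared between responders and non-responders
channel by channel with an assumption-gated test choice — Lilliefors-corrected
Kolmogorov-Smirnov normality checks on each group, Levene's test for equal
variances, then a pooled t, Welch t, or Mann-Whitney U as appropriate — and
the per-band p-value family is Benjamini-Hochberg FDR adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .core import BandPowerTable, ClinicalRecord, DataValidationError

logger = logging.getLogger("eegresp")

ALPHA_ASSUMPTION = 0.05  # gate level for normality / equal-variance checks


# ------------------------------------------------------------------ labeling


def label_responders(
    clinical: Sequence[ClinicalRecord],
    threshold: float = 0.5,
    rule: str = "both",
) -> dict[str, bool]:
    """Responder labels from fractional improvement of the clinical totals.

    A subject is a responder when improvement exceeds ``threshold``
    (strictly) on both Sev and Sx totals (``rule='both'``), or on Sev alone
    (``rule='sev'``).  Subjects with a zero pre-treatment score have an
    undefined improvement fraction and are excluded with a warning.
    """
    if rule not in ("both", "sev"):
        raise ValueError(f"rule must be 'both' or 'sev', got {rule!r}")
    labels: dict[str, bool] = {}
    for rec in clinical:
        if rec.sev_pre <= 0 or (rule == "both" and rec.sx_pre <= 0):
            logger.warning(
                "subject %s excluded from labeling: zero pre-treatment score",
                rec.subject_id,
            )
            continue
        ok = rec.improvement("sev") > threshold
        if rule == "both":
            ok = ok and rec.improvement("sx") > threshold
        labels[rec.subject_id] = bool(ok)
    return labels


# --------------------------------------------------------------- change rate


@dataclass
class ChangeRateTable:
    """Per-subject fractional band-power change rates.

    ``valid`` flags entries whose pre-treatment power was positive; invalid
    entries hold NaN and are excluded from group comparisons.
    """

    subjects: tuple[str, ...]
    channels: tuple[str, ...]
    bands: tuple[str, ...]
    values: np.ndarray
    valid: np.ndarray

    def get_band(self, band: str) -> tuple[np.ndarray, np.ndarray]:
        j = self.bands.index(band)
        return self.values[:, :, j], self.valid[:, :, j]


def change_rate(pre: BandPowerTable, post: BandPowerTable) -> ChangeRateTable:
    """Elementwise (P_pre - P_post) / P_pre on axis-matched tables."""
    for axis in ("subjects", "channels", "bands"):
        if getattr(pre, axis) != getattr(post, axis):
            raise DataValidationError(
                f"pre/post tables disagree on {axis}: "
                f"{getattr(pre, axis)} vs {getattr(post, axis)}"
            )
    valid = pre.values > 0
    if not valid.all():
        n_bad = int((~valid).sum())
        logger.warning("change_rate: %d entries with nonpositive pre power flagged invalid", n_bad)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = (pre.values - post.values) / pre.values
    values = np.where(valid, values, np.nan)
    return ChangeRateTable(pre.subjects, pre.channels, pre.bands, values, valid)


# ----------------------------------------------------------- FDR adjustment


def fdr_adjust(p_raw: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to 1)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # step-up monotonicity: running minimum from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


# --------------------------------------------------------- group comparison


@dataclass
class ChannelTest:
    channel: str
    n_resp: int
    n_nonresp: int
    valid: bool
    normality_ok: bool | None = None
    variance_equal: bool | None = None
    test_used: str | None = None
    statistic: float = np.nan
    df: float | None = None
    p_raw: float = np.nan
    p_adj: float = np.nan
    note: str = ""


@dataclass
class GroupComparisonResult:
    """Per-channel responder vs non-responder tests for one band's change rates."""

    band: str
    tests: list[ChannelTest] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "band": self.band,
                    "channel": t.channel,
                    "n_resp": t.n_resp,
                    "n_nonresp": t.n_nonresp,
                    "valid": t.valid,
                    "normality_ok": t.normality_ok,
                    "variance_equal": t.variance_equal,
                    "test_used": t.test_used,
                    "statistic": t.statistic,
                    "df": t.df,
                    "p_raw": t.p_raw,
                    "p_adj": t.p_adj,
                    "note": t.note,
                }
                for t in self.tests
            ]
        )

    @property
    def p_adj(self) -> np.ndarray:
        return np.array([t.p_adj for t in self.tests])


def _normality_ok(x: np.ndarray) -> bool:
    """Lilliefors-corrected KS normality check at ALPHA_ASSUMPTION.

    Samples too small for the test (n < 4) are conservatively treated as
    non-normal, routing the comparison to the rank test.
    """
    if x.size < 4 or np.ptp(x) == 0:
        return False
    _, p = lilliefors(x, dist="norm")
    return p >= ALPHA_ASSUMPTION


def _welch_df(x: np.ndarray, y: np.ndarray) -> float:
    vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    return (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))


def compare_two_samples(x: np.ndarray, y: np.ndarray) -> dict:
    """Assumption-gated two-sample comparison of responders (x) vs non (y)."""
    normal = _normality_ok(x) and _normality_ok(y)
    if not normal:
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        return {
            "normality_ok": False,
            "variance_equal": None,
            "test_used": "mann-whitney",
            "statistic": float(stat),
            "df": None,
            "p_raw": float(p),
        }
    _, p_lev = stats.levene(x, y, center="mean")
    equal_var = p_lev >= ALPHA_ASSUMPTION
    stat, p = stats.ttest_ind(x, y, equal_var=equal_var)
    df = x.size + y.size - 2 if equal_var else _welch_df(x, y)
    return {
        "normality_ok": True,
        "variance_equal": bool(equal_var),
        "test_used": "pooled-t" if equal_var else "welch-t",
        "statistic": float(stat),
        "df": float(df),
        "p_raw": float(p),
    }


def compare_groups(
    changes: ChangeRateTable,
    labels: Mapping[str, bool] | Sequence[bool],
    band: str,
) -> GroupComparisonResult:
    """Channel-wise group comparison of one band's change rates, BH-adjusted.

    The FDR family is the set of valid channels within this band.  Channels
    where every change rate is invalid or where both groups are constant are
    excluded from testing (and from the family), with a note.
    """
    if isinstance(labels, Mapping):
        missing = [s for s in changes.subjects if s not in labels]
        if missing:
            raise DataValidationError(f"labels missing for subjects {missing}")
        is_resp = np.array([labels[s] for s in changes.subjects], dtype=bool)
    else:
        is_resp = np.asarray(labels, dtype=bool)
        if is_resp.size != len(changes.subjects):
            raise DataValidationError("labels length does not match subjects")
    values, valid = changes.get_band(band)

    result = GroupComparisonResult(band=band)
    testable: list[ChannelTest] = []
    for c, channel in enumerate(changes.channels):
        ok = valid[:, c]
        x = values[is_resp & ok, c]
        y = values[~is_resp & ok, c]
        t = ChannelTest(channel=channel, n_resp=x.size, n_nonresp=y.size, valid=True)
        if x.size < 2 or y.size < 2:
            raise DataValidationError(
                f"channel {channel}: fewer than 2 valid subjects in a group"
            )
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            t.valid = False
            t.note = "degenerate: zero variance in both groups"
            logger.warning("band %s channel %s excluded: %s", band, channel, t.note)
        else:
            res = compare_two_samples(x, y)
            for k, v in res.items():
                setattr(t, k, v)
            testable.append(t)
        result.tests.append(t)

    if testable:
        adj = fdr_adjust([t.p_raw for t in testable])
        for t, a in zip(testable, adj):
            t.p_adj = float(a)
    return result


def compare_all_bands(
    changes: ChangeRateTable, labels
) -> dict[str, GroupComparisonResult]:
    return {band: compare_groups(changes, labels, band) for band in changes.bands}
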