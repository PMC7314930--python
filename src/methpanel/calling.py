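"""Replicate scoring rules for the two-marker methylation panel.

Each marker is assayed in three replicate PCR wells.  A marker is scored
with a *k-of-3 algorithm*: the sample is marker-positive when at least
``k`` of the three wells detect the target, where a well "detects" when
its Ct is strictly below the marker's detection limit (45.0 cycles for
mSEPT9, 50.0 for mSDC2).  A rule may additionally require the mean Ct of
the detected wells to fall strictly below a cut-off; the operative stool
rule tightens mSEPT9 this way.

The panel decision is the OR of the two marker calls.  The operative
cut-off, fixed on the training cohort, is::

    mSEPT9 3/3 with mean Ct < 38   OR   mSDC2 2/3

For ROC analysis each marker contributes a continuous *censored score*:
the mean Ct of detected wells, or 50.0 (the maximal cycle number) when no
well detected — lower scores mean more methylated DNA, i.e. more evidence
of disease.  The panel score is the minimum of the two marker scores, the
continuous analogue of the OR rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .cohort import (
    CALL_COLUMNS,
    CT_MAX,
    DEFAULT_ACTB_LIMIT,
    Cohort,
    ValidityStatus,
    validate_sample,
)

__all__ = [
    "SEPT9_DETECTION_LIMIT",
    "SDC2_DETECTION_LIMIT",
    "MarkerRule",
    "PanelRule",
    "PanelCall",
    "DEFAULT_PANEL_RULE",
    "replicate_detections",
    "mean_ct",
    "call_marker",
    "call_panel",
    "call_cohort",
    "censored_score",
    "censored_scores",
]

SEPT9_DETECTION_LIMIT = 45.0
SDC2_DETECTION_LIMIT = 50.0
_DEFAULT_LIMITS = {"sept9": SEPT9_DETECTION_LIMIT, "sdc2": SDC2_DETECTION_LIMIT}


@dataclass(frozen=True)
class MarkerRule:
    """A k-of-3 scoring algorithm for one marker.

    Parameters
    ----------
    marker
        ``"sept9"`` or ``"sdc2"``.
    k_of_n
        Number of replicate wells (out of 3) that must detect the target.
    detection_limit
        Ct strictly below this counts as detected (cycles).
    mean_ct_cutoff
        Optional extra requirement: mean Ct of detected wells strictly
        below this value.
    """

    marker: Literal["sept9", "sdc2"]
    k_of_n: int
    detection_limit: float | None = None
    mean_ct_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.marker not in _DEFAULT_LIMITS:
            raise ValueError(f"unknown marker {self.marker!r}")
        if self.detection_limit is None:
            object.__setattr__(self, "detection_limit", _DEFAULT_LIMITS[self.marker])
        if not 1 <= self.k_of_n <= 3:
            raise ValueError("k_of_n must be 1, 2 or 3")
        if not 0 < self.detection_limit <= CT_MAX:
            raise ValueError(f"detection_limit outside (0, {CT_MAX}]")
        if self.mean_ct_cutoff is not None and self.mean_ct_cutoff > self.detection_limit:
            raise ValueError("mean_ct_cutoff cannot exceed the detection limit")

    @property
    def label(self) -> str:
        base = f"{self.k_of_n}/3"
        if self.mean_ct_cutoff is not None:
            return f"{base} and mean Ct <{self.mean_ct_cutoff:g}"
        return base


@dataclass(frozen=True)
class PanelRule:
    """OR-combination of one rule per marker."""

    sept9: MarkerRule
    sdc2: MarkerRule

    def __post_init__(self) -> None:
        if self.sept9.marker != "sept9" or self.sdc2.marker != "sdc2":
            raise ValueError("PanelRule needs one sept9 rule and one sdc2 rule")

    @property
    def label(self) -> str:
        return f"mSEPT9 {self.sept9.label} OR mSDC2 {self.sdc2.label}"


#: The operative stool cut-off fixed on the training cohort.
DEFAULT_PANEL_RULE = PanelRule(
    sept9=MarkerRule("sept9", k_of_n=3, mean_ct_cutoff=38.0),
    sdc2=MarkerRule("sdc2", k_of_n=2),
)


@dataclass(frozen=True)
class PanelCall:
    """Per-sample call under a panel rule.

    Marker and panel calls are ``None`` when the sample is invalid — an
    invalid sample carries no diagnostic information and is excluded from
    every downstream numerator and denominator.
    """

    validity: ValidityStatus
    sept9_positive: bool | None
    sdc2_positive: bool | None
    panel_positive: bool | None
    sept9_mean_ct: float
    sdc2_mean_ct: float


def replicate_detections(cts: Iterable[float], detection_limit: float) -> int:
    """Count replicate wells with Ct strictly below ``detection_limit``."""
    values = np.asarray(list(cts), dtype=float)
    if values.shape != (3,):
        raise ValueError("expected exactly 3 replicate Ct slots")
    return int(np.nansum(values < detection_limit))


def mean_ct(cts: Iterable[float], detection_limit: float) -> float:
    """Arithmetic mean Ct over detected replicates; NaN when none detected."""
    values = np.asarray(list(cts), dtype=float)
    if values.shape != (3,):
        raise ValueError("expected exactly 3 replicate Ct slots")
    detected = values[np.less(values, detection_limit, where=~np.isnan(values),
                              out=np.zeros(3, bool))]
    if detected.size == 0:
        return math.nan
    return float(detected.mean())


def call_marker(cts: Iterable[float], rule: MarkerRule) -> bool:
    """Apply one marker rule to a Ct triplicate."""
    cts = list(cts)
    if replicate_detections(cts, rule.detection_limit) < rule.k_of_n:
        return False
    if rule.mean_ct_cutoff is not None:
        m = mean_ct(cts, rule.detection_limit)
        if not m < rule.mean_ct_cutoff:
            return False
    return True


def _record_cts(record: pd.Series, target: str) -> list[float]:
    return [float(record[f"{target}_ct_{i}"]) for i in (1, 2, 3)]


def call_panel(
    record: pd.Series,
    rule: PanelRule = DEFAULT_PANEL_RULE,
    actb_limit: float = DEFAULT_ACTB_LIMIT,
    actb_aggregation: str = "min",
) -> PanelCall:
    """Call one sample: validity first, then each marker, then their OR."""
    validity = validate_sample(_record_cts(record, "actb"), actb_limit,
                               actb_aggregation)
    sept9_cts = _record_cts(record, "sept9")
    sdc2_cts = _record_cts(record, "sdc2")
    m9 = mean_ct(sept9_cts, rule.sept9.detection_limit)
    m2 = mean_ct(sdc2_cts, rule.sdc2.detection_limit)
    if not validity.valid:
        return PanelCall(validity, None, None, None, m9, m2)
    s9 = call_marker(sept9_cts, rule.sept9)
    s2 = call_marker(sdc2_cts, rule.sdc2)
    return PanelCall(validity, s9, s2, s9 or s2, m9, m2)


def _detections_matrix(cts: np.ndarray, limit: float) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.nansum(cts < limit, axis=1).astype(int)


def _mean_ct_matrix(cts: np.ndarray, limit: float) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        det = np.where(np.nan_to_num(cts, nan=np.inf) < limit, cts, np.nan)
        k = (~np.isnan(det)).sum(axis=1)
        s = np.nansum(det, axis=1)
    return np.where(k > 0, s / np.maximum(k, 1), np.nan)


def _marker_calls_matrix(cts: np.ndarray, rule: MarkerRule) -> np.ndarray:
    k = _detections_matrix(cts, rule.detection_limit)
    calls = k >= rule.k_of_n
    if rule.mean_ct_cutoff is not None:
        m = _mean_ct_matrix(cts, rule.detection_limit)
        calls &= np.nan_to_num(m, nan=np.inf) < rule.mean_ct_cutoff
    return calls


def call_cohort(
    cohort: Cohort,
    rule: PanelRule = DEFAULT_PANEL_RULE,
    actb_limit: float = DEFAULT_ACTB_LIMIT,
    actb_aggregation: str = "min",
) -> pd.DataFrame:
    """Vectorised panel calls for a whole cohort.

    Returns a frame with one row per sample: the :data:`~methpanel.cohort.CALL_COLUMNS`
    plus ``group`` and ``stage`` for downstream summaries.  Call columns are
    nullable booleans; they are ``NA`` for invalid samples.
    """
    actb = cohort.ct_matrix("actb")
    sept9 = cohort.ct_matrix("sept9")
    sdc2 = cohort.ct_matrix("sdc2")

    if actb_aggregation == "min":
        agg = np.nanmin
    elif actb_aggregation == "mean":
        agg = np.nanmean
    elif actb_aggregation == "all":
        agg = np.nanmax
    else:
        raise ValueError(f"unknown ACTB aggregation {actb_aggregation!r}")
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN ACTB rows
        summary = agg(actb, axis=1)
    valid = np.nan_to_num(summary, nan=np.inf) <= actb_limit

    s9 = _marker_calls_matrix(sept9, rule.sept9)
    s2 = _marker_calls_matrix(sdc2, rule.sdc2)
    panel = s9 | s2

    frame = pd.DataFrame({
        "sample_id": cohort.frame["sample_id"],
        "group": cohort.frame["group"],
        "stage": cohort.frame["stage"],
        "valid": valid,
        "sept9_call": pd.array(np.where(valid, s9, None), dtype="boolean"),
        "sdc2_call": pd.array(np.where(valid, s2, None), dtype="boolean"),
        "panel_call": pd.array(np.where(valid, panel, None), dtype="boolean"),
        "sept9_mean_ct": _mean_ct_matrix(sept9, rule.sept9.detection_limit),
        "sdc2_mean_ct": _mean_ct_matrix(sdc2, rule.sdc2.detection_limit),
    })
    return frame


def censored_score(
    record: pd.Series,
    target: Literal["sept9", "sdc2", "panel"] = "panel",
    combine: Literal["min", "mean"] = "min",
) -> float:
    """Censored continuous score for ROC analysis of one valid sample.

    Per-marker score: mean Ct of detected replicates, or ``CT_MAX`` (50.0)
    when nothing amplified.  The panel score combines the two marker scores
    with ``min`` (default; the continuous analogue of the OR call) or
    ``mean``.
    """
    scores = {}
    for marker in ("sept9", "sdc2"):
        m = mean_ct(_record_cts(record, marker), _DEFAULT_LIMITS[marker])
        scores[marker] = CT_MAX if math.isnan(m) else m
    if target in scores:
        return scores[target]
    if target != "panel":
        raise ValueError(f"unknown score target {target!r}")
    if combine == "min":
        return min(scores.values())
    if combine == "mean":
        return (scores["sept9"] + scores["sdc2"]) / 2.0
    raise ValueError(f"unknown combine {combine!r}")


def censored_scores(
    cohort: Cohort,
    target: Literal["sept9", "sdc2", "panel"] = "panel",
    combine: Literal["min", "mean"] = "min",
) -> pd.Series:
    """Vectorised :func:`censored_score` over a cohort (all samples)."""
    per_marker = {}
    for marker in ("sept9", "sdc2"):
        m = _mean_ct_matrix(cohort.ct_matrix(marker), _DEFAULT_LIMITS[marker])
        per_marker[marker] = np.where(np.isnan(m), CT_MAX, m)
    if target in per_marker:
        values = per_marker[target]
    elif combine == "min":
        values = np.minimum(per_marker["sept9"], per_marker["sdc2"])
    else:
        values = (per_marker["sept9"] + per_marker["sdc2"]) / 2.0
    return pd.Series(values, index=cohort.frame.index, name=f"{target}_score")
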