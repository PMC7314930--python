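"""Cohort data model and table I/O for a triplicate multiplex qPCR panel.

A cohort is a table of subjects, one row per stool sample, carrying the
triplicate cycle-threshold (Ct) values of three qPCR targets — the *ACTB*
internal amplification control, methylated *SEPT9* (mSEPT9) and methylated
*SDC2* (mSDC2) — together with clinical covariates (diagnostic group,
tumor stage, age, sex, tumor location and size).

Ct values are real cycle numbers in ``(0, 50]``; 50 is the maximal number
of PCR cycles run by the assay.  A well that never crossed the fluorescence
threshold has *no* Ct; in the CSV schema this is an empty cell and in
memory it is ``NaN``.  Empty cells are reserved for non-amplified wells —
missing covariates use explicit ``unknown``/``NA`` tokens instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "STAGES",
    "SEXES",
    "LOCATIONS",
    "MARKERS",
    "CT_MAX",
    "DEFAULT_ACTB_LIMIT",
    "CT_COLUMNS",
    "SCHEMA_COLUMNS",
    "CALL_COLUMNS",
    "CohortSchemaError",
    "ValidityStatus",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "validate_sample",
    "write_calls",
    "read_calls",
]

GROUPS = ("control", "AA", "CRC")
STAGES = ("0", "I", "II", "III", "IV", "unknown", "NA")
SEXES = ("male", "female", "unknown")
LOCATIONS = ("proximal", "distal", "unknown")
MARKERS = ("sept9", "sdc2")

#: Maximal number of PCR cycles; no Ct value can exceed it.
CT_MAX = 50.0
#: A sample is invalid when its ACTB Ct is greater than this (strictly).
DEFAULT_ACTB_LIMIT = 41.0

CT_COLUMNS = tuple(
    f"{target}_ct_{i}" for target in ("actb", "sept9", "sdc2") for i in (1, 2, 3)
)
COVARIATE_COLUMNS = (
    "sample_id", "group", "stage", "age", "sex", "location", "tumor_size_cm",
)
SCHEMA_COLUMNS = COVARIATE_COLUMNS + CT_COLUMNS

CALL_COLUMNS = (
    "sample_id", "valid", "sept9_call", "sdc2_call", "panel_call",
    "sept9_mean_ct", "sdc2_mean_ct",
)

ActbAggregation = Literal["min", "mean", "all"]


class CohortSchemaError(ValueError):
    """The cohort table violates the documented schema."""


@dataclass(frozen=True)
class ValidityStatus:
    """Outcome of the internal-control validity check for one sample."""

    valid: bool
    reason: str = ""

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.valid


def _aggregate_actb(cts: Iterable[float], how: ActbAggregation) -> float:
    """Reduce a triplicate of ACTB Cts to the single value the validity
    rule is applied to.  Non-amplified wells (NaN) are ignored; if no well
    amplified the result is NaN."""
    values = np.asarray(list(cts), dtype=float)
    detected = values[~np.isnan(values)]
    if detected.size == 0:
        return math.nan
    if how == "min":
        return float(detected.min())
    if how == "mean":
        return float(detected.mean())
    if how == "all":
        return float(detected.max())
    raise ValueError(f"unknown ACTB aggregation {how!r}")


def validate_sample(
    actb_cts: Iterable[float],
    actb_limit: float = DEFAULT_ACTB_LIMIT,
    aggregation: ActbAggregation = "min",
) -> ValidityStatus:
    """Apply the internal-control validity rule to one sample.

    The sample is invalid when the aggregated ACTB Ct is greater than
    ``actb_limit`` (strictly — a Ct equal to the limit passes), or when no
    ACTB well amplified at all.  The internal control exists to prove that
    amplifiable DNA survived collection and processing, so the default
    aggregation is ``min``: one passing replicate suffices.

    Parameters
    ----------
    actb_cts
        The three ACTB replicate Cts; ``NaN`` for wells that did not amplify.
    actb_limit
        Validity threshold in cycles, strictly ``> 0``.
    aggregation
        ``min`` (default), ``mean`` over detected replicates, or ``all``
        (every detected replicate must pass, i.e. the max is compared).
    """
    if not actb_limit > 0:
        raise ValueError("actb_limit must be positive")
    summary = _aggregate_actb(actb_cts, aggregation)
    if math.isnan(summary):
        return ValidityStatus(False, "no ACTB replicate amplified")
    if summary > actb_limit:
        return ValidityStatus(
            False, f"ACTB Ct ({aggregation}) {summary:.2f} > {actb_limit:.1f}"
        )
    return ValidityStatus(True, f"ACTB Ct ({aggregation}) {summary:.2f} <= {actb_limit:.1f}")


@dataclass
class Cohort:
    """An ordered collection of samples backed by a :class:`pandas.DataFrame`.

    The frame carries one row per sample with the columns of
    :data:`SCHEMA_COLUMNS`.  Construction validates the schema: unique
    sample ids, enumerated covariates, Ct values inside ``(0, 50]`` and the
    stage/group consistency rule (stage is ``NA`` exactly for non-CRC
    subjects).
    """

    frame: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        self.frame = _normalise_frame(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        a = self.frame.reset_index(drop=True)
        b = other.frame.reset_index(drop=True)
        if a.shape != b.shape:
            return False
        try:
            pd.testing.assert_frame_equal(a, b, check_exact=False, rtol=0, atol=1e-9)
        except AssertionError:
            return False
        return True

    def records(self) -> Iterator[pd.Series]:
        """Iterate over samples in row order."""
        for _, row in self.frame.iterrows():
            yield row

    def group_counts(self) -> dict[str, int]:
        counts = self.frame["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS}

    def subset(self, group: str) -> "Cohort":
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return Cohort(self.frame[self.frame["group"] == group].reset_index(drop=True),
                      label=f"{self.label}:{group}" if self.label else group)

    def ct_matrix(self, target: str) -> np.ndarray:
        """(n, 3) float matrix of replicate Cts for ``actb``/``sept9``/``sdc2``."""
        cols = [f"{target}_ct_{i}" for i in (1, 2, 3)]
        return self.frame[cols].to_numpy(dtype=float)


def _normalise_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SCHEMA_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    frame = frame.loc[:, list(SCHEMA_COLUMNS)].copy().reset_index(drop=True)

    frame["sample_id"] = frame["sample_id"].astype(str)
    dup = frame["sample_id"][frame["sample_id"].duplicated()]
    if not dup.empty:
        raise CohortSchemaError(f"duplicate sample_id: {dup.iloc[0]!r}")

    for col, allowed in (("group", GROUPS), ("stage", STAGES),
                         ("sex", SEXES), ("location", LOCATIONS)):
        frame[col] = frame[col].astype(str).str.strip()
        bad = frame.loc[~frame[col].isin(allowed), col]
        if not bad.empty:
            raise CohortSchemaError(
                f"row {bad.index[0] + 1}: {col} value {bad.iloc[0]!r} not in {allowed}"
            )

    bad_stage = frame[(frame["group"] != "CRC") != (frame["stage"] == "NA")]
    if not bad_stage.empty:
        i = bad_stage.index[0]
        raise CohortSchemaError(
            f"row {i + 1}: stage must be 'NA' exactly when group is not CRC "
            f"(group={frame.at[i, 'group']!r}, stage={frame.at[i, 'stage']!r})"
        )

    frame["age"] = pd.to_numeric(frame["age"], errors="raise").astype(int)
    frame["tumor_size_cm"] = pd.to_numeric(frame["tumor_size_cm"], errors="coerce")
    neg = frame["tumor_size_cm"] < 0
    if neg.any():
        raise CohortSchemaError(f"row {neg.idxmax() + 1}: negative tumor_size_cm")

    for col in CT_COLUMNS:
        frame[col] = pd.to_numeric(frame[col], errors="raise").astype(float)
        values = frame[col]
        bad = values.notna() & ~((values > 0) & (values <= CT_MAX))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise CohortSchemaError(
                f"row {i + 1}: {col}={values.iloc[i]} outside (0, {CT_MAX}]"
            )
    return frame


def read_cohort(path: str | Path, label: str | None = None) -> Cohort:
    """Read a cohort CSV (UTF-8, comma separated, header required).

    Empty Ct cells mean "no amplification" and become ``NaN``.  Row order
    is preserved; every data row yields exactly one sample or an error is
    raised — rows are never silently dropped.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except pd.errors.EmptyDataError as exc:
        raise CohortSchemaError(f"{path}: no header row") from exc
    frame = frame.replace({"": None})
    # covariate unknowns must be explicit tokens; empty covariate cells are
    # schema violations surfaced by _normalise_frame's enum check, except for
    # tumor_size_cm where empty means unknown size.
    n_rows = len(frame)
    cohort = Cohort(frame, label=label if label is not None else path.stem)
    assert len(cohort) == n_rows
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write the cohort back to CSV; ``read_cohort`` round-trips exactly."""
    path = Path(path)
    frame = cohort.frame.copy()
    frame.to_csv(path, index=False)
    return path


def write_calls(cohort: Cohort, calls: pd.DataFrame, path: str | Path) -> Path:
    """Write per-sample panel calls aligned to ``cohort``.

    ``calls`` must have one row per cohort record (same order, matching
    ``sample_id``); a count or id mismatch raises ``ValueError``.
    """
    if len(calls) != len(cohort):
        raise ValueError(
            f"call/record count mismatch: {len(calls)} calls for {len(cohort)} records"
        )
    if not (calls["sample_id"].to_numpy() == cohort.frame["sample_id"].to_numpy()).all():
        raise ValueError("calls are not aligned with the cohort (sample_id mismatch)")
    out = calls.loc[:, list(CALL_COLUMNS)].copy()
    out.to_csv(path, index=False)
    return Path(path)


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a calls CSV written by :func:`write_calls`."""
    frame = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in CALL_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"calls file missing column(s): {', '.join(missing)}")
    for col in ("valid", "sept9_call", "sdc2_call", "panel_call"):
        frame[col] = frame[col].astype("boolean")
    return frame
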