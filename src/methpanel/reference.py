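"""Reference operating characteristics of the stool ColoDefense panel.

The stool ColoDefense assay (a multiplex qPCR test for methylated *SEPT9*
and *SDC2* with an *ACTB* control) was developed on a training cohort of
126 subjects (65 colonoscopy-negative controls, 6 advanced adenomas, 55
CRC) and confirmed on an independent validation cohort of 104 subjects
(59 controls, 6 AA, 39 CRC).  This module records the reported group-wise
detection counts of that development work as fixed reference inputs:

* per-marker counts under the 1/3, 2/3 and 3/3 algorithms (step one of
  the cut-off search),
* counts under the operative cut-off (mSEPT9 3/3 with mean Ct < 38 OR
  mSDC2 2/3) per cohort, per stage, and pooled,
* deterministic *pattern tables* — per-sample replicate patterns that
  realise those counts exactly, used to rebuild "reference cohorts" whose
  summary statistics reproduce the reported figures to the printed digit.

The reported tables are not perfectly mutually consistent (a handful of
cells differ by one sample from any jointly realisable dataset); the
pattern tables reproduce all single-marker counts exactly and the
operative-rule row exactly, and match the remaining combination rows
wherever a realisable joint exists.

These numbers are *inputs*, used to calibrate the synthetic-cohort
generator and to exercise the pipeline; nothing in the package computes
from them silently.
"""

from __future__ import annotations

__all__ = [
    "SINGLE_MARKER_COUNTS",
    "OPERATIVE_COUNTS",
    "POOLED_COUNTS",
    "STAGE_COUNTS",
    "SUBGROUP_COUNTS",
    "TRAINING_PATTERNS",
    "VALIDATION_PATTERNS",
    "SEX_COUNTS",
    "AGE_RANGES",
]

# --- step-one single-marker counts: {cohort: {(marker, group): (n, k1, k2, k3)}}
# kX = number of samples with >= X of 3 replicates detected.
SINGLE_MARKER_COUNTS = {
    "training": {
        ("sept9", "AA"): (6, 6, 6, 5),
        ("sept9", "CRC"): (55, 54, 52, 47),
        ("sept9", "control"): (65, 35, 27, 15),
        ("sdc2", "AA"): (6, 3, 2, 2),
        ("sdc2", "CRC"): (55, 50, 46, 43),
        ("sdc2", "control"): (65, 17, 4, 0),
    },
}

# --- operative-rule counts: {cohort: {group: (n, positives)}}
OPERATIVE_COUNTS = {
    "training": {"control": (65, 6), "AA": (6, 4), "CRC": (55, 49)},
    "validation": {"control": (59, 4), "AA": (6, 4), "CRC": (39, 36)},
}

# --- pooled counts across both cohorts (as reported in the assay summary)
POOLED_COUNTS = {
    "AA": (12, 8),            # 66.7 %
    "CRC": (94, 85),          # 90.4 %
    "CRC_early": (44, 40),    # stages 0-II, 90.9 %
    "control": (124, 10),     # specificity 91.9 %
}

# --- per-stage operative-rule counts {cohort: {stage: (n, positives)}}
STAGE_COUNTS = {
    "training": {"0": (1, 1), "I": (11, 9), "II": (15, 15), "III": (18, 16),
                 "IV": (4, 3), "unknown": (6, 5)},
    "validation": {"I": (9, 8), "II": (8, 7), "III": (16, 15), "IV": (3, 3),
                   "unknown": (3, 3)},
}

# --- pooled CRC subgroup counts (n, positives) under the panel, with the
# per-marker counts kept for the comparison probes.
SUBGROUP_COUNTS = {
    "sex": {"male": (53, 48), "female": (41, 37)},
    "sex_sept9": {"male": (53, 46), "female": (41, 29)},
    "age": {"<60": (48, 45), ">=60": (46, 40)},
    "location": {"proximal": (46, 43), "distal": (41, 36), "unknown": (7, 6)},
    "size": {"<3": (11, 9), "3-6": (59, 54), ">6": (8, 8), "NA": (16, 14)},
}

# Sex counts (male, female) and age ranges (min, max) per cohort and group.
SEX_COUNTS = {
    "training": {"AA": (5, 1), "CRC": (32, 23), "control": (31, 34)},
    "validation": {"AA": (3, 3), "CRC": (21, 18), "control": (31, 28)},
}
AGE_RANGES = {
    "training": {"AA": (47, 75), "CRC": (35, 86), "control": (24, 69)},
    "validation": {"AA": (46, 67), "CRC": (27, 83), "control": (24, 83)},
}

# --- deterministic per-sample patterns -------------------------------------
#
# Each row: dict(group=..., n=..., sept9=(k_detected, band), sdc2=(k_detected,
# band), stages=[...optional, length n...]).  "band" picks the replicate Ct
# value and therefore the mean-Ct stratum of the sample:
#
#   sept9:  lo -> 33.0 (mean < 38)   b38 -> 38.4 ([38, 39))
#           b39 -> 39.4 ([39, 40))   b40 -> 41.0 ([40, 45))
#   sdc2:   case -> 36.0             ctrl -> 43.0
#
# The joint assignment was solved so that every single-marker count above is
# met exactly and the operative-rule row is met exactly in every group.

SEPT9_BANDS = {"lo": 33.0, "b38": 38.4, "b39": 39.4, "b40": 41.0}
SDC2_BANDS = {"case": 36.0, "ctrl": 43.0}

TRAINING_PATTERNS = [
    # controls: 65 samples
    dict(group="control", n=2, sept9=(3, "lo"), sdc2=(0, "ctrl")),
    dict(group="control", n=2, sept9=(3, "b38"), sdc2=(0, "ctrl")),
    dict(group="control", n=7, sept9=(3, "b39"), sdc2=(0, "ctrl")),
    dict(group="control", n=4, sept9=(3, "b40"), sdc2=(0, "ctrl")),
    dict(group="control", n=4, sept9=(2, "b40"), sdc2=(2, "ctrl")),
    dict(group="control", n=8, sept9=(2, "b40"), sdc2=(0, "ctrl")),
    dict(group="control", n=8, sept9=(1, "b40"), sdc2=(0, "ctrl")),
    dict(group="control", n=13, sept9=(0, "b40"), sdc2=(1, "ctrl")),
    dict(group="control", n=17, sept9=(0, "b40"), sdc2=(0, "ctrl")),
    # advanced adenomas: 6 samples
    dict(group="AA", n=1, sept9=(3, "lo"), sdc2=(0, "case")),
    dict(group="AA", n=1, sept9=(3, "lo"), sdc2=(1, "case")),
    dict(group="AA", n=1, sept9=(3, "b38"), sdc2=(3, "case")),
    dict(group="AA", n=1, sept9=(3, "b38"), sdc2=(0, "case")),
    dict(group="AA", n=1, sept9=(3, "b40"), sdc2=(3, "case")),
    dict(group="AA", n=1, sept9=(2, "b40"), sdc2=(0, "case")),
    # CRC: 55 samples
    dict(group="CRC", n=39, sept9=(3, "lo"), sdc2=(3, "case"),
         stages=["0"] + ["I"] * 7 + ["II"] * 13 + ["III"] * 13 + ["IV"] * 2
                + ["unknown"] * 3),
    dict(group="CRC", n=2, sept9=(3, "lo"), sdc2=(2, "case"), stages=["II", "II"]),
    dict(group="CRC", n=1, sept9=(3, "lo"), sdc2=(1, "case"), stages=["I"]),
    dict(group="CRC", n=2, sept9=(3, "lo"), sdc2=(0, "case"), stages=["I", "III"]),
    dict(group="CRC", n=1, sept9=(3, "b39"), sdc2=(0, "case"), stages=["I"]),
    dict(group="CRC", n=1, sept9=(3, "b40"), sdc2=(1, "case"), stages=["I"]),
    dict(group="CRC", n=1, sept9=(3, "b40"), sdc2=(0, "case"), stages=["III"]),
    dict(group="CRC", n=3, sept9=(2, "b40"), sdc2=(3, "case"),
         stages=["III", "III", "unknown"]),
    dict(group="CRC", n=1, sept9=(2, "b40"), sdc2=(2, "case"), stages=["IV"]),
    dict(group="CRC", n=1, sept9=(2, "b40"), sdc2=(1, "case"), stages=["III"]),
    dict(group="CRC", n=1, sept9=(1, "b40"), sdc2=(3, "case"), stages=["unknown"]),
    dict(group="CRC", n=1, sept9=(1, "b40"), sdc2=(1, "case"), stages=["IV"]),
    dict(group="CRC", n=1, sept9=(0, "b40"), sdc2=(0, "case"), stages=["unknown"]),
]

VALIDATION_PATTERNS = [
    # controls: 59 samples
    dict(group="control", n=2, sept9=(3, "lo"), sdc2=(0, "ctrl")),
    dict(group="control", n=2, sept9=(0, "b40"), sdc2=(2, "ctrl")),
    dict(group="control", n=55, sept9=(0, "b40"), sdc2=(0, "ctrl")),
    # advanced adenomas: 6 samples
    dict(group="AA", n=3, sept9=(3, "lo"), sdc2=(3, "case")),
    dict(group="AA", n=1, sept9=(0, "b40"), sdc2=(3, "case")),
    dict(group="AA", n=2, sept9=(0, "b40"), sdc2=(0, "case")),
    # CRC: 39 samples
    dict(group="CRC", n=30, sept9=(3, "lo"), sdc2=(3, "case"),
         stages=["I"] * 7 + ["II"] * 6 + ["III"] * 12 + ["IV"] * 3
                + ["unknown"] * 2),
    dict(group="CRC", n=2, sept9=(3, "lo"), sdc2=(0, "case"), stages=["I", "II"]),
    dict(group="CRC", n=4, sept9=(2, "b40"), sdc2=(3, "case"),
         stages=["III", "III", "III", "unknown"]),
    dict(group="CRC", n=3, sept9=(1, "b40"), sdc2=(0, "case"),
         stages=["I", "II", "III"]),
]

# CRC tumor location and size pools per cohort (assigned deterministically
# to CRC samples in row order; sums match the pooled subgroup table).
LOCATION_POOLS = {
    "training": ["proximal"] * 27 + ["distal"] * 24 + ["unknown"] * 4,
    "validation": ["proximal"] * 19 + ["distal"] * 17 + ["unknown"] * 3,
}
SIZE_POOLS = {
    "training": [2.0] * 6 + [4.5] * 35 + [7.0] * 5 + [float("nan")] * 9,
    "validation": [2.0] * 5 + [4.5] * 24 + [7.0] * 3 + [float("nan")] * 7,
}
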