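"""Report tables: per-stage rates, clinical subgroup comparisons, ROC exports.

All tables are pure functions of the per-sample calls, so re-running a
report on saved calls reproduces every cell.  Percentages are rounded
half-up to one decimal only at the formatting layer; computation stays at
full precision.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .calling import PanelRule, call_cohort, censored_scores
from .stats import compare_positivity, proportion_ci, roc_curve, round_half_up

__all__ = [
    "stage_table",
    "subgroup_table",
    "export_roc_points",
    "format_percent",
    "run_manifest",
]

STAGE_ORDER = ("0", "I", "II", "III", "IV", "unknown")
SIZE_BINS = ("<3 cm", "3-6 cm", ">6 cm", "NA")


def format_percent(x: float) -> str:
    return "" if np.isnan(x) else f"{round_half_up(100 * x, 1):.1f}"


def stage_table(calls: pd.DataFrame, confidence: float = 0.95) -> pd.DataFrame:
    """Positive detection rate per CRC stage (plus the control row).

    Samples with missing stage labels fall into the ``unknown`` bucket;
    nothing is dropped.  Stages absent from the cohort appear with n = 0
    and an undefined rate.
    """
    valid = calls[calls["valid"].fillna(False).astype(bool)]
    rows = []

    def add_row(label: str, sub: pd.DataFrame) -> None:
        n = len(sub)
        pos = int(sub["panel_call"].sum()) if n else 0
        rate = pos / n if n else float("nan")
        ci = proportion_ci(pos, n, confidence) if n else (float("nan"),) * 2
        rows.append({"stratum": label, "n": n, "positive": pos, "rate": rate,
                     "ci_low": ci[0], "ci_high": ci[1]})

    add_row("control", valid[valid["group"] == "control"])
    crc = valid[valid["group"] == "CRC"].copy()
    crc.loc[~crc["stage"].isin(STAGE_ORDER), "stage"] = "unknown"
    for stage in STAGE_ORDER:
        add_row(f"CRC stage {stage}", crc[crc["stage"] == stage])
    return pd.DataFrame(rows)


def _size_bin(size: float) -> str:
    # boundaries: [0, 3) / [3, 6] / (6, inf); unknown sizes go to NA
    if np.isnan(size):
        return "NA"
    if size < 3:
        return "<3 cm"
    if size <= 6:
        return "3-6 cm"
    return ">6 cm"


def subgroup_table(
    cohort: Cohort,
    calls: pd.DataFrame,
    call_column: str = "panel_call",
    method: str = "welch",
) -> pd.DataFrame:
    """CRC positivity by stage group, age group, sex, location and size.

    Stage is dichotomised as 0–II versus III–IV (unknown shown, excluded
    from the test); age as <60 versus >=60; size into [0,3), [3,6] and
    (6,inf) cm with unknown sizes in an NA bin.  Each factor's p-value
    compares the two primary levels' positivity indicators.
    """
    frame = cohort.frame.copy()
    frame["call"] = calls[call_column].to_numpy()
    frame["valid"] = calls["valid"].to_numpy()
    crc = frame[(frame["group"] == "CRC") & frame["valid"].astype(bool)].copy()

    crc["stage_group"] = np.select(
        [crc["stage"].isin(["0", "I", "II"]), crc["stage"].isin(["III", "IV"])],
        ["0-II", "III-IV"], default="NA")
    crc["age_group"] = np.where(crc["age"] < 60, "<60", ">=60")
    crc["size_bin"] = [_size_bin(s) for s in crc["tumor_size_cm"]]

    factors = {
        "stage": ("stage_group", ["0-II", "III-IV", "NA"]),
        "age": ("age_group", ["<60", ">=60"]),
        "sex": ("sex", ["male", "female"]),
        "location": ("location", ["proximal", "distal", "unknown"]),
        "size": ("size_bin", list(SIZE_BINS)),
    }
    rows = []
    for factor, (col, levels) in factors.items():
        arms = {}
        for level in levels:
            sub = crc[crc[col] == level]
            n = len(sub)
            pos = int(sub["call"].sum()) if n else 0
            arms[level] = sub["call"].astype(bool).to_numpy()
            rows.append({"factor": factor, "level": level, "n": n,
                         "positive": pos,
                         "rate": pos / n if n else float("nan"),
                         "p_value": float("nan")})
        a, b = arms[levels[0]], arms[levels[1]]
        if len(a) >= 2 and len(b) >= 2:
            p = compare_positivity(a, b, method=method)
            rows[-len(levels)]["p_value"] = p
    return pd.DataFrame(rows)


def export_roc_points(cohort: Cohort, calls: pd.DataFrame, out_dir: str | Path,
                      case_group: str = "CRC") -> dict[str, Path]:
    """Write censored-Ct ROC point files for each marker and the panel."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    keep = calls["valid"].fillna(False).astype(bool).to_numpy() & \
        cohort.frame["group"].isin(["control", case_group]).to_numpy()
    labels = (cohort.frame["group"].to_numpy() == case_group)[keep]
    paths = {}
    for target in ("sept9", "sdc2", "panel"):
        scores = censored_scores(cohort, target).to_numpy()[keep]
        curve = roc_curve(scores, labels)
        path = out_dir / f"roc_{target}.tsv"
        curve.to_frame().to_csv(path, sep="\t", index=False)
        paths[target] = path
    return paths


def run_manifest(config: dict, seed: int | None, out_dir: str | Path) -> Path:
    """Write a small JSON manifest (package version, config hash, seed)."""
    from . import __version__

    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package": "methpanel",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "config": config,
    }
    path = Path(out_dir) / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
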