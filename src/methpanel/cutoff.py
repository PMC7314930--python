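"""Two-step cut-off optimization over k-of-3 rule combinations.

Step one evaluates each marker alone under the 1/3, 2/3 and 3/3
algorithms.  Step two forms panel rules by combining an mSEPT9 arm — 3/3,
optionally tightened by a mean-Ct cut-off (none, <40, <39, <38) — with an
mSDC2 arm (2/3 or 3/3), evaluates every combination on the training
cohort, and ranks them.

Ranking is lexicographic over named keys; the default order is
``("youden_crc", "youden_aa", "specificity")``: CRC discrimination first,
then performance on advanced adenomas, then specificity as the tie-break.
The choice is configurable because "best balance" is not a single number;
``youden_all`` (both lesion classes pooled as cases) is also available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .cohort import DEFAULT_ACTB_LIMIT, Cohort, GROUPS
from .calling import MarkerRule, PanelRule, call_cohort, _marker_calls_matrix
from .stats import proportion_ci, youden

__all__ = [
    "GroupPerf",
    "PerfSummary",
    "RuleGrid",
    "GridResult",
    "evaluate_rule",
    "single_marker_table",
    "optimize",
    "DEFAULT_RANKING",
]

DEFAULT_RANKING = ("youden_crc", "youden_aa", "specificity")


class GroupMissingError(ValueError):
    """The cohort lacks valid samples in a required group."""


@dataclass(frozen=True)
class GroupPerf:
    """Positive detection in one diagnostic group under one rule."""

    n_valid: int
    n_positive: int
    ci: tuple[float, float]

    @property
    def rate(self) -> float:
        return self.n_positive / self.n_valid if self.n_valid else float("nan")


@dataclass(frozen=True)
class PerfSummary:
    """Group-wise performance of a panel rule on one cohort.

    ``youden_crc`` and ``youden_aa`` are the Youden indexes of the rule
    for detecting CRC and advanced adenomas (case rate minus control
    rate); ``youden_all`` pools both lesion classes as cases.
    """

    rule: PanelRule
    groups: dict[str, GroupPerf]
    confidence: float = 0.95

    @property
    def specificity(self) -> float:
        return 1.0 - self.groups["control"].rate

    @property
    def sensitivity_crc(self) -> float:
        return self.groups["CRC"].rate

    @property
    def sensitivity_aa(self) -> float:
        return self.groups["AA"].rate if self.groups["AA"].n_valid else float("nan")

    @property
    def youden_crc(self) -> float:
        return youden(self.sensitivity_crc, self.specificity)

    @property
    def youden_aa(self) -> float:
        if np.isnan(self.sensitivity_aa):
            return float("nan")
        return youden(self.sensitivity_aa, self.specificity)

    @property
    def youden_all(self) -> float:
        cases_n = self.groups["CRC"].n_valid + self.groups["AA"].n_valid
        cases_pos = self.groups["CRC"].n_positive + self.groups["AA"].n_positive
        return youden(cases_pos / cases_n, self.specificity)

    def ranking_value(self, key: str) -> float:
        values = {
            "youden_crc": self.youden_crc,
            "youden_aa": self.youden_aa,
            "youden_all": self.youden_all,
            "specificity": self.specificity,
            "sensitivity_crc": self.sensitivity_crc,
            "sensitivity_aa": self.sensitivity_aa,
        }
        try:
            v = values[key]
        except KeyError:
            raise ValueError(f"unknown ranking key {key!r}") from None
        return -np.inf if np.isnan(v) else v

    def as_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "sept9_rule": self.rule.sept9.label,
            "sdc2_rule": self.rule.sdc2.label,
        }
        for g in GROUPS:
            gp = self.groups[g]
            row[f"{g}_n"] = gp.n_valid
            row[f"{g}_positive"] = gp.n_positive
            row[f"{g}_rate"] = gp.rate
            row[f"{g}_ci_low"], row[f"{g}_ci_high"] = gp.ci
        row["specificity"] = self.specificity
        row["youden_crc"] = self.youden_crc
        row["youden_aa"] = self.youden_aa
        row["youden_all"] = self.youden_all
        return row


def _group_perf(calls: pd.DataFrame, group: str, confidence: float,
                ci_method: str) -> GroupPerf:
    sub = calls[(calls["group"] == group) & calls["valid"]]
    n = len(sub)
    pos = int(sub["panel_call"].sum()) if n else 0
    ci = proportion_ci(pos, n, confidence, ci_method) if n else (float("nan"),) * 2
    return GroupPerf(n_valid=n, n_positive=pos, ci=ci)


def evaluate_rule(
    cohort: Cohort,
    rule: PanelRule,
    actb_limit: float = DEFAULT_ACTB_LIMIT,
    confidence: float = 0.95,
    ci_method: str = "wilson_cc",
) -> PerfSummary:
    """Group-wise rates, CIs and Youden indexes of one panel rule.

    Invalid samples are excluded from numerators and denominators alike.
    Requires at least one valid control and one valid CRC sample; an empty
    AA group is reported as n = 0 with undefined rate.
    """
    calls = call_cohort(cohort, rule, actb_limit)
    groups = {g: _group_perf(calls, g, confidence, ci_method) for g in GROUPS}
    for required in ("control", "CRC"):
        if groups[required].n_valid == 0:
            raise GroupMissingError(f"no valid samples in group {required!r}")
    return PerfSummary(rule=rule, groups=groups, confidence=confidence)


def single_marker_table(
    cohort: Cohort,
    actb_limit: float = DEFAULT_ACTB_LIMIT,
    confidence: float = 0.95,
    ci_method: str = "wilson_cc",
) -> pd.DataFrame:
    """Step one: per-marker, per-algorithm positive detection rates.

    One row per (marker, k) with each group's count, rate and CI — the
    2 markers x 3 algorithms grid that motivates which arms enter the
    combination search.
    """
    rows = []
    valid_mask = call_cohort(cohort, actb_limit=actb_limit)["valid"].to_numpy()
    group_col = cohort.frame["group"].to_numpy()
    if not ((group_col == "control") & valid_mask).any():
        raise GroupMissingError("no valid samples in group 'control'")
    if not ((group_col == "CRC") & valid_mask).any():
        raise GroupMissingError("no valid samples in group 'CRC'")
    for marker in ("sept9", "sdc2"):
        cts = cohort.ct_matrix(marker)
        for k in (1, 2, 3):
            mrule = MarkerRule(marker, k_of_n=k)
            calls = _marker_calls_matrix(cts, mrule)
            row: dict[str, object] = {"marker": marker, "algorithm": f"{k}/3"}
            for g in GROUPS:
                mask = (group_col == g) & valid_mask
                n = int(mask.sum())
                pos = int(calls[mask].sum())
                row[f"{g}_n"] = n
                row[f"{g}_positive"] = pos
                row[f"{g}_rate"] = pos / n if n else float("nan")
                if n:
                    lo, hi = proportion_ci(pos, n, confidence, ci_method)
                else:
                    lo = hi = float("nan")
                row[f"{g}_ci_low"], row[f"{g}_ci_high"] = lo, hi
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RuleGrid:
    """Candidate rule combinations for the step-two search.

    Defaults mirror the operative search: mSEPT9 3/3 with mean-Ct
    requirement from {none, <40, <39, <38}, crossed with mSDC2 2/3 and
    3/3.  Mean-Ct cut-offs are listed loosest first.
    """

    sept9_k: tuple[int, ...] = (3,)
    sept9_mean_cutoffs: tuple[float | None, ...] = (None, 40.0, 39.0, 38.0)
    sdc2_k: tuple[int, ...] = (2, 3)
    sdc2_mean_cutoffs: tuple[float | None, ...] = (None,)

    def __post_init__(self) -> None:
        for name in ("sept9_k", "sdc2_k"):
            ks = getattr(self, name)
            if not ks or not all(k in (1, 2, 3) for k in ks):
                raise ValueError(f"{name} must be a non-empty subset of {{1,2,3}}")
        for name in ("sept9_mean_cutoffs", "sdc2_mean_cutoffs"):
            cuts = getattr(self, name)
            if not cuts:
                raise ValueError(f"{name} must be non-empty")
            finite = [c for c in cuts if c is not None]
            if finite != sorted(finite, reverse=True):
                raise ValueError(f"{name} must be sorted loosest (largest) first")

    def rules(self) -> Iterator[PanelRule]:
        for k9, c9, k2, c2 in itertools.product(
            self.sept9_k, self.sept9_mean_cutoffs, self.sdc2_k, self.sdc2_mean_cutoffs
        ):
            yield PanelRule(
                sept9=MarkerRule("sept9", k_of_n=k9, mean_ct_cutoff=c9),
                sdc2=MarkerRule("sdc2", k_of_n=k2, mean_ct_cutoff=c2),
            )

    def __len__(self) -> int:
        return (len(self.sept9_k) * len(self.sept9_mean_cutoffs)
                * len(self.sdc2_k) * len(self.sdc2_mean_cutoffs))


@dataclass
class GridResult:
    """Exhaustive evaluation of a rule grid plus the selected best rule."""

    summaries: list[PerfSummary]
    ranking: tuple[str, ...]
    best_index: int

    @property
    def best_rule(self) -> PanelRule:
        return self.summaries[self.best_index].rule

    @property
    def best_summary(self) -> PerfSummary:
        return self.summaries[self.best_index]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame([s.as_row() for s in self.summaries])
        frame["selected"] = [i == self.best_index for i in range(len(frame))]
        return frame


def optimize(
    cohort: Cohort,
    grid: RuleGrid | None = None,
    ranking: Sequence[str] = DEFAULT_RANKING,
    actb_limit: float = DEFAULT_ACTB_LIMIT,
    confidence: float = 0.95,
) -> GridResult:
    """Evaluate every rule in the grid and select the ranking maximiser.

    The ranking is lexicographic over the named keys; on exact ties in all
    keys the earliest rule in grid order (loosest mean-Ct first) wins.
    """
    grid = grid if grid is not None else RuleGrid()
    ranking = tuple(ranking)
    if not ranking:
        raise ValueError("ranking must name at least one key")
    summaries = [evaluate_rule(cohort, rule, actb_limit, confidence)
                 for rule in grid.rules()]
    keys = [tuple(s.ranking_value(k) for k in ranking) for s in summaries]
    best_index = int(max(range(len(keys)), key=lambda i: (keys[i], -i)))
    return GridResult(summaries=summaries, ranking=ranking, best_index=best_index)
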