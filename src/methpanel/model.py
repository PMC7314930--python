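"""Model/Results interface for fitting the panel cut-off on a cohort.

:class:`PanelCutoffModel` wraps a training cohort together with the
analysis configuration (ACTB validity limit, candidate rule grid, ranking
order, confidence level).  ``fit()`` runs the exhaustive grid search and
returns a :class:`PanelCutoffResults` carrying the full grid table, the
selected rule, its group-wise performance with confidence intervals, and
methods to score further cohorts with the *frozen* rule — the
training/validation discipline of a locked cut-off.

Example
-------
>>> from methpanel import PanelCutoffModel, simulate
>>> train = simulate.reference_cohort("training")
>>> res = PanelCutoffModel(train).fit()
>>> print(res.summary())            # doctest: +SKIP
>>> res.evaluate(simulate.reference_cohort("validation"))  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, DEFAULT_ACTB_LIMIT, read_cohort
from .calling import PanelRule, call_cohort, censored_scores
from .cutoff import (
    DEFAULT_RANKING,
    GridResult,
    PerfSummary,
    RuleGrid,
    evaluate_rule,
    optimize,
    single_marker_table,
)
from .stats import RocCurve, delong_auc_ci, roc_curve, round_half_up

__all__ = ["PanelCutoffModel", "PanelCutoffResults"]


class PanelCutoffModel:
    """Two-step cut-off optimization on a training cohort.

    Parameters
    ----------
    cohort
        Training data (a :class:`~methpanel.cohort.Cohort` or a raw
        DataFrame in the cohort schema).
    grid
        Candidate rules; defaults to the operative search grid.
    ranking
        Lexicographic ranking keys for selecting the best rule.
    actb_limit, confidence
        Validity threshold (cycles) and CI level.
    """

    def __init__(
        self,
        cohort: Cohort | pd.DataFrame,
        grid: RuleGrid | None = None,
        ranking: Sequence[str] = DEFAULT_RANKING,
        actb_limit: float = DEFAULT_ACTB_LIMIT,
        confidence: float = 0.95,
    ) -> None:
        self.cohort = cohort if isinstance(cohort, Cohort) else Cohort(cohort)
        self.grid = grid if grid is not None else RuleGrid()
        self.ranking = tuple(ranking)
        self.actb_limit = float(actb_limit)
        self.confidence = float(confidence)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "PanelCutoffModel":
        return cls(Cohort(frame), **kwargs)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "PanelCutoffModel":
        return cls(read_cohort(path), **kwargs)

    def single_marker_table(self) -> pd.DataFrame:
        """Step one: per-marker 1/3, 2/3, 3/3 performance on the training data."""
        return single_marker_table(self.cohort, self.actb_limit, self.confidence)

    def fit(self) -> "PanelCutoffResults":
        """Step two: exhaustive grid evaluation and rule selection."""
        grid_result = optimize(self.cohort, self.grid, self.ranking,
                               self.actb_limit, self.confidence)
        return PanelCutoffResults(self, grid_result)


@dataclass
class PanelCutoffResults:
    """Fitted cut-off: selected rule, grid table, and scoring methods."""

    model: PanelCutoffModel
    grid_result: GridResult

    @property
    def rule(self) -> PanelRule:
        return self.grid_result.best_rule

    @property
    def training_performance(self) -> PerfSummary:
        return self.grid_result.best_summary

    def grid_table(self) -> pd.DataFrame:
        return self.grid_result.to_frame()

    def evaluate(self, cohort: Cohort, rule: PanelRule | None = None) -> PerfSummary:
        """Score a cohort with the frozen rule (no re-fitting)."""
        return evaluate_rule(cohort, rule or self.rule,
                             self.model.actb_limit, self.model.confidence)

    def predict(self, cohort: Cohort | None = None) -> pd.DataFrame:
        """Per-sample calls under the frozen rule."""
        cohort = cohort if cohort is not None else self.model.cohort
        return call_cohort(cohort, self.rule, self.model.actb_limit)

    def roc(self, cohort: Cohort | None = None, target: str = "panel",
            case_group: str = "CRC") -> tuple[RocCurve, tuple[float, float]]:
        """Censored-Ct ROC of ``case_group`` vs controls, with DeLong CI."""
        cohort = cohort if cohort is not None else self.model.cohort
        calls = call_cohort(cohort, self.rule, self.model.actb_limit)
        keep = calls["valid"].to_numpy() & cohort.frame["group"].isin(
            ["control", case_group]).to_numpy()
        scores = censored_scores(cohort, target).to_numpy()[keep]
        labels = (cohort.frame["group"].to_numpy() == case_group)[keep]
        curve = roc_curve(scores, labels)
        _, ci = delong_auc_ci(scores, labels, self.model.confidence)
        return curve, ci

    def summary(self) -> str:
        """Readable report: selected rule and group-wise performance."""
        perf = self.training_performance
        lines = [
            "Panel cut-off optimization",
            "=" * 60,
            f"Training cohort: {self.model.cohort.label or '<unnamed>'} "
            f"(n={len(self.model.cohort)})",
            f"Grid size: {len(self.grid_result.summaries)} rule combinations",
            f"Ranking: {' > '.join(self.grid_result.ranking)}",
            "",
            f"Selected rule: {self.rule.label}",
            "",
            f"{'group':<10}{'n':>5}{'pos':>5}{'rate %':>9}"
            f"{'95% CI %':>17}{'Youden %':>10}",
            "-" * 60,
        ]
        for g in ("control", "AA", "CRC"):
            gp = perf.groups[g]
            rate = round_half_up(100 * gp.rate, 1)
            lo = round_half_up(100 * gp.ci[0], 1)
            hi = round_half_up(100 * gp.ci[1], 1)
            yi = {"control": float("nan"), "AA": perf.youden_aa,
                  "CRC": perf.youden_crc}[g]
            ystr = "" if np.isnan(yi) else f"{round_half_up(100 * yi, 1):.1f}"
            lines.append(f"{g:<10}{gp.n_valid:>5}{gp.n_positive:>5}{rate:>9.1f}"
                         f"{f'({lo:.1f}-{hi:.1f})':>17}{ystr:>10}")
        lines += [
            "-" * 60,
            f"Specificity: {round_half_up(100 * perf.specificity, 1):.1f} %",
        ]
        return "\n".join(lines)
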