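"""Model/Results interface over the bias-analysis engine.

:class:`LossToFollowUpBiasModel` binds a cohort table to a scenario;
``fit()`` runs the Monte Carlo simulation and returns a
:class:`BiasAnalysisResults` carrying the geometric-mean estimates, their
certainty intervals, per-trial diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortTable, crude_odds_ratio, wald_ci
from .engine import SimulationResult, run_simulation
from .scenarios import Scenario
from .summaries import SimulationSummary, summarize

__all__ = ["LossToFollowUpBiasModel", "BiasAnalysisResults"]


class LossToFollowUpBiasModel:
    """Probabilistic bias model for disease misclassification from losses.

    Parameters
    ----------
    table : CohortTable
        Exposure-stratified mortality counts plus the number lost to
        follow-up.
    scenario : Scenario
        Classification-parameter distributions for one bias scenario.
    exposed_label : str, optional
        Stratum contrasted against the reference; defaults to the last
        non-reference stratum.

    Examples
    --------
    >>> from ltfbias import LossToFollowUpBiasModel, builtin_table, builtin_scenarios
    >>> model = LossToFollowUpBiasModel(builtin_table(), builtin_scenarios()[0])
    >>> res = model.fit(seed=1)
    >>> round(res.or_observed, 2)
    3.05
    """

    def __init__(
        self,
        table: CohortTable,
        scenario: Scenario,
        exposed_label: str | None = None,
    ) -> None:
        if exposed_label is None:
            exposed_label = next(
                s.label for s in reversed(table.strata) if s.label != table.reference_label
            )
        scenario.validate_against(table, exposed_label)
        self.table = table
        self.scenario = scenario
        self.exposed_label = exposed_label

    @classmethod
    def from_counts(
        cls,
        strata: "CohortTable | list",
        n_lost: int,
        reference_label: str,
        scenario: Scenario,
        exposed_label: str | None = None,
    ) -> "LossToFollowUpBiasModel":
        """Build the model directly from stratum counts."""
        from .cohort import CohortTable as _CT

        table = _CT(tuple(strata), n_lost, reference_label)
        return cls(table, scenario, exposed_label)

    @property
    def or_observed(self) -> float:
        return crude_odds_ratio(self.table, self.exposed_label)

    def fit(
        self,
        n_trials: int | None = None,
        seed: int | None = None,
        level: float = 0.95,
    ) -> "BiasAnalysisResults":
        """Run the Monte Carlo simulation and summarize it."""
        result = run_simulation(
            self.scenario, self.table, self.exposed_label, n_trials=n_trials, seed=seed
        )
        return BiasAnalysisResults(self, result, level=level)


class BiasAnalysisResults:
    """Fitted results: estimates, certainty intervals and diagnostics."""

    def __init__(
        self, model: LossToFollowUpBiasModel, result: SimulationResult, level: float = 0.95
    ) -> None:
        self.model = model
        self.result = result
        self.level = level
        self._summary: SimulationSummary = summarize(result, level=level)

    # -- estimates ---------------------------------------------------------

    @property
    def or_observed(self) -> float:
        return self.result.or_observed

    @property
    def gm_or(self) -> float:
        """Geometric mean adjusted odds ratio."""
        return self._summary.gm_or

    @property
    def ci_or(self) -> tuple[float, float]:
        return self._summary.ci_or

    @property
    def gm_epsilon(self) -> float:
        """Geometric mean error factor (observed OR / adjusted OR)."""
        return self._summary.gm_epsilon

    @property
    def ci_epsilon(self) -> tuple[float, float]:
        return self._summary.ci_epsilon

    @property
    def simulation_summary(self) -> SimulationSummary:
        return self._summary

    def to_frame(self) -> pd.DataFrame:
        """Per-trial audit records."""
        return self.result.to_frame()

    def summary(self) -> str:
        """Human-readable summary table."""
        m = self.model
        lo, hi = wald_ci(m.table, m.exposed_label, 0.95)
        s = self._summary
        pct = int(round(self.level * 100))
        lines = [
            "Loss-to-Follow-Up Bias Analysis Results",
            "=" * 55,
            f"Scenario:             {s.scenario_name}",
            f"Exposed stratum:      {m.exposed_label}",
            f"Reference stratum:    {m.table.reference_label}",
            f"Trials:               {s.n_trials}   (seed {self.result.seed})",
            "-" * 55,
            f"Observed crude OR:    {self.or_observed:.2f}  "
            f"(95% Wald CI {lo:.2f}-{hi:.2f})",
            f"GM adjusted OR:       {s.gm_or:.2f}  "
            f"({pct}% certainty interval {s.ci_or[0]:.2f}-{s.ci_or[1]:.2f})",
            f"GM error factor:      {s.gm_epsilon:.2f}  "
            f"({pct}% certainty interval {s.ci_epsilon[0]:.2f}-{s.ci_epsilon[1]:.2f})",
            f"OR interval width:    {s.ci_width_or:.2f}",
            "=" * 55,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<BiasAnalysisResults scenario={self._summary.scenario_name!r} "
            f"gm_or={self.gm_or:.3f} gm_epsilon={self.gm_epsilon:.3f}>"
        )
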