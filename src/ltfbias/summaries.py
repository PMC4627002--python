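"""Summaries of a simulation: geometric means, certainty intervals, histograms.

The central-tendency summary for the ratio-scale outputs (adjusted odds
ratio and error factor) is the geometric mean; uncertainty is reported as
an empirical certainty interval — percentiles of the Monte Carlo
distribution, interpreted (under conditions) as an approximate Bayesian
posterior interval rather than a frequentist confidence interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .engine import SimulationResult

__all__ = [
    "geometric_mean",
    "certainty_interval",
    "interval_width",
    "SimulationSummary",
    "summarize",
    "summary_table",
]


def geometric_mean(values) -> float:
    """exp(mean(ln values)); requires a non-empty all-positive sample."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("geometric mean of an empty sample is undefined")
    bad = np.flatnonzero(~(x > 0))
    if bad.size:
        raise ValueError(
            f"geometric mean requires positive values; offending indices: "
            f"{bad[:10].tolist()}{'...' if bad.size > 10 else ''}"
        )
    return float(np.exp(np.mean(np.log(x))))


def certainty_interval(values, level: float = 0.95) -> tuple[float, float]:
    """Empirical percentile interval at the given coverage level.

    Quantiles use linear interpolation between order statistics; with tens
    of thousands of trials any standard convention differs negligibly, but
    the convention is pinned for reproducibility.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("certainty interval of an empty sample is undefined")
    if not 0 < level < 1:
        raise ValueError("level must lie strictly in (0, 1)")
    tail = (1 - level) / 2
    lo, hi = np.quantile(x, [tail, 1 - tail], method="linear")
    return float(lo), float(hi)


def interval_width(ci: tuple[float, float]) -> float:
    """Upper bound minus lower bound."""
    lo, hi = ci
    if lo > hi:
        raise ValueError(f"inverted interval ({lo}, {hi})")
    return hi - lo


@dataclass(frozen=True)
class SimulationSummary:
    """Scenario-level summary of the adjusted OR and error-factor samples."""

    scenario_name: str
    n_trials: int
    or_observed: float
    gm_or: float
    ci_or: tuple[float, float]
    gm_epsilon: float
    ci_epsilon: tuple[float, float]
    ci_width_or: float
    histogram_or: tuple[tuple[float, ...], tuple[int, ...]]  # (edges, counts)
    histogram_epsilon: tuple[tuple[float, ...], tuple[int, ...]]

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _histogram(x: np.ndarray, bins: int) -> tuple[tuple[float, ...], tuple[int, ...]]:
    counts, edges = np.histogram(x, bins=bins)
    return tuple(edges.tolist()), tuple(int(c) for c in counts)


def summarize(
    result: SimulationResult, level: float = 0.95, bins: int = 50
) -> SimulationSummary:
    """Reduce a simulation to its reported quantities."""
    if result.n_flagged:
        raise ValueError(
            f"{result.n_flagged} trials produced a non-positive adjusted cell; "
            "inspect result.flagged before summarizing"
        )
    gm_or = geometric_mean(result.or_adjusted)
    ci_or = certainty_interval(result.or_adjusted, level)
    return SimulationSummary(
        scenario_name=result.scenario_name,
        n_trials=len(result),
        or_observed=result.or_observed,
        gm_or=gm_or,
        ci_or=ci_or,
        gm_epsilon=geometric_mean(result.epsilon),
        ci_epsilon=certainty_interval(result.epsilon, level),
        ci_width_or=interval_width(ci_or),
        histogram_or=_histogram(result.or_adjusted, bins),
        histogram_epsilon=_histogram(result.epsilon, bins),
    )


def summary_table(summaries: list[SimulationSummary]) -> pd.DataFrame:
    """One row per scenario mirroring the result columns of a scenario table."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "scenario": s.scenario_name,
                "n_trials": s.n_trials,
                "gm_epsilon": s.gm_epsilon,
                "epsilon_ci_lower": s.ci_epsilon[0],
                "epsilon_ci_upper": s.ci_epsilon[1],
                "gm_or": s.gm_or,
                "or_ci_lower": s.ci_or[0],
                "or_ci_upper": s.ci_or[1],
                "or_ci_width": s.ci_width_or,
            }
        )
    return pd.DataFrame(rows)
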