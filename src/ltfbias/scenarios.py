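"""Bias-analysis scenarios and the four-stage misclassification sampling chain.

Each scenario describes how subjects lost to follow-up could have died of
the cause of interest without being counted as cases:

1. ``AD`` — total all-cause deaths among the lost, drawn from a truncated
   negative binomial on ``[0, n_lost]``.
2. ``ID`` — total cause-specific deaths, BetaPERT(0, p·AD, AD) where ``p``
   is the external cause-specific death proportion.
3. ``ID_never`` — the share allocated to the never-exposed (reference)
   stratum, BetaPERT(0, f·ID, ID); ``f`` is 3/4 under Differential A
   (never-exposed more likely misclassified as alive) and 1/4 under
   Differential B.
4. ``ID_high`` — the share of the remaining ever-exposed deaths allocated
   to the highest stratum, BetaPERT(0, ½·ID_ever, min(ID_ever, cap)) where
   the cap is the number of living non-cases in that stratum (only the
   living can have been misclassified).

A zero drawn at any stage forces every downstream value in that trial to
zero (zero-propagation); such trials are retained, never discarded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .cohort import CohortTable
from .distributions import PertSpec, TruncatedNegBinSpec, sample_pert_int, sample_trunc_negbin

__all__ = [
    "Differential",
    "differential_fraction",
    "Scenario",
    "TrialDraw",
    "draw_trial",
    "chain_likeliest",
]


class Differential(str, enum.Enum):
    """Direction of differential misclassification between strata."""

    A = "A"  # never-exposed more likely misclassified as alive
    B = "B"  # never-exposed less likely misclassified as alive


def differential_fraction(direction: Differential | str) -> float:
    """Never-exposed allocation fraction for a misclassification direction."""
    try:
        direction = Differential(direction)
    except ValueError:
        raise ValueError(
            f"unknown differential direction {direction!r}; expected 'A' or 'B'"
        ) from None
    return 0.75 if direction is Differential.A else 0.25


@dataclass(frozen=True)
class Scenario:
    """One bias-analysis scenario.

    Parameters
    ----------
    name : str
        Scenario identifier.
    allcause_spec : TruncatedNegBinSpec
        Law of the total all-cause deaths among the lost.
    cause_proportion : float
        External proportion of all-cause deaths due to the cause of
        interest, strictly in (0, 1).
    never_fraction : float
        PERT-mode fraction of total cause-specific deaths allocated to the
        reference stratum (3/4 or 1/4 for the two differential directions).
    high_fraction : float
        PERT-mode fraction of ever-exposed deaths allocated to the highest
        stratum.
    high_cap : int
        Living non-cases in the highest stratum; upper bound for ID_high.
    n_trials : int
        Monte Carlo trials per simulation.
    seed : int
        Default random seed for this scenario's stream.
    """

    name: str
    allcause_spec: TruncatedNegBinSpec
    cause_proportion: float
    never_fraction: float
    high_fraction: float
    high_cap: int
    n_trials: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        for fname in ("cause_proportion", "never_fraction", "high_fraction"):
            v = getattr(self, fname)
            if not 0 < v < 1:
                raise ValueError(f"{fname} must lie strictly in (0, 1), got {v}")
        if self.high_cap <= 0:
            raise ValueError("high_cap must be a positive integer")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be a positive integer")

    def validate_against(self, table: CohortTable, exposed_label: str) -> None:
        """Check the scenario is consistent with the table it is bound to."""
        if len(table.strata) < 3:
            raise ValueError("the three-way allocation chain needs >= 3 strata")
        if exposed_label == table.reference_label:
            raise ValueError("exposed stratum cannot be the reference stratum")
        if self.allcause_spec.upper > table.n_lost:
            raise ValueError(
                f"all-cause upper bound {self.allcause_spec.upper} exceeds the "
                f"number lost to follow-up ({table.n_lost})"
            )
        exposed = table.stratum(exposed_label)
        if self.high_cap > exposed.alive_noncases:
            raise ValueError(
                f"high_cap {self.high_cap} exceeds living non-cases "
                f"({exposed.alive_noncases}) of stratum {exposed_label!r}"
            )


@dataclass(frozen=True)
class TrialDraw:
    """One trial of the sampling chain (all counts among the lost)."""

    ad: int         # all-cause deaths
    id_total: int   # cause-specific deaths
    id_never: int   # allocated to the reference stratum
    id_ever: int    # id_total - id_never
    id_high: int    # allocated to the highest stratum
    id_middle: int  # residual; bookkeeping only, never enters the odds ratio

    def __post_init__(self) -> None:
        ok = (
            0 <= self.id_total <= self.ad
            and 0 <= self.id_never <= self.id_total
            and self.id_ever == self.id_total - self.id_never
            and 0 <= self.id_high <= self.id_ever
            and self.id_middle == self.id_ever - self.id_high
            and self.id_middle >= 0
        )
        if not ok:
            raise ValueError(f"inconsistent trial draw: {self}")


def draw_trial(
    scenario: Scenario, table: CohortTable, rng: np.random.Generator
) -> TrialDraw:
    """Execute one trial of the four-stage chain with zero-propagation."""
    ad = sample_trunc_negbin(scenario.allcause_spec, rng)
    if ad > table.n_lost:
        raise ValueError("all-cause deaths cannot exceed the number lost")
    if ad == 0:
        return TrialDraw(0, 0, 0, 0, 0, 0)
    id_total = sample_pert_int(
        PertSpec(0.0, scenario.cause_proportion * ad, float(ad)), rng
    )
    if id_total == 0:
        return TrialDraw(ad, 0, 0, 0, 0, 0)
    id_never = sample_pert_int(
        PertSpec(0.0, scenario.never_fraction * id_total, float(id_total)), rng
    )
    # the reference stratum's living non-cases exceed n_lost for the bundled
    # cohort, but cap defensively for foreign tables
    id_never = min(id_never, table.reference.alive_noncases)
    id_ever = id_total - id_never
    if id_ever == 0:
        return TrialDraw(ad, id_total, id_never, 0, 0, 0)
    hmax = min(id_ever, scenario.high_cap)
    hmode = min(scenario.high_fraction * id_ever, float(hmax))
    id_high = sample_pert_int(PertSpec(0.0, hmode, float(hmax)), rng)
    return TrialDraw(ad, id_total, id_never, id_ever, id_high, id_ever - id_high)


def chain_likeliest(scenario: Scenario, ad: int) -> dict[str, float]:
    """Likeliest values along the chain, conditional on ``ad`` all-cause deaths.

    Returns both the continuous PERT modes and the truncated integer counts
    a worked example would print: the cause-specific mode ``p·AD``, the
    never-exposed mode given the truncated cause-specific count, and the
    highest-stratum mode given the truncated never-exposed count.
    """
    id_mode = scenario.cause_proportion * ad
    id_count = int(np.trunc(id_mode))
    never_mode = scenario.never_fraction * id_count
    never_count = int(np.trunc(never_mode))
    id_ever = id_count - never_count
    high_mode = min(scenario.high_fraction * id_ever, float(min(id_ever, scenario.high_cap)))
    return {
        "id_total_mode": id_mode,
        "id_total": id_count,
        "id_never_mode": never_mode,
        "id_never": never_count,
        "id_ever": id_ever,
        "id_high_mode": high_mode,
        "id_high": int(np.trunc(high_mode)),
    }
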