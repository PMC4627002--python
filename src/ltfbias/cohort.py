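"""Exposure-stratified mortality tables and crude association measures.

A historical cohort mortality study tabulates, per exposure stratum, the
deaths from the cause of interest (cases) and the non-cases, the latter
split into subjects classified alive at study end and subjects who died of
other causes.  Subjects lost to follow-up are conventionally counted among
the "alive" non-cases — the misclassification this package quantifies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DegenerateTableError",
    "ExposureStratum",
    "CohortTable",
    "crude_odds",
    "crude_odds_ratio",
    "wald_ci",
    "mcbride_table",
]


class DegenerateTableError(ValueError):
    """A table cell required for an odds computation is zero."""


def _check_count(name: str, value: object) -> int:
    # bool is an int subclass; reject it along with floats
    if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
        raise TypeError(f"{name} must be an integer count, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")
    return int(value)


@dataclass(frozen=True)
class ExposureStratum:
    """Counts for one exposure level.

    Parameters
    ----------
    label : str
        Exposure-stratum name (e.g. a cumulative-exposure range).
    cases : int
        Deaths from the cause of interest.
    alive_noncases : int
        Non-cases classified alive at study end (includes anyone lost to
        follow-up, tabulated as alive by convention).
    deceased_other : int
        Non-cases who died of causes other than the cause of interest.
    """

    label: str
    cases: int
    alive_noncases: int
    deceased_other: int

    def __post_init__(self) -> None:
        for name in ("cases", "alive_noncases", "deceased_other"):
            object.__setattr__(self, name, _check_count(name, getattr(self, name)))

    @property
    def noncases(self) -> int:
        """Total non-cases: alive plus deceased of other causes."""
        return self.alive_noncases + self.deceased_other


@dataclass(frozen=True)
class CohortTable:
    """Ordered exposure strata plus the count lost to follow-up.

    The reference stratum is named explicitly rather than inferred from
    position.
    """

    strata: tuple[ExposureStratum, ...]
    n_lost: int
    reference_label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "strata", tuple(self.strata))
        object.__setattr__(self, "n_lost", _check_count("n_lost", self.n_lost))
        if len(self.strata) < 2:
            raise ValueError("a cohort table needs at least two strata")
        labels = [s.label for s in self.strata]
        if len(set(labels)) != len(labels):
            raise ValueError("stratum labels must be unique")
        if self.reference_label not in labels:
            raise ValueError(
                f"reference stratum {self.reference_label!r} not among {labels}"
            )

    def stratum(self, label: str) -> ExposureStratum:
        for s in self.strata:
            if s.label == label:
                return s
        raise KeyError(f"no stratum labelled {label!r}")

    @property
    def reference(self) -> ExposureStratum:
        return self.stratum(self.reference_label)

    # -- crude measures ----------------------------------------------------

    def crude_odds(self, label: str) -> float:
        return crude_odds(self, label)

    def crude_odds_ratio(self, exposed_label: str) -> float:
        return crude_odds_ratio(self, exposed_label)

    def wald_ci(self, exposed_label: str, level: float = 0.95) -> tuple[float, float]:
        return wald_ci(self, exposed_label, level)

    # -- serialization -----------------------------------------------------

    def to_tsv(self) -> str:
        """Serialize to the flat delimited format (see :func:`read_table`)."""
        buf = io.StringIO()
        buf.write(f"# n_lost={self.n_lost}\treference={self.reference_label}\n")
        buf.write("label\tcases\talive_noncases\tdeceased_other\n")
        for s in self.strata:
            buf.write(f"{s.label}\t{s.cases}\t{s.alive_noncases}\t{s.deceased_other}\n")
        return buf.getvalue()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_tsv())


def read_table(path_or_buffer) -> CohortTable:
    """Read a cohort table from the flat delimited text format.

    The first line is a metadata header ``# n_lost=<int>\treference=<label>``;
    subsequent lines are tab-separated ``label cases alive_noncases
    deceased_other`` rows under a column-header line.
    """
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#"):
        raise ValueError("missing metadata header line '# n_lost=... reference=...'")
    meta: dict[str, str] = {}
    for tok in lines[0].lstrip("#").split("\t"):
        key, _, val = tok.strip().partition("=")
        meta[key] = val
    n_lost = int(meta["n_lost"])
    reference = meta["reference"]
    strata = []
    for ln in lines[2:]:  # skip column header
        label, cases, alive, dead = ln.split("\t")
        strata.append(ExposureStratum(label, int(cases), int(alive), int(dead)))
    return CohortTable(tuple(strata), n_lost, reference)


def crude_odds(table: CohortTable, label: str) -> float:
    """Odds of the cause-specific death for one stratum: cases / non-cases."""
    s = table.stratum(label)
    if s.noncases == 0:
        raise DegenerateTableError(f"stratum {label!r} has zero non-cases")
    return s.cases / s.noncases


def crude_odds_ratio(table: CohortTable, exposed_label: str) -> float:
    """Crude odds ratio of the exposed stratum versus the reference stratum."""
    exp_s = table.stratum(exposed_label)
    ref_s = table.reference
    for s in (exp_s, ref_s):
        if s.cases == 0 or s.noncases == 0:
            raise DegenerateTableError(
                f"stratum {s.label!r} has a zero cell; odds ratio undefined"
            )
    return (exp_s.cases / exp_s.noncases) / (ref_s.cases / ref_s.noncases)


def wald_ci(
    table: CohortTable, exposed_label: str, level: float = 0.95
) -> tuple[float, float]:
    """Wald confidence interval for the crude odds ratio.

    Computed on the log scale: ``exp(ln OR ± z * sqrt(1/a + 1/b + 1/c + 1/d))``
    with ``z`` the two-sided normal quantile for ``level``.  No continuity
    correction.
    """
    if not 0 <= level < 1:
        raise ValueError("level must lie in [0, 1)")
    exp_s = table.stratum(exposed_label)
    ref_s = table.reference
    a, b = exp_s.cases, exp_s.noncases
    c, d = ref_s.cases, ref_s.noncases
    if min(a, b, c, d) == 0:
        raise DegenerateTableError("zero cell; Wald interval undefined")
    or_ = (a / b) / (c / d)
    z = stats.norm.ppf(0.5 + level / 2)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(or_ * np.exp(-z * se)), float(or_ * np.exp(z * se))


def mcbride_table() -> CohortTable:
    """The bundled trichlorophenol-cohort fixture.

    Ischemic-heart-disease deaths versus TCDD exposure in a New Zealand
    occupational cohort; 338 workers (~21%) were lost to follow-up.
    """
    from .config import builtin_table

    return builtin_table()
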