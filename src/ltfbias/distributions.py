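"""The two sampling laws of the bias chain.

*Truncated negative binomial* — all-cause deaths among the lost are drawn
from a negative binomial (number of failures before the ``shape``-th
success, success probability ``probability``; support starts at 0)
conditioned on lying inside ``[lower, upper]``.  The conditioning
renormalizes the pmf over the truncated support; it never clamps, which
would pile mass on the bounds.

*Integer-truncated BetaPERT* — counts that depend on an earlier draw use
the PERT distribution, a beta re-parameterized by (minimum, likeliest,
maximum) with shape weight ``lambda`` (classically 4), rescaled to
``[minimum, maximum]``.  The continuous draw is truncated toward zero to
give a whole count; the effect of truncating versus not is negligible for
the summaries this package reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TruncatedNegBinSpec",
    "PertSpec",
    "sample_trunc_negbin",
    "sample_pert",
    "sample_pert_int",
    "fit_negbin_from_mode",
]


@dataclass(frozen=True)
class TruncatedNegBinSpec:
    """Negative binomial (probability, shape) truncated to [lower, upper]."""

    probability: float
    shape: int
    lower: int
    upper: int

    def __post_init__(self) -> None:
        if not 0 < self.probability < 1:
            raise ValueError("probability must lie strictly in (0, 1)")
        if not (isinstance(self.shape, (int, np.integer)) and self.shape >= 1):
            raise ValueError("shape must be a positive integer")
        if self.lower < 0 or self.lower > self.upper:
            raise ValueError("require 0 <= lower <= upper")

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.lower, self.upper + 1)

    def pmf(self) -> np.ndarray:
        """Renormalized pmf over the truncated support."""
        p = stats.nbinom.pmf(self.support, self.shape, self.probability)
        total = p.sum()
        if total <= 0 or not np.isfinite(total):
            raise ValueError("truncated support carries zero probability mass")
        return p / total

    def mode(self) -> int:
        """Mode of the truncated law (argmax of the pmf over the support)."""
        return int(self.support[np.argmax(self.pmf())])

    def mean(self) -> float:
        pmf = self.pmf()
        return float((self.support * pmf).sum())


@dataclass(frozen=True)
class PertSpec:
    """BetaPERT parameter bundle (minimum, likeliest, maximum, shape weight)."""

    minimum: float
    mode: float
    maximum: float
    lam: float = 4.0

    def __post_init__(self) -> None:
        if not self.minimum <= self.mode <= self.maximum:
            raise ValueError("require minimum <= mode <= maximum")
        if self.minimum < 0:
            raise ValueError("minimum must be non-negative")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")

    @property
    def alpha(self) -> float:
        span = self.maximum - self.minimum
        return 1.0 + self.lam * (self.mode - self.minimum) / span

    @property
    def beta(self) -> float:
        span = self.maximum - self.minimum
        return 1.0 + self.lam * (self.maximum - self.mode) / span

    def mean(self) -> float:
        """Mean of the continuous law; (min + λ·mode + max)/(λ + 2)."""
        return (self.minimum + self.lam * self.mode + self.maximum) / (self.lam + 2)


def sample_trunc_negbin(
    spec: TruncatedNegBinSpec, rng: np.random.Generator, size: int | None = None
):
    """Draw from the truncated negative binomial via inverse CDF on the support."""
    pmf = spec.pmf()
    out = rng.choice(spec.support, size=size if size is not None else 1, p=pmf)
    return int(out[0]) if size is None else out


def sample_pert(
    spec: PertSpec, rng: np.random.Generator, size: int | None = None
):
    """Draw the continuous PERT variate (no integer truncation)."""
    if spec.maximum == spec.minimum:
        out = np.full(size if size is not None else 1, float(spec.minimum))
    else:
        u = rng.beta(spec.alpha, spec.beta, size=size if size is not None else 1)
        out = spec.minimum + u * (spec.maximum - spec.minimum)
    return float(out[0]) if size is None else out


def sample_pert_int(
    spec: PertSpec, rng: np.random.Generator, size: int | None = None
):
    """Draw a PERT variate and truncate toward zero to an integer count."""
    x = sample_pert(spec, rng, size=1 if size is None else size)
    out = np.trunc(x).astype(np.int64)
    return int(out[0]) if size is None else out


def fit_negbin_from_mode(
    likeliest: int,
    lower: int,
    upper: int,
    max_shape: int = 10,
    n_probability: int = 4000,
) -> TruncatedNegBinSpec:
    """Find a truncated negative binomial whose mode matches a likeliest count.

    Searches ``shape`` over ``1..max_shape`` and ``probability`` over a fine
    grid, scoring each candidate by the distance between its truncated mode
    and ``likeliest``; ties break toward the smaller shape, then toward the
    candidate closest in untruncated (continuous) mode.  Intended for
    specifying new studies from (minimum, likeliest, maximum) expert
    elicitations; published (probability, shape) pairs can be used directly.
    """
    if not lower <= likeliest <= upper:
        raise ValueError("require lower <= likeliest <= upper")
    best: tuple[float, int, float] | None = None
    best_spec: TruncatedNegBinSpec | None = None
    p_grid = np.linspace(1.0 / n_probability, 1 - 1.0 / n_probability, n_probability - 1)
    for shape in range(1, max_shape + 1):
        if shape == 1:
            modes = np.zeros_like(p_grid)
        else:
            modes = np.floor((shape - 1) * (1 - p_grid) / p_grid)
        trunc_modes = np.clip(modes, lower, upper)
        err = np.abs(trunc_modes - likeliest)
        i = int(np.argmin(err))
        key = (float(err[i]), shape, abs(float(modes[i]) - likeliest))
        if best is None or key < best:
            best = key
            best_spec = TruncatedNegBinSpec(float(p_grid[i]), shape, lower, upper)
    assert best_spec is not None
    return best_spec
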