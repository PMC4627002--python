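"""Scenario configuration files, bundled fixtures and synthetic tables."""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import yaml

from .cohort import CohortTable, ExposureStratum, read_table
from .distributions import TruncatedNegBinSpec
from .scenarios import Differential, Scenario, differential_fraction

__all__ = [
    "ConfigError",
    "load_scenarios",
    "dump_scenarios",
    "builtin_table",
    "builtin_scenarios",
    "generate_synthetic_table",
]

logger = logging.getLogger("ltfbias")


class ConfigError(ValueError):
    """A scenario or run configuration failed validation."""


def _scenario_from_mapping(block: dict) -> Scenario:
    name = str(block.get("name", "?"))
    try:
        ac = block["allcause"]
        allcause = TruncatedNegBinSpec(
            probability=float(ac["probability"]),
            shape=int(ac["shape"]),
            lower=int(ac["lower"]),
            upper=int(ac["upper"]),
        )
        if "differential" in block:
            never_fraction = differential_fraction(Differential(str(block["differential"])))
        else:
            never_fraction = float(block["never_fraction"])
        return Scenario(
            name=name,
            allcause_spec=allcause,
            cause_proportion=float(block["cause_proportion"]),
            never_fraction=never_fraction,
            high_fraction=float(block["high_fraction"]),
            high_cap=int(block["high_cap"]),
            n_trials=int(block.get("n_trials", 50_000)),
            seed=int(block.get("seed", 0)),
        )
    except KeyError as exc:
        raise ConfigError(f"scenario {name!r}: missing field {exc}") from None
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"scenario {name!r}: {exc}") from exc


def load_scenarios(path) -> list[Scenario]:
    """Load and validate scenarios from a YAML file.

    An empty file yields an empty list (with a logged warning); a malformed
    block raises :class:`ConfigError` naming the scenario and field.
    """
    if hasattr(path, "read"):
        doc = yaml.safe_load(path)
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    if not doc:
        logger.warning("scenario file %s is empty", path)
        return []
    blocks = doc.get("scenarios") if isinstance(doc, dict) else doc
    if not blocks:
        logger.warning("scenario file %s defines no scenarios", path)
        return []
    return [_scenario_from_mapping(b) for b in blocks]


def dump_scenarios(scenarios: list[Scenario], path) -> None:
    """Write scenarios back to YAML; round-trips with :func:`load_scenarios`."""
    blocks = []
    for s in scenarios:
        blocks.append(
            {
                "name": s.name,
                "allcause": {
                    "probability": s.allcause_spec.probability,
                    "shape": s.allcause_spec.shape,
                    "lower": s.allcause_spec.lower,
                    "upper": s.allcause_spec.upper,
                },
                "cause_proportion": s.cause_proportion,
                "never_fraction": s.never_fraction,
                "high_fraction": s.high_fraction,
                "high_cap": s.high_cap,
                "n_trials": s.n_trials,
                "seed": s.seed,
            }
        )
    text = yaml.safe_dump({"scenarios": blocks}, sort_keys=False)
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def builtin_table() -> CohortTable:
    """The bundled three-stratum cohort fixture."""
    ref = resources.files("ltfbias.data").joinpath("mcbride_table1.tsv")
    with ref.open() as fh:
        return read_table(fh)


def builtin_scenarios() -> list[Scenario]:
    """The eight bundled bias-analysis scenarios."""
    ref = resources.files("ltfbias.data").joinpath("scenarios.yaml")
    with ref.open() as fh:
        return load_scenarios(fh)


def generate_synthetic_table(
    n_strata: int, rng: np.random.Generator
) -> CohortTable:
    """Generate a random valid cohort table for property tests.

    Strata have positive cells of realistic occupational-cohort magnitude;
    the first stratum is the reference and every stratum's living non-cases
    exceed a plausible loss count so the allocation chain's defensive caps
    rarely bind.
    """
    if n_strata < 2:
        raise ValueError("need at least two strata")
    strata = []
    for i in range(n_strata):
        cases = int(rng.integers(1, 60))
        alive = int(rng.integers(50, 1200))
        dead = int(rng.integers(1, 150))
        label = "reference" if i == 0 else f"stratum-{i}"
        strata.append(ExposureStratum(label, cases, alive, dead))
    total = sum(s.cases + s.noncases for s in strata)
    n_lost = int(rng.integers(1, max(2, total // 4)))
    return CohortTable(tuple(strata), n_lost, "reference")
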