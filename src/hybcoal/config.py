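"""Run configuration: a validated YAML schema driving a full simulation run.

Example::

    seed: 1
    success_function: linear
    epochs:                       # contiguous from time 0; last is open-ended
      - end: 2.0
        speciation_rate: 1.0
        hybrid_rate: 0.1
        introgression_rate: 0.1
        coalescence_rate: 10.0
        success_threshold: 1.3
      - speciation_rate: 1.0
        coalescence_rate: 10.0
        success_threshold: 1.3
    hybrid_contributions: [[0.75, 1.0]]        # (gamma, probability) atoms
    introgression_contributions: [[0.1, 1.0]]
    halting:
      max_species: 20
      min_reticulations: 0
    n_gene_trees: 100

Unknown keys are rejected; rates, gammas and halting limits are validated
before any simulation starts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .params import (
    SUCCESS_KINDS,
    ContributionDistribution,
    Epoch,
    EpochSchedule,
    HaltingConfig,
    RateSet,
)

__all__ = ["RunConfig", "load_config"]

_EPOCH_KEYS = {"end", "speciation_rate", "hybrid_rate", "introgression_rate",
               "coalescence_rate", "success_threshold"}
_HALT_KEYS = {"max_depth", "max_species", "max_reticulations",
              "min_reticulations", "reduce_to_reticulations"}
_TOP_KEYS = {"seed", "success_function", "epochs", "hybrid_contributions",
             "introgression_contributions", "halting", "n_gene_trees"}


def _reject_unknown(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}")


@dataclass
class RunConfig:
    schedule: EpochSchedule
    halting: HaltingConfig
    hybrid_contributions: ContributionDistribution
    introgression_contributions: ContributionDistribution
    n_gene_trees: int
    seed: Optional[int] = None


def _parse_contributions(raw, where: str) -> ContributionDistribution:
    if raw is None:
        return ContributionDistribution.point(0.5)
    if isinstance(raw, (int, float)):
        return ContributionDistribution.point(float(raw))
    try:
        atoms = [(float(g), float(p)) for g, p in raw]
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{where} must be a gamma or a list of (gamma, probability) pairs") from exc
    return ContributionDistribution(atoms)


def parse_config(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ValueError("configuration must be a mapping")
    _reject_unknown(data, _TOP_KEYS, "configuration")
    kind = data.get("success_function", "step")
    if kind not in SUCCESS_KINDS:
        raise ValueError(f"success_function must be one of {SUCCESS_KINDS}, got {kind!r}")

    raw_epochs = data.get("epochs")
    if not raw_epochs:
        raise ValueError("configuration needs a non-empty 'epochs' list")
    epochs = []
    start = 0.0
    for i, ep in enumerate(raw_epochs):
        _reject_unknown(ep, _EPOCH_KEYS, f"epochs[{i}]")
        end = float(ep.get("end", math.inf))
        if i < len(raw_epochs) - 1 and math.isinf(end):
            raise ValueError("only the last epoch may omit 'end'")
        rates = RateSet(
            lambda_S=float(ep.get("speciation_rate", 1.0)),
            lambda_H=float(ep.get("hybrid_rate", 0.0)),
            lambda_I=float(ep.get("introgression_rate", 0.0)),
            lambda_C=float(ep.get("coalescence_rate", 1.0)),
            T=float(ep.get("success_threshold", 1.0)),
        )
        epochs.append(Epoch(start, end, rates))
        start = end
    schedule = EpochSchedule(epochs, kind)

    halt_raw = data.get("halting") or {}
    _reject_unknown(halt_raw, _HALT_KEYS, "halting")
    halting = HaltingConfig(
        max_depth=float(halt_raw.get("max_depth", math.inf)),
        max_species=float(halt_raw.get("max_species", math.inf)),
        max_reticulations=float(halt_raw.get("max_reticulations", math.inf)),
        min_reticulations=int(halt_raw.get("min_reticulations", 0)),
        reduce_to_reticulations=float(halt_raw.get("reduce_to_reticulations", math.inf)),
    )

    n_gene_trees = int(data.get("n_gene_trees", 0))
    if n_gene_trees < 1:
        raise ValueError("n_gene_trees must be >= 1")

    return RunConfig(
        schedule=schedule,
        halting=halting,
        hybrid_contributions=_parse_contributions(data.get("hybrid_contributions"), "hybrid_contributions"),
        introgression_contributions=_parse_contributions(
            data.get("introgression_contributions"), "introgression_contributions"),
        n_gene_trees=n_gene_trees,
        seed=None if data.get("seed") is None else int(data["seed"]),
    )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return parse_config(data)
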