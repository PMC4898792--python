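"""Model parameters: event rates, epochs, success functions, contribution distributions.

The simulator models three memoryless processes acting on N extant species:

* divergence speciation at total rate ``lambda_S * N`` (a Yule process),
* proposed hybrid speciations at rate ``lambda_H * N * (N - 1)``,
* proposed introgressions at rate ``lambda_I * N * (N - 1)``.

A proposed reticulation between species at genetic distance ``d`` establishes
with probability ``F(d)``, one of five monotone non-increasing success
functions parameterized by a threshold/scale ``T``.  Rates and ``T`` may vary
between epochs (contiguous time intervals); the *kind* of success function is
global.  The per-pair coalescence rate ``lambda_C`` used by the gene-tree
engine lives in the same rate container so that it, too, can vary by epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "SUCCESS_KINDS",
    "RateSet",
    "Epoch",
    "EpochSchedule",
    "ContributionDistribution",
    "HaltingConfig",
    "success_probability",
    "total_event_rate",
]

SUCCESS_KINDS = ("linear", "step", "quadratic", "snowball", "exponential")


def success_probability(kind: str, T: float, d: float) -> float:
    """Probability F(d) that a proposed reticulation at genetic distance d succeeds.

    Kinds (all satisfy F(0) = 1 and are non-increasing in d):

    * ``linear``:      max(0, 1 - d/T)
    * ``step``:        1 if d <= T else 0
    * ``quadratic``:   max(0, 1 - (d/T)^2)
    * ``snowball``:    exp(-d^2 / T)
    * ``exponential``: exp(-d / T)

    Distance-independent success ("always succeeds") is obtained with the step
    function and T at least twice the maximum tree depth.
    """
    if T <= 0:
        raise ValueError(f"success threshold T must be positive, got {T}")
    if d < 0:
        raise ValueError(f"genetic distance must be nonnegative, got {d}")
    if kind == "linear":
        return max(0.0, 1.0 - d / T)
    if kind == "step":
        return 1.0 if d <= T else 0.0
    if kind == "quadratic":
        return max(0.0, 1.0 - (d / T) ** 2)
    if kind == "snowball":
        return math.exp(-(d * d) / T)
    if kind == "exponential":
        return math.exp(-d / T)
    raise ValueError(f"unknown success-function kind {kind!r}; expected one of {SUCCESS_KINDS}")


@dataclass(frozen=True)
class RateSet:
    """Per-epoch process rates (relative to the speciation rate, conventionally 1)."""

    lambda_S: float = 1.0  # divergence speciation, per lineage per time
    lambda_H: float = 0.0  # hybrid-speciation proposals, per ordered species pair per time
    lambda_I: float = 0.0  # introgression proposals, per ordered species pair per time
    lambda_C: float = 1.0  # coalescence, per lineage pair per time
    T: float = 1.0         # success-function threshold / scale (distance units)

    def __post_init__(self) -> None:
        for name in ("lambda_S", "lambda_H", "lambda_I", "lambda_C"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.T <= 0:
            raise ValueError(f"T must be > 0, got {self.T}")


def total_event_rate(N: int, rates: RateSet) -> tuple[float, float, float, float]:
    """Total event rate and event-type probabilities for N extant species.

    Returns ``(lam, pS, pH, pI)`` where
    ``lam = lambda_S*N + lambda_H*N*(N-1) + lambda_I*N*(N-1)`` and the p's are
    the corresponding fractions of ``lam`` (they sum to 1).

    Raises if lam == 0 (no process active: the simulation would stall).
    """
    if N < 1:
        raise ValueError(f"need at least one species, got N={N}")
    pairs = N * (N - 1)
    rS = rates.lambda_S * N
    rH = rates.lambda_H * pairs
    rI = rates.lambda_I * pairs
    lam = rS + rH + rI
    if lam == 0:
        raise ValueError("total event rate is zero: no active process, simulation stalled")
    return lam, rS / lam, rH / lam, rI / lam


@dataclass(frozen=True)
class Epoch:
    start_time: float
    end_time: float  # math.inf for an open-ended final epoch
    rates: RateSet = field(default_factory=RateSet)

    def __post_init__(self) -> None:
        if not self.start_time < self.end_time:
            raise ValueError(f"epoch must have start_time < end_time, got [{self.start_time}, {self.end_time}]")


class EpochSchedule:
    """Contiguous, non-overlapping epochs from time 0; the last is open-ended.

    ``success_kind`` is shared by all epochs; only rates and T may differ.
    """

    def __init__(self, epochs: Sequence[Epoch], success_kind: str = "step"):
        if success_kind not in SUCCESS_KINDS:
            raise ValueError(f"unknown success kind {success_kind!r}")
        epochs = list(epochs)
        if not epochs:
            raise ValueError("need at least one epoch")
        if epochs[0].start_time != 0:
            raise ValueError("first epoch must start at time 0")
        for a, b in zip(epochs, epochs[1:]):
            if a.end_time != b.start_time:
                raise ValueError("epochs must be contiguous and non-overlapping")
        self.epochs = epochs
        self.success_kind = success_kind

    @classmethod
    def constant(cls, rates: RateSet, success_kind: str = "step") -> "EpochSchedule":
        """Single open-ended epoch with the given rates."""
        return cls([Epoch(0.0, math.inf, rates)], success_kind)

    def epoch_at(self, t: float) -> Epoch:
        """Epoch covering time t; the final epoch is treated as open-ended."""
        for ep in self.epochs:
            if t < ep.end_time:
                return ep
        return self.epochs[-1]

    def rates_at(self, t: float) -> RateSet:
        return self.epoch_at(t).rates

    def success_probability_at(self, t: float, d: float) -> float:
        return success_probability(self.success_kind, self.rates_at(t).T, d)

    @property
    def is_constant(self) -> bool:
        return len(self.epochs) == 1


class ContributionDistribution:
    """Discrete distribution of the genome fraction gamma contributed by one parent.

    For hybrid speciation, gamma is the fraction inherited from the first
    parent of the (ordered, uniformly drawn) pair; because the pair is ordered
    and exchangeable, a single atom such as 0.75 realizes a 75:25 split with
    either parent equally likely to be the major contributor.  For
    introgression, gamma is the fraction of the recipient genome overwritten
    by the donor (90:10 retained:replaced is the atom 0.1).
    """

    def __init__(self, atoms: Sequence[tuple[float, float]]):
        atoms = [(float(g), float(p)) for g, p in atoms]
        if not atoms:
            raise ValueError("contribution distribution needs at least one atom")
        for g, p in atoms:
            if not 0.0 < g <= 1.0:
                raise ValueError(f"contribution gamma must be in (0, 1], got {g}")
            if p < 0:
                raise ValueError("atom probabilities must be nonnegative")
        total = sum(p for _, p in atoms)
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"atom probabilities must sum to 1, got {total}")
        self.gammas = [g for g, _ in atoms]
        self.probs = [p for _, p in atoms]

    @classmethod
    def point(cls, gamma: float) -> "ContributionDistribution":
        return cls([(gamma, 1.0)])

    def draw(self, rng) -> float:
        if len(self.gammas) == 1:
            return self.gammas[0]
        u = rng.random()
        acc = 0.0
        for g, p in zip(self.gammas, self.probs):
            acc += p
            if u < acc:
                return g
        return self.gammas[-1]


@dataclass(frozen=True)
class HaltingConfig:
    """Halting limits and reticulation-count constraints.

    The simulation stops when the next event would exceed ``max_depth`` (time
    is then advanced so every root-to-tip path equals ``max_depth``),
    ``max_species``, or ``max_reticulations`` (time advanced to the moment of
    the violating event, which is discarded).  ``min_reticulations`` triggers
    rejection-and-resimulation; networks with more than
    ``reduce_to_reticulations`` reticulations have randomly chosen ones
    eliminated down to that count.
    """

    max_depth: float = math.inf
    max_species: float = math.inf
    max_reticulations: float = math.inf
    min_reticulations: int = 0
    reduce_to_reticulations: float = math.inf

    def __post_init__(self) -> None:
        if math.isinf(self.max_depth) and math.isinf(self.max_species) and math.isinf(self.max_reticulations):
            raise ValueError("at least one of max_depth, max_species, max_reticulations must be finite")
        if self.min_reticulations < 0:
            raise ValueError("min_reticulations must be >= 0")
        if self.min_reticulations > self.reduce_to_reticulations:
            raise ValueError("min_reticulations must be <= reduce_to_reticulations")

    @classmethod
    def species_count(cls, n: int, **kw) -> "HaltingConfig":
        return cls(max_species=n, **kw)
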