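"""Forward-in-time growth of a hybridization network over a species set.

The network starts from a speciation at time 0 yielding two species at
genetic distance zero.  Three memoryless processes then act on the extant
species: divergence speciation, hybrid speciation (a new species formed from
two parents, inheriting fraction gamma of its genome from one and 1-gamma
from the other) and introgression (fraction gamma of a recipient genome
overwritten by a donor's).  Proposed reticulations succeed with probability
F(d) of the current genetic distance d between the chosen pair.

A symmetric genetic-distance matrix over the extant species is maintained
throughout: every off-diagonal entry grows by twice the elapsed time between
events, a hybrid's distances are the gamma-weighted average of its parents'
rows, and an introgression gamma-averages the recipient's row toward the
donor's.  There is no extinction: every species ever created is a leaf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .params import (
    ContributionDistribution,
    EpochSchedule,
    HaltingConfig,
    success_probability,
    total_event_rate,
)

__all__ = [
    "NetworkEvent",
    "SpeciesNetwork",
    "EventDraw",
    "draw_event",
    "advance_time",
    "apply_speciation",
    "apply_hybrid_speciation",
    "apply_introgression",
    "simulate_network",
    "enforce_reticulation_count",
    "simulate_conditioned_network",
    "RejectedNetwork",
]


@dataclass(frozen=True)
class NetworkEvent:
    """One recorded event.

    kind='speciation':    parent ``a`` begets child ``child`` at ``time``.
    kind='hybrid':        parents ``a`` (contribution gamma) and ``b``
                          (contribution 1-gamma) beget ``child``.
    kind='introgression': donor ``a`` overwrites fraction gamma of the genome
                          of recipient ``b``; no new species.
    """

    kind: str
    time: float
    a: int
    b: int = -1
    child: int = -1
    gamma: float = 1.0


class SpeciesNetwork:
    """Event-list representation of a rooted, time-calibrated species network.

    Species are integers 0..n_species-1 in order of creation; all are extant
    leaves at ``end_time``.  ``events`` are chronological.  Reticulation
    events are the hybrid and introgression events.
    """

    def __init__(
        self,
        events: Sequence[NetworkEvent],
        n_species: int,
        end_time: float,
        names: Optional[Sequence[str]] = None,
        halt_reason: str = "",
        seed: Optional[int] = None,
    ):
        self.events = list(events)
        self.n_species = int(n_species)
        self.end_time = float(end_time)
        if names is None:
            names = [f"t{i + 1}" for i in range(self.n_species)]
        if len(names) != self.n_species:
            raise ValueError("names must match species count")
        self.names = list(names)
        self.halt_reason = halt_reason
        self.seed = seed
        t = 0.0
        for ev in self.events:
            if ev.time < t:
                raise ValueError("events must be chronological")
            t = ev.time
        if self.events and self.events[-1].time > end_time:
            raise ValueError("events occur after end_time")

    @property
    def hybrid_events(self) -> list[NetworkEvent]:
        return [e for e in self.events if e.kind == "hybrid"]

    @property
    def introgression_events(self) -> list[NetworkEvent]:
        return [e for e in self.events if e.kind == "introgression"]

    @property
    def reticulation_events(self) -> list[NetworkEvent]:
        return [e for e in self.events if e.kind in ("hybrid", "introgression")]

    @property
    def n_reticulations(self) -> int:
        return len(self.reticulation_events)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SpeciesNetwork(n_species={self.n_species}, end_time={self.end_time:g}, "
            f"hybrids={len(self.hybrid_events)}, introgressions={len(self.introgression_events)})"
        )


# ---------------------------------------------------------------------------
# Distance-matrix updates


def advance_time(distances: np.ndarray, delta_t: float) -> np.ndarray:
    """Grow every off-diagonal entry by twice the elapsed time (in place).

    Two diverged species each accumulate delta_t of independent evolution, so
    their pairwise distance grows by 2*delta_t.
    """
    if delta_t < 0:
        raise ValueError("delta_t must be >= 0")
    n = distances.shape[0]
    distances += 2.0 * delta_t
    distances[np.diag_indices(n)] = 0.0
    return distances


def _grow(distances: np.ndarray) -> np.ndarray:
    n = distances.shape[0]
    out = np.zeros((n + 1, n + 1))
    out[:n, :n] = distances
    return out


def apply_speciation(distances: np.ndarray, parent: int) -> np.ndarray:
    """New child species at distance 0 from its parent, copying the parent's row."""
    n = distances.shape[0]
    out = _grow(distances)
    out[n, :n] = distances[parent]
    out[:n, n] = distances[parent]
    out[n, parent] = out[parent, n] = 0.0
    return out


def apply_hybrid_speciation(distances: np.ndarray, a: int, b: int, gamma: float) -> np.ndarray:
    """New hybrid species: gamma-weighted average of the parents' distance rows.

    d(h, x) = gamma*d(a, x) + (1-gamma)*d(b, x) for third parties x; to the
    parents themselves d(h, a) = (1-gamma)*d(a, b) and d(h, b) = gamma*d(a, b)
    (the self-distance-zero convention applied to the same average).
    """
    if a == b:
        raise ValueError("hybrid parents must be distinct")
    n = distances.shape[0]
    out = _grow(distances)
    row = gamma * distances[a] + (1.0 - gamma) * distances[b]
    row[a] = (1.0 - gamma) * distances[a, b]
    row[b] = gamma * distances[a, b]
    out[n, :n] = row
    out[:n, n] = row
    return out


def apply_introgression(distances: np.ndarray, donor: int, recipient: int, gamma: float) -> np.ndarray:
    """Average the recipient's distance row toward the donor's by fraction gamma (in place).

    d'(r, x) = (1-gamma)*d(r, x) + gamma*d(donor, x) for x not in {r, donor};
    d'(r, donor) = (1-gamma)*d(r, donor).
    """
    if donor == recipient:
        raise ValueError("donor and recipient must be distinct")
    row = (1.0 - gamma) * distances[recipient] + gamma * distances[donor]
    row[donor] = (1.0 - gamma) * distances[recipient, donor]
    row[recipient] = 0.0
    distances[recipient, :] = row
    distances[:, recipient] = row
    return distances


# ---------------------------------------------------------------------------
# Event drawing


@dataclass(frozen=True)
class EventDraw:
    delta_t: float  # total elapsed time, including any epoch-boundary restarts
    kind: str       # 'speciation' | 'hybrid_attempt' | 'introgression_attempt'


def draw_event(t: float, N: int, schedule: EpochSchedule, rng: np.random.Generator) -> EventDraw:
    """Draw the waiting time to the next event and its type.

    The waiting time is exponential with the current epoch's total rate; if
    the draw crosses an epoch boundary, time advances to the boundary and the
    draw restarts with the new epoch's rates (exact, by memorylessness).  The
    type is chosen with probabilities (pS, pH, pI) of the epoch in which the
    event lands.
    """
    t0 = t
    while True:
        ep = schedule.epoch_at(t)
        lam, pS, pH, _pI = total_event_rate(N, ep.rates)
        dt = rng.exponential(1.0 / lam)
        if t + dt <= ep.end_time:
            t += dt
            break
        t = ep.end_time
    u = rng.random()
    if u < pS:
        kind = "speciation"
    elif u < pS + pH:
        kind = "hybrid_attempt"
    else:
        kind = "introgression_attempt"
    return EventDraw(delta_t=t - t0, kind=kind)


# ---------------------------------------------------------------------------
# Main simulation loop


def simulate_network(
    schedule: EpochSchedule,
    halting: HaltingConfig,
    rng: np.random.Generator,
    hybrid_contributions: ContributionDistribution | None = None,
    introgression_contributions: ContributionDistribution | None = None,
    keep_distances: bool = False,
    _check_invariants: bool = False,
) -> SpeciesNetwork:
    """Grow one species network until a halting condition fires.

    Halting follows the drawn (not necessarily successful) event: if the next
    event would push root-to-tip depth past ``max_depth``, time advances to
    exactly ``max_depth``; if a species-creating event would exceed
    ``max_species``, or a reticulation attempt would exceed
    ``max_reticulations``, time advances to the moment of the violating event
    and the event is discarded.  Reticulation-count conditioning
    (min/reduce) is handled separately by :func:`enforce_reticulation_count`.
    """
    if hybrid_contributions is None:
        hybrid_contributions = ContributionDistribution.point(0.5)
    if introgression_contributions is None:
        introgression_contributions = ContributionDistribution.point(0.5)

    t = 0.0
    N = 2
    D = np.zeros((2, 2))
    events: list[NetworkEvent] = [NetworkEvent("speciation", 0.0, a=0, child=1)]
    n_retic = 0
    halt_reason = ""

    while True:
        draw = draw_event(t, N, schedule, rng)
        t_next = t + draw.delta_t

        if t_next > halting.max_depth:
            advance_time(D, halting.max_depth - t)
            t = halting.max_depth
            halt_reason = "max_depth"
            break
        creates_species = draw.kind in ("speciation", "hybrid_attempt")
        if creates_species and N + 1 > halting.max_species:
            advance_time(D, draw.delta_t)
            t = t_next
            halt_reason = "max_species"
            break
        is_attempt = draw.kind in ("hybrid_attempt", "introgression_attempt")
        if is_attempt and n_retic + 1 > halting.max_reticulations:
            advance_time(D, draw.delta_t)
            t = t_next
            halt_reason = "max_reticulations"
            break

        advance_time(D, draw.delta_t)
        t = t_next
        rates = schedule.rates_at(t)

        if draw.kind == "speciation":
            parent = int(rng.integers(N))
            D = apply_speciation(D, parent)
            events.append(NetworkEvent("speciation", t, a=parent, child=N))
            N += 1
        else:
            a = int(rng.integers(N))
            b = int(rng.integers(N - 1))
            if b >= a:
                b += 1
            d = D[a, b]
            if rng.random() < success_probability(schedule.success_kind, rates.T, d):
                if draw.kind == "hybrid_attempt":
                    gamma = hybrid_contributions.draw(rng)
                    D = apply_hybrid_speciation(D, a, b, gamma)
                    events.append(NetworkEvent("hybrid", t, a=a, b=b, child=N, gamma=gamma))
                    N += 1
                else:
                    gamma = introgression_contributions.draw(rng)
                    apply_introgression(D, donor=a, recipient=b, gamma=gamma)
                    events.append(NetworkEvent("introgression", t, a=a, b=b, gamma=gamma))
                n_retic += 1

        if _check_invariants:
            assert np.allclose(D, D.T)
            assert np.all(np.diag(D) == 0)
            assert np.all(D >= 0)

    net = SpeciesNetwork(events, N, t, halt_reason=halt_reason)
    if keep_distances:
        net.distances = D
    return net


class RejectedNetwork(Exception):
    """Simulated network failed the minimum-reticulation requirement."""


def enforce_reticulation_count(
    network: SpeciesNetwork,
    min_reticulations: int,
    reduce_to: float,
    rng: np.random.Generator,
) -> SpeciesNetwork:
    """Reject (raise) if below the minimum; randomly eliminate down to ``reduce_to``.

    Eliminating a hybrid speciation keeps one parent with probability equal to
    its genetic contribution, turning the event into a divergence speciation;
    eliminating an introgression removes the event.  Reduction can be
    inconsistent when success depends on distance (a surviving reticulation
    may owe its success to an eliminated one), so it should only be combined
    with distance-independent success.
    """
    retic_idx = [i for i, e in enumerate(network.events) if e.kind in ("hybrid", "introgression")]
    if len(retic_idx) < min_reticulations:
        raise RejectedNetwork(f"{len(retic_idx)} reticulations < minimum {min_reticulations}")
    if len(retic_idx) <= reduce_to:
        return network
    n_drop = len(retic_idx) - int(reduce_to)
    drop = set(rng.choice(len(retic_idx), size=n_drop, replace=False).tolist())
    events: list[NetworkEvent | None] = list(network.events)
    for j, i in enumerate(retic_idx):
        if j not in drop:
            continue
        ev = events[i]
        if ev.kind == "hybrid":
            keep_a = rng.random() < ev.gamma
            parent = ev.a if keep_a else ev.b
            events[i] = NetworkEvent("speciation", ev.time, a=parent, child=ev.child)
        else:
            events[i] = None  # type: ignore[call-overload]
    events = [e for e in events if e is not None]
    return SpeciesNetwork(events, network.n_species, network.end_time, names=network.names, halt_reason=network.halt_reason)


def simulate_conditioned_network(
    schedule: EpochSchedule,
    halting: HaltingConfig,
    rng: np.random.Generator,
    hybrid_contributions: ContributionDistribution | None = None,
    introgression_contributions: ContributionDistribution | None = None,
    max_retries: int = 10_000,
) -> SpeciesNetwork:
    """Simulate, rejecting and resimulating until the reticulation minimum is met,
    then reduce to the configured count.  With min == reduce the result has
    exactly that many reticulations."""
    for _ in range(max_retries):
        net = simulate_network(
            schedule,
            halting,
            rng,
            hybrid_contributions=hybrid_contributions,
            introgression_contributions=introgression_contributions,
        )
        try:
            return enforce_reticulation_count(
                net, halting.min_reticulations, halting.reduce_to_reticulations, rng
            )
        except RejectedNetwork:
            continue
    raise RuntimeError(
        f"no network met min_reticulations={halting.min_reticulations} in {max_retries} attempts"
    )
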