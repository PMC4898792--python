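"""Resolving a hybridization network into per-locus lineage trees.

Under the restricted coalescent, every locus evolves on a single *lineage
tree*: each hybrid node is routed to exactly one of its two parents (with
probabilities given by the parents' genetic contributions gamma / 1-gamma)
and each introgression event either captures the recipient's lineage into
the donor (probability gamma, the replaced genome fraction) or is ignored.
With R reticulations there are 2^R resolutions; grouping their products of
routing probabilities by resulting topology yields a weighted distribution
over lineage trees, which can be enumerated exactly for small R or sampled.

A lineage tree is rooted, binary and ultrametric: every tip sits at the
network's end time and internal nodes carry the (forward) time of the
divergence, hybrid or introgression event at which the two lineages merged.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np

from .network import NetworkEvent, SpeciesNetwork

__all__ = [
    "LineageTree",
    "WeightedTopologyDistribution",
    "resolve_lineage_tree",
    "enumerate_resolutions",
    "enumerate_lineage_distribution",
]

# Internal node representation: a leaf is an int (species index); an internal
# node is a tuple (left, right, forward_time).


class LineageTree:
    """A rooted ultrametric tree of species lineages (one tip per species)."""

    def __init__(self, root, end_time: float, n_species: int, names: Sequence[str]):
        self.root = root
        self.end_time = float(end_time)
        self.n_species = int(n_species)
        self.names = list(names)

    def clade_masks(self) -> list[int]:
        """Bitmasks of the species below each internal node."""
        out: list[int] = []

        def walk(node) -> int:
            if isinstance(node, int):
                return 1 << node
            mask = walk(node[0]) | walk(node[1])
            out.append(mask)
            return mask

        walk(self.root)
        return out

    def topology_key(self) -> frozenset[int]:
        """Canonical rooted-topology identity (the set of clade bitmasks)."""
        return frozenset(self.clade_masks())

    def node_times(self) -> list[float]:
        out: list[float] = []

        def walk(node):
            if isinstance(node, int):
                return
            out.append(node[2])
            walk(node[0])
            walk(node[1])

        walk(self.root)
        return out

    def newick(self, lengths: bool = False) -> str:
        """Canonical newick (children ordered by smallest contained taxon name)."""

        def walk(node, parent_time: float):
            if isinstance(node, int):
                lab = self.names[node]
                if lengths:
                    lab += f":{self.end_time - parent_time:g}"
                return lab, self.names[node]
            left, lmin = walk(node[0], node[2])
            right, rmin = walk(node[1], node[2])
            if rmin < lmin:
                left, right, lmin = right, left, rmin
            s = f"({left},{right})"
            if lengths:
                s += f":{node[2] - parent_time:g}"
            return s, lmin

        s, _ = walk(self.root, self.root[2] if not isinstance(self.root, int) else 0.0)
        return s + ";"


def _build_lineage_tree(
    network: SpeciesNetwork, choices: dict[int, bool]
) -> LineageTree:
    """Deterministic lineage tree for one assignment of reticulation routings.

    ``choices[i]`` for the i-th event (by index into ``network.events``):
    for a hybrid event, True routes the child through parent ``a`` (the
    gamma-contribution parent); for an introgression event, True routes the
    recipient's lineage through the donor.

    Events are replayed in reverse time; a lineage entering the branch of a
    species already carrying a lineage merges with it at that moment (in a
    lineage tree, cohabiting lineages are the same lineage).
    """
    active: dict[int, object] = {s: s for s in range(network.n_species)}

    def merge(child: int, parent: int, t: float) -> None:
        node = active.pop(child, None)
        if node is None:
            return
        if parent in active:
            active[parent] = (active[parent], node, t)
        else:
            active[parent] = node

    for i in range(len(network.events) - 1, -1, -1):
        ev = network.events[i]
        if ev.kind == "speciation":
            merge(ev.child, ev.a, ev.time)
        elif ev.kind == "hybrid":
            target = ev.a if choices[i] else ev.b
            merge(ev.child, target, ev.time)
        else:  # introgression
            if choices[i]:
                merge(ev.b, ev.a, ev.time)

    if len(active) != 1:
        raise RuntimeError(f"network did not resolve to a single root lineage: {sorted(active)}")
    (root,) = active.values()
    return LineageTree(root, network.end_time, network.n_species, network.names)


def resolve_lineage_tree(network: SpeciesNetwork, rng: np.random.Generator) -> LineageTree:
    """Sample one lineage tree: independently route every reticulation."""
    choices: dict[int, bool] = {}
    for i, ev in enumerate(network.events):
        if ev.kind == "hybrid" or ev.kind == "introgression":
            choices[i] = rng.random() < ev.gamma
    return _build_lineage_tree(network, choices)


def enumerate_resolutions(
    network: SpeciesNetwork, max_reticulations: int = 16
) -> list[tuple[float, LineageTree]]:
    """All 2^R reticulation resolutions with their routing probabilities.

    Probabilities sum to 1 over resolutions; distinct resolutions may yield
    identical trees (use :func:`enumerate_lineage_distribution` for the
    grouped-by-topology view).
    """
    retic = [(i, ev) for i, ev in enumerate(network.events) if ev.kind in ("hybrid", "introgression")]
    if len(retic) > max_reticulations:
        raise ValueError(
            f"{len(retic)} reticulations exceed the enumeration cap {max_reticulations}; "
            "sample resolutions instead (resolve_lineage_tree)"
        )
    out = []
    for bits in product((True, False), repeat=len(retic)):
        prob = 1.0
        choices = {}
        for (i, ev), primary in zip(retic, bits):
            choices[i] = primary
            prob *= ev.gamma if primary else 1.0 - ev.gamma
        if prob == 0.0:
            continue
        out.append((prob, _build_lineage_tree(network, choices)))
    return out


@dataclass
class WeightedTopologyDistribution:
    """Topologies (canonical newick, no branch lengths) with weights summing to 1."""

    topologies: list[str]
    weights: list[float]
    representatives: Optional[list[LineageTree]] = None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.topologies, self.weights))


def enumerate_lineage_distribution(
    network: SpeciesNetwork, max_reticulations: int = 16
) -> WeightedTopologyDistribution:
    """Exact weighted distribution over lineage-tree topologies.

    The weight of a topology is the total genome proportion that evolves on
    it: the sum over resolutions yielding it of the product of per-
    reticulation routing probabilities.
    """
    acc: dict[frozenset[int], float] = {}
    rep: dict[frozenset[int], LineageTree] = {}
    for prob, tree in enumerate_resolutions(network, max_reticulations):
        key = tree.topology_key()
        acc[key] = acc.get(key, 0.0) + prob
        rep.setdefault(key, tree)
    items = sorted(acc.items(), key=lambda kv: -kv[1])
    return WeightedTopologyDistribution(
        topologies=[rep[k].newick() for k, _ in items],
        weights=[w for _, w in items],
        representatives=[rep[k] for k, _ in items],
    )
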