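"""Containers for collections of rooted trees on a shared taxon set.

Trees are stored in a compact form designed for the discordance statistics:

* ``clades`` — the bitmask (over taxon indices) of every internal node's
  leaf set; the clade set determines the rooted topology.
* ``pairs`` — an m x m matrix whose (i, j) entry ranks the node at which
  leaves i and j first unite, tipward-most first (coalescent backward times,
  or postorder ranks for parsed trees).  Quartet resolutions are read off
  this matrix: among the six pairs of a 4-subset, the pair with the smallest
  entry is the resolved cherry of the induced quartet.
* ``root`` — optionally, the full (left, right, backward-time) structure for
  branch-length output.
"""

from __future__ import annotations

from collections import Counter
from typing import Optional, Sequence

import numpy as np

__all__ = ["TreeRecord", "TreeProfile"]


class TreeRecord:
    """One rooted tree in clade-bitmask form."""

    __slots__ = ("clades", "pairs", "root", "m")

    def __init__(self, clades: Sequence[int], pairs, m: int, root=None):
        self.clades = list(clades)
        self.pairs = pairs
        self.m = m
        self.root = root

    def topology_key(self) -> frozenset[int]:
        """Rooted topology identity: the set of internal-node clade masks."""
        return frozenset(self.clades)

    def splits(self) -> set[int]:
        """Canonical nontrivial splits (min-valued side of each bipartition)."""
        full = (1 << self.m) - 1
        out = set()
        for c in self.clades:
            pc = c.bit_count()
            if 2 <= pc <= self.m - 2:
                out.add(min(c, full ^ c))
        return out

    def cherries(self) -> set[int]:
        """Leaf pairs adjacent to a common node in the unrooted view."""
        full = (1 << self.m) - 1
        out = set()
        for s in self.splits():
            if s.bit_count() == 2:
                out.add(s)
            comp = full ^ s
            if comp.bit_count() == 2:
                out.add(comp)
        return out

    def newick(self, names: Sequence[str]) -> str:
        """Newick with branch lengths (requires the full ``root`` structure)."""
        if self.root is None:
            raise ValueError("tree was stored without node times")

        def walk(node, parent_tau: float) -> str:
            if isinstance(node, (int, np.integer)):
                return f"{names[node]}:{parent_tau:.12g}"
            l, r, tau = node
            return f"({walk(l, tau)},{walk(r, tau)}):{parent_tau - tau:.12g}"

        if isinstance(self.root, (int, np.integer)):
            return f"{names[self.root]};"
        l, r, tau = self.root
        return f"({walk(l, tau)},{walk(r, tau)});"


class TreeProfile:
    """An ordered collection of rooted trees on one taxon set.

    Derived tables (topology counts, split weights, cherry sets, the pairwise
    first-union array) are computed lazily and cached.
    """

    def __init__(self, records: Sequence[TreeRecord], taxa: Sequence[str]):
        if not records:
            raise ValueError("profile needs at least one tree")
        self.records = list(records)
        self.taxa = list(taxa)
        m = len(self.taxa)
        for r in self.records:
            if r.m != m:
                raise ValueError("all trees must share the profile's taxon set")
        self._topo_counts: Optional[Counter] = None
        self._tree_splits: Optional[list[set[int]]] = None
        self._split_weights: Optional[Counter] = None
        self._cherries: Optional[set[int]] = None
        self._pair_array: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def m(self) -> int:
        return len(self.taxa)

    def topology_counts(self) -> Counter:
        if self._topo_counts is None:
            self._topo_counts = Counter(r.topology_key() for r in self.records)
        return self._topo_counts

    def tree_splits(self) -> list[set[int]]:
        if self._tree_splits is None:
            self._tree_splits = [r.splits() for r in self.records]
        return self._tree_splits

    def split_weights(self) -> Counter:
        """wS(s): number of trees displaying each observed split."""
        if self._split_weights is None:
            c: Counter = Counter()
            for s in self.tree_splits():
                c.update(s)
            self._split_weights = c
        return self._split_weights

    def unique_cherries(self) -> set[int]:
        if self._cherries is None:
            out: set[int] = set()
            for r in self.records:
                out |= r.cherries()
            self._cherries = out
        return self._cherries

    def pair_array(self) -> np.ndarray:
        """(n, m, m) float32 array of first-union ranks/times per tree."""
        if self._pair_array is None:
            self._pair_array = np.asarray([r.pairs for r in self.records], dtype=np.float32)
        return self._pair_array

    def newicks(self, lengths: bool = True) -> list[str]:
        return [r.newick(self.taxa) for r in self.records]
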