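"""Restricted coalescent within a lineage tree.

Each locus is assigned a single lineage tree (one resolution of every
reticulation, drawn once per locus) and an ordinary multispecies coalescent
runs inside it: one lineage enters at each tip; within a branch carrying k
lineages, pairs coalesce at rate ``lambda_C * k * (k - 1) / 2`` (the
two-lineage branch survival probability e^{-t*lambda_C} fixes the per-pair
rate);
lineages that fail to coalesce by the top of a branch join the parent
branch's pool; the branch above the root is unbounded, so every locus fully
coalesces.  ``lambda_C`` may vary by epoch (piecewise constant in time).

Coalescence times are recorded as backward times (tips at 0), so gene-tree
node times never postdate the corresponding lineage-tree divergences.
"""

from __future__ import annotations

import math
from typing import Sequence, Union

import numpy as np

from .lineage import LineageTree, enumerate_resolutions, resolve_lineage_tree
from .network import SpeciesNetwork
from .params import EpochSchedule
from .profiles import TreeProfile, TreeRecord

__all__ = ["sample_coalescent_gene_tree", "simulate_gene_trees"]

Coalescence = Union[float, EpochSchedule]

# Loci are distributed over reticulation resolutions by exact enumeration
# (a multinomial draw over the 2^R lineage trees) up to this many
# reticulations; beyond it, each locus samples its own resolution.
_ENUMERATION_CAP = 10


class _RandomBlocks:
    """Blocked draws of Exp(1) and U(0,1) variates (cuts per-call overhead)."""

    __slots__ = ("rng", "_exp", "_uni", "_ie", "_iu", "_size")

    def __init__(self, rng: np.random.Generator, size: int = 8192):
        self.rng = rng
        self._size = size
        self._exp = rng.standard_exponential(size)
        self._uni = rng.random(size)
        self._ie = 0
        self._iu = 0

    def exp(self) -> float:
        i = self._ie
        if i >= self._size:
            self._exp = self.rng.standard_exponential(self._size)
            i = 0
        self._ie = i + 1
        return self._exp[i]

    def uni(self) -> float:
        i = self._iu
        if i >= self._size:
            self._uni = self.rng.random(self._size)
            i = 0
        self._iu = i + 1
        return self._uni[i]


def _rate_segments(coalescence: Coalescence, end_time: float) -> list[tuple[float, float]]:
    """Piecewise-constant lambda_C over backward time tau = end_time - t.

    Returns [(tau_upper, lam), ...] ascending, last tau_upper == inf.  Epochs
    before time 0 do not exist; the first epoch's rate extends above the root.
    """
    if isinstance(coalescence, (int, float)):
        lam = float(coalescence)
        if lam <= 0:
            raise ValueError("coalescence rate must be positive")
        return [(math.inf, lam)]
    segs: list[tuple[float, float]] = []
    for ep in reversed(coalescence.epochs):
        if ep.rates.lambda_C <= 0:
            raise ValueError("coalescence rate must be positive in every epoch")
        if ep.start_time >= end_time:
            continue
        tau_upper = end_time - ep.start_time
        segs.append((tau_upper, ep.rates.lambda_C))
    if not segs:
        segs.append((end_time, coalescence.epochs[-1].rates.lambda_C))
    segs[-1] = (math.inf, segs[-1][1])
    return segs


def _evolve(pool: list, tau: float, tau_top: float, segs, blocks: _RandomBlocks,
            clades: list, pairs: list) -> None:
    """Coalesce the pool along one branch from backward time tau to tau_top."""
    k = len(pool)
    si = 0
    while segs[si][0] <= tau:
        si += 1
    while k > 1:
        seg_end, lam = segs[si]
        rate = lam * k * (k - 1) * 0.5
        w = blocks.exp() / rate if rate != math.inf else 0.0
        # a draw is only valid within the current constant-rate segment;
        # crossing the boundary restarts it (memoryless) with the next rate
        if tau + w > seg_end and seg_end < tau_top:
            tau = seg_end
            si += 1
            continue
        if tau + w > tau_top:
            return
        tau += w
        i = int(blocks.uni() * k)
        j = int(blocks.uni() * (k - 1))
        if j >= i:
            j += 1
        a = pool[i]
        b = pool[j]
        mask = a[0] | b[0]
        for x in a[1]:
            row = pairs[x]
            for y in b[1]:
                row[y] = tau
                pairs[y][x] = tau
        pool[i] = (mask, a[1] + b[1], (a[2], b[2], tau))
        last = k - 1
        if j != last:
            pool[j] = pool[last]
        pool.pop()
        clades.append(mask)
        k = last


def sample_coalescent_gene_tree(
    lineage_tree: LineageTree,
    coalescence: Coalescence,
    rng: np.random.Generator,
    _blocks: _RandomBlocks | None = None,
) -> TreeRecord:
    """One coalescent gene tree within a lineage tree.

    Node times in the returned record are backward times (tips at 0); the
    pairwise first-coalescence matrix and clade masks are filled in along the
    way so the record is ready for the discordance statistics.
    """
    m = lineage_tree.n_species
    end = lineage_tree.end_time
    segs = _rate_segments(coalescence, end)
    blocks = _blocks if _blocks is not None else _RandomBlocks(rng)
    clades: list[int] = []
    pairs = [[0.0] * m for _ in range(m)]

    def walk(node) -> tuple[list, float]:
        if isinstance(node, int):
            return [(1 << node, [node], node)], 0.0
        tau_node = end - node[2]
        pl, tau_l = walk(node[0])
        _evolve(pl, tau_l, tau_node, segs, blocks, clades, pairs)
        pr, tau_r = walk(node[1])
        _evolve(pr, tau_r, tau_node, segs, blocks, clades, pairs)
        pl.extend(pr)
        return pl, tau_node

    pool, tau_root = walk(lineage_tree.root)
    _evolve(pool, tau_root, math.inf, segs, blocks, clades, pairs)
    return TreeRecord(clades, pairs, m, root=pool[0][2])


def simulate_gene_trees(
    network: SpeciesNetwork,
    n_loci: int,
    coalescence: Coalescence,
    rng: np.random.Generator,
) -> TreeProfile:
    """Profile of ``n_loci`` gene trees from a species network.

    Each locus gets an independent reticulation resolution and coalescent
    draw.  For few reticulations, loci are apportioned over the enumerated
    lineage trees with a single multinomial draw (distributionally identical
    to per-locus resolution and much faster); otherwise each locus samples
    its own resolution.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    blocks = _RandomBlocks(rng)
    records: list[TreeRecord] = []
    if network.n_reticulations <= _ENUMERATION_CAP:
        resolutions = enumerate_resolutions(network)
        probs = np.array([p for p, _ in resolutions])
        counts = rng.multinomial(n_loci, probs / probs.sum())
        for (_, ltree), c in zip(resolutions, counts):
            for _ in range(int(c)):
                records.append(sample_coalescent_gene_tree(ltree, coalescence, rng, _blocks=blocks))
    else:
        for _ in range(n_loci):
            ltree = resolve_lineage_tree(network, rng)
            records.append(sample_coalescent_gene_tree(ltree, coalescence, rng, _blocks=blocks))
    return TreeProfile(records, network.names)
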