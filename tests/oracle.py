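"""Brute-force reference implementations of the discordance statistics.

Everything here works from newick strings via dendropy, with splits as
frozensets of taxon labels and quartet resolutions found by scanning split
sets — deliberately different routes from the package's bitmask/first-union
machinery, so agreement is a meaningful cross-check.  Only usable for small
profiles (m <= ~8).
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import combinations

import dendropy


def parse(newicks: list[str]) -> list[dendropy.Tree]:
    tns = dendropy.TaxonNamespace()
    return [dendropy.Tree.get(data=s, schema="newick", taxon_namespace=tns) for s in newicks]


def leafset(node) -> frozenset:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def taxa_of(tree) -> frozenset:
    return leafset(tree.seed_node)


def splits_of(tree) -> set[frozenset]:
    """Nontrivial splits, canonicalized as frozenset({A, complement})."""
    X = taxa_of(tree)
    out = set()
    for node in tree.preorder_node_iter():
        A = leafset(node)
        if 2 <= len(A) <= len(X) - 2:
            out.add(frozenset({A, X - A}))
    return out


def compatible(s1: frozenset, s2: frozenset) -> bool:
    (A, Ab), (B, Bb) = list(s1), list(s2)
    return not (A & B) or not (A & Bb) or not (Ab & B) or not (Ab & Bb)


def rooted_topology(tree) -> str:
    def walk(node):
        if node.is_leaf():
            return node.taxon.label
        return "(" + ",".join(sorted(walk(c) for c in node.child_nodes())) + ")"

    return walk(tree.seed_node)


def tree_entropy(newicks) -> float:
    counts = Counter(rooted_topology(t) for t in parse(newicks))
    return sum(c * math.log(c) for c in counts.values())


def quartet_resolution(tree_splits: set[frozenset], X: frozenset, four: tuple) -> frozenset | None:
    """Which pair of `four` is split off, judged purely from the split set."""
    a, b, c, d = four
    for pairing in ((a, b, c, d), (a, c, b, d), (a, d, b, c)):
        p, q, r, s = pairing
        for sp in tree_splits:
            A, Ab = list(sp)
            if {p, q} <= A and {r, s} <= Ab or {p, q} <= Ab and {r, s} <= A:
                return frozenset({frozenset({p, q}), frozenset({r, s})})
    return None


def quartet_entropy(newicks) -> float:
    trees = parse(newicks)
    X = taxa_of(trees[0])
    per_tree = [splits_of(t) for t in trees]
    total = 0.0
    for four in combinations(sorted(X), 4):
        counts = Counter()
        for sp in per_tree:
            res = quartet_resolution(sp, X, four)
            if res is not None:
                counts[res] += 1
        total += sum(c * math.log(c) for c in counts.values())
    return total


def split_weights(newicks) -> Counter:
    w = Counter()
    for t in parse(newicks):
        w.update(splits_of(t))
    return w


def split_incompatibility(newicks, k: int = 0) -> float:
    w = split_weights(newicks)
    splits = [s for s in w if w[s] > k]
    total = 0.0
    for s1 in splits:
        for s2 in splits:
            if not compatible(s1, s2):
                total += (w[s1] - k) * (w[s2] - k)
    return total


def rare_splits(newicks) -> int:
    return sum(1 for c in split_weights(newicks).values() if c == 1)


def distance_to_consensus(newicks) -> int:
    n = len(newicks)
    return sum(min(c, n - c) for c in split_weights(newicks).values())


def majority_consensus_rf_sum(newicks) -> int:
    """DC the long way: build the majority split set, sum RF distances to it."""
    n = len(newicks)
    w = split_weights(newicks)
    majority = {s for s, c in w.items() if c > n / 2}
    total = 0
    for t in parse(newicks):
        st = splits_of(t)
        total += len(st ^ majority)
    return total


def unique_cherries(newicks) -> int:
    """Cherries by direct adjacency in the derooted tree: every pair of leaf
    children of a common vertex."""
    out = set()
    for t in parse(newicks):
        t2 = t.clone(depth=1)
        t2.deroot()
        for node in t2.preorder_internal_node_iter():
            leaf_children = [c for c in node.child_nodes() if c.is_leaf()]
            for pair in combinations(leaf_children, 2):
                out.add(frozenset(c.taxon.label for c in pair))
    return len(out)


def unique_splits(newicks) -> int:
    return len(split_weights(newicks))


def greedy_consensus_splits(newicks, m: int):
    w = split_weights(newicks)
    taxa = sorted(taxa_of(parse(newicks)[0]))
    index = {t: i for i, t in enumerate(taxa)}

    def canon_key(s: frozenset) -> int:
        # same tie-break as the package: smaller bitmask side, taxa sorted by name
        masks = [sum(1 << index[x] for x in side) for side in s]
        return min(masks)

    accepted = []
    for s in sorted(w, key=lambda s: (-w[s], canon_key(s))):
        if all(compatible(s, t) for t in accepted):
            accepted.append(s)
    return accepted, w


def tree_certainty(newicks, m: int) -> float:
    accepted, w = greedy_consensus_splits(newicks, m)
    total = 0.0
    for s in accepted:
        conflicts = [w[t] for t in w if not compatible(s, t)]
        x1, x2 = w[s], max(conflicts, default=0)
        p = x1 / (x1 + x2)
        ic = 1.0
        if 0 < p < 1:
            ic = 1.0 + p * math.log2(p) + (1 - p) * math.log2(1 - p)
        total += ic
    return total


def tree_certainty_all(newicks, m: int) -> float:
    accepted, w = greedy_consensus_splits(newicks, m)
    total = 0.0
    for s in accepted:
        ws = [w[s]] + [w[t] for t in w if not compatible(s, t)]
        h = len(ws)
        if h == 1:
            total += 1.0
            continue
        tot = sum(ws)
        total += 1.0 + sum((x / tot) * math.log(x / tot, h) for x in ws)
    return total


def base_statistics(newicks, include_si2=True) -> dict:
    m = len(taxa_of(parse(newicks)[0]))
    out = {
        "TE": tree_entropy(newicks),
        "QE": quartet_entropy(newicks),
        "SI": split_incompatibility(newicks, 0),
        "SI1": split_incompatibility(newicks, 1),
    }
    if include_si2:
        out["SI2"] = split_incompatibility(newicks, 2)
    out.update(
        RS=float(rare_splits(newicks)),
        DC=float(distance_to_consensus(newicks)),
        UC=float(unique_cherries(newicks)),
        US=float(unique_splits(newicks)),
        TC=tree_certainty(newicks, m),
        TCA=tree_certainty_all(newicks, m),
    )
    return out
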