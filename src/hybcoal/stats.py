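"""Discordance statistics over a profile of gene trees.

Given a profile P = (T1..Tn) of rooted trees on a shared taxon set X
(|X| = m), these statistics each measure — in a different way — how much the
trees disagree, and together form the feature vector used by the scenario
classifier and the ABC summary-statistic fits:

TE   tree entropy, sum over unique rooted topologies of w*ln(w)
QE   quartet entropy, sum over 4-subsets and their three resolutions of
     wQ*ln(wQ)
SI   split incompatibility, sum over ordered pairs of observed unrooted
     splits of wS(si)*wS(sj)*I(si, sj), with I the incompatibility indicator
SI-k thresholded SI over splits with weight > k, using weights wS - k
RS   number of splits observed in exactly one tree
DC   distance to the majority-rule consensus, computed as
     sum over observed splits of min(wS, n - wS) (Robinson-Foulds distances
     here are unhalved symmetric-difference counts, which makes this formula
     exactly the sum of RF distances from each tree to the consensus)
UC   number of unique cherries across trees (unrooted view)
US   number of unique splits across trees
TC   sum of internode certainties over the greedy-consensus splits
TCA  same with "internode certainty all" (all conflicting splits, no
     frequency threshold)

Topology identity for TE is rooted; splits, quartets and cherries use the
unrooted view.  TE/QE use natural log, IC uses log2, ICA uses log base h
(the size of its conflict set).  A separate pairwise Robinson-Foulds sum
(``rf_sum``) is provided because the ordered-split-pair form of SI is not,
in general, equal to the sum of pairwise RF distances.
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import combinations
from typing import Sequence

import numpy as np

from .profiles import TreeProfile

__all__ = [
    "splits_compatible",
    "tree_entropy",
    "quartet_entropy",
    "split_incompatibility",
    "rf_sum",
    "rare_splits",
    "distance_to_consensus",
    "unique_counts",
    "greedy_consensus",
    "consensus_newick",
    "internode_certainty",
    "tree_certainty",
    "tree_certainty_all",
    "base_statistics",
    "BASE_STATISTIC_NAMES",
    "CLASSIFIER_STATISTIC_NAMES",
]

#: Table layout of the full feature vector.
BASE_STATISTIC_NAMES = ("TE", "QE", "SI", "SI1", "SI2", "RS", "DC", "UC", "US", "TC", "TCA")
#: The ten statistics used by the scenario classifier (no SI2).
CLASSIFIER_STATISTIC_NAMES = ("TE", "SI", "DC", "UC", "US", "QE", "RS", "SI1", "TC", "TCA")


def splits_compatible(s1: int, s2: int, m: int) -> bool:
    """Two splits (canonical bitmasks over m taxa) are compatible iff one of
    the four side-intersections is empty."""
    full = (1 << m) - 1
    n1 = full ^ s1
    n2 = full ^ s2
    return (s1 & s2) == 0 or (s1 & n2) == 0 or (n1 & s2) == 0 or (n1 & n2) == 0


def _xlogx(c: np.ndarray) -> float:
    c = c[c > 0].astype(float)
    return float(np.sum(c * np.log(c)))


def tree_entropy(profile: TreeProfile) -> float:
    """TE: sum of w*ln(w) over unique rooted topologies (0 at full discordance)."""
    counts = np.array(list(profile.topology_counts().values()))
    return _xlogx(counts)


@lru_cache(maxsize=8)
def _quartet_index(m: int) -> tuple[np.ndarray, np.ndarray]:
    """Flattened pair indices (nq*6,) and resolution codes (6,) for m taxa."""
    pairs = []
    for i, j, k, l in combinations(range(m), 4):
        pairs.extend([i * m + j, k * m + l, i * m + k, j * m + l, i * m + l, j * m + k])
    res = np.array([0, 0, 1, 1, 2, 2], dtype=np.int64)
    return np.array(pairs, dtype=np.intp), res


def quartet_resolution_counts(profile: TreeProfile) -> np.ndarray:
    """(n_quartets, 3) counts of the three resolutions of every 4-subset.

    The resolution of a quartet within a tree is read off the pairwise
    first-union array: among the six pairs of the 4-subset, the pair uniting
    tipward-most is the quartet's cherry.
    """
    m = profile.m
    if m < 4:
        return np.zeros((0, 3), dtype=np.int64)
    pair_idx, res_codes = _quartet_index(m)
    P = profile.pair_array().reshape(profile.n, m * m)
    Q = P[:, pair_idx].reshape(profile.n, -1, 6)
    res = res_codes[np.argmin(Q, axis=2)]  # (n, nq)
    nq = res.shape[1]
    qidx = np.arange(nq, dtype=np.int64)
    flat = (qidx[None, :] * 3 + res).ravel()
    counts = np.bincount(flat, minlength=nq * 3).reshape(nq, 3)
    return counts


def quartet_entropy(profile: TreeProfile) -> float:
    """QE: sum over 4-subsets of the three resolutions' w*ln(w)."""
    return _xlogx(quartet_resolution_counts(profile).ravel())


def _split_arrays(profile: TreeProfile) -> tuple[np.ndarray, np.ndarray]:
    w = profile.split_weights()
    masks = np.array(sorted(w), dtype=np.int64)
    weights = np.array([w[int(s)] for s in masks], dtype=np.int64)
    return masks, weights


def _incompatibility_matrix(masks: np.ndarray, m: int) -> np.ndarray:
    full = (1 << m) - 1
    a = masks[:, None]
    b = masks[None, :]
    na = full ^ a
    nb = full ^ b
    return ((a & b) != 0) & ((a & nb) != 0) & ((na & b) != 0) & ((na & nb) != 0)


def split_incompatibility(profile: TreeProfile, k: int = 0) -> float:
    """SI (k=0) / SI-k: weighted incompatible ordered split pairs.

    Splits with weight <= k are ignored and surviving weights are reduced by
    k.  Each unordered conflict is counted twice (ordered-pair convention).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    masks, weights = _split_arrays(profile)
    keep = weights > k
    masks = masks[keep]
    w = (weights[keep] - k).astype(float)
    if len(masks) < 2:
        return 0.0
    I = _incompatibility_matrix(masks, profile.m)
    return float(w @ I @ w)


def rf_sum(profile: TreeProfile) -> int:
    """Sum of unhalved Robinson-Foulds distances over ordered tree pairs.

    The 'intuitive' pairwise-distance form of split incompatibility; not equal
    to :func:`split_incompatibility` in general.
    """
    splits = profile.tree_splits()
    total = 0
    for i, si in enumerate(splits):
        for sj in splits[i + 1:]:
            total += len(si) + len(sj) - 2 * len(si & sj)
    return 2 * total


def rare_splits(profile: TreeProfile) -> int:
    """RS: number of splits displayed by exactly one tree."""
    return sum(1 for w in profile.split_weights().values() if w == 1)


def distance_to_consensus(profile: TreeProfile) -> int:
    """DC: sum over observed splits of min(wS, n - wS).

    Equals the sum of (unhalved) RF distances from each tree to the
    majority-rule consensus, without building the consensus.
    """
    n = profile.n
    return sum(min(w, n - w) for w in profile.split_weights().values())


def unique_counts(profile: TreeProfile) -> tuple[int, int]:
    """(UC, US): unique cherries and unique splits across the profile."""
    return len(profile.unique_cherries()), len(profile.split_weights())


def greedy_consensus(profile: TreeProfile) -> list[int]:
    """Greedy consensus split set: observed splits in decreasing-weight order
    (ties broken by canonical mask value), each accepted iff compatible with
    everything already accepted.  Contains every majority split."""
    w = profile.split_weights()
    m = profile.m
    accepted: list[int] = []
    for s in sorted(w, key=lambda s: (-w[s], s)):
        if all(splits_compatible(s, t, m) for t in accepted):
            accepted.append(s)
    return accepted


def consensus_newick(splits: Sequence[int], taxa: Sequence[str]) -> str:
    """Rooted newick displaying a pairwise-compatible split set.

    Each split is represented by its side not containing taxon 0 (a clade of
    the tree rooted at taxon 0's side); nesting clades by containment gives
    the tree, with polytomies where splits are missing.
    """
    m = len(taxa)
    full = (1 << m) - 1
    clades = []
    for s in splits:
        c = s if not (s & 1) else (full ^ s)
        clades.append(c)
    clades = sorted(set(clades), key=lambda c: c.bit_count())

    def build(mask: int, available: list[int]) -> str:
        inner = [c for c in available if (c & mask) == c and c != mask]
        maximal = [c for c in inner if not any((c & d) == c and c != d for d in inner)]
        parts = []
        covered = 0
        for c in maximal:
            parts.append(build(c, inner))
            covered |= c
        for i in range(m):
            if (mask >> i) & 1 and not (covered >> i) & 1:
                parts.append(taxa[i])
        if len(parts) == 1:
            return parts[0]
        return "(" + ",".join(sorted(parts)) + ")"

    return build(full, clades) + ";"


def internode_certainty(x1: int, x2: int) -> float:
    """IC = 1 + p*log2(p) + (1-p)*log2(1-p), p = x1/(x1+x2).

    x1 is the count of the evaluated split, x2 the count of the most numerous
    incompatible split (0 if unopposed, giving IC = 1).
    """
    if x1 < 1:
        raise ValueError("x1 must be >= 1")
    if x2 < 0:
        raise ValueError("x2 must be >= 0")
    p = x1 / (x1 + x2)
    ic = 1.0
    if p > 0:
        ic += p * math.log2(p)
    if p < 1:
        ic += (1 - p) * math.log2(1 - p)
    return ic


def _consensus_conflicts(profile: TreeProfile):
    """For each greedy-consensus split: (weight, weights of conflicting observed splits)."""
    masks, weights = _split_arrays(profile)
    w = profile.split_weights()
    m = profile.m
    out = []
    for s in greedy_consensus(profile):
        conflicts = [int(wt) for mask, wt in zip(masks, weights)
                     if not splits_compatible(s, int(mask), m)]
        out.append((w[s], conflicts))
    return out


def tree_certainty(profile: TreeProfile) -> float:
    """TC: sum of IC over the greedy-consensus splits (x2 = heaviest conflict)."""
    total = 0.0
    for x1, conflicts in _consensus_conflicts(profile):
        total += internode_certainty(x1, max(conflicts) if conflicts else 0)
    return total


def tree_certainty_all(profile: TreeProfile) -> float:
    """TCA: sum of ICA over the greedy-consensus splits.

    ICA = 1 + sum_i p_i * log_h(p_i) over the h splits consisting of the
    evaluated split and every observed split conflicting with it (no
    frequency threshold); h = 1 gives ICA = 1.
    """
    total = 0.0
    for x1, conflicts in _consensus_conflicts(profile):
        ws = [x1] + conflicts
        h = len(ws)
        if h == 1:
            total += 1.0
            continue
        tot = sum(ws)
        ica = 1.0 + sum((w / tot) * math.log(w / tot, h) for w in ws if w > 0)
        total += ica
    return total


def base_statistics(profile: TreeProfile, include_si2: bool = True) -> dict[str, float]:
    """The full discordance feature vector for one profile.

    With ``include_si2`` the vector has the 11 table-layout entries
    (TE, QE, SI, SI-1, SI-2, RS, DC, UC, US, TC, TCA); without it, SI2 is
    omitted, leaving the ten classifier features.
    """
    uc, us = unique_counts(profile)
    out = {
        "TE": tree_entropy(profile),
        "QE": quartet_entropy(profile),
        "SI": split_incompatibility(profile, 0),
        "SI1": split_incompatibility(profile, 1),
    }
    if include_si2:
        out["SI2"] = split_incompatibility(profile, 2)
    out.update(
        RS=float(rare_splits(profile)),
        DC=float(distance_to_consensus(profile)),
        UC=float(uc),
        US=float(us),
        TC=tree_certainty(profile),
        TCA=tree_certainty_all(profile),
    )
    return out
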