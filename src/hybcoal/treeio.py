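"""Reading and writing trees, networks and result tables.

Gene-tree profiles are read from multi-tree Newick files or Nexus TREES
blocks (translate tables honored, via dendropy) and written as Newick or
Nexus with branch lengths.  Species networks are written as extended Newick
(hybrid nodes tagged ``#H<i>`` and appearing under both parents, the
gamma-contribution parent carrying the subtree and a ``[&gamma=..]``
annotation) with introgression events in a sidecar TSV, since introgression
does not create a node of the network.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import dendropy

from .lineage import WeightedTopologyDistribution
from .network import SpeciesNetwork
from .profiles import TreeProfile, TreeRecord

__all__ = [
    "read_tree_profile",
    "profile_from_dendropy",
    "write_newick",
    "write_nexus",
    "network_enewick",
    "write_network",
    "write_distribution_tsv",
    "write_statistics_tsv",
    "write_metadata",
]


def _record_from_dendropy(tree: dendropy.Tree, index: dict[str, int], m: int) -> TreeRecord:
    """Clade masks and first-union ranks from a dendropy tree.

    Ranks are postorder indices of internal nodes: descendants rank below
    ancestors, so the tipward-most uniting node of any leaf pair has the
    smallest rank (all the quartet machinery needs)."""
    pairs = [[0.0] * m for _ in range(m)]
    clades: list[int] = []
    rank = 0
    members: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in index:
                raise ValueError(f"taxon {label!r} not in the profile's taxon set")
            members[node] = [index[label]]
        else:
            kids = [members[c] for c in node.child_nodes()]
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    for x in kids[i]:
                        row = pairs[x]
                        for y in kids[j]:
                            row[y] = rank
                            pairs[y][x] = rank
            merged = [x for k in kids for x in k]
            members[node] = merged
            mask = 0
            for x in merged:
                mask |= 1 << x
            clades.append(mask)
            rank += 1
    return TreeRecord(clades, pairs, m)


def profile_from_dendropy(trees: dendropy.TreeList) -> TreeProfile:
    """Convert a dendropy tree list (shared taxon namespace) to a profile."""
    if len(trees) == 0:
        raise ValueError("no trees found")
    taxa = sorted(t.label for t in trees.taxon_namespace)
    index = {t: i for i, t in enumerate(taxa)}
    m = len(taxa)
    records = []
    for k, tree in enumerate(trees):
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        if leaves != set(taxa):
            raise ValueError(
                f"tree {k + 1} has taxa {sorted(leaves)} but the profile's taxon set is {taxa}"
            )
        records.append(_record_from_dendropy(tree, index, m))
    return TreeProfile(records, taxa)


def read_tree_profile(path: str | Path, schema: str = "auto") -> TreeProfile:
    """Read a profile from a multi-tree Newick file or a Nexus TREES block."""
    path = Path(path)
    if schema == "auto":
        head = path.read_text().lstrip()[:6].lower()
        schema = "nexus" if head.startswith("#nexus") else "newick"
    trees = dendropy.TreeList.get(path=str(path), schema=schema)
    return profile_from_dendropy(trees)


def write_newick(profile: TreeProfile, path: str | Path) -> None:
    Path(path).write_text("\n".join(profile.newicks()) + "\n")


def write_nexus(profile: TreeProfile, path: str | Path) -> None:
    lines = ["#NEXUS", "", "BEGIN TAXA;", f"    DIMENSIONS NTAX={profile.m};",
             "    TAXLABELS " + " ".join(profile.taxa) + ";", "END;", "", "BEGIN TREES;"]
    for i, nwk in enumerate(profile.newicks()):
        lines.append(f"    TREE locus_{i + 1} = [&R] {nwk}")
    lines += ["END;", ""]
    Path(path).write_text("\n".join(lines))


def network_enewick(network: SpeciesNetwork) -> str:
    """Extended-Newick string of the network's speciation/hybrid structure."""
    children: dict[int, list] = {s: [] for s in range(network.n_species)}
    hybrid_tag: dict[int, int] = {}
    for ev in network.events:
        if ev.kind == "speciation" and ev.time > 0:
            children[ev.a].append(ev)
        elif ev.kind == "hybrid":
            hybrid_tag[ev.child] = len(hybrid_tag) + 1
            children[ev.a].append(ev)
            children[ev.b].append(ev)

    for evs in children.values():
        evs.sort(key=lambda e: e.time)

    def walk(s: int, t_start: float, i: int) -> str:
        """Species s's lineage from t_start to its tip, nesting attachments i.."""
        evs = children[s]
        if i >= len(evs):
            return f"{network.names[s]}:{network.end_time - t_start:g}"
        ev = evs[i]
        rest = walk(s, ev.time, i + 1)
        if ev.kind == "speciation":
            attach = walk(ev.child, ev.time, 0)
        elif ev.a == s:  # gamma-contribution parent carries the hybrid subtree
            sub = walk(ev.child, ev.time, 0)
            attach = f"({sub})#H{hybrid_tag[ev.child]}:0[&gamma={ev.gamma:g}]"
        else:
            attach = f"#H{hybrid_tag[ev.child]}:0"
        return f"({rest},{attach}):{ev.time - t_start:g}"

    root_time = network.events[0].time  # founding speciation at time 0
    left = walk(0, root_time, 0)
    right = walk(network.events[0].child, root_time, 0)
    return f"({left},{right});"


def write_network(network: SpeciesNetwork, enewick_path: str | Path,
                  introgressions_path: str | Path | None = None) -> None:
    Path(enewick_path).write_text(network_enewick(network) + "\n")
    if introgressions_path is not None:
        lines = ["time\tdonor\trecipient\tgamma"]
        for ev in network.introgression_events:
            lines.append(f"{ev.time:g}\t{network.names[ev.a]}\t{network.names[ev.b]}\t{ev.gamma:g}")
        Path(introgressions_path).write_text("\n".join(lines) + "\n")


def write_distribution_tsv(dist: WeightedTopologyDistribution, path: str | Path) -> None:
    lines = ["topology\tweight"]
    for topo, w in zip(dist.topologies, dist.weights):
        lines.append(f"{topo}\t{w:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_statistics_tsv(rows: Sequence[dict], path: str | Path) -> None:
    """One row of base statistics per profile, table-layout column order."""
    if not rows:
        raise ValueError("no statistics rows to write")
    cols = list(rows[0].keys())
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append("\t".join(f"{row[c]:g}" if isinstance(row[c], float) else str(row[c]) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")


def write_metadata(path: str | Path, **fields) -> None:
    Path(path).write_text(json.dumps(fields, indent=2, default=str) + "\n")
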