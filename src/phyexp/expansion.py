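"""Lineage-specific in-paralog groups, cross-tree merging, size distribution.

An in-paralog group is a maximal clade whose internal nodes are all
duplications and whose leaves all belong to the focal species: repeated
rounds of duplication after the focal lineage's last speciation collapse
into a single group.  Groups from different trees are merged into
non-redundant expansion families whenever they share at least a threshold
fraction (default 50%) of the smaller group's members, closed transitively.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio.Phylo.BaseTree import Tree

from .core_io import PhyexpError, SpeciesMap
from .reconciliation import DUPLICATION, EventLabel

__all__ = [
    "InParalogGroup",
    "ExpansionFamily",
    "MergeParams",
    "detect_inparalog_groups",
    "merge_groups",
    "size_distribution",
]


@dataclass(frozen=True)
class InParalogGroup:
    members: frozenset[str]
    tree_id: str = ""

    def __post_init__(self):
        if len(self.members) < 2:
            raise PhyexpError("in-paralog group needs at least 2 members")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ExpansionFamily:
    members: frozenset[str]
    group_ids: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class MergeParams:
    """Overlap threshold for cross-tree merging, measured against the
    smaller group's size."""

    threshold: float = 0.5

    def __post_init__(self):
        if not 0 < self.threshold <= 1:
            raise PhyexpError("merge threshold must be in (0, 1]")


def detect_inparalog_groups(
    tree: Tree,
    labels: EventLabel,
    focal: str,
    species: SpeciesMap,
    tree_id: str = "",
) -> list[InParalogGroup]:
    """Maximal all-duplication, all-focal clades with >= 2 leaves.

    Returns groups in leaf order; a tree without focal genes yields [].
    """
    # per-node: are all leaves focal AND all internal nodes duplications?
    ok: dict[int, bool] = {}
    leafsets: dict[int, list[str]] = {}
    for clade in tree.find_clades(order="postorder"):
        if clade.is_terminal():
            ok[id(clade)] = species.species_of(clade.name) == focal
            leafsets[id(clade)] = [clade.name]
        else:
            ok[id(clade)] = labels[clade] == DUPLICATION and all(
                ok[id(c)] for c in clade.clades
            )
            leafsets[id(clade)] = [n for c in clade.clades for n in leafsets[id(c)]]

    groups: list[InParalogGroup] = []

    def walk(clade, parent_ok: bool):
        if not clade.is_terminal() and ok[id(clade)] and not parent_ok:
            if len(leafsets[id(clade)]) >= 2:
                groups.append(InParalogGroup(frozenset(leafsets[id(clade)]), tree_id))
        for child in clade.clades:
            walk(child, ok[id(clade)])

    walk(tree.root, False)
    return groups


def merge_groups(groups: list[InParalogGroup], params: MergeParams | None = None) -> list[ExpansionFamily]:
    """Union-find closure of groups overlapping above the threshold.

    Clusters are merged repeatedly until no two clusters share >= threshold
    of the smaller *original group* entering either cluster, making the
    result independent of input order.  Output sorted by descending size,
    then by smallest member.
    """
    params = params or MergeParams()
    n = len(groups)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    changed = True
    while changed:
        changed = False
        members: dict[int, set[str]] = {}
        for i, g in enumerate(groups):
            members.setdefault(find(i), set()).update(g.members)
        roots = sorted(members)
        for ai in range(len(roots)):
            for bi in range(ai + 1, len(roots)):
                a, b = members[roots[ai]], members[roots[bi]]
                inter = len(a & b)
                if inter and inter / min(len(a), len(b)) >= params.threshold:
                    union(roots[ai], roots[bi])
                    changed = True
        # recompute clusters after any merge round

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    fams = [
        ExpansionFamily(
            frozenset().union(*(groups[i].members for i in idxs)), tuple(sorted(idxs))
        )
        for idxs in clusters.values()
    ]
    fams.sort(key=lambda f: (-f.size, min(f.members)))
    return fams


def size_distribution(families: list[ExpansionFamily]) -> dict:
    """Histogram of family sizes plus summary tallies."""
    hist = Counter(f.size for f in families)
    return {
        "histogram": dict(sorted(hist.items())),
        "n_families": len(families),
        "largest": max(hist) if hist else 0,
        "n_genes": sum(s * c for s, c in hist.items()),
        "n_size2": hist.get(2, 0),
        "n_size3plus": sum(c for s, c in hist.items() if s >= 3),
    }
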