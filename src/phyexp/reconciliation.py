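"""Species-overlap reconciliation and phylogeny-based orthology inference.

The species-overlap rule labels a gene-tree node a duplication when the
species sets of (any) two of its child partitions intersect, and a
speciation otherwise — no species tree required.  A configurable fractional
threshold generalises the strict rule: a node is a duplication when
max over child pairs of ``|overlap| / |union|`` exceeds the threshold
(default 0, i.e. any shared species).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from Bio.Phylo.BaseTree import Clade, Tree

from .core_io import PhyexpError, SpeciesMap, write_newick

__all__ = [
    "DUPLICATION",
    "SPECIATION",
    "EventLabel",
    "OrthologyRelation",
    "AnnotationTransfer",
    "label_events",
    "infer_orthology",
    "transfer_annotations",
    "labeled_newick",
]

DUPLICATION = "duplication"
SPECIATION = "speciation"


@dataclass
class EventLabel:
    """Per-internal-node event labels for one gene tree.

    ``labels`` maps clade objects to 'duplication'/'speciation';
    ``focal_only`` flags duplication nodes all of whose descendant leaves
    belong to the focal species (populated when a focal species is given).
    """

    labels: dict[Clade, str] = field(default_factory=dict)
    focal_only: dict[Clade, bool] = field(default_factory=dict)

    def __getitem__(self, clade: Clade) -> str:
        return self.labels[clade]

    def duplications(self) -> list[Clade]:
        return [c for c, e in self.labels.items() if e == DUPLICATION]


@dataclass(frozen=True)
class OrthologyRelation:
    gene_a: str
    gene_b: str
    relation: str  # one-to-one | one-to-many | many-to-one | many-to-many | paralog


@dataclass(frozen=True)
class AnnotationTransfer:
    gene_id: str
    source_gene_id: str
    go_terms: tuple[str, ...]
    confidence: str  # direct | tentative


def _species_sets(tree: Tree, species: SpeciesMap) -> dict[Clade, frozenset[str]]:
    sets: dict[Clade, frozenset[str]] = {}
    for clade in tree.find_clades(order="postorder"):
        if clade.is_terminal():
            sets[clade] = frozenset({species.species_of(clade.name)})
        else:
            acc: frozenset[str] = frozenset()
            for child in clade.clades:
                acc |= sets[child]
            sets[clade] = acc
    return sets


def label_events(
    tree: Tree,
    species: SpeciesMap,
    overlap_threshold: float = 0.0,
    focal: str | None = None,
) -> EventLabel:
    """Label every internal node duplication or speciation by species overlap.

    Multifurcations are evaluated over all child pairs (duplication if any
    pair overlaps above the threshold).
    """
    if not getattr(tree, "rooted", True):
        raise PhyexpError("tree is unrooted: root it first (see root_tree)")
    if not 0 <= overlap_threshold < 1:
        raise PhyexpError("overlap threshold must be in [0, 1)")
    sets = _species_sets(tree, species)
    out = EventLabel()
    for clade in tree.find_clades(order="postorder"):
        if clade.is_terminal():
            continue
        dup = False
        for c1, c2 in combinations(clade.clades, 2):
            inter = sets[c1] & sets[c2]
            if inter:
                frac = len(inter) / len(sets[c1] | sets[c2])
                if frac > overlap_threshold:
                    dup = True
                    break
        out.labels[clade] = DUPLICATION if dup else SPECIATION
        if focal is not None and dup:
            out.focal_only[clade] = sets[clade] == frozenset({focal})
    return out


def _lca_table(tree: Tree) -> dict[Clade, Clade]:
    parents = {}
    for clade in tree.find_clades():
        for child in clade.clades:
            parents[child] = clade
    return parents


def infer_orthology(tree: Tree, labels: EventLabel, species: SpeciesMap) -> list[OrthologyRelation]:
    """Classify every leaf pair of the family.

    Cross-species pairs whose LCA is a speciation are orthologs; the
    relation arity counts, on each side of the LCA, the co-orthologous genes
    of that side's species.  Same-species pairs and duplication-LCA pairs
    are paralogs.
    """
    if any(c not in labels.labels for c in tree.get_nonterminals()):
        raise PhyexpError("incomplete event labels: run label_events first")
    parents = _lca_table(tree)
    leaves = tree.get_terminals()
    # ancestors of each leaf, root last
    anc: dict[Clade, list[Clade]] = {}
    for leaf in leaves:
        chain = [leaf]
        while chain[-1] in parents:
            chain.append(parents[chain[-1]])
        anc[leaf] = chain
    leaf_sp = {l: species.species_of(l.name) for l in leaves}
    # species counts per clade
    counts: dict[Clade, dict[str, int]] = {}
    for clade in tree.find_clades(order="postorder"):
        if clade.is_terminal():
            counts[clade] = {leaf_sp[clade]: 1}
        else:
            acc: dict[str, int] = {}
            for ch in clade.clades:
                for sp, k in counts[ch].items():
                    acc[sp] = acc.get(sp, 0) + k
            counts[clade] = acc

    out = []
    for a, b in combinations(sorted(leaves, key=lambda l: l.name), 2):
        set_b = set(anc[b])
        lca = next(c for c in anc[a] if c in set_b)
        side_a = anc[a][anc[a].index(lca) - 1] if anc[a][0] is not lca else lca
        side_b = anc[b][anc[b].index(lca) - 1] if anc[b][0] is not lca else lca
        if leaf_sp[a] == leaf_sp[b] or labels[lca] == DUPLICATION:
            rel = "paralog"
        else:
            na = counts[side_a].get(leaf_sp[a], 0)
            nb = counts[side_b].get(leaf_sp[b], 0)
            if na == 1 and nb == 1:
                rel = "one-to-one"
            elif na == 1:
                rel = "one-to-many"
            elif nb == 1:
                rel = "many-to-one"
            else:
                rel = "many-to-many"
        out.append(OrthologyRelation(a.name, b.name, rel))
    return out


def transfer_annotations(
    relations: list[OrthologyRelation],
    source_annotations: dict[str, tuple[str, ...]],
    source_species: str,
    species: SpeciesMap,
    focal: str | None = None,
) -> list[AnnotationTransfer]:
    """Copy GO terms from annotated source-species orthologs.

    One-to-one orthology transfers with confidence 'direct'; several genes
    sharing a single annotated source ortholog (many-to-one from the
    receiving side) transfer with confidence 'tentative'.  Genes with no
    annotated source ortholog, or with several candidate source genes,
    yield no record.
    """
    candidates: dict[str, list[tuple[str, str]]] = {}
    for rel in relations:
        for gene, other in ((rel.gene_a, rel.gene_b), (rel.gene_b, rel.gene_a)):
            if species.species_of(other) != source_species:
                continue
            if focal is not None and species.species_of(gene) != focal:
                continue
            if species.species_of(gene) == source_species:
                continue
            # mirror the relation to the receiving gene's perspective
            r = rel.relation
            if gene == rel.gene_b:
                r = {"one-to-many": "many-to-one", "many-to-one": "one-to-many"}.get(r, r)
            if r in ("one-to-one", "many-to-one"):
                candidates.setdefault(gene, []).append((other, r))
    out = []
    for gene in sorted(candidates):
        sources = candidates[gene]
        annotated = [(s, r) for s, r in sources if source_annotations.get(s)]
        if len({s for s, _ in annotated}) != 1:
            continue  # no annotated ortholog, or ambiguous sources
        source, rel = annotated[0]
        out.append(
            AnnotationTransfer(
                gene,
                source,
                tuple(source_annotations[source]),
                "direct" if rel == "one-to-one" else "tentative",
            )
        )
    return out


def labeled_newick(tree: Tree, labels: EventLabel) -> str:
    """Newick text with event labels as internal-node comments (D/S)."""
    import copy

    mapping = {id(c): e for c, e in labels.labels.items()}
    clone = copy.deepcopy(tree)
    for orig, new in zip(tree.find_clades(), clone.find_clades()):
        if id(orig) in mapping:
            new.comment = "D" if mapping[id(orig)] == DUPLICATION else "S"
    return write_newick(clone)
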