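"""Domain types and readers/writers for FASTA, Newick and TSV mapping files.

Sequence sets are plain lists of :class:`ProteinSequence` /
:class:`CodingSequence` records; gene trees are ``Bio.Phylo`` trees.  All
readers normalise to upper case and preserve input order; duplicate gene
identifiers are an error at read time because every downstream stage keys on
them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO

from typing import Iterable, Sequence

from Bio import Phylo
from Bio.Phylo.BaseTree import Clade, Tree

__all__ = [
    "PhyexpError",
    "DuplicateIdError",
    "NewickParseError",
    "ProteinSequence",
    "CodingSequence",
    "SpeciesMap",
    "OutgroupRanking",
    "read_fasta",
    "write_fasta",
    "parse_newick",
    "write_newick",
    "read_species_map",
    "write_species_map",
    "read_annotations",
    "write_annotations",
    "root_tree",
]

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX-")
DNA_ALPHABET = set("ACGTN-")

STOP_CODONS = {"TAA", "TAG", "TGA"}


class PhyexpError(Exception):
    """Base class for all package errors."""


class DuplicateIdError(PhyexpError):
    pass


class NewickParseError(PhyexpError):
    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message if offset is None else f"{message} (offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence (20-letter alphabet plus X; '-' allowed in
    aligned records)."""

    gene_id: str
    residues: str

    def __post_init__(self):
        if not self.gene_id or not self.residues:
            raise PhyexpError("protein record needs a non-empty id and sequence")
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            raise PhyexpError(
                f"invalid residues {sorted(bad)} in protein {self.gene_id!r}"
            )

    @property
    def seq(self) -> str:
        return self.residues

    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CodingSequence:
    """A DNA coding sequence (ACGT plus N; '-' allowed in aligned records).

    Frame/stop validation is deliberately deferred to :meth:`validate_cds`,
    invoked by the dS path: CpG profiling accepts any CDS-like sequence.
    """

    gene_id: str
    nucleotides: str

    def __post_init__(self):
        if not self.gene_id or not self.nucleotides:
            raise PhyexpError("CDS record needs a non-empty id and sequence")
        bad = set(self.nucleotides) - DNA_ALPHABET
        if bad:
            raise PhyexpError(
                f"invalid bases {sorted(bad)} in CDS {self.gene_id!r}"
            )

    @property
    def seq(self) -> str:
        return self.nucleotides

    def ungapped(self) -> str:
        return self.nucleotides.replace("-", "")

    def __len__(self) -> int:
        return len(self.nucleotides)

    def validate_cds(self) -> None:
        """Require length divisible by 3 and no internal stop codon."""
        s = self.ungapped()
        if len(s) % 3:
            raise PhyexpError(
                f"CDS {self.gene_id!r} length {len(s)} not divisible by 3"
            )
        for i in range(0, len(s) - 3, 3):
            if s[i : i + 3] in STOP_CODONS:
                raise PhyexpError(
                    f"internal stop codon at position {i} in CDS {self.gene_id!r}"
                )


@dataclass
class SpeciesMap:
    """Total mapping from gene_id to a short species code.

    The primary mechanism is an explicit TSV table; as a fallback,
    identifiers of the form ``SPECIES|gene`` resolve from their prefix.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    species_list: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.species_list is not None:
            extra = set(self.mapping.values()) - set(self.species_list)
            if extra:
                raise PhyexpError(f"species codes {sorted(extra)} not declared")

    def species_of(self, gene_id: str) -> str:
        if gene_id in self.mapping:
            return self.mapping[gene_id]
        if "|" in gene_id:
            sp = gene_id.split("|", 1)[0]
            if self.species_list is None or sp in self.species_list:
                return sp
        raise PhyexpError(f"gene {gene_id!r} not resolvable to a species")

    def __contains__(self, gene_id: str) -> bool:
        try:
            self.species_of(gene_id)
            return True
        except PhyexpError:
            return False

    @property
    def species(self) -> set[str]:
        out = set(self.mapping.values())
        if self.species_list:
            out |= set(self.species_list)
        return out


@dataclass(frozen=True)
class OutgroupRanking:
    """Species codes ordered from most external to least."""

    ranking: tuple[str, ...]

    def __post_init__(self):
        if not self.ranking:
            raise PhyexpError("outgroup ranking must be non-empty")

    def __iter__(self):
        return iter(self.ranking)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, kind: str = "protein"):
    """Read a FASTA file into a list of sequence records.

    ``kind`` selects the record type ('protein' or 'dna').  Sequences are
    upper-cased; record order is preserved; a duplicated header is an error.
    """
    cls = ProteinSequence if kind == "protein" else CodingSequence
    records: list = []
    seen: set[str] = set()
    gene_id, chunks = None, []

    def flush():
        if gene_id is None:
            return
        if gene_id in seen:
            raise DuplicateIdError(f"duplicate FASTA id {gene_id!r}")
        seen.add(gene_id)
        records.append(cls(gene_id, "".join(chunks).upper()))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                gene_id = line[1:].split()[0]
                chunks = []
            else:
                if gene_id is None:
                    raise PhyexpError(f"FASTA {path}: sequence before first header")
                chunks.append(line)
        flush()
    return records


def write_fasta(records: Iterable, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            s = rec.seq
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick


def _check_newick(text: str) -> None:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError("unbalanced ')'", offset=i)
    if depth != 0:
        raise NewickParseError("unbalanced '('", offset=len(text))
    if ";" not in text:
        raise NewickParseError("missing terminal ';'", offset=len(text))


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a rooted ``Bio.Phylo`` tree."""
    _check_newick(text)
    try:
        tree = Phylo.read(StringIO(text), "newick")
    except Exception as exc:  # malformed beyond the paren pre-check
        raise NewickParseError(str(exc)) from exc
    tree.rooted = True
    return tree


def _clade_to_newick(clade: Clade) -> str:
    if clade.clades:
        inner = ",".join(_clade_to_newick(c) for c in clade.clades)
        out = f"({inner})"
        if clade.name:
            out += clade.name
    else:
        out = clade.name or ""
    if clade.branch_length is not None:
        out += f":{clade.branch_length:.6f}"
    if getattr(clade, "comment", None):
        out += f"[{clade.comment}]"
    return out


def write_newick(tree: Tree) -> str:
    """Serialise a tree to Newick; branch lengths to 6 decimals, omitted
    where absent; node comments emitted in square brackets."""
    return _clade_to_newick(tree.root) + ";"


# ---------------------------------------------------------------------------
# TSV tables


def read_species_map(path, species_list: Sequence[str] | None = None) -> SpeciesMap:
    mapping: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_id", "species_code"]:
            raise PhyexpError(
                f"{path}: expected header 'gene_id\\tspecies_code', got {header!r}"
            )
        for line in fh:
            if not line.strip():
                continue
            gene, sp = line.rstrip("\n").split("\t")[:2]
            if gene in mapping:
                raise DuplicateIdError(f"duplicate gene {gene!r} in species map")
            mapping[gene] = sp
    return SpeciesMap(mapping, tuple(species_list) if species_list else None)


def write_species_map(smap: SpeciesMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tspecies_code\n")
        for gene in sorted(smap.mapping):
            fh.write(f"{gene}\t{smap.mapping[gene]}\n")


def read_annotations(path) -> dict[str, tuple[str, ...]]:
    """Read a gene→GO-terms table (terms comma-separated in column 2)."""
    out: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "gene_id":
            raise PhyexpError(f"{path}: expected 'gene_id' in first column")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            gene = parts[0]
            terms = tuple(t for t in parts[1].split(",") if t) if len(parts) > 1 else ()
            out[gene] = terms
    return out


def write_annotations(annotations: dict[str, tuple[str, ...]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgo_terms\n")
        for gene in sorted(annotations):
            fh.write(f"{gene}\t{','.join(annotations[gene])}\n")


# ---------------------------------------------------------------------------
# Rooting


def _leaf_names(clade: Clade) -> frozenset[str]:
    return frozenset(t.name for t in clade.get_terminals())


def root_tree(tree: Tree, ranking: OutgroupRanking, species: SpeciesMap) -> Tree:
    """Root a gene tree on the most external ranked outgroup present.

    The root is placed on the branch separating the smallest clade holding
    all genes of the highest-ranked outgroup species from the rest.  If the
    outgroup genes are not monophyletic in the unrooted topology, the edge
    maximising outgroup-side purity (Jaccard overlap with the outgroup leaf
    set) is used and a warning is emitted.  With no ranked species present,
    falls back to midpoint rooting on the longest leaf-to-leaf path, ties
    broken toward the lexicographically smallest leaf pair.
    """
    leaves = tree.get_terminals()
    if len(leaves) < 2:
        raise PhyexpError("cannot root a tree with fewer than 2 leaves")
    leaf_species = {t.name: species.species_of(t.name) for t in leaves}
    all_names = frozenset(leaf_species)

    outgroup: frozenset[str] | None = None
    for sp in ranking:
        og = frozenset(n for n, s in leaf_species.items() if s == sp)
        if og and og != all_names:
            outgroup = og
            break

    if outgroup is None:
        return _midpoint_root(tree)

    # score every edge (= every non-root clade) by Jaccard overlap between
    # one side of its split and the outgroup leaf set
    best = None
    for clade in tree.find_clades():
        if clade is tree.root:
            continue
        side = _leaf_names(clade)
        for cand in (side, all_names - side):
            j = len(cand & outgroup) / len(cand | outgroup)
            key = (-j, len(cand), tuple(sorted(cand)))
            if best is None or key < best[0]:
                best = (key, clade, cand)
    assert best is not None
    key, clade, cand = best
    purity = -key[0]
    if purity < 1.0:
        warnings.warn(
            "outgroup genes are not monophyletic; rooting on the edge with "
            f"maximal outgroup-side purity (Jaccard {purity:.2f})"
        )
    bl = clade.branch_length
    tree.root_with_outgroup(clade, outgroup_branch_length=(bl or 0.0) / 2)
    tree.rooted = True
    return tree


def _midpoint_root(tree: Tree) -> Tree:
    leaves = sorted(tree.get_terminals(), key=lambda t: t.name)
    best = None
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            key = (-tree.distance(a, b), a.name, b.name)
            if best is None or key < best[0]:
                best = (key, a, b)
    assert best is not None
    _, a, b = best
    dmax = -best[0][0]
    if dmax <= 0:
        return tree
    # walk from a to b; the midpoint lies dmax/2 from a along the path
    path = [a] + tree.trace(a, b)
    depth = {c: len(tree.get_path(c)) for c in path if c is not tree.root}
    half = dmax / 2
    acc = 0.0
    for prev, nxt in zip(path, path[1:]):
        step = tree.distance(prev, nxt)
        if acc + step >= half - 1e-12:
            # midpoint sits on the edge between prev and nxt; the child end
            # of that edge is the deeper of the two in the current rooting
            child = max((prev, nxt), key=lambda c: depth.get(c, 0))
            # distance from the child node up to the midpoint
            d_child_mid = (acc + step - half) if child is nxt else (half - acc)
            if child is tree.root:
                return tree
            bl = child.branch_length or 0.0
            tree.root_with_outgroup(
                child, outgroup_branch_length=min(max(d_child_mid, 0.0), bl)
            )
            tree.rooted = True
            return tree
        acc += step
    return tree
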