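"""Generators for gene families, paralog pairs and CpG cohorts with ground truth.

Every generator is a pure function of its configuration and seed.  Gene
families evolve along a known species tree: each lineage entering a branch
duplicates a Poisson(lambda) number of times (daughters continue but do not
re-duplicate within the same branch, so the expected duplication count per
branch per incoming gene is exactly lambda) and is lost with Poisson(mu)
probability.  Focal-lineage expansions of requested sizes are injected as
forced duplications on the focal terminal branch.  Sequences are emitted
without indels, so the true alignment is the sequence set itself.

Paralog-pair fixtures isolate the synonymous-distance estimator: ancestral
codons are drawn from the five amino acids whose codon families are purely
four-fold degenerate (Ala/Gly/Pro/Thr/Val), so each codon carries exactly
one synonymous site and third positions evolve as genuine 4-state
Jukes-Cantor sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from Bio.Phylo.BaseTree import Clade, Tree

from .core_io import (
    CodingSequence,
    OutgroupRanking,
    PhyexpError,
    ProteinSequence,
    SpeciesMap,
    parse_newick,
    write_annotations,
    write_fasta,
    write_newick,
    write_species_map,
)
from .divergence import GENETIC_CODE
from .reconciliation import DUPLICATION, SPECIATION, EventLabel
from .expansion import detect_inparalog_groups

__all__ = [
    "SimulationConfig",
    "SimulatedFamily",
    "simulate_gene_family",
    "simulate_paralog_pair",
    "simulate_cpg_classes",
    "make_fixture_proteome",
    "enumerate_gene_trees",
    "DEFAULT_SPECIES_TREE",
    "DEFAULT_RANKING",
]

# five-species study tree: focal aphid-like species, its closest included
# relative (louse-like), two more distant insects, one external outgroup
DEFAULT_SPECIES_TREE = (
    "(((APIS:0.30,PHUM:0.30):0.20,(DMEL:0.35,TCAS:0.35):0.15):0.30,HSAP:0.80);"
)
DEFAULT_RANKING = OutgroupRanking(("HSAP", "TCAS", "DMEL"))

# codons of the five purely four-fold degenerate amino-acid families
_CLEAN_AAS = "AGPTV"
_CLEAN_CODONS = sorted(
    c for c, aa in GENETIC_CODE.items() if aa in _CLEAN_AAS
)
_CODONS_OF_AA: dict[str, list[str]] = {}
for c, aa in sorted(GENETIC_CODE.items()):
    if aa != "*":
        _CODONS_OF_AA.setdefault(aa, []).append(c)
_AAS = sorted(a for a in _CODONS_OF_AA)

# codons whose third position is four-fold degenerate
_FOURFOLD_THIRD = {
    c
    for c, aa in GENETIC_CODE.items()
    if aa != "*"
    and all(GENETIC_CODE[c[:2] + b] == aa for b in "ACGT")
}


@dataclass(frozen=True)
class SimulationConfig:
    species_tree: str = DEFAULT_SPECIES_TREE
    dup_rate: float = 0.0          # Poisson duplications per branch per gene
    loss_rate: float = 0.0         # Poisson loss events per branch per gene
    focal: str = "APIS"
    expansion_sizes: tuple[int, ...] = ()
    pre_duplications: int = 0      # forced dups on the branch above the focal parent
    codons: int = 300
    syn_rate: float = 0.8          # synonymous divergence per unit branch length
    aa_rate: float = 0.5           # amino-acid substitutions per site per unit length
    seed: int = 0

    def __post_init__(self):
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise PhyexpError("rates must be non-negative")


@dataclass
class SimulatedFamily:
    tree: Tree
    events: EventLabel
    true_groups: list[frozenset[str]]
    proteins: list[ProteinSequence]
    cds: list[CodingSequence]
    species_map: SpeciesMap
    config: SimulationConfig


class _AllLostError(PhyexpError):
    pass


def _build_dup_scaffold(n_dups, times, rng):
    """Random sequential-splitting scaffold for n_dups duplications on one
    branch; leaves are 'slot' dicts to be resolved at the branch bottom."""
    root = {"type": "slot"}
    live = [root]
    for t in times:
        chosen = live[rng.integers(len(live))]
        a, b = {"type": "slot"}, {"type": "slot"}
        chosen.clear()
        chosen.update({"type": "dup", "t": float(t), "children": [a, b]})
        live.remove(chosen)
        live.extend([a, b])
    return root


def _simulate_topology(config: SimulationConfig, rng):
    """Gene tree + true events + node depths along the species tree."""
    sp_tree = parse_newick(config.species_tree)
    events: dict[Clade, str] = {}
    depth: dict[Clade, float] = {}
    counter = [0]
    focal_leaf = next(
        (t for t in sp_tree.get_terminals() if t.name == config.focal), None
    )
    if focal_leaf is None:
        raise PhyexpError(f"focal species {config.focal!r} not in species tree")
    parents = {}
    for cl in sp_tree.find_clades():
        for ch in cl.clades:
            parents[ch] = cl
    focal_parent = parents.get(focal_leaf)
    expansions = list(config.expansion_sizes)

    def new_leaf(sp: str, d: float) -> Clade:
        counter[0] += 1
        leaf = Clade(name=f"{sp}|g{counter[0]:04d}")
        depth[leaf] = d
        return leaf

    def at_node(sp_clade: Clade, d: float) -> Clade | None:
        # one gene lineage sitting at a species-tree node
        if sp_clade.is_terminal():
            return new_leaf(sp_clade.name, d)
        kids = [into_branch(ch, d) for ch in sp_clade.clades]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        node = Clade(clades=kids)
        events[node] = SPECIATION
        depth[node] = d
        return node

    def into_branch(sp_clade: Clade, d_top: float) -> Clade | None:
        # one gene lineage entering the branch above sp_clade
        T = sp_clade.branch_length if sp_clade.branch_length is not None else 1.0
        if config.loss_rate > 0 and rng.poisson(config.loss_rate) >= 1:
            return None
        n = int(rng.poisson(config.dup_rate)) if config.dup_rate > 0 else 0
        forced = 0
        if sp_clade is focal_leaf and expansions:
            forced = expansions.pop(0) - 1
        elif sp_clade is focal_parent and config.pre_duplications and not hasattr(
            into_branch, "_pre_done"
        ):
            forced = config.pre_duplications
            into_branch._pre_done = True  # type: ignore[attr-defined]
        # injected expansions model a recent duplication wave: forced events
        # fall in the most recent 60% of the branch, background events anywhere
        times = np.sort(
            np.concatenate(
                [rng.uniform(0.0, T, size=n), rng.uniform(0.4 * T, T, size=forced)]
            )
        )
        n += forced
        scaffold = _build_dup_scaffold(n, times, rng)

        def resolve(item, d_item: float) -> Clade | None:
            if item["type"] == "slot":
                return at_node(sp_clade, d_top + T)
            kids = [resolve(c, d_top + item["t"]) for c in item["children"]]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            node = Clade(clades=kids)
            events[node] = DUPLICATION
            depth[node] = d_top + item["t"]
            return node

        return resolve(scaffold, d_top)

    root_clade = at_node(sp_tree.root, 0.0)
    if root_clade is None or root_clade.is_terminal():
        raise _AllLostError("family extinct or single-gene")
    gene_tree = Tree(root=root_clade, rooted=True)
    # branch lengths from depth differences
    for clade in gene_tree.find_clades():
        for ch in clade.clades:
            ch.branch_length = max(depth[ch] - depth[clade], 0.0)
    root_clade.branch_length = None
    return gene_tree, events, depth


_BASE_ORDER = "ACGT"


def _evolve_sequences(tree: Tree, config: SimulationConfig, rng):
    """Codon sequences along the gene tree: amino-acid replacements at
    aa_rate per site per unit length, synonymous third-position Jukes-Cantor
    churn (four-fold codons only) at syn_rate."""
    n = config.codons
    sense = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
    anc = [sense[i] for i in rng.integers(len(sense), size=n)]
    out: dict[str, str] = {}

    def jc_mutate_third(codon: str, d: float) -> str:
        if codon not in _FOURFOLD_THIRD:
            return codon
        p_change = 0.75 * (1 - np.exp(-4.0 * d / 3.0))
        if rng.random() < p_change:
            others = [b for b in _BASE_ORDER if b != codon[2]]
            return codon[:2] + others[rng.integers(3)]
        return codon

    def walk(clade: Clade, codons: list[str]):
        bl = clade.branch_length or 0.0
        if bl > 0:
            codons = list(codons)
            p_aa = min(config.aa_rate * bl, 0.95)
            d_syn = config.syn_rate * bl
            for i in range(n):
                if rng.random() < p_aa:
                    aa_now = GENETIC_CODE[codons[i]]
                    choices = [a for a in _AAS if a != aa_now]
                    aa_new = choices[rng.integers(len(choices))]
                    cods = _CODONS_OF_AA[aa_new]
                    codons[i] = cods[rng.integers(len(cods))]
                else:
                    codons[i] = jc_mutate_third(codons[i], d_syn)
        if clade.is_terminal():
            out[clade.name] = "".join(codons)
        for ch in clade.clades:
            walk(ch, codons)

    walk(tree.root, anc)
    return out


def simulate_gene_family(config: SimulationConfig, max_retries: int = 20) -> SimulatedFamily:
    """Simulate one gene family with its ground-truth event log.

    With all rates zero the gene tree is congruent with the species tree and
    every internal node is a speciation.  If the family goes extinct (all
    genes lost), simulation retries up to ``max_retries`` times with a
    warning-free reseed derived from the configured seed.
    """
    rng = np.random.default_rng(config.seed)
    last_exc: Exception | None = None
    for _ in range(max_retries):
        try:
            tree, events, _ = _simulate_topology(config, rng)
            break
        except _AllLostError as exc:
            last_exc = exc
    else:
        raise PhyexpError(f"family extinct after {max_retries} retries: {last_exc}")
    label = EventLabel(labels=dict(events))
    smap = SpeciesMap(
        {t.name: t.name.split("|", 1)[0] for t in tree.get_terminals()}
    )
    truth = detect_inparalog_groups(tree, label, config.focal, smap)
    seqs = _evolve_sequences(tree, config, rng)
    cds = [CodingSequence(g, seqs[g]) for g in sorted(seqs)]
    proteins = [
        ProteinSequence(
            c.gene_id,
            "".join(GENETIC_CODE[c.seq[i : i + 3]] for i in range(0, len(c.seq), 3)),
        )
        for c in cds
    ]
    return SimulatedFamily(
        tree=tree,
        events=label,
        true_groups=[g.members for g in truth],
        proteins=proteins,
        cds=cds,
        species_map=smap,
        config=config,
    )


# ---------------------------------------------------------------------------
# paralog pairs for dS recovery


def simulate_paralog_pair(true_ds: float, codons: int, seed: int):
    """A codon-sequence pair diverged purely synonymously to ``true_ds``.

    Each side accumulates true_ds/2 substitutions per synonymous site at the
    four-fold third positions under Jukes-Cantor dynamics; first and second
    positions never change, so dN is exactly zero.
    """
    if true_ds < 0:
        raise PhyexpError("true_dS must be non-negative")
    rng = np.random.default_rng(seed)
    idx = rng.integers(len(_CLEAN_CODONS), size=codons)
    anc = np.array([list(_CLEAN_CODONS[i]) for i in idx])  # (codons, 3)
    t = true_ds / 2.0
    p_change = 0.75 * (1 - np.exp(-4.0 * t / 3.0))
    base_idx = {b: i for i, b in enumerate(_BASE_ORDER)}

    def mutate(third: np.ndarray) -> np.ndarray:
        third = third.copy()
        hit = rng.random(codons) < p_change
        if hit.any():
            cur = np.array([base_idx[b] for b in third[hit]])
            shift = rng.integers(1, 4, size=cur.size)
            new = (cur + shift) % 4
            third[hit] = np.array(list(_BASE_ORDER))[new]
        return third

    rows = []
    for name in ("dup_a", "dup_b"):
        seq = anc.copy()
        seq[:, 2] = mutate(anc[:, 2])
        rows.append(CodingSequence(name, "".join(seq.ravel())))
    return rows[0], rows[1]


# ---------------------------------------------------------------------------
# CpG cohorts


def simulate_cpg_classes(
    n_per_class,
    class_means,
    class_sds,
    length: int = 300,
    gc: float = 0.4,
    seed: int = 0,
):
    """CDS cohort with per-class CpG O/E targets.

    Sequences are first-order Markov chains over ACGT with the C->G
    transition probability scaled toward each gene's target O/E (drawn from
    the class Normal); internal stop codons are repaired to sense codons.
    Returns (records, labels, targets).
    """
    if length % 3:
        raise PhyexpError("length must be divisible by 3")
    rng = np.random.default_rng(seed)
    pG = pC = gc / 2.0
    pA = pT = (1.0 - gc) / 2.0
    bound = 0.95 / pG
    targets_all, labels = [], []
    for k, (n, m, s) in enumerate(zip(n_per_class, class_means, class_sds)):
        if m <= 0:
            raise PhyexpError("class means must be positive")
        if m > bound:
            raise PhyexpError(
                f"target O/E {m} unattainable (bound {bound:.2f} at GC={gc})"
            )
        targets_all.append(np.clip(rng.normal(m, s, size=n), 0.02, bound))
        labels.extend([k] * n)
    targets = np.concatenate(targets_all)
    n_total = targets.size

    seq = np.empty((n_total, length), dtype=np.int8)  # 0=A 1=C 2=G 3=T
    r0 = rng.random(n_total)
    seq[:, 0] = (r0 >= pA) + (r0 >= pA + pC) + (r0 >= pA + pC + pG)
    # conditional P(G | prev C) solving O/E = g / ((1-fC) pG + fC g) for the
    # target, with the stationary C frequency fC refined alongside (the
    # renormalisation after C inflates fC slightly)
    fC = np.full(n_total, pC)
    g = np.clip(targets * pG, 1e-4, 0.95)
    for _ in range(4):
        g = np.clip(targets * (1 - fC) * pG / np.maximum(1 - targets * fC, 1e-6), 1e-4, 0.95)
        fC = pC / np.maximum(1 - pC * ((1 - g) / (1 - pG) - 1), 1e-6)
    pG_mod = g
    scale = (1.0 - pG_mod) / (1.0 - pG)
    for i in range(1, length):
        prevC = seq[:, i - 1] == 1
        pg = np.where(prevC, pG_mod, pG)
        sc = np.where(prevC, scale, 1.0)
        c1 = pA * sc
        c2 = c1 + pC * sc
        c3 = c2 + pg
        r = rng.random(n_total)
        seq[:, i] = (r >= c1).astype(np.int8) + (r >= c2) + (r >= c3)

    # repair stop codons in frame without touching any C-G adjacency:
    # TAA/TAG -> TAT (Tyr), TGA -> TGG (Trp)
    cod = seq.reshape(n_total, length // 3, 3)
    isT = cod[:, :, 0] == 3
    stop_ta = isT & (cod[:, :, 1] == 0) & ((cod[:, :, 2] == 0) | (cod[:, :, 2] == 2))
    stop_tga = isT & (cod[:, :, 1] == 2) & (cod[:, :, 2] == 0)
    cod[:, :, 2] = np.where(stop_ta, 3, cod[:, :, 2])
    cod[:, :, 2] = np.where(stop_tga, 2, cod[:, :, 2])

    lut = np.frombuffer(b"ACGT", dtype="S1")
    records = [
        CodingSequence(f"cpg{i:05d}", bytes(lut[row].tobytes()).decode())
        for i, row in enumerate(seq)
    ]
    return records, labels, targets.tolist()


# ---------------------------------------------------------------------------
# full miniature input set


def make_fixture_proteome(
    out_dir,
    n_families: int = 50,
    expansion_sizes: tuple[int, ...] = (5, 10, 20),
    base_config: SimulationConfig | None = None,
    seed: int = 42,
    annotate_species: str = "DMEL",
):
    """Write a complete miniature pipeline input set with ground truth.

    The first ``len(expansion_sizes)`` families carry injected focal
    expansions; the rest evolve under the background rates.  Produces
    proteins.faa, cds.fna, species_map.tsv, annotations.tsv, true_trees.txt
    and truth.json under ``out_dir``; files are byte-identical for a fixed
    seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = base_config or SimulationConfig()
    rng = np.random.default_rng(seed)
    families = []
    for f in range(n_families):
        sizes = (expansion_sizes[f],) if f < len(expansion_sizes) else ()
        cfg = replace(
            base,
            expansion_sizes=sizes,
            seed=int(rng.integers(2**31 - 1)),
        )
        families.append(simulate_gene_family(cfg))

    proteins, cds, mapping = [], [], {}
    truth = {"families": [], "seed": seed, "expansion_sizes": list(expansion_sizes)}
    tree_lines = []
    for f, fam in enumerate(families):
        prefix = f"F{f:03d}"
        rename = {
            p.gene_id: f"{p.gene_id.split('|')[0]}|{prefix}{p.gene_id.split('|')[1]}"
            for p in fam.proteins
        }
        for t in fam.tree.get_terminals():
            t.name = rename[t.name]
        proteins += [ProteinSequence(rename[p.gene_id], p.residues) for p in fam.proteins]
        cds += [CodingSequence(rename[c.gene_id], c.nucleotides) for c in fam.cds]
        for old, new in rename.items():
            mapping[new] = old.split("|")[0]
        truth["families"].append(
            {
                "id": prefix,
                "n_genes": len(fam.proteins),
                "true_groups": [sorted(rename[g] for g in grp) for grp in fam.true_groups],
            }
        )
        tree_lines.append(f"{prefix}\t{write_newick(fam.tree)}")

    smap = SpeciesMap(mapping)
    annotations = {}
    for gene, sp in sorted(mapping.items()):
        if sp == annotate_species and rng.random() < 0.8:
            terms = tuple(
                f"GO:{int(rng.integers(1, 9999)):07d}"
                for _ in range(int(rng.integers(1, 4)))
            )
            annotations[gene] = terms

    write_fasta(proteins, out / "proteins.faa")
    write_fasta(cds, out / "cds.fna")
    write_species_map(smap, out / "species_map.tsv")
    write_annotations(annotations, out / "annotations.tsv")
    (out / "true_trees.txt").write_text("\n".join(tree_lines) + "\n")
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return truth


# ---------------------------------------------------------------------------
# exhaustive enumeration of species-labeled rooted binary shapes


def _canon(struct) -> str:
    if isinstance(struct, str):
        return struct
    return "(" + ",".join(sorted(_canon(s) for s in struct)) + ")"


def enumerate_shapes(n_leaves: int, species=("A", "B", "C")):
    """All rooted binary trees with leaves labeled by species, up to
    isomorphism (gene identities do not affect species overlap)."""
    memo: dict[int, list] = {1: [s for s in species]}

    def trees(n):
        if n in memo:
            return memo[n]
        out = {}
        for k in range(1, n // 2 + 1):
            for left in trees(k):
                for right in trees(n - k):
                    t = (left, right)
                    out[_canon(t)] = t
        memo[n] = list(out.values())
        return memo[n]

    return trees(n_leaves)


def enumerate_gene_trees(max_leaves: int, species=("A", "B", "C")):
    """Yield Bio.Phylo trees for every distinct species-labeled shape with
    2..max_leaves leaves; leaf names are unique gene ids 'SP|gN'."""
    for n in range(2, max_leaves + 1):
        for struct in enumerate_shapes(n, species):
            counter = [0]

            def build(s) -> Clade:
                if isinstance(s, str):
                    counter[0] += 1
                    return Clade(name=f"{s}|g{counter[0]}")
                return Clade(clades=[build(x) for x in s])

            yield Tree(root=build(struct), rooted=True)
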