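"""Stage orchestration: search -> trees -> reconcile -> expansions; RBH -> dS; CpG.

Each stage reads its inputs and the previous stage's outputs from the run
directory and writes fixed-name TSV/Newick/JSON artifacts, so stages are
independently restartable and a run is reproducible byte-for-byte for a
fixed configuration and seed.  Family multiple alignments are expected as
inputs (or simulator products): sequences within a family must share a
length, otherwise the stage fails asking for aligned FASTA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .core_io import (
    OutgroupRanking,
    PhyexpError,
    parse_newick,
    read_annotations,
    read_fasta,
    read_species_map,
    root_tree,
    write_newick,
)
from .cpg import cpg_oe, oe_distribution, test_bimodality
from .divergence import DivergenceParams, classify_pairs, ds_histogram, pair_ds_dn
from .expansion import InParalogGroup, MergeParams, merge_groups, size_distribution
from .homology import (
    SearchParams,
    TrimParams,
    alignment_score,
    distance_matrix,
    local_align,
    nj_tree,
    rbh_pairs,
    trim_alignment,
)
from .reconciliation import (
    infer_orthology,
    label_events,
    labeled_newick,
    transfer_annotations,
)

STAGE_OUTPUTS = {
    "search": ["hits.tsv", "families.tsv", "rbh.tsv"],
    "trees": ["trees"],
    "reconcile": ["labeled", "relations.tsv", "transfers.tsv"],
    "expansions": ["groups.tsv", "expansion_families.tsv", "size_histogram.tsv"],
    "ds": ["pairs_ds.tsv", "ds_histogram.tsv"],
    "cpg": ["cpg_profiles.tsv", "cpg_report.json"],
    "report": ["report.json"],
}

STAGE_PREREQS = {
    "search": [],
    "trees": ["search"],
    "reconcile": ["trees"],
    "expansions": ["reconcile"],
    "ds": ["search"],
    "cpg": [],
    "report": ["expansions", "ds", "cpg"],
}


@dataclass
class PipelineConfig:
    proteins: str = ""
    cds: str = ""
    species_map: str = ""
    annotations: str = ""
    trees: str = ""              # optional TSV 'family<TAB>newick'; skips NJ
    focal: str = "APIS"
    outgroup_ranking: tuple[str, ...] = ("HSAP",)
    source_species: str = "DMEL"
    distance_method: str = "scoredist"
    overlap_threshold: float = 0.0
    q_cov: float = 0.5
    # raw-score stand-in for the e-value 1e-3 search filter, calibrated for
    # ~300-residue proteins against a desk-scale database (null scores for
    # unrelated pairs top out well below this; true homologs score far above)
    s_min: float = 80.0
    gap_open: float = 11.0
    gap_extend: float = 1.0
    gap_threshold: float = 0.25
    conservation_threshold: float = 0.50
    merge_threshold: float = 0.5
    allelic_cutoff: float = 0.05
    ancient_cutoff: float = 1.5
    ds_bin_width: float = 0.05
    cpg_bin_width: float = 0.05
    seed: int = 0
    out_dir: str = "phyexp_out"

    @property
    def search_params(self) -> SearchParams:
        return SearchParams(
            q_cov=self.q_cov,
            s_min=self.s_min,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
        )

    @property
    def trim_params(self) -> TrimParams:
        return TrimParams(self.gap_threshold, self.conservation_threshold)

    @property
    def divergence_params(self) -> DivergenceParams:
        return DivergenceParams(
            allelic_cutoff=self.allelic_cutoff,
            ancient_cutoff=self.ancient_cutoff,
            bin_width=self.ds_bin_width,
        )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    extra = set(data) - known
    if extra:
        raise PhyexpError(f"unknown config keys: {sorted(extra)}")
    if "outgroup_ranking" in data:
        data["outgroup_ranking"] = tuple(data["outgroup_ranking"])
    return PipelineConfig(**data)


def _require(cfg: PipelineConfig, *paths: str):
    for p in paths:
        if not p:
            raise PhyexpError("required input path missing from config")
        if not Path(p).exists():
            raise PhyexpError(f"input not found: {p}")


def check_prereqs(cfg: PipelineConfig, stage: str) -> None:
    out = Path(cfg.out_dir)
    missing = []
    for pre in STAGE_PREREQS[stage]:
        for artifact in STAGE_OUTPUTS[pre]:
            if not (out / artifact).exists():
                missing.append(f"{artifact} (from stage '{pre}')")
    if missing:
        raise PhyexpError(
            f"stage '{stage}' prerequisites missing: {', '.join(missing)}"
        )


def _out(cfg: PipelineConfig) -> Path:
    p = Path(cfg.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


# ---------------------------------------------------------------------------


def stage_search(cfg: PipelineConfig) -> dict:
    """All-vs-all search, homolog graph, family components, focal RBH pairs."""
    _require(cfg, cfg.proteins, cfg.species_map)
    out = _out(cfg)
    proteins = read_fasta(cfg.proteins, kind="protein")
    smap = read_species_map(cfg.species_map)
    params = cfg.search_params

    hits = []
    n = len(proteins)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = proteins[i], proteins[j]
            if alignment_score(a, b, params) < params.s_min:
                continue
            h_ab = local_align(a, b, params)
            h_ba = local_align(b, a, params)
            if (h_ab.coverage > params.q_cov or h_ba.coverage > params.q_cov) and (
                h_ab.score >= params.s_min
            ):
                hits.append(h_ab)

    with open(out / "hits.tsv", "w") as fh:
        fh.write("query\tsubject\tscore\tcoverage\n")
        for h in sorted(hits, key=lambda h: (h.query_id, h.subject_id)):
            fh.write(f"{h.query_id}\t{h.subject_id}\t{h.score:.1f}\t{h.coverage:.4f}\n")

    # family components over the homolog graph
    parent = {p.gene_id: p.gene_id for p in proteins}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for h in hits:
        ra, rb = find(h.query_id), find(h.subject_id)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    comps: dict[str, list[str]] = {}
    for p in proteins:
        comps.setdefault(find(p.gene_id), []).append(p.gene_id)
    families = {
        f"F{i:04d}": sorted(members)
        for i, (_, members) in enumerate(sorted(comps.items()))
        if len(members) >= 2
    }
    with open(out / "families.tsv", "w") as fh:
        fh.write("family\tsize\tmembers\n")
        for fam, members in families.items():
            fh.write(f"{fam}\t{len(members)}\t{','.join(members)}\n")

    focal_seqs = [p for p in proteins if smap.species_of(p.gene_id) == cfg.focal]
    pairs = rbh_pairs(focal_seqs, params) if len(focal_seqs) >= 2 else []
    with open(out / "rbh.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")
    return {"n_proteins": n, "n_hits": len(hits), "n_families": len(families), "n_rbh_pairs": len(pairs)}


def _read_families(out: Path) -> dict[str, list[str]]:
    families = {}
    with open(out / "families.tsv") as fh:
        fh.readline()
        for line in fh:
            fam, _, members = line.rstrip("\n").split("\t")
            families[fam] = members.split(",")
    return families


def stage_trees(cfg: PipelineConfig) -> dict:
    """Per-family trees: provided Newick if configured, else trim ->
    distance -> NJ -> outgroup rooting."""
    check_prereqs(cfg, "trees")
    out = _out(cfg)
    (out / "trees").mkdir(exist_ok=True)
    smap = read_species_map(cfg.species_map)
    ranking = OutgroupRanking(cfg.outgroup_ranking)
    families = _read_families(out)

    provided = {}
    if cfg.trees:
        _require(cfg, cfg.trees)
        with open(cfg.trees) as fh:
            for line in fh:
                if line.strip():
                    fam, nwk = line.rstrip("\n").split("\t")
                    provided[fam] = nwk

    if provided:
        # provided trees are keyed by their own family ids; use them directly
        families = {fam: None for fam in provided}

    proteins = {p.gene_id: p for p in read_fasta(cfg.proteins, kind="protein")}
    n_built = 0
    for fam in sorted(families):
        if fam in provided:
            tree = parse_newick(provided[fam])
            tree = root_tree(tree, ranking, smap)
        else:
            members = families[fam]
            rows = [proteins[g] for g in members]
            lengths = {len(r.residues) for r in rows}
            if len(lengths) != 1:
                raise PhyexpError(
                    f"family {fam}: sequences differ in length; supply aligned "
                    "FASTA or per-family trees (multiple alignment is out of scope)"
                )
            aln = trim_alignment(rows, cfg.trim_params)
            if not aln:
                continue
            if len(members) == 2:
                from Bio.Phylo.BaseTree import Clade, Tree as _Tree

                d = distance_matrix(aln, cfg.distance_method)
                half = d[(members[0], members[1])] / 2
                root = Clade(
                    clades=[
                        Clade(name=members[0], branch_length=half),
                        Clade(name=members[1], branch_length=half),
                    ]
                )
                tree = _Tree(root=root, rooted=True)
            else:
                d = distance_matrix(aln, cfg.distance_method)
                tree = nj_tree(d)
                tree = root_tree(tree, ranking, smap)
        (out / "trees" / f"{fam}.nwk").write_text(write_newick(tree) + "\n")
        n_built += 1
    return {"n_trees": n_built}


def _iter_trees(out: Path):
    for path in sorted((out / "trees").glob("*.nwk")):
        yield path.stem, parse_newick(path.read_text())


def stage_reconcile(cfg: PipelineConfig) -> dict:
    """Species-overlap labeling, orthology relations, GO transfer."""
    check_prereqs(cfg, "reconcile")
    out = _out(cfg)
    (out / "labeled").mkdir(exist_ok=True)
    smap = read_species_map(cfg.species_map)
    annotations = read_annotations(cfg.annotations) if cfg.annotations else {}
    n_dup = n_spec = 0
    rel_rows, transfer_rows = [], []
    for fam, tree in _iter_trees(out):
        labels = label_events(tree, smap, cfg.overlap_threshold, focal=cfg.focal)
        n_dup += sum(1 for e in labels.labels.values() if e == "duplication")
        n_spec += sum(1 for e in labels.labels.values() if e == "speciation")
        (out / "labeled" / f"{fam}.nwk").write_text(labeled_newick(tree, labels) + "\n")
        relations = infer_orthology(tree, labels, smap)
        rel_rows += [(fam, r.gene_a, r.gene_b, r.relation) for r in relations]
        if annotations:
            for t in transfer_annotations(
                relations, annotations, cfg.source_species, smap, focal=cfg.focal
            ):
                transfer_rows.append(
                    (t.gene_id, t.source_gene_id, ",".join(t.go_terms), t.confidence)
                )
    with open(out / "relations.tsv", "w") as fh:
        fh.write("family\tgene_a\tgene_b\trelation\n")
        for row in sorted(rel_rows):
            fh.write("\t".join(row) + "\n")
    with open(out / "transfers.tsv", "w") as fh:
        fh.write("gene_id\tsource_gene_id\tgo_terms\tconfidence\n")
        for row in sorted(transfer_rows):
            fh.write("\t".join(row) + "\n")
    n_direct = sum(1 for r in transfer_rows if r[3] == "direct")
    return {
        "n_duplication_nodes": n_dup,
        "n_speciation_nodes": n_spec,
        "n_relations": len(rel_rows),
        "n_transfers_direct": n_direct,
        "n_transfers_tentative": len(transfer_rows) - n_direct,
    }


def stage_expansions(cfg: PipelineConfig) -> dict:
    """Focal in-paralog groups, 50%-overlap merge, size distribution."""
    check_prereqs(cfg, "expansions")
    out = _out(cfg)
    smap = read_species_map(cfg.species_map)
    from .expansion import detect_inparalog_groups

    groups: list[InParalogGroup] = []
    for fam, tree in _iter_trees(out):
        labels = label_events(tree, smap, cfg.overlap_threshold, focal=cfg.focal)
        groups += detect_inparalog_groups(tree, labels, cfg.focal, smap, tree_id=fam)
    with open(out / "groups.tsv", "w") as fh:
        fh.write("tree\tsize\tmembers\n")
        for g in sorted(groups, key=lambda g: (g.tree_id, sorted(g.members))):
            fh.write(f"{g.tree_id}\t{g.size}\t{','.join(sorted(g.members))}\n")
    fams = merge_groups(groups, MergeParams(cfg.merge_threshold))
    with open(out / "expansion_families.tsv", "w") as fh:
        fh.write("family_id\tsize\tmembers\n")
        for i, f in enumerate(fams):
            fh.write(f"E{i:04d}\t{f.size}\t{','.join(sorted(f.members))}\n")
    dist = size_distribution(fams)
    with open(out / "size_histogram.tsv", "w") as fh:
        fh.write("size\tcount\n")
        for s, c in dist["histogram"].items():
            fh.write(f"{s}\t{c}\n")
    return {
        "n_inparalog_groups": len(groups),
        "n_expansion_families": dist["n_families"],
        "largest_family": dist["largest"],
        "n_genes_in_families": dist["n_genes"],
    }


def stage_ds(cfg: PipelineConfig) -> dict:
    """NG86 dS/dN over the focal RBH pairs, classification and histogram."""
    check_prereqs(cfg, "ds")
    out = _out(cfg)
    if not (out / "rbh.tsv").exists():
        raise PhyexpError("stage 'ds' needs rbh.tsv: run 'search' first")
    _require(cfg, cfg.cds, cfg.proteins)
    proteins = {p.gene_id: p for p in read_fasta(cfg.proteins, kind="protein")}
    cds = {c.gene_id: c for c in read_fasta(cfg.cds, kind="dna")}
    pairs = []
    with open(out / "rbh.tsv") as fh:
        fh.readline()
        for line in fh:
            if line.strip():
                a, b = line.rstrip("\n").split("\t")
                if len(proteins[a].residues) != len(proteins[b].residues):
                    raise PhyexpError(
                        f"pair ({a}, {b}): protein rows differ in length; "
                        "supply aligned sequences"
                    )
                pairs.append(
                    pair_ds_dn(
                        proteins[a], proteins[b], cds[a], cds[b], trim=cfg.trim_params
                    )
                )
    params = cfg.divergence_params
    pairs = classify_pairs(pairs, params)
    with open(out / "pairs_ds.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\tdS\tdN\tstatus\n")
        for p in sorted(pairs, key=lambda p: (p.gene_a, p.gene_b)):
            ds = "NA" if p.ds is None else f"{p.ds:.4f}"
            dn = "NA" if p.dn is None else f"{p.dn:.4f}"
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{ds}\t{dn}\t{p.status}\n")
    hist = ds_histogram(pairs, params)
    with open(out / "ds_histogram.tsv", "w") as fh:
        fh.write("bin_start\tbin_end\tcount\n")
        for i, c in enumerate(hist.counts):
            fh.write(f"{hist.edges[i]:.2f}\t{hist.edges[i + 1]:.2f}\t{c}\n")
    tally = {s: sum(1 for p in pairs if p.status == s) for s in
             ("allelic_candidate", "paralog", "ancient", "saturated")}
    return {"n_pairs": len(pairs), **{f"n_{k}": v for k, v in tally.items()}}


def stage_cpg(cfg: PipelineConfig) -> dict:
    """Focal-genome CpG O/E profiles, distribution, bimodality verdict."""
    _require(cfg, cfg.cds, cfg.species_map)
    out = _out(cfg)
    smap = read_species_map(cfg.species_map)
    cds = read_fasta(cfg.cds, kind="dna")
    focal_cds = [c for c in cds if c.gene_id in smap and smap.species_of(c.gene_id) == cfg.focal]
    profiles, undefined = [], 0
    for c in focal_cds:
        try:
            profiles.append(cpg_oe(c))
        except PhyexpError:
            undefined += 1
    with open(out / "cpg_profiles.tsv", "w") as fh:
        fh.write("gene_id\tlength\tnC\tnG\tnCpG\toe\n")
        for p in sorted(profiles, key=lambda p: p.gene_id):
            fh.write(
                f"{p.gene_id}\t{p.length}\t{p.n_C}\t{p.n_G}\t{p.n_CpG}\t{p.oe_ratio:.4f}\n"
            )
    dist = oe_distribution(profiles, cfg.cpg_bin_width)
    report: dict = {"n_profiles": len(profiles), "n_undefined": undefined, "distribution": dist}
    if len(profiles) >= 50:
        res = test_bimodality([p.oe_ratio for p in profiles], seed=cfg.seed)
        report["bimodality"] = {
            "verdict": res.verdict,
            "delta_bic": round(res.delta_bic, 4),
            "means": [round(m, 4) for m in res.means],
            "sds": [round(s, 4) for s in res.sds],
            "weights": [round(w, 4) for w in res.weights],
        }
    else:
        report["bimodality"] = {"verdict": "not_tested", "reason": "fewer than 50 profiles"}
    (out / "cpg_report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return {"n_cpg_profiles": len(profiles), "cpg_verdict": report["bimodality"]["verdict"]}


STAGES = {
    "search": stage_search,
    "trees": stage_trees,
    "reconcile": stage_reconcile,
    "expansions": stage_expansions,
    "ds": stage_ds,
    "cpg": stage_cpg,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages in order and write a consistency-checked report."""
    out = _out(cfg)
    report: dict = {"version": __version__, "config": asdict(cfg), "stages": {}}
    for name in ("search", "trees", "reconcile", "expansions", "ds", "cpg"):
        report["stages"][name] = STAGES[name](cfg)
    exp = report["stages"]["expansions"]
    sizes_path = out / "size_histogram.tsv"
    total = 0
    with open(sizes_path) as fh:
        fh.readline()
        for line in fh:
            s, c = line.split("\t")
            total += int(s) * int(c)
    if total != exp["n_genes_in_families"]:
        raise PhyexpError("report inconsistency: histogram mass != genes in families")
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report
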