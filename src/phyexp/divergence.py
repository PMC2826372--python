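"""Codon-level dating of duplications: NG86 dS/dN with Jukes-Cantor correction.

Synonymous/nonsynonymous site counting follows the Nei-Gojobori (1986)
pathway method: per-codon fractional synonymous sites (mutations to stop
codons count as nonsynonymous), differences between codons resolved by
averaging over all minimal mutational pathways, pathways through stop
codons excluded when an alternative exists.  Proportions are corrected with
the Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p); p >= 3/4 saturates.

Paralog pairs are classified by dS against an allelic-variant cutoff
(default 0.05: pairs below it may be alleles of one locus assembled twice)
and an ancient-duplication cutoff (default 1.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from itertools import permutations

from .core_io import CodingSequence, PhyexpError, ProteinSequence
from .homology import TrimParams, trim_columns

__all__ = [
    "CodonAlignment",
    "SiteCounts",
    "DsDnEstimate",
    "ParalogPair",
    "DivergenceParams",
    "GENETIC_CODE",
    "thread_codons",
    "trim_codon_alignment",
    "count_sites_ng86",
    "estimate_ds_dn",
    "pair_ds_dn",
    "classify_pairs",
    "ds_histogram",
]

BASES = "ACGT"

# standard genetic code
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-aligned CDS rows; the gap unit is a whole codon '---'."""

    rows: tuple[tuple[str, str], ...]  # (gene_id, codon string)

    def __post_init__(self):
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1 or next(iter(lengths)) % 3:
            raise PhyexpError("codon alignment rows must share a length divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.rows[0][1]) // 3

    def codon_columns(self):
        for i in range(self.n_codons):
            yield tuple(s[3 * i : 3 * i + 3] for _, s in self.rows)


@dataclass(frozen=True)
class SiteCounts:
    S: float   # synonymous sites
    N: float   # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences
    codons: int


@dataclass(frozen=True)
class DsDnEstimate:
    ds: float | None
    dn: float | None
    ds_saturated: bool = False
    dn_saturated: bool = False


@dataclass
class ParalogPair:
    gene_a: str
    gene_b: str
    ds: float | None = None
    dn: float | None = None
    status: str = ""  # allelic_candidate | paralog | ancient | saturated


@dataclass(frozen=True)
class DivergenceParams:
    allelic_cutoff: float = 0.05
    ancient_cutoff: float = 1.5
    bin_width: float = 0.05
    reference_lines: tuple[float, ...] = (0.25, 0.35)
    include_allelic: bool = False

    def __post_init__(self):
        if not 0 < self.allelic_cutoff < self.ancient_cutoff:
            raise PhyexpError("require 0 < allelic cutoff < ancient cutoff")


def _is_stop(codon: str) -> bool:
    return GENETIC_CODE[codon] == "*"


@lru_cache(maxsize=None)
def syn_fraction_sites(codon: str) -> float:
    """Fractional synonymous sites of a sense codon (NG86).

    For each position, the fraction of the three possible single-base
    changes that preserve the amino acid; changes to stop codons are
    nonsynonymous.
    """
    if codon not in GENETIC_CODE or _is_stop(codon):
        raise PhyexpError(f"not a sense codon: {codon!r}")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if not _is_stop(mut) and GENETIC_CODE[mut] == aa:
                s += 1 / 3
    return s


def _step_synonymous(c1: str, c2: str) -> bool:
    return (not _is_stop(c1)) and (not _is_stop(c2)) and GENETIC_CODE[c1] == GENETIC_CODE[c2]


@lru_cache(maxsize=None)
def codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over minimal mutational pathways.

    Pathways passing through a stop codon are excluded when any stop-free
    pathway exists; otherwise all pathways contribute, with every step
    to/from a stop counted nonsynonymous.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return (0.0, 0.0)
    pathways = []
    for order in permutations(diff):
        cur = c1
        steps = []
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _is_stop(nxt) and nxt != c2:
                through_stop = True
            steps.append(1.0 if _step_synonymous(cur, nxt) else 0.0)
            cur = nxt
        pathways.append((through_stop, steps))
    usable = [p for p in pathways if not p[0]] or pathways
    sd = sum(sum(steps) for _, steps in usable) / len(usable)
    return (sd, len(diff) - sd)


def thread_codons(
    protein_aln: list[ProteinSequence],
    cds_a: CodingSequence,
    cds_b: CodingSequence,
) -> CodonAlignment:
    """Back-thread an aligned protein pair onto its coding sequences."""
    if len(protein_aln) != 2:
        raise PhyexpError("thread_codons expects exactly two aligned proteins")
    rows = []
    for prot, cds in zip(protein_aln, (cds_a, cds_b)):
        cds.validate_cds()
        nts = cds.ungapped()
        residues = prot.residues
        n_res = len(residues.replace("-", ""))
        if len(nts) != 3 * n_res:
            raise PhyexpError(
                f"{cds.gene_id}: CDS length {len(nts)} != 3 x {n_res} residues"
            )
        codons, k = [], 0
        for i, aa in enumerate(residues):
            if aa == "-":
                codons.append("---")
                continue
            codon = nts[3 * k : 3 * k + 3]
            trans = GENETIC_CODE.get(codon, "X")
            if aa != "X" and trans != aa:
                raise PhyexpError(
                    f"{cds.gene_id}: codon {codon} at column {i} translates to "
                    f"{trans}, protein row has {aa}"
                )
            codons.append(codon)
            k += 1
        rows.append((cds.gene_id, "".join(codons)))
    return CodonAlignment(tuple(rows))


def trim_codon_alignment(
    protein_aln: list[ProteinSequence],
    codon_aln: CodonAlignment,
    params: TrimParams | None = None,
) -> CodonAlignment:
    """Propagate protein-level column trimming to codons (the alignment
    filtering stage before dS estimation)."""
    kept = trim_columns([r.seq for r in protein_aln], params)
    rows = tuple(
        (gid, "".join(s[3 * j : 3 * j + 3] for j in kept))
        for gid, s in codon_aln.rows
    )
    if not kept:
        raise PhyexpError("no codon columns survive trimming")
    return CodonAlignment(rows)


def count_sites_ng86(codon_aln: CodonAlignment) -> SiteCounts:
    """NG86 site and difference counts for a pairwise codon alignment.

    Codon columns containing a gap or an ambiguous base are skipped; S is
    the per-codon synonymous-site fraction averaged over the two sequences.
    """
    if len(codon_aln.rows) != 2:
        raise PhyexpError("NG86 counting is pairwise")
    S = Sd = Nd = 0.0
    used = 0
    for ca, cb in codon_aln.codon_columns():
        if "-" in ca + cb or "N" in ca + cb:
            continue
        if _is_stop(ca) or _is_stop(cb):
            raise PhyexpError(f"stop codon in compared column: {ca}/{cb}")
        S += (syn_fraction_sites(ca) + syn_fraction_sites(cb)) / 2
        sd, nd = codon_pair_differences(ca, cb)
        Sd += sd
        Nd += nd
        used += 1
    if used == 0:
        raise PhyexpError("no comparable codons (all gapped or ambiguous)")
    return SiteCounts(S=S, N=3 * used - S, Sd=Sd, Nd=Nd, codons=used)


def _jc(p: float) -> tuple[float | None, bool]:
    if p >= 0.75:
        return None, True
    return -0.75 * math.log(1 - 4 * p / 3) + 0.0, False


def estimate_ds_dn(counts: SiteCounts) -> DsDnEstimate:
    """Jukes-Cantor-corrected dS and dN from NG86 counts."""
    if counts.S <= 0:
        raise PhyexpError("S = 0: dS undefined")
    ds, ds_sat = _jc(counts.Sd / counts.S)
    if counts.N <= 0:
        raise PhyexpError("N = 0: dN undefined")
    dn, dn_sat = _jc(counts.Nd / counts.N)
    return DsDnEstimate(ds=ds, dn=dn, ds_saturated=ds_sat, dn_saturated=dn_sat)


def pair_ds_dn(
    prot_a: ProteinSequence,
    prot_b: ProteinSequence,
    cds_a: CodingSequence,
    cds_b: CodingSequence,
    trim: TrimParams | None = None,
) -> ParalogPair:
    """Convenience: thread, optionally trim, count, estimate, for one pair."""
    codon_aln = thread_codons([prot_a, prot_b], cds_a, cds_b)
    if trim is not None:
        codon_aln = trim_codon_alignment([prot_a, prot_b], codon_aln, trim)
    est = estimate_ds_dn(count_sites_ng86(codon_aln))
    pair = ParalogPair(cds_a.gene_id, cds_b.gene_id, ds=est.ds, dn=est.dn)
    if est.ds_saturated:
        pair.status = "saturated"
    return pair


def classify_pairs(pairs: list[ParalogPair], params: DivergenceParams | None = None) -> list[ParalogPair]:
    """Assign status by dS thresholds (allelic / paralog / ancient /
    saturated)."""
    params = params or DivergenceParams()
    out = []
    for p in pairs:
        if p.ds is None:
            status = "saturated"
        elif p.ds <= params.allelic_cutoff:
            status = "allelic_candidate"
        elif p.ds <= params.ancient_cutoff:
            status = "paralog"
        else:
            status = "ancient"
        out.append(replace_status(p, status))
    return out


def replace_status(p: ParalogPair, status: str) -> ParalogPair:
    return ParalogPair(p.gene_a, p.gene_b, p.ds, p.dn, status)


@dataclass
class DsHistogram:
    bin_width: float
    counts: list[int]
    n_ancient: int
    n_saturated: int
    n_allelic_excluded: int
    reference_lines: tuple[float, ...] = (0.25, 0.35)
    edges: list[float] = field(default_factory=list)


def ds_histogram(pairs: list[ParalogPair], params: DivergenceParams | None = None) -> DsHistogram:
    """Binned dS counts over [0, ancient cutoff); ancient and saturated
    pairs tallied separately; allelic candidates excluded unless
    ``include_allelic`` is set."""
    params = params or DivergenceParams()
    n_bins = int(math.ceil(params.ancient_cutoff / params.bin_width))
    counts = [0] * n_bins
    n_ancient = n_sat = n_excl = 0
    for p in pairs:
        if p.status == "saturated" or p.ds is None:
            n_sat += 1
        elif p.status == "ancient":
            n_ancient += 1
        elif p.status == "allelic_candidate" and not params.include_allelic:
            n_excl += 1
        else:
            b = min(int(p.ds / params.bin_width), n_bins - 1)
            counts[b] += 1
    return DsHistogram(
        bin_width=params.bin_width,
        counts=counts,
        n_ancient=n_ancient,
        n_saturated=n_sat,
        n_allelic_excluded=n_excl,
        reference_lines=params.reference_lines,
        edges=[i * params.bin_width for i in range(n_bins + 1)],
    )
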