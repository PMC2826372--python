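# Methods

`phyexp` re-implements, as a tested and reusable pipeline, the comparative
analyses used to characterise a wave of lineage-specific gene duplication in
the pea aphid genome: phylome-style gene-tree reconciliation by species
overlap, detection and merging of lineage-specific in-paralog groups, dS
dating of recent paralog pairs, and the CpG observed/expected statistic used
as a DNA-methylation signature. Every stage runs on synthetic inputs with
ground truth, so the whole analysis is verifiable without any genome
download.

## Species-overlap reconciliation

Given a rooted gene tree whose leaves map to species, an internal node is
labelled a **duplication** when the species sets of two of its child
partitions intersect, and a **speciation** otherwise. The rule requires no
species tree and is exact on loss-free histories: a duplication's daughters
both descend to the same species set, while a speciation's daughters
partition the species. A fractional threshold generalises the strict rule
(duplication iff `|overlap| / |union|` over some child pair exceeds the
threshold); the default is 0, i.e. any shared species. Multifurcations are
evaluated over all child pairs, which reduces to the usual rule on binary
trees.

Losses confound the rule (a duplication that loses complementary copies in
complementary lineages masquerades as a speciation), which is why the
recovery guarantees below are stated for loss-free simulations; loss
scenarios can be simulated but are not asserted.

Orthology follows from the labels: a cross-species pair whose LCA is a
speciation is orthologous, with arity given by counting each species' genes
on its side of the LCA (one-to-one, one-to-many, many-to-many); same-species
pairs and duplication-LCA pairs are paralogs. GO terms transfer from an
annotated reference species (default `DMEL`) with confidence `direct` for
one-to-one orthology and `tentative` when several genes share a single
annotated source ortholog; ambiguous cases (several candidate source genes)
transfer nothing.

## Expansion detection

An **in-paralog group** is a maximal clade whose internal nodes are all
duplications and whose leaves all belong to the focal species; nested rounds
of duplication collapse into a single group, and groups of size 2 (a single
duplication) are included and tallied separately from size >= 3. Groups from
different trees are merged into non-redundant **expansion families**
whenever they share at least 50% of the smaller group's members; merging is
run to a transitive fixed point against cluster unions, which makes the
result independent of input order. The overlap denominator (smaller group)
and the fixed-point closure are our choices where the procedure is
underdetermined; both are the most permissive readings and keep merging
monotone in the threshold.

## Sequence search, trimming, distances, trees

Homology search is optimal Smith-Waterman with affine gaps (BLOSUM62, open
11, extend 1, via `Bio.Align.PairwiseAligner`). A hit is kept when the
aligned query span exceeds 50% of the query (`q_cov`) and the raw score
clears `s_min`. `s_min` stands in for a database e-value filter: e-value
calibration needs database-scale statistics that are meaningless at desk
scale. The library default is 50 BLOSUM62 units; the pipeline default is 80,
the Karlin-Altschul raw-score equivalent of e ~ 1e-3 for ~300-residue
queries against a few-hundred-protein database (measured null scores for
unrelated sequence pairs at this scale top out near 68, while genuinely
homologous pairs in the simulations score above 240).

Reciprocal best hits are computed over the filtered hit lists; best-hit
score ties resolve toward the smaller gene identifier with a warning.

Alignment columns are kept when their non-gap fraction is >= 25% and the
modal non-gap residue frequency is >= 50%. The conservation score is the
modal-residue frequency rather than a similarity-matrix score — a
reproducible convention that needs no matrix choice. A "super-alignment"
mode keeps columns with gaps in at most half the rows. Only `-` is a gap.

Distances are **scoredist** (normalised BLOSUM62 alignment score,
`d = -1.337 * 100 * ln(sigma)` with `sigma` floored at 0.01, per its
published definition including the calibration factor) or Poisson
(`-ln(1 - p)`). Trees are Saitou-Nei neighbor joining
(`Bio.Phylo.TreeConstruction`), exact on additive matrices; negative branch
lengths are clamped to zero with a warning. Gene trees are rooted on the
most external ranked outgroup species present (the smallest clade holding
all its genes); a non-monophyletic outgroup roots on the edge of maximal
outgroup-side purity (Jaccard) with a warning, and trees without any ranked
species fall back to midpoint rooting with lexicographic tie-breaks.

## dS dating of paralog pairs

Pairs come from within-genome RBH. Protein alignments are threaded back
onto their coding sequences codon-by-codon (protein gaps become `---`
codons), and the same column-trimming rule as above is propagated to codons
as the alignment-filtering stage before distance estimation — one trimming
implementation serves both the tree and dating paths.

Synonymous and nonsynonymous sites and differences follow Nei-Gojobori
(1986), chosen because the procedure is exactly specifiable and
hand-checkable; maximum-likelihood codon models are out of scope. Per codon,
the synonymous-site fraction counts the single-base neighbours preserving
the amino acid (mutations to stops count as nonsynonymous), averaged over
the two sequences; multi-position codon differences average over all
minimal mutational pathways, excluding pathways through stop codons when an
alternative exists and otherwise counting stop steps as nonsynonymous.
`S + N = 3 x compared codons` holds identically (a property test asserts
it). Proportions are Jukes-Cantor corrected,
`d = -(3/4) ln(1 - (4/3) p)`; `p >= 3/4` is flagged saturated rather than
given a number. Codon columns with gaps or ambiguous bases are skipped.

Pairs are classified by dS: `<= 0.05` **allelic candidates** (possibly two
alleles of one locus assembled separately, excluded from the histogram by
default), `(0.05, 1.5]` **paralogs**, `> 1.5` **ancient**, else
**saturated**. The dS histogram uses 0.05-wide bins with optional reference
lines at 0.25 and 0.35, the published mean ortholog dS between the pea
aphid and two other aphid species, consumed here as constants.

## CpG observed/expected and bimodality

Per coding sequence, `O/E = n_CpG * L / (n_C * n_G)` — observed CG
dinucleotides over the expectation from base composition, the dominant
convention in the methylation literature (a `(GC/2)^2` variant is available
by flag). Positions containing N are excluded from all counts. CpG counting
is strand- and orientation-sensitive by design. Historical germline
methylation depletes CpG (deamination of methylated cytosine), so a cohort
with two methylation classes shows a bimodal O/E distribution.

The published analysis made the bimodal/unimodal call visually; we impose a
reproducible surrogate: fit 1- and 2-component Gaussian mixtures
(sklearn EM, 20 k-means++ restarts, fixed seed) and call **bimodal** iff
`BIC(1) - BIC(2) > 10` and the component means are separated by more than
the sum of their standard deviations. At least 50 finite values are
required; a degenerate (constant) input is unimodal with a warning. The
verdict-rate guarantees (>= 95/100 seeds each way) are stated for Gaussian
cohorts at the design effect sizes (means 0.4/1.0, sd 0.15, n = 2000 per
class vs a single class at 0.7/0.2, n = 4000); sequence-realised cohorts
carry additional Poisson count noise in O/E that skews a single class at
short sequence lengths, so only the positive (two-class) verdict is
asserted on the sequence route.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of configuration plus seed.

**Gene families** evolve along a known 5-species tree (focal aphid-like
species, a louse-like sister, two more distant insects, one external
outgroup; branch lengths 0.15-0.8). Each lineage entering a branch
duplicates `Poisson(lambda)` times (daughters continue but do not
re-duplicate within that branch, so the expected duplication count per
branch per incoming gene is exactly `lambda` — a property test checks this
against the closed-form expectation) and dies with `Poisson(mu) >= 1`.
Injected focal expansions force the requested number of duplications on the
focal terminal branch, placed uniformly in its most recent 60%: the
generator emulates a *recent* duplication wave, and an injected duplication
arbitrarily close to the preceding speciation would be unresolvable by any
distance method (the separating internal edge has length approaching zero),
which is a statement about phylogenetics, not about this implementation.
Sequences evolve without indels (the true alignment is the sequence set;
real data needs an external aligner, which is out of scope), with
amino-acid replacements at a per-site rate and synonymous third-position
churn at four-fold sites. Event logs, true in-paralog groups and trees are
recorded as ground truth.

**Paralog pairs** for dS recovery draw ancestral codons only from the five
purely four-fold-degenerate codon families (Ala/Gly/Pro/Thr/Val), so every
codon carries exactly one synonymous site and third positions evolve as
genuine 4-state Jukes-Cantor sites with `true_dS / 2` substitutions per
site per branch. This isolates the estimator: NG86 + JC is then unbiased
for the injected dS (recovered means are within +/-0.005 at n = 500), and
dN is exactly zero. Real codon evolution mixes degeneracy classes and
violates JC, so this is a statement about the estimator's correctness, not
about its accuracy on real genes.

**CpG cohorts** are first-order Markov chains over ACGT (GC content 0.4)
whose C->G transition probability is solved from the target O/E by
inverting `O/E = g / ((1 - f_C) p_G + f_C g)` with the stationary C
frequency refined in a short fixed point; per-gene targets are Normal draws
from the class parameters. In-frame stop codons are repaired
(TAA/TAG -> TAT, TGA -> TGG), chosen because these replacements cannot
create or destroy a C-G adjacency. Realised O/E tracks the target to
within +/-0.01 on average at the design cohort sizes. Real coding
sequences have codon-usage and neighbour-dependence structure this chain
does not model.

**The standard fixture** (5 species x 50 families, injected expansions of
sizes 5, 10, 20 on a zero-background duplication rate, 300-codon genes,
seed 42) drives the end-to-end pipeline: passing it shows the stages
compose correctly and deterministically, not that the method is robust to
alignment error, losses, or assembly artifacts in real data.

## Pipeline and numerical choices

Stages (`search -> trees -> reconcile -> expansions`; `search -> ds`;
`cpg`) read fixed-name artifacts from the run directory and are
independently restartable; a run is byte-reproducible for a fixed
configuration and seed (JSON is written with sorted keys, tables sorted, no
timestamps). Families are connected components of the filtered hit graph.
Families of two genes get a trivial cherry tree; three or more go through
trim -> distance -> NJ -> rooting. Supplied per-family Newick trees bypass
tree building so reconciliation can be tested independently of alignment
quality. The run report cross-checks that histogram mass equals genes in
families and fails loudly otherwise.

Default thresholds follow the source procedure: coverage 0.5, gap threshold
0.25, conservation threshold 0.50, merge overlap 0.5, allelic cutoff 0.05,
ancient cutoff 1.5, bin width 0.05; everything is overridable in one YAML
config, and the log/report echoes every default so a run is
self-describing.

Problem sizes used by the verification suite (chosen as the scale at which
each guarantee is meaningful): exhaustive reconciliation oracle over all
10,260 distinct species-labelled rooted binary shapes with up to 7 leaves
over 3 species; 200 loss-free birth-death families at lambda = 0.3; 1,000
random group sets for merge order-independence; 500 simulated pairs of 300
codons per dS level; 100 random additive matrices up to 12 taxa; 50 random
RBH fixtures up to 20 sequences; 100 seeds per bimodality scenario; the
standard fixture run twice for byte-identity.

## Known limitations

- Species-overlap labelling is only exact without gene loss; the package
  reports but does not assert loss scenarios.
- No multiple aligner is included: real-data runs must supply aligned FASTA
  or per-family trees.
- The e-value filter is emulated by a raw-score threshold; cross-database
  comparability of `s_min` is not claimed.
- NG86 with JC correction underestimates dS under strong transition bias or
  unequal base frequencies; the dS histogram is comparable to published
  distributions qualitatively, not bin-by-bin.
- The bimodality rule's constants (Delta BIC 10, one-sigma-sum separation)
  are a pragmatic surrogate for a visual call, validated only at the design
  effect sizes.
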