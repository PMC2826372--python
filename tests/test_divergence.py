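import math

import numpy as np
import pytest

from phyexp.core_io import CodingSequence, PhyexpError, ProteinSequence
from phyexp.divergence import (
    GENETIC_CODE,
    CodonAlignment,
    DivergenceParams,
    ParalogPair,
    SiteCounts,
    classify_pairs,
    codon_pair_differences,
    count_sites_ng86,
    ds_histogram,
    estimate_ds_dn,
    pair_ds_dn,
    syn_fraction_sites,
    thread_codons,
    trim_codon_alignment,
)
from phyexp.homology import TrimParams

SENSE = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


def translate(cds: str) -> str:
    return "".join(GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds), 3))


class TestThreadCodons:
    def test_gapless_pair_concatenates_codons(self):
        a = CodingSequence("a", "ATGGGG")
        b = CodingSequence("b", "ATGGGA")
        aln = thread_codons(
            [ProteinSequence("a", "MG"), ProteinSequence("b", "MG")], a, b
        )
        assert aln.rows == (("a", "ATGGGG"), ("b", "ATGGGA"))

    def test_protein_gap_becomes_codon_gap(self):
        a = CodingSequence("a", "ATGAAAGGG")
        b = CodingSequence("b", "ATGGGG")
        aln = thread_codons(
            [ProteinSequence("a", "MKG"), ProteinSequence("b", "M-G")], a, b
        )
        assert aln.rows[1] == ("b", "ATG---GGG")

    def test_length_mismatch_is_error(self):
        a = CodingSequence("a", "ATGGGGATGA")  # 10 nt for 4 residues
        b = CodingSequence("b", "ATGGGGATGGGG")
        with pytest.raises(PhyexpError, match="a"):
            thread_codons(
                [ProteinSequence("a", "MGMX"), ProteinSequence("b", "MGMG")], a, b
            )

    def test_translation_mismatch_is_error(self):
        a = CodingSequence("a", "ATGGGG")
        b = CodingSequence("b", "ATGGGA")
        with pytest.raises(PhyexpError, match="translates"):
            thread_codons(
                [ProteinSequence("a", "MK"), ProteinSequence("b", "MG")], a, b
            )


class TestSiteCounts:
    def test_fourfold_codon_has_one_synonymous_site(self):
        # GGG: third position fully degenerate, positions 1-2 not
        assert syn_fraction_sites("GGG") == pytest.approx(1.0)

    def test_twofold_codon_third(self):
        # AAA -> only AAA->AAG synonymous among the 9 neighbors
        assert syn_fraction_sites("AAA") == pytest.approx(1 / 3)

    @pytest.mark.parametrize("codon", SENSE)
    def test_site_fractions_match_neighbor_enumeration(self, codon):
        # oracle: direct enumeration of the nine single-base neighbors
        syn = 0
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                if GENETIC_CODE[mut] not in ("*",) and GENETIC_CODE[mut] == GENETIC_CODE[codon]:
                    syn += 1
        assert syn_fraction_sites(codon) == pytest.approx(syn / 3)

    def test_sites_conserved_at_three_per_codon(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c1, c2 = (SENSE[i] for i in rng.integers(len(SENSE), size=2))
            aln = CodonAlignment((("a", c1), ("b", c2)))
            counts = count_sites_ng86(aln)
            assert counts.S + counts.N == pytest.approx(3.0)

    def test_two_difference_codon_averages_pathways(self):
        # TTT (Phe) vs TTA (Leu) one diff nonsyn; worked multi-step case:
        # CCT (Pro) vs CCA (Pro) synonymous single step
        sd, nd = codon_pair_differences("CCT", "CCA")
        assert (sd, nd) == (1.0, 0.0)
        # TTG (Leu) vs CTA (Leu): paths TTG->CTG->CTA (syn, syn) and
        # TTG->TTA->CTA (syn, syn): both fully synonymous
        sd, nd = codon_pair_differences("TTG", "CTA")
        assert sd == pytest.approx(2.0)
        assert nd == pytest.approx(0.0)

    def test_gapped_and_ambiguous_columns_skipped(self):
        aln = CodonAlignment((("a", "GGG---GGN"), ("b", "GGAGGGGGG")))
        counts = count_sites_ng86(aln)
        assert counts.codons == 1

    def test_all_gapped_is_error(self):
        aln = CodonAlignment((("a", "---"), ("b", "GGG")))
        with pytest.raises(PhyexpError, match="comparable"):
            count_sites_ng86(aln)


class TestEstimate:
    def test_identical_sequences_zero_distances(self):
        aln = CodonAlignment((("a", "ATGGGGAAA"), ("b", "ATGGGGAAA")))
        est = estimate_ds_dn(count_sites_ng86(aln))
        assert est.ds == 0.0
        assert est.dn == 0.0

    def test_hand_computed_worked_example(self):
        # GGG GGG GGG vs GGA GGG GGG: S=3, Sd=1, pS=1/3 ->
        # dS = -0.75 ln(1 - 4/9) = 0.4408; dN = 0
        aln = CodonAlignment((("a", "GGGGGGGGG"), ("b", "GGAGGGGGG")))
        counts = count_sites_ng86(aln)
        assert counts.S == pytest.approx(3.0)
        assert counts.Sd == pytest.approx(1.0)
        assert counts.Nd == pytest.approx(0.0)
        est = estimate_ds_dn(counts)
        assert est.ds == pytest.approx(-0.75 * math.log(5 / 9), abs=1e-9)
        assert est.dn == 0.0

    def test_saturation_beyond_correction_domain(self):
        est = estimate_ds_dn(SiteCounts(S=5.0, N=10.0, Sd=4.0, Nd=0.0, codons=5))
        assert est.ds is None
        assert est.ds_saturated

    def test_symmetry_under_row_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            codons_a = "".join(SENSE[i] for i in rng.integers(len(SENSE), size=10))
            codons_b = "".join(SENSE[i] for i in rng.integers(len(SENSE), size=10))
            ab = estimate_ds_dn(
                count_sites_ng86(CodonAlignment((("a", codons_a), ("b", codons_b))))
            )
            ba = estimate_ds_dn(
                count_sites_ng86(CodonAlignment((("b", codons_b), ("a", codons_a))))
            )
            assert ab == ba

    def test_matches_biopython_ng86_oracle(self):
        # independent cross-check against Bio.codonalign's NG86; tolerances
        # allow for its different handling of stop-adjacent mutation sites
        # (here S+N = 3 x codons exactly; Biopython rescales those sites)
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        rng = np.random.default_rng(2)
        checked = 0
        for _ in range(15):
            base = [SENSE[i] for i in rng.integers(len(SENSE), size=30)]
            other = list(base)
            for k in rng.integers(30, size=6):
                other[k] = SENSE[rng.integers(len(SENSE))]
            a, b = "".join(base), "".join(other)
            est = estimate_ds_dn(count_sites_ng86(CodonAlignment((("a", a), ("b", b)))))
            if est.ds is None or est.dn is None:
                continue
            dn_ref, ds_ref = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            assert est.ds == pytest.approx(ds_ref, abs=0.02)
            assert est.dn == pytest.approx(dn_ref, abs=0.02)
            checked += 1
        assert checked >= 10


class TestClassifyAndHistogram:
    def _pair(self, ds):
        return ParalogPair("a", "b", ds=ds, dn=0.0)

    def test_threshold_classification(self):
        pairs = classify_pairs(
            [self._pair(0.0), self._pair(0.25), self._pair(2.0), ParalogPair("x", "y")]
        )
        assert [p.status for p in pairs] == [
            "allelic_candidate",
            "paralog",
            "ancient",
            "saturated",
        ]

    def test_boundary_values(self):
        pairs = classify_pairs([self._pair(0.05), self._pair(1.5)])
        assert pairs[0].status == "allelic_candidate"
        assert pairs[1].status == "paralog"

    def test_default_cutoffs(self):
        p = DivergenceParams()
        assert p.allelic_cutoff == 0.05
        assert p.ancient_cutoff == 1.5

    def test_empty_histogram(self):
        hist = ds_histogram([])
        assert sum(hist.counts) == 0
        assert hist.n_ancient == 0
        assert hist.reference_lines == (0.25, 0.35)

    def test_allelic_excluded_by_default(self):
        pairs = classify_pairs([self._pair(0.01), self._pair(0.3)])
        hist = ds_histogram(pairs)
        assert sum(hist.counts) == 1
        assert hist.n_allelic_excluded == 1
        inc = ds_histogram(pairs, DivergenceParams(include_allelic=True))
        assert sum(inc.counts) == 2

    def test_ancient_and_saturated_tallied_separately(self):
        pairs = classify_pairs(
            [self._pair(2.0), ParalogPair("x", "y"), self._pair(0.3)]
        )
        hist = ds_histogram(pairs)
        assert hist.n_ancient == 1
        assert hist.n_saturated == 1
        assert sum(hist.counts) == 1

    def test_simulated_cohort_mode_at_true_ds(self):
        from phyexp.synthetic_data import simulate_paralog_pair

        pairs = []
        for k in range(60):
            a, b = simulate_paralog_pair(0.25, 300, seed=500 + k)
            pairs.append(
                pair_ds_dn(
                    ProteinSequence("a", translate(a.seq)),
                    ProteinSequence("b", translate(b.seq)),
                    a,
                    b,
                )
            )
        hist = ds_histogram(classify_pairs(pairs))
        mode_bin = int(np.argmax(hist.counts))
        assert hist.edges[mode_bin] <= 0.25 <= hist.edges[mode_bin + 1] + 0.05


class TestTrimCodonAlignment:
    def test_trim_mask_propagates_to_codons(self):
        prot = [ProteinSequence("a", "MKV"), ProteinSequence("b", "M-V")]
        cds_a = CodingSequence("a", "ATGAAAGTT")
        cds_b = CodingSequence("b", "ATGGTT")
        codon_aln = thread_codons(prot, cds_a, cds_b)
        trimmed = trim_codon_alignment(prot, codon_aln, TrimParams(0.6, 0.5))
        assert trimmed.rows == (("a", "ATGGTT"), ("b", "ATGGTT"))

    def test_pair_ds_dn_end_to_end(self):
        cds_a = CodingSequence("a", "GGGGGGGGG")
        cds_b = CodingSequence("b", "GGAGGGGGG")
        pair = pair_ds_dn(
            ProteinSequence("a", "GGG"),
            ProteinSequence("b", "GGG"),
            cds_a,
            cds_b,
        )
        assert pair.ds == pytest.approx(-0.75 * math.log(5 / 9))
        assert pair.dn == 0.0
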