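import math
import warnings

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from phyexp.core_io import PhyexpError, ProteinSequence
from phyexp.homology import (
    SCOREDIST_CALIBRATION,
    SCOREDIST_FLOOR,
    DistanceMatrix,
    SearchParams,
    TrimParams,
    distance_matrix,
    find_homologs,
    local_align,
    nj_tree,
    rbh_pairs,
    trim_alignment,
    trim_columns,
)

B62 = substitution_matrices.load("BLOSUM62")


def sw_affine_oracle(a: str, b: str, gap_open=11.0, gap_extend=1.0) -> float:
    """Independent affine-gap Smith-Waterman scorer (Gotoh recurrences).

    Opening a gap of length k costs open + (k-1)*extend.
    """
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), 0.0)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = B62[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0, s + max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]))
            Ix[i, j] = max(M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend)
            Iy[i, j] = max(M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend)
            best = max(best, M[i, j])
    return best


def random_protein(rng, length):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aas[i] for i in rng.integers(20, size=length))


class TestLocalAlign:
    def test_self_alignment_scores_diagonal_sum(self):
        seq = ProteinSequence("q", "ACDEFGHIKL")
        hit = local_align(seq, ProteinSequence("s", "ACDEFGHIKL"))
        assert hit.score == sum(B62[c, c] for c in "ACDEFGHIKL")
        assert hit.coverage == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_protein(rng, int(rng.integers(8, 16)))
        b = random_protein(rng, int(rng.integers(8, 16)))
        hit = local_align(ProteinSequence("a", a), ProteinSequence("b", b))
        assert hit.score == pytest.approx(sw_affine_oracle(a, b))

    def test_partial_island_coverage(self):
        # only the 4-residue WCYW island aligns; flanks score negatively
        query = ProteinSequence("q", "PPPPWCYWPP")
        subject = ProteinSequence("s", "GGGGWCYWGG")
        hit = local_align(query, subject)
        assert hit.span == 4
        assert hit.coverage == pytest.approx(0.4)

    def test_empty_sequence_is_error(self):
        with pytest.raises(PhyexpError):
            ProteinSequence("q", "")


class TestFindHomologs:
    def test_identical_copy_is_top_hit_with_full_coverage(self):
        rng = np.random.default_rng(1)
        q = ProteinSequence("q", random_protein(rng, 40))
        db = [
            ProteinSequence("copy", q.residues),
            ProteinSequence("junk", random_protein(rng, 40)),
        ]
        hits = find_homologs(q, db)
        assert hits[0].subject_id == "copy"
        assert hits[0].coverage == 1.0

    def test_low_coverage_hit_excluded(self):
        # island spans 40% of the query: below the default 50% coverage rule
        q = ProteinSequence("q", "PPPPWCYWPP")
        db = [ProteinSequence("s", "GGGGWCYWGG")]
        assert find_homologs(q, db, SearchParams(s_min=5.0)) == []

    def test_unrelated_db_below_score_threshold_is_empty(self):
        rng = np.random.default_rng(2)
        q = ProteinSequence("q", random_protein(rng, 30))
        db = [ProteinSequence(f"s{i}", random_protein(rng, 30)) for i in range(5)]
        assert find_homologs(q, db, SearchParams(s_min=120.0)) == []

    def test_output_invariant_under_db_permutation(self):
        rng = np.random.default_rng(3)
        base = random_protein(rng, 50)
        db = []
        for i in range(6):
            s = list(base)
            for _ in range(int(rng.integers(0, 12))):
                s[rng.integers(50)] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
            db.append(ProteinSequence(f"s{i}", "".join(s)))
        q = ProteinSequence("q", base)
        h1 = find_homologs(q, db)
        h2 = find_homologs(q, db[::-1])
        assert h1 == h2


class TestRBH:
    def test_two_homologs_form_one_pair(self):
        rng = np.random.default_rng(4)
        base = random_protein(rng, 60)
        mutated = base[:55] + "WWWWW"
        pairs = rbh_pairs(
            [ProteinSequence("a", base), ProteinSequence("b", mutated)]
        )
        assert pairs == [("a", "b")]

    def test_non_reciprocal_chain_excludes_weak_member(self):
        # c is b with 1 change, a is b with many: a->b, b->c, c->b
        rng = np.random.default_rng(5)
        base = random_protein(rng, 60)
        c = base[:59] + ("W" if base[59] != "W" else "Y")
        a = list(base)
        for k in range(0, 24, 2):
            a[k] = "W" if a[k] != "W" else "Y"
        seqs = [
            ProteinSequence("a", "".join(a)),
            ProteinSequence("b", base),
            ProteinSequence("c", c),
        ]
        pairs = rbh_pairs(seqs)
        assert pairs == [("b", "c")]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(4, 12))
        base = random_protein(rng, 60)
        seqs = []
        for i in range(n):
            s = list(base)
            for _ in range(int(rng.integers(1, 25))):
                s[rng.integers(60)] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
            seqs.append(ProteinSequence(f"g{i:02d}", "".join(s)))
        params = SearchParams()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = rbh_pairs(seqs, params)
            best = {}
            for q in seqs:
                cand = []
                for s in seqs:
                    if s.gene_id == q.gene_id:
                        continue
                    h = local_align(q, s, params)
                    if h.score >= params.s_min and h.coverage > params.q_cov:
                        cand.append((-h.score, s.gene_id))
                best[q.gene_id] = sorted(cand)[0][1] if cand else None
        oracle = sorted(
            {
                tuple(sorted((g, b)))
                for g, b in best.items()
                if b is not None and best.get(b) == g
            }
        )
        assert got == oracle

    def test_each_gene_in_at_most_one_pair(self):
        rng = np.random.default_rng(6)
        base = random_protein(rng, 60)
        seqs = []
        for i in range(8):
            s = list(base)
            for _ in range(int(rng.integers(0, 15))):
                s[rng.integers(60)] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
            seqs.append(ProteinSequence(f"g{i}", "".join(s)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pairs = rbh_pairs(seqs)
        flat = [g for p in pairs for g in p]
        assert len(flat) == len(set(flat))


class TestTrim:
    def test_gapless_conserved_alignment_unchanged(self):
        aln = [ProteinSequence("a", "MKV"), ProteinSequence("b", "MKV")]
        out = trim_alignment(aln)
        assert [(r.gene_id, r.seq) for r in out] == [("a", "MKV"), ("b", "MKV")]

    def test_all_gap_column_removed(self):
        aln = [ProteinSequence("a", "M-V"), ProteinSequence("b", "M-V")]
        assert [r.seq for r in trim_alignment(aln)] == ["MV", "MV"]

    def test_default_thresholds(self):
        p = TrimParams()
        assert p.gap_threshold == 0.25
        assert p.conservation_threshold == 0.50

    def test_gap_threshold_drops_gappy_columns(self):
        # column 1 has 3/4 gaps (non-gap fraction 0.25 >= 0.25 kept at
        # default), column 2 has 1/4 non-gap at conservation 1.0
        rows = ["MAV", "M-V", "M-V", "M-V"]
        kept_default = trim_columns(rows)
        assert kept_default == [0, 1, 2]
        kept_strict = trim_columns(rows, TrimParams(gap_threshold=0.5))
        assert kept_strict == [0, 2]

    def test_conservation_threshold_drops_diverse_columns(self):
        rows = ["MAV", "MCV", "MDV", "MEV"]
        assert trim_columns(rows) == [0, 2]

    @pytest.mark.parametrize("seed", range(5))
    def test_column_set_monotone_in_thresholds(self, seed):
        rng = np.random.default_rng(300 + seed)
        chars = "ACDE-"
        rows = [
            "".join(chars[i] for i in rng.integers(5, size=30)) for _ in range(6)
        ]
        base = set(trim_columns(rows, TrimParams(0.3, 0.4)))
        for gt, ct in [(0.5, 0.4), (0.3, 0.6), (0.6, 0.7)]:
            assert set(trim_columns(rows, TrimParams(gt, ct))) <= base

    def test_super_alignment_mode_keeps_half_gapped(self):
        rows = ["MA", "M-", "MC", "M-"]
        assert trim_columns(rows, TrimParams(super_alignment=True)) == [0, 1]

    def test_dot_gap_character_rejected(self):
        with pytest.raises(PhyexpError, match="'-'"):
            trim_columns(["M.V", "MAV"])


class TestDistances:
    def test_identical_rows_distance_zero(self):
        aln = [ProteinSequence("a", "MKVLW"), ProteinSequence("b", "MKVLW")]
        for method in ("poisson", "scoredist"):
            assert distance_matrix(aln, method)[("a", "b")] == pytest.approx(0.0, abs=1e-9)

    def test_poisson_closed_form(self):
        # 1 mismatch in 10 -> p = 0.1 -> -ln(0.9)
        aln = [ProteinSequence("a", "MKVLWMKVLW"), ProteinSequence("b", "MKVLWMKVLY")]
        assert distance_matrix(aln, "poisson")[("a", "b")] == pytest.approx(
            -math.log(0.9), abs=1e-9
        )

    def test_scoredist_hand_computed_pair(self):
        # rows AC / AD, hand computation of the published formula:
        # S=1, E=-0.5, upper=11.5, sigma=1.5/12 -> -ln(0.125)*100*1.337
        aln = [ProteinSequence("a", "AC"), ProteinSequence("b", "AD")]
        expected = -math.log(1.5 / 12.0) * 100.0 * SCOREDIST_CALIBRATION
        assert distance_matrix(aln, "scoredist")[("a", "b")] == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_scoredist_matches_independent_recomputation(self, seed):
        rng = np.random.default_rng(400 + seed)
        rows = [
            ProteinSequence(f"r{i}", random_protein(rng, 40)) for i in range(3)
        ]
        got = distance_matrix(rows, "scoredist")

        def oracle(x, y):
            S = sum(B62[a, b] for a, b in zip(x, y))
            E = sum(B62[a, b] for a in x for b in y) / len(x)
            U = (sum(B62[a, a] for a in x) + sum(B62[b, b] for b in y)) / 2
            sigma = max((S - E) / (U - E), SCOREDIST_FLOOR)
            return max(0.0, -math.log(sigma) * 100 * SCOREDIST_CALIBRATION)

        for i in range(3):
            for j in range(i + 1, 3):
                assert got.values[i, j] == pytest.approx(
                    oracle(rows[i].seq, rows[j].seq)
                )

    def test_no_overlap_pair_is_error_naming_pair(self):
        aln = [ProteinSequence("a", "MK--"), ProteinSequence("b", "--VL")]
        with pytest.raises(PhyexpError, match="a, b"):
            distance_matrix(aln, "poisson")

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(PhyexpError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNJ:
    def test_four_taxon_additive_topology(self):
        d = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array(
                [
                    [0, 2, 4, 4],
                    [2, 0, 4, 4],
                    [4, 4, 0, 2],
                    [4, 4, 2, 0],
                ],
                dtype=float,
            ),
        )
        tree = nj_tree(d)
        splits = {
            frozenset(t.name for t in c.get_terminals())
            for c in tree.find_clades()
            if 1 < len(c.get_terminals()) < 3
        }
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_three_taxon_lengths_from_three_point_formulas(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float),
        )
        tree = nj_tree(d)
        lengths = {t.name: t.branch_length for t in tree.get_terminals()}
        # a=(dAB+dAC-dBC)/2 etc.
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_unrooted_flag_set(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float),
        )
        assert nj_tree(d).rooted is False

    def test_fewer_than_three_taxa_is_error(self):
        d = DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], dtype=float))
        with pytest.raises(PhyexpError):
            nj_tree(d)
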