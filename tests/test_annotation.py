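import pytest

from itsphylo.annotation import (
    build_consensus_structure,
    check_its2_hallmarks,
    classify_helix_variants,
    decompose_helices,
    select_structure,
)
from itsphylo.core_io import PairTable, SequenceRecord, StructuredSequence
from itsphylo.struct_align import AlignedRow, StructuralAlignment
from itsphylo.synthetic import make_its2_toy

from conftest import random_structured_sequence


class TestDecompose:
    def test_single_hairpin(self):
        helices = decompose_helices(PairTable.from_dotbracket("(((...)))"))
        assert len(helices) == 1
        h = helices[0]
        assert h.n_pairs == 3
        assert h.internal_loops == []
        assert len(h.pair_runs) == 1

    def test_two_hairpins_indexed_5prime_to_3prime(self):
        helices = decompose_helices(PairTable.from_dotbracket("((...))((...))"))
        assert [h.index for h in helices] == [1, 2]
        assert helices[0].span[0] < helices[1].span[0]

    def test_branched_structure_three_helices(self):
        # closing stem + two branch hairpins
        db = "((..((...))..((...))))"
        helices = decompose_helices(PairTable.from_dotbracket(db))
        assert len(helices) == 3
        assert helices[0].n_pairs == 2   # the closing stem
        assert helices[1].n_pairs == 2
        assert helices[2].n_pairs == 2

    def test_bulge_does_not_split_helix(self):
        db = "((.((...))))"
        helices = decompose_helices(PairTable.from_dotbracket(db))
        assert len(helices) == 1
        assert helices[0].n_pairs == 4
        assert helices[0].internal_loops == [(1, 0)]

    def test_partition_property(self, rng):
        for _ in range(25):
            ss = random_structured_sequence(rng, rng.randint(15, 60))
            helices = decompose_helices(ss.structure)
            assigned = [p for h in helices for p in h.pairs]
            assert sorted(assigned) == ss.structure.pairs()


class TestHallmarks:
    def test_toy_with_all_hallmarks_passes(self):
        ss, f58, f28 = make_its2_toy()
        rep = check_its2_hallmarks(ss, f58, f28)
        assert rep.motif_found and rep.uu_mismatch_found and rep.hybrid_stem_ok
        assert rep.overall_pass

    def test_uu_mutated_to_uc_fails_only_that_check(self):
        ss, f58, f28 = make_its2_toy(uu=False)
        rep = check_its2_hallmarks(ss, f58, f28)
        assert not rep.uu_mismatch_found
        assert rep.motif_found and rep.hybrid_stem_ok
        assert not rep.overall_pass

    def test_hybrid_stem_threshold(self):
        ss, f58, f28 = make_its2_toy()
        rep6 = check_its2_hallmarks(ss, f58, f28, min_hybrid_pairs=6)
        assert rep6.hybrid_stem_ok and rep6.hybrid_stem_length == 6
        rep7 = check_its2_hallmarks(ss, f58, f28, min_hybrid_pairs=7)
        assert not rep7.hybrid_stem_ok

    def test_broken_hybrid_flanks(self):
        ss, f58, f28 = make_its2_toy(hybrid=False)
        rep = check_its2_hallmarks(ss, f58, f28)
        assert not rep.hybrid_stem_ok

    def test_missing_helices_reported_absent(self):
        ss = StructuredSequence(
            SequenceRecord("x", "GGGAAACCC"), PairTable.from_dotbracket("(((...)))")
        )
        rep = check_its2_hallmarks(ss)
        assert rep.motif_found is False
        assert any("helix absent" in r for r in rep.reasons)

    def test_flankless_check_skipped(self):
        ss, _, _ = make_its2_toy()
        rep = check_its2_hallmarks(ss)
        assert rep.hybrid_stem_ok is None
        assert rep.overall_pass  # remaining enabled checks pass


class TestSelectStructure:
    def test_single_passing_candidate_returned(self):
        ss, f58, f28 = make_its2_toy()
        picked = select_structure([(ss.structure, -10.0)], ss.record, f58, f28)
        assert picked.structure == ss.structure
        assert "unverified" not in picked.flags

    def test_second_best_picked_when_mfe_fails(self):
        ss, f58, f28 = make_its2_toy()
        # a bogus "MFE" structure with no pairs fails every hallmark
        empty = PairTable([None] * len(ss.residues))
        picked = select_structure(
            [(empty, -20.0), (ss.structure, -10.0)], ss.record, f58, f28
        )
        assert picked.structure == ss.structure
        assert "unverified" not in picked.flags

    def test_all_failing_returns_mfe_flagged(self):
        ss, f58, f28 = make_its2_toy()
        empty = PairTable([None] * len(ss.residues))
        picked = select_structure([(empty, -20.0)], ss.record, f58, f28)
        assert picked.structure == empty
        assert "unverified" in picked.flags

    def test_empty_candidates_rejected(self):
        ss, f58, f28 = make_its2_toy()
        with pytest.raises(ValueError, match="empty"):
            select_structure([], ss.record, f58, f28)


def _aln(rows):
    return StructuralAlignment([AlignedRow(*r) for r in rows])


class TestVariants:
    def test_all_same_shape_one_variant(self):
        rows = [(f"s{k}", "GGGAAACCC", "(((...)))") for k in range(5)]
        cat = classify_helix_variants(_aln(rows), "H1")
        assert cat.n_variants == 1
        assert cat.variants[0][0] == "A"
        assert len(cat.variants[0][2]) == 5

    def test_membership_ordering(self):
        rows = [
            ("a", "GGGAAACCC", "(((...)))"),
            ("b", "GGGAAACCC", "(((...)))"),
            ("c", "GGGAAACCC", "((.....))"),
        ]
        cat = classify_helix_variants(_aln(rows), "H1")
        assert [v[0] for v in cat.variants] == ["A", "B"]
        assert cat.members("A") == ["a", "b"]
        assert cat.members("B") == ["c"]

    def test_ambiguous_site_unpaired_collapses_variants(self):
        # N at a stem position folds as unpaired in both rows, so the two
        # rows share one shape even though the sequences differ
        rows = [
            ("a", "GNGAAACCC", "(.(...).)"),
            ("b", "GAGAAACCC", "(.(...).)"),
        ]
        cat = classify_helix_variants(_aln(rows), "H1")
        assert cat.n_variants == 1

    def test_row_order_invariance(self, toy_alignment):
        cat1 = classify_helix_variants(toy_alignment, "H1")
        rev = StructuralAlignment(list(reversed(toy_alignment.rows)))
        cat2 = classify_helix_variants(rev, "H1")
        shapes1 = sorted((shape, sorted(mem)) for _, shape, mem in cat1.variants)
        shapes2 = sorted((shape, sorted(mem)) for _, shape, mem in cat2.variants)
        assert shapes1 == shapes2

    def test_unknown_helix_rejected(self, toy_alignment):
        with pytest.raises(ValueError, match="unknown helix"):
            classify_helix_variants(toy_alignment, "H9")


class TestConsensus:
    def test_identical_rows_full_frequency(self):
        rows = [(f"s{k}", "GGGAAACCC", "(((...)))") for k in range(4)]
        cons = build_consensus_structure(_aln(rows))
        assert cons.pairs() == [(0, 8), (1, 7), (2, 6)]
        assert all(f == 1.0 for f in cons.pair_freq.values())

    def test_threshold_arithmetic(self):
        rows = [
            ("a", "GGGAAACCC", "(((...)))"),
            ("b", "GGGAAACCC", "(((...)))"),
            ("c", "GGGAAACCC", ".((...))."),
            ("d", "GGGAAACCC", ".((...))."),
        ]
        cons = build_consensus_structure(_aln(rows), pair_threshold=0.5)
        assert (0, 8) in cons.pair_freq          # 2 of 4 -> included at 0.5
        rows[1] = ("b", "GGGAAACCC", ".((...)).")
        cons2 = build_consensus_structure(_aln(rows), pair_threshold=0.5)
        assert (0, 8) not in cons2.pair_freq     # 1 of 4 -> excluded

    def test_crossing_resolved_by_frequency(self):
        # (0, 5) at 0.8 crosses (2, 7) at 0.6; the stronger pair wins
        rows = []
        for k in range(4):
            rows.append((f"x{k}", "GAAAACAAAA", "(....)...."))
        rows.append(("y0", "AAGAAAACAA", "..(....).."))
        aln = _aln(rows)
        cons = build_consensus_structure(aln, pair_threshold=0.1)
        assert (0, 5) in cons.pair_freq
        assert (2, 8) not in cons.pair_freq
        # consensus must stay nested
        cons.pair_table()  # raises if crossing

    def test_threshold_one_is_intersection(self, toy_alignment):
        # at threshold 1.0 a pair survives iff every row that has residues
        # at both columns is paired there (gapped rows are outside the
        # denominator)
        cons = build_consensus_structure(toy_alignment, pair_threshold=1.0)
        expected = set()
        candidates = {p for r in toy_alignment.rows for p in r.pair_columns()}
        for i, j in candidates:
            eligible = [r for r in toy_alignment.rows
                        if r.seq[i] != "-" and r.seq[j] != "-"]
            if all((i, j) in r.pair_columns() for r in eligible):
                expected.add((i, j))
        assert set(cons.pairs()) == expected
        # and on a gapless alignment it is the plain intersection
        gapless = StructuralAlignment(
            [r for r in toy_alignment.rows if "-" not in r.seq]
        )
        cons2 = build_consensus_structure(gapless, pair_threshold=1.0)
        shared = set.intersection(*(set(r.pair_columns()) for r in gapless.rows))
        assert set(cons2.pairs()) == shared

    def test_indel_columns_lowercased(self, toy_alignment):
        cons = build_consensus_structure(toy_alignment)
        assert 2 in cons.indel_columns
        rendered = cons.render("GGGAAACCCAU")
        assert rendered[2] == "g"
        assert rendered[0] == "G"
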