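"""Codon-position constraint matrix, RC scoring, exon conservation."""

import numpy as np
import pytest

from savscan.constraint import (
    AlignmentWindow,
    CodonConstraintMatrix,
    MafIndex,
    UndefinedCellError,
    build_codon_matrix,
    exon_conservation,
    non_overlapping_contexts,
    rc_score,
    variant_rc,
)

from helpers import make_ctx, random_seq


def matrix_with(cells: dict[tuple[str, int], float]) -> CodonConstraintMatrix:
    """Matrix whose listed cells have the requested scores (0..10)."""
    m = CodonConstraintMatrix()
    for (codon, pos), score in cells.items():
        m.observed[(codon, pos)] = 1000
        m.conserved[(codon, pos)] = round(1000 * (1 - score / 10))
    return m


def window_from(rows: list[str], keys) -> AlignmentWindow:
    return AlignmentWindow(tuple(rows), tuple(keys))


class TestMatrix:
    def test_score_formula(self):
        m = CodonConstraintMatrix({("AAA", 1): 200}, {("AAA", 1): 50})
        assert m.pr("AAA", 1) == pytest.approx(0.25)
        assert m.score("AAA", 1) == pytest.approx(7.5, abs=1e-12)

    def test_fully_conserved_cell_scores_zero(self):
        m = CodonConstraintMatrix({("AAA", 1): 10}, {("AAA", 1): 10})
        assert m.score("AAA", 1) == 0.0

    def test_never_conserved_cell_scores_ten(self):
        m = CodonConstraintMatrix({("AAA", 1): 10}, {})
        assert m.score("AAA", 1) == 10.0

    def test_undefined_cell_raises(self):
        m = CodonConstraintMatrix()
        with pytest.raises(UndefinedCellError):
            m.score("AAA", 1)

    def test_tsv_round_trip(self, rc_matrix, tmp_path):
        p = tmp_path / "m.tsv"
        rc_matrix.to_tsv(p)
        again = CodonConstraintMatrix.from_tsv(p)
        assert again.observed == rc_matrix.observed
        assert again.conserved == rc_matrix.conserved

    def test_fixture_matrix_has_192_cells_defined(self, rc_matrix):
        cells = rc_matrix.cells()
        assert len(cells) == 192
        assert all(rc_matrix.defined(c, p) for c, p in cells)
        for c, p in cells:
            assert 0.0 <= rc_matrix.pr(c, p) <= 1.0

    def test_cpg_third_positions_score_highest(self, rc_matrix):
        """Synonymous positions of hypermutable CpG codons top the matrix."""
        cpg3 = [rc_matrix.score(c, 3) for c in ("TCG", "ACG", "CCG", "GCG")]
        other3 = [
            rc_matrix.score(c, 3)
            for c, p in rc_matrix.cells()
            if p == 3 and c not in {"TCG", "ACG", "CCG", "GCG"}
        ]
        pos12 = [rc_matrix.score(c, p) for c, p in rc_matrix.cells() if p in (1, 2)]
        assert min(cpg3) > max(pos12)
        assert np.mean(cpg3) > np.mean(other3)


class TestRCScore:
    def test_no_conserved_columns_scores_zero(self):
        rows = ["AAAA", "CCCC", "GGGG"]
        keys = [("AAA", 1)] * 4
        m = matrix_with({("AAA", 1): 5.0})
        assert rc_score(m, window_from(rows, keys)) == 0.0

    def test_all_conserved_max_weight_scores_ten(self):
        rows = ["AAAA"] * 3
        keys = [("AAA", 1)] * 4
        m = matrix_with({("AAA", 1): 10.0})
        assert rc_score(m, window_from(rows, keys)) == pytest.approx(10.0)

    def test_hand_evaluated_eleven_column_window(self):
        """Conserved columns 3 and 7 with weights 8.2 and 4.0 over 11 columns."""
        ref = "ACGTACGTACG"
        other = "".join(
            b if i in (3, 7) else ("T" if b != "T" else "A") for i, b in enumerate(ref)
        )
        keys = [None] * 11
        keys[3] = ("TTT", 1)
        keys[7] = ("GGG", 2)
        m = matrix_with({("TTT", 1): 8.2, ("GGG", 2): 4.0})
        score = rc_score(m, window_from([ref, other, other], keys))
        assert score == pytest.approx(12.2 / 11)

    def test_invariant_under_permuting_non_reference_rows(self):
        rng = np.random.default_rng(6)
        ref = random_seq(rng, 12)
        others = [
            "".join(b if rng.random() < 0.7 else "ACGT"[rng.integers(0, 4)] for b in ref)
            for _ in range(3)
        ]
        keys = [("AAA", (i % 3) + 1) for i in range(12)]
        m = matrix_with({("AAA", 1): 3.0, ("AAA", 2): 5.0, ("AAA", 3): 9.0})
        a = rc_score(m, window_from([ref] + others, keys))
        b = rc_score(m, window_from([ref] + others[::-1], keys))
        assert a == b

    def test_bounded_by_matrix_maximum(self, rc_matrix, maf, contexts):
        top = rc_matrix.max_score
        for ctx in contexts["control"][:50]:
            rc = variant_rc(rc_matrix, maf, ctx)
            if rc.scored:
                assert 0.0 <= rc.score <= top

    def test_adding_high_weight_conserved_column_increases_rc(self):
        m = matrix_with({("AAA", 1): 2.0, ("CCC", 1): 9.0})
        rows = ["AAA"] * 3
        keys = [("AAA", 1)] * 3
        base = rc_score(m, window_from(rows, keys))
        extended = rc_score(m, window_from(["AAAC"] * 3, keys + [("CCC", 1)]))
        assert extended > base

    def test_gapped_window_rejected_at_construction(self):
        with pytest.raises(ValueError, match="ungapped"):
            window_from(["AC-T", "ACGT", "ACGT"], [None] * 4)

    def test_two_species_window_rejected(self):
        with pytest.raises(ValueError, match="2 other species"):
            window_from(["ACGT", "ACGT"], [None] * 4)


class TestVariantRC:
    def test_window_truncation_arithmetic(self, rc_matrix, maf, contexts):
        """Window width is min(offset,5) + 1 + min(remaining,5) columns."""
        checked_truncated = 0
        for ctx in contexts["control"][:200]:
            rc = variant_rc(rc_matrix, maf, ctx)
            if not rc.scored:
                continue
            left = min(ctx.var_offset, 5)
            right = min(len(ctx.exon_seq) - 1 - ctx.var_offset, 5)
            assert rc.n_columns == left + 1 + right
            if left + right < 10:
                checked_truncated += 1
        assert checked_truncated > 0  # the cohort includes junction-proximal variants

    def test_gap_column_is_unscored(self, rc_matrix, tmp_path):
        maf_text = (
            "##maf version=1\n\n"
            "a score=0\n"
            "s hum.chrT 1000 12 + 2000 ACGTACGTACGT\n"
            "s mus.chrT 0 11 + 2000 ACGTAC-TACGT\n"
            "s rat.chrT 0 12 + 2000 ACGTACGTACGT\n\n"
        )
        p = tmp_path / "g.maf"
        p.write_text(maf_text)
        maf = MafIndex(p, "hum")
        ctx = make_ctx("ACGTACGTACGT", 6, "A")
        rc = variant_rc(rc_matrix, maf, ctx)
        assert not rc.scored and rc.reason == "GAPPED"

    def test_missing_alignment_is_unscored(self, rc_matrix, tmp_path):
        p = tmp_path / "empty.maf"
        p.write_text("##maf version=1\n")
        ctx = make_ctx("ACGTACGTACGT", 6, "A")
        rc = variant_rc(rc_matrix, MafIndex(p, "hum"), ctx)
        assert rc.reason == "MISSING_ALIGNMENT"

    def test_batch_matches_independent_scorer(self, rc_matrix, maf, contexts):
        """Mean RC of non-overlapping variants equals an oracle recomputation."""
        ctxs = non_overlapping_contexts(contexts["skipping"])
        assert len(ctxs) > 20
        scores, oracle_scores = [], []
        for ctx in ctxs:
            rc = variant_rc(rc_matrix, maf, ctx)
            if not rc.scored:
                continue
            scores.append(rc.score)
            # oracle: refetch and apply the published formula directly
            exon = ctx.exon
            lo = max(0, ctx.var_offset - 5)
            hi = min(len(ctx.exon_seq), ctx.var_offset + 6)
            if exon.strand == "+":
                g = (exon.start + lo, exon.start + hi)
            else:
                g = (exon.end - hi, exon.end - lo)
            rows = maf.fetch(exon.chrom, *g)
            seqs = [s for _, s in rows]
            if exon.strand == "-":
                from Bio.Seq import reverse_complement

                seqs = [reverse_complement(s) for s in seqs]
            total = 0.0
            for i in range(len(seqs[0])):
                col = {s[i] for s in seqs}
                if len(col) != 1:
                    continue
                off = lo + i
                pos_in_codon = (off - exon.phase) % 3
                codon_start = off - pos_in_codon
                if codon_start < 0 or codon_start + 3 > len(ctx.exon_seq):
                    continue
                codon = ctx.exon_seq[codon_start : codon_start + 3]
                total += rc_matrix.score(codon, pos_in_codon + 1)
            oracle_scores.append(total / len(seqs[0]))
        assert scores == pytest.approx(oracle_scores)
        assert np.mean(scores) == pytest.approx(np.mean(oracle_scores))

    def test_non_overlapping_dedup_keeps_first_by_coordinate(self):
        a = make_ctx("ACGTACGTACGTACGTACGT", 8, "C", pos=100)
        b = make_ctx("ACGTACGTACGTACGTACGT", 8, "C", pos=105)  # window overlaps a
        c = make_ctx("ACGTACGTACGTACGTACGT", 8, "C", pos=200)
        kept = non_overlapping_contexts([b, c, a])
        assert [k.variant.pos for k in kept] == [100, 200]


class TestBuildMatrix:
    def test_all_conserved_alignment_scores_zero(self, tmp_path):
        seq = "ATGAAACCCGGGTTTTAA"  # 6 codons
        maf_text = (
            "##maf version=1\n\na score=0\n"
            + "".join(
                f"s {sp}.chrT 300 {len(seq)} + 1000 {seq}\n"
                for sp in ("hum", "mus", "rat")
            )
            + "\n"
        )
        p = tmp_path / "c.maf"
        p.write_text(maf_text)
        from helpers import make_exon

        exon = make_exon(len(seq), start=300)
        m = build_codon_matrix(MafIndex(p, "hum"), [exon])
        for codon in ("ATG", "AAA", "CCC"):
            for pos in (1, 2, 3):
                assert m.score(codon, pos) == 0.0

    def test_nothing_conserved_scores_ten(self, tmp_path):
        seq = "ATGAAACCC"
        other = "CATCCCAAA"
        maf_text = (
            "##maf version=1\n\na score=0\n"
            f"s hum.chrT 300 9 + 1000 {seq}\n"
            f"s mus.chrT 0 9 + 1000 {other}\n"
            f"s rat.chrT 0 9 + 1000 {other}\n\n"
        )
        p = tmp_path / "c.maf"
        p.write_text(maf_text)
        from helpers import make_exon

        m = build_codon_matrix(MafIndex(p, "hum"), [make_exon(9, start=300)])
        assert m.score("ATG", 1) == 10.0


class TestExonConservation:
    def test_identical_alignment_is_fully_conserved(self):
        rows = ["ATGAAACCCGGG"] * 3
        overall, nonsyn = exon_conservation(rows, phase=0)
        assert overall == 100.0 and nonsyn == 100.0

    def test_fourfold_third_position_changes_spare_nonsyn_identity(self):
        ref = "ATGCCCGGGACC"  # CCN, GGN, ACN all 4-fold at position 3
        other = "ATGCCAGGAACA"
        overall, nonsyn = exon_conservation([ref, other, ref], phase=0)
        assert nonsyn == 100.0
        assert overall < 100.0

    def test_random_fixture_matches_brute_force_classification(self):
        from Bio.Data.CodonTable import standard_dna_table

        rng = np.random.default_rng(11)
        ref = random_seq(rng, 60)
        others = [
            "".join(b if rng.random() < 0.8 else "ACGT"[rng.integers(0, 4)] for b in ref)
            for _ in range(2)
        ]
        overall, nonsyn = exon_conservation([ref] + others, phase=0)
        # brute force: classify every column independently
        cons = [len({r[i] for r in [ref] + others}) == 1 for i in range(60)]
        fwd = standard_dna_table.forward_table
        stops = set(standard_dna_table.stop_codons)

        def aa(codon):
            return "*" if codon in stops else fwd.get(codon)

        zero_fold = []
        for i in range(60):
            codon = ref[(i // 3) * 3 : (i // 3) * 3 + 3]
            k = i % 3
            zf = all(
                aa(codon[:k] + b + codon[k + 1 :]) != aa(codon)
                for b in "ACGT"
                if b != codon[k]
            )
            zero_fold.append(zf)
        assert overall == pytest.approx(100 * np.mean(cons))
        n_zf = sum(zero_fold)
        expected_nonsyn = 100 * sum(c for c, z in zip(cons, zero_fold) if z) / n_zf
        assert nonsyn == pytest.approx(expected_nonsyn)
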