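"""Splice-site scoring backend and the delta-SS ectopic metric."""

import math
import warnings

import numpy as np
import pytest

from savscan.splice import (
    ACCEPTOR_WIDTH,
    DONOR_WIDTH,
    DeltaSSResult,
    PositionWeightSpliceModel,
    SideDelta,
    delta_ss,
    ectopic_assessment,
    score_splice_site,
    select_ectopic_like_controls,
)

from helpers import make_ctx, random_seq


class TestBackend:
    def test_degenerate_training_closed_form(self):
        """A model trained on one repeated window scores it by the
        pseudocount formula, hand-computable per position."""
        donor = "CAGGTAAGT"
        acceptor = "T" * 20 + "CAG"
        n = 3
        model = PositionWeightSpliceModel.train([donor] * n, [acceptor] * n)
        # per position: foreground (n + 0.5) / (n + 2), background 0.25
        expected = DONOR_WIDTH * math.log2(((n + 0.5) / (n + 2)) / 0.25)
        assert model.score(donor, "5p") == pytest.approx(expected)
        expected3 = ACCEPTOR_WIDTH * math.log2(((n + 0.5) / (n + 2)) / 0.25)
        assert model.score(acceptor, "3p") == pytest.approx(expected3)
        # a never-seen base scores the complementary pseudocount odds
        off = model.score("AAGGTAAGT", "5p") - model.score(donor, "5p")
        assert off == pytest.approx(
            math.log2((0.5 / (n + 2)) / 0.25) - math.log2(((n + 0.5) / (n + 2)) / 0.25)
        )

    def test_scoring_is_deterministic(self, splice_model):
        w = "CAGGTAAGT"
        assert splice_model.score(w, "5p") == splice_model.score(w, "5p")

    @pytest.mark.parametrize("window,side", [("ACGTACGT", "5p"), ("ACGTACGTA", "3p")])
    def test_wrong_width_is_contract_error(self, splice_model, window, side):
        with pytest.raises(ValueError, match="window must be"):
            score_splice_site(splice_model, window, side)

    def test_non_acgt_window_is_contract_error(self, splice_model):
        with pytest.raises(ValueError, match="non-ACGT"):
            splice_model.score("CAGGTANGT", "5p")

    def test_model_file_round_trip(self, splice_model, tmp_path):
        p = tmp_path / "model.tsv"
        splice_model.to_file(p)
        again = PositionWeightSpliceModel.from_file(p)
        np.testing.assert_array_equal(again.donor_weights, splice_model.donor_weights)
        np.testing.assert_array_equal(again.acceptor_weights, splice_model.acceptor_weights)

    def test_trained_background_changes_weights(self):
        donor = ["CAGGTAAGT"] * 4
        acceptor = ["T" * 20 + "CAG"] * 4
        uniform_bg = PositionWeightSpliceModel.train(donor, acceptor)
        skewed_bg = PositionWeightSpliceModel.train(
            donor, acceptor, donor_background=["AAAAAAAAA"] * 4
        )
        assert not np.allclose(uniform_bg.donor_weights, skewed_bg.donor_weights)


def _toy_model() -> PositionWeightSpliceModel:
    """Donor rewards the exact 9-mer CAGGTAAGT; acceptor rewards poly-T + CAG."""
    donor = np.full((4, DONOR_WIDTH), -1.0)
    for j, b in enumerate("CAGGTAAGT"):
        donor["ACGT".index(b), j] = 1.0
    acceptor = np.full((4, ACCEPTOR_WIDTH), -0.2)
    for j, b in enumerate("T" * 20 + "CAG"):
        acceptor["ACGT".index(b), j] = 0.2
    return PositionWeightSpliceModel(donor, acceptor)


class TestDeltaSS:
    def test_mid_exon_full_flanks_evaluates_9_and_23_windows(self, splice_model):
        ctx = make_ctx(
            random_seq(np.random.default_rng(0), 60), 30, "A",
            up_intron_seq="T" * 40, down_intron_seq="G" * 40,
        )
        res = delta_ss(splice_model, ctx)
        assert res.donor.n_windows == 9
        assert res.acceptor.n_windows == 23

    def test_single_window_completion_matches_brute_force(self):
        """Derived base completes the donor consensus in one placement."""
        model = _toy_model()
        exon = "ACGTACGTAC" + "CAGGTATGT" + "ACGTACGTACG"  # near-consensus, T at +5
        offset = 10 + 6
        ctx = make_ctx(exon, offset, "A")  # restores CAGGTAAGT
        res = delta_ss(model, ctx)
        # brute force over every placement
        wild = ctx.exon_seq
        derived = ctx.derived_exon_seq
        best5 = max(
            model.score(derived[s : s + 9], "5p") - model.score(wild[s : s + 9], "5p")
            for s in range(offset - 8, offset + 1)
            if 0 <= s and s + 9 <= len(wild)
        )
        assert res.donor.delta == pytest.approx(best5)
        assert res.donor.delta == pytest.approx(2.0)  # one mismatch fixed: -1 -> +1

    def test_delta_matches_exhaustive_enumeration_on_fixture_contexts(
        self, splice_model, contexts
    ):
        for ctx in contexts["ectopic"][:25] + contexts["control"][:25]:
            res = delta_ss(splice_model, ctx)
            wild = ctx.upstream_intron_seq + ctx.exon_seq + ctx.downstream_intron_seq
            derived = (
                ctx.upstream_intron_seq + ctx.derived_exon_seq + ctx.downstream_intron_seq
            )
            vpos = len(ctx.upstream_intron_seq) + ctx.var_offset
            for side, width, got in (
                ("5p", 9, res.donor),
                ("3p", 23, res.acceptor),
            ):
                deltas = [
                    splice_model.score(derived[s : s + width], side)
                    - splice_model.score(wild[s : s + width], side)
                    for s in range(max(0, vpos - width + 1), min(len(wild) - width, vpos) + 1)
                ]
                assert got.delta == pytest.approx(max(deltas))
            assert res.delta_ss == pytest.approx(
                max(res.donor.delta, res.acceptor.delta)
            )

    def test_antisymmetric_under_allele_swap(self, splice_model):
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 50)
        offset = 25
        alt = "ACGT"[("ACGT".index(seq[offset]) + 1) % 4]
        fwd = make_ctx(seq, offset, alt, up_intron_seq=random_seq(rng, 30),
                       down_intron_seq=random_seq(rng, 30))
        swapped = seq[:offset] + alt + seq[offset + 1 :]
        rev = make_ctx(swapped, offset, seq[offset],
                       up_intron_seq=fwd.upstream_intron_seq,
                       down_intron_seq=fwd.downstream_intron_seq)
        f, r = delta_ss(splice_model, fwd), delta_ss(splice_model, rev)
        # swapping alleles turns the best gain into the best loss
        def min_delta(model, ctx, side, width):
            wild = ctx.upstream_intron_seq + ctx.exon_seq + ctx.downstream_intron_seq
            derived = ctx.upstream_intron_seq + ctx.derived_exon_seq + ctx.downstream_intron_seq
            vpos = len(ctx.upstream_intron_seq) + ctx.var_offset
            return min(
                model.score(derived[s : s + width], side)
                - model.score(wild[s : s + width], side)
                for s in range(max(0, vpos - width + 1), min(len(wild) - width, vpos) + 1)
            )

        assert f.donor.delta == pytest.approx(-min_delta(splice_model, rev, "5p", 9))
        assert f.acceptor.delta == pytest.approx(-min_delta(splice_model, rev, "3p", 23))

    def test_strand_consistency_through_extraction(self, splice_model):
        """A minus-strand exon scores identically to its plus-strand mirror."""
        from Bio.Seq import reverse_complement

        from savscan.variants import Variant, extract_context, polarize
        from helpers import make_exon

        rng = np.random.default_rng(17)
        up, exon_seq, down = random_seq(rng, 50), random_seq(rng, 60), random_seq(rng, 50)
        plus_chrom = up + exon_seq + down
        minus_chrom = reverse_complement(plus_chrom)
        offset = 30
        plus_exon = make_exon(60, start=50, up_intron=50, down_intron=50)
        minus_exon = make_exon(60, start=50, strand="-", up_intron=50, down_intron=50)
        anc = exon_seq[offset]
        der = "ACGT"[("ACGT".index(anc) + 1) % 4]
        pv_plus = polarize(Variant("chrT", 50 + offset + 1, anc, der), anc, anc)
        gpos_minus = len(plus_chrom) - (50 + offset)
        anc_m, der_m = reverse_complement(anc), reverse_complement(der)
        pv_minus = polarize(Variant("chrT", gpos_minus, anc_m, der_m), anc_m, anc_m)
        ctx_plus = extract_context({"chrT": plus_chrom}, plus_exon, pv_plus, intron_flank=50)
        ctx_minus = extract_context({"chrT": minus_chrom}, minus_exon, pv_minus, intron_flank=50)
        assert ctx_plus.exon_seq == ctx_minus.exon_seq
        rp, rm = delta_ss(splice_model, ctx_plus), delta_ss(splice_model, ctx_minus)
        assert rp.donor.delta == pytest.approx(rm.donor.delta)
        assert rp.acceptor.delta == pytest.approx(rm.acceptor.delta)
        assert rp.natural_donor_score == pytest.approx(rm.natural_donor_score)

    def test_no_intron_sequence_still_scores_exonic_windows(self, splice_model):
        ctx = make_ctx(random_seq(np.random.default_rng(2), 40), 20, "A")
        res = delta_ss(splice_model, ctx)
        assert res.donor.n_windows == 9
        assert res.natural_donor_score is None  # no intron to read the junction from


class TestEctopicAssessment:
    def _result(self, delta, best_score, natural_donor):
        side = SideDelta(delta, best_start=-3, best_derived_score=best_score, n_windows=9)
        empty = SideDelta(None, None, None, 0)
        return DeltaSSResult(side, empty, natural_donor, None)

    def test_below_threshold_not_ectopic_like(self):
        ctx = make_ctx("ACGTACGTACGTACGTACGT", 5, "G")
        assess = ectopic_assessment(self._result(0.5, 3.0, 8.0), ctx, threshold=1.0)
        assert not assess.ectopic_like

    def test_stronger_than_natural_flagged(self):
        ctx = make_ctx("ACGTACGTACGTACGTACGT", 5, "G")
        assess = ectopic_assessment(self._result(2.0, 8.1, 7.9), ctx)
        assert assess.ectopic_like
        assert assess.ectopic_ge_natural is True
        assert assess.side == "5p"

    def test_opposite_half_recorded(self):
        # variant in the acceptor-proximal (first) half creating a donor site
        ctx = make_ctx("ACGTACGTACGTACGTACGT", 5, "G")
        assess = ectopic_assessment(self._result(2.0, 8.1, 7.9), ctx)
        assert assess.variant_half == "acceptor_half"
        assert assess.same_half_as_site is False
        # and the mirrored case
        ctx2 = make_ctx("ACGTACGTACGTACGTACGT", 15, "C")
        assess2 = ectopic_assessment(self._result(2.0, 8.1, 7.9), ctx2)
        assert assess2.same_half_as_site is True

    def test_fixture_ectopic_cohort_recovers_planted_sides(self, scored, bundle):
        report = scored["ectopic"].report
        truth = {v["id"]: v for v in bundle.manifest["variants"]}
        matches = [
            report.iloc[i]["ectopic_side"] == truth[report.iloc[i]["id"]]["ectopic_side"]
            for i in range(len(report))
        ]
        assert np.mean(matches) > 0.9


class TestSelectEctopicLikeControls:
    def _scored(self, n, rng):
        out = []
        for i in range(n):
            delta = float(rng.uniform(-2, 3))
            best = float(rng.uniform(0, 10))
            side = SideDelta(delta, 0, best, 9)
            out.append((f"v{i:03d}", DeltaSSResult(side, SideDelta(None, None, None, 0), None, None)))
        return out

    def test_top_n_by_best_score_among_qualifiers(self):
        rng = np.random.default_rng(5)
        scored = self._scored(100, rng)
        picked = select_ectopic_like_controls(scored, n=5, threshold=1.0)
        qual = [(k, r) for k, r in scored if r.delta_ss >= 1.0]
        expected = sorted(qual, key=lambda kr: (-kr[1].donor.best_derived_score, kr[0]))[:5]
        assert [k for k, _ in picked] == [k for k, _ in expected]

    def test_zero_requested_returns_empty(self):
        rng = np.random.default_rng(6)
        assert select_ectopic_like_controls(self._scored(10, rng), n=0) == []

    def test_insufficient_qualifiers_warns(self):
        rng = np.random.default_rng(7)
        scored = self._scored(10, rng)
        with pytest.warns(UserWarning, match="requested 9999"):
            picked = select_ectopic_like_controls(scored, n=9999, threshold=1.0)
        assert all(r.delta_ss >= 1.0 for _, r in picked)
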