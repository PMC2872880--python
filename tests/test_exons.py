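"""Exon-definition features: densities, sections, occupancy, site strengths."""

import numpy as np
import pytest

from savscan.exons import (
    FlankDensities,
    esefinder_density,
    esr_density,
    exon_feature_profile,
    exon_position_section,
    exon_sequences,
    expected_snp_exon_length_dist,
    intron_flank_density,
    junction_occupancy_profile,
    qualifies_exon_length,
    splice_site_strengths,
)
from savscan.motifs import ESRMotifSet, Label, PWM, PWMSet
from savscan.variants import ExonModel

from helpers import make_exon, random_seq


class TestESRDensity:
    ess_only = ESRMotifSet("s", 6, {"AAAAAA": Label.ESS})

    def test_saturated_sequence(self):
        d = esr_density(self.ess_only, "A" * 10)
        assert d[Label.ESS] == pytest.approx(1.0)
        assert d[Label.ESE] == 0.0

    def test_no_matches(self):
        assert esr_density(self.ess_only, "CGTCGTCGTC")[Label.ESS] == 0.0

    def test_short_sequence_unscored(self):
        assert esr_density(self.ess_only, "AAAA") is None

    def test_random_sequence_matches_window_count_oracle(self, ni_set):
        rng = np.random.default_rng(21)
        for _ in range(50):
            seq = random_seq(rng, 60)
            d = esr_density(ni_set, seq)
            for label in (Label.ESE, Label.ESS):
                hits = sum(
                    ni_set.motifs.get(seq[s : s + 6]) is label for s in range(55)
                )
                assert d[label] == pytest.approx(hits / 55)

    def test_disjoint_label_densities_sum_below_one(self, ni_set):
        rng = np.random.default_rng(22)
        seq = random_seq(rng, 200)
        d = esr_density(ni_set, seq)
        assert 0.0 <= d[Label.ESE] + d[Label.ESS] <= 1.0


class TestPWMDensity:
    def test_unreachable_thresholds_give_zero(self):
        pwms = PWMSet("p", (PWM("m", np.zeros((4, 6)), threshold=1e12),))
        assert esefinder_density(pwms, "ACGT" * 10) == 0.0

    def test_always_hitting_matrix_contributes_one(self):
        pwms = PWMSet(
            "p",
            (
                PWM("hit", np.zeros((4, 6)), threshold=-1.0),
                PWM("miss", np.zeros((4, 8)), threshold=1e12),
            ),
        )
        assert esefinder_density(pwms, "ACGT" * 10) == pytest.approx(1.0)

    def test_matches_per_matrix_oracle(self, pwms):
        rng = np.random.default_rng(23)
        seq = random_seq(rng, 120)
        total = esefinder_density(pwms, seq)
        expected = 0.0
        for pwm in pwms.matrices:
            n = len(seq) - pwm.width + 1
            hits = sum(pwm.score(seq[s : s + pwm.width]) >= pwm.threshold for s in range(n))
            expected += hits / n
        assert total == pytest.approx(expected)


class TestIntronFlankDensity:
    def _exon_on_chrom(self, up_intron: str, exon_seq: str, down_intron: str):
        chrom = "C" * 20 + up_intron + exon_seq + down_intron + "C" * 20
        start = 20 + len(up_intron)
        exon = ExonModel(
            "chrT", start, start + len(exon_seq), "+",
            transcript_id="t", exon_index=1, n_exons=3,
            upstream_intron_length=len(up_intron),
            downstream_intron_length=len(down_intron),
        )
        return {"chrT": chrom}, exon

    def test_intron_101_excluded(self):
        genome, exon = self._exon_on_chrom("T" * 101, "ACGT" * 10, "G" * 300)
        assert intron_flank_density(ESRMotifSet("s", 6, {}), genome, exon) is None

    def test_intron_102_scored_on_exactly_100_bases(self):
        ess = ESRMotifSet("s", 6, {"TTTTTT": Label.ESS})
        up = "A" * 2 + "T" * 98 + "AG"  # junction AG excluded; 98 T's + 2 A's measured
        genome, exon = self._exon_on_chrom(up, "ACGT" * 10, "GT" + "C" * 100)
        d = intron_flank_density(ess, genome, exon)
        assert d is not None
        # measured window is up[:-2][-100:]: 2 A's then 98 T's -> 93 of 95 windows
        assert d.upstream[Label.ESS] == pytest.approx(93 / 95)

    def test_planted_ess_flank_saturates(self):
        ess = ESRMotifSet("s", 6, {"TTTTTT": Label.ESS})
        genome, exon = self._exon_on_chrom("T" * 100 + "AG", "ACGT" * 10, "GT" + "T" * 100)
        d = intron_flank_density(ess, genome, exon)
        assert d.upstream[Label.ESS] == pytest.approx(1.0)
        assert d.downstream[Label.ESS] == pytest.approx(1.0)


class TestExonPositionSection:
    @pytest.mark.parametrize(
        "length,offset,section,peripheral",
        [
            (120, 0, 1, True),
            (600, 300, 4, False),  # exact midpoint falls in section 4 (half-open bins)
            (120, 119, 6, True),
            (120, 60, 4, False),
        ],
    )
    def test_binning(self, length, offset, section, peripheral):
        assert exon_position_section(length, offset) == (section, peripheral)

    def test_outside_exon_is_contract_error(self):
        with pytest.raises(ValueError):
            exon_position_section(100, 100)

    def test_symmetric_under_reversal(self):
        # exact mirror symmetry holds when the exon divides evenly into sixths
        rng = np.random.default_rng(31)
        for _ in range(200):
            length = 6 * int(rng.integers(4, 80))
            offset = int(rng.integers(0, length))
            s_fwd, _ = exon_position_section(length, offset)
            s_rev, _ = exon_position_section(length, length - 1 - offset)
            assert s_fwd == 7 - s_rev


class TestExpectedExonLengthDist:
    def test_literal_formula(self):
        fr = expected_snp_exon_length_dist({100: 500}, p_snp=0.001)
        assert fr[100] == pytest.approx(0.5)

    def test_zero_probability(self):
        fr = expected_snp_exon_length_dist({50: 10, 60: 20}, p_snp=0.0)
        assert all(v == 0.0 for v in fr.values())

    def test_length_weighted_mode_matches_placement_simulation(self):
        """Under per-base SNP placement, the chance an exon carries a SNP
        scales with its length; the weighted mode reproduces that shape."""
        rng = np.random.default_rng(41)
        hist = {n: int(rng.integers(50, 300)) for n in range(20, 320, 50)}
        p_snp = 1e-4  # SNP-per-base rate; small enough for the linear regime
        fr = expected_snp_exon_length_dist(hist, p_snp=p_snp, length_weighted=True)
        total = sum(fr.values())
        # oracle: per-base placement, P(exon of length n carries a SNP)
        carriers = {n: obs * (1 - (1 - p_snp) ** n) for n, obs in hist.items()}
        carrier_total = sum(carriers.values())
        for n in hist:
            assert fr[n] / total == pytest.approx(carriers[n] / carrier_total, rel=0.05)

    def test_empty_histogram_is_error(self):
        with pytest.raises(ValueError):
            expected_snp_exon_length_dist({})


class TestJunctionOccupancy:
    def _cohort(self, n_exons: int, up: str, exon_seq: str, down: str):
        genome = {}
        exons = []
        for i in range(n_exons):
            chrom = f"chr{i}"
            genome[chrom] = "A" * 10 + up + exon_seq + down + "A" * 10
            start = 10 + len(up)
            exons.append(
                ExonModel(
                    chrom, start, start + len(exon_seq), "+",
                    transcript_id=f"t{i}", exon_index=1, n_exons=3,
                    upstream_intron_length=len(up), downstream_intron_length=len(down),
                )
            )
        return genome, exons

    def test_empty_motif_set_gives_zero_occupancy(self):
        genome, exons = self._cohort(3, "T" * 220, "ACGT" * 30, "G" * 220)
        profile = junction_occupancy_profile(ESRMotifSet("e", 6, {}), genome, exons)
        assert (profile["ese_fraction"] == 0).all()
        assert (profile["ess_fraction"] == 0).all()
        assert len(profile) == 2 * (150 - 5)

    def test_planted_intronic_ess_recovered_at_exact_positions(self):
        """An ESS placed at intron -10..-5 of every exon shows occupancy 1.0."""
        up = "C" * 220
        up = up[:-10] + "TTTTTT" + up[-4:]  # motif occupies intron -10..-5
        genome, exons = self._cohort(4, up, "ACGT" * 30, "G" * 220)
        ess = ESRMotifSet("s", 6, {"TTTTTT": Label.ESS})
        profile = junction_occupancy_profile(ess, genome, exons)
        acceptor = profile[profile["junction"] == "acceptor"].set_index("position")
        assert acceptor.loc[-10, "ess_fraction"] == pytest.approx(1.0)
        assert acceptor.loc[-20, "ess_fraction"] == 0.0

    def test_fractions_bounded_and_disjoint(self, ni_set, genome, internal_exons):
        profile = junction_occupancy_profile(ni_set, genome, internal_exons)
        assert ((profile["ese_fraction"] >= 0) & (profile["ese_fraction"] <= 1)).all()
        assert ((profile["ese_fraction"] + profile["ess_fraction"]) <= 1 + 1e-12).all()

    def test_no_qualifying_exons_is_error(self):
        genome, exons = self._cohort(2, "T" * 50, "ACGT" * 30, "G" * 50)  # introns too short
        with pytest.raises(ValueError, match="qualify"):
            junction_occupancy_profile(ESRMotifSet("e", 6, {}), genome, exons)


class TestSpliceSiteStrengths:
    def test_deterministic_pair(self, splice_model, genome, internal_exons):
        exon = internal_exons[0]
        a = splice_site_strengths(splice_model, genome, exon)
        b = splice_site_strengths(splice_model, genome, exon)
        assert (a.donor, a.acceptor) == (b.donor, b.acceptor)

    def test_fixture_junctions_are_canonical(self, splice_model, genome, internal_exons):
        flags = [splice_site_strengths(splice_model, genome, e).canonical for e in internal_exons]
        assert all(flags)

    def test_gc_donor_flagged_noncanonical(self, splice_model):
        up = "T" * 25
        down = "GC" + "A" * 25  # GC donor
        chrom = up + "ACG" * 20 + down
        exon = ExonModel(
            "chrT", 25, 25 + 60, "+", transcript_id="t", exon_index=1, n_exons=3,
            upstream_intron_length=25, downstream_intron_length=27,
        )
        scores = splice_site_strengths(splice_model, {"chrT": chrom}, exon)
        assert scores.donor_dinucleotide == "GC"
        assert scores.canonical is False
        assert scores.donor is not None  # scored anyway

    def test_matches_direct_backend_on_hand_extracted_windows(
        self, splice_model, genome, internal_exons
    ):
        for exon in internal_exons[:10]:
            up, exon_seq, down = exon_sequences(genome, exon, 25)
            expected_donor = splice_model.score(exon_seq[-3:] + down[:6], "5p")
            expected_acceptor = splice_model.score(up[-20:] + exon_seq[:3], "3p")
            scores = splice_site_strengths(splice_model, genome, exon)
            assert scores.donor == pytest.approx(expected_donor)
            assert scores.acceptor == pytest.approx(expected_acceptor)


class TestExonProfile:
    def test_length_bounds_filter(self):
        assert qualifies_exon_length(make_exon(20))
        assert qualifies_exon_length(make_exon(1000))
        assert not qualifies_exon_length(make_exon(19))
        assert not qualifies_exon_length(make_exon(1001))

    def test_profile_row_is_complete(self, genome, internal_exons, ni_set, pwms, splice_model):
        profile = exon_feature_profile(genome, internal_exons[0], [ni_set], pwms, splice_model)
        row = profile.to_row()
        assert row["exon_length"] == internal_exons[0].length
        assert 0 <= row["ni_like_ese_density"] <= 1
        assert 0 <= row["ni_like_ess_density"] <= 1
        assert row["canonical_junctions"] is True
        assert not row["ni_like_flank_excluded"]
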