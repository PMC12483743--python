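"""Cleavage, nomenclature, features, CAP18 scoring and the 8-type classifier."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cathmine.core_io import CathmineError
from cathmine.peptide_derivation import (
    Cap18Motif,
    Cap18Status,
    NoCleavageSiteError,
    PeptideType,
    cap18_score,
    classify,
    cleave_at_first_valine,
    cysteine_spacings,
    name_peptide,
    peptide_features,
    secondary_structure,
)

AA = "ACDEFGHIKLMNPQRSTWY"  # no V, for the left-inverse property


class TestCleavage:
    @pytest.mark.parametrize(
        "precursor,peptide,propiece",
        [
            ("QAVGRRK", "GRRK", "QAV"),
            ("VKRFK", "KRFK", "V"),
            ("QAVGRRK*", "GRRK", "QAV"),  # stop-trimmed input accepted
        ],
    )
    def test_rule(self, precursor, peptide, propiece):
        cut = cleave_at_first_valine(precursor)
        assert (cut.peptide, cut.propiece) == (peptide, propiece)

    def test_no_valine_is_an_error(self):
        with pytest.raises(NoCleavageSiteError):
            cleave_at_first_valine("GRRKK")

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(pep=st.text(alphabet=AA, min_size=1, max_size=30))
    def test_left_inverse_of_prepending_valine(self, pep):
        assert cleave_at_first_valine("V" + pep).peptide == pep


class TestNaming:
    def test_documented_example(self):
        pep = "PR" + "K" * 29  # 31 residues starting PR
        assert name_peptide("Pteronotus", "mesoamericanus", pep) == "Pme_PR31"

    def test_grammar(self):
        assert name_peptide("Desmodus", "rotundus", "GRK") == "Dro_GR3"

    def test_collision_appends_occurrence_index(self):
        prior = {"Dro_GR3"}
        assert name_peptide("Desmodus", "rotundus", "GRK", prior) == "Dro_GR3-2"
        prior.add("Dro_GR3-2")
        assert name_peptide("Desmodus", "rotundus", "GRK", prior) == "Dro_GR3-3"

    def test_invalid_inputs(self):
        with pytest.raises(CathmineError):
            name_peptide("D3smodus", "rotundus", "GRK")
        with pytest.raises(CathmineError):
            name_peptide("Desmodus", "rotundus", "G")

    def test_injective_within_run(self):
        prior: set = set()
        names = []
        for _ in range(5):
            n = name_peptide("Desmodus", "rotundus", "GRKK", prior)
            assert n not in prior
            prior.add(n)
            names.append(n)
        assert len(set(names)) == 5


class TestCysteineSpacings:
    def test_probe_quartet(self, probe):
        assert cysteine_spacings(probe.residues, conserved_quartet=True) == [10, 10, 16]

    @pytest.mark.parametrize(
        "seq,expected", [("CACC", [1, 0]), ("AAAA", []), ("C", [])]
    )
    def test_plain(self, seq, expected):
        assert cysteine_spacings(seq) == expected

    def test_quartet_requires_four(self):
        with pytest.raises(CathmineError):
            cysteine_spacings("CAC", conserved_quartet=True)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seq=st.text(alphabet="ACDEFGHIK", min_size=0, max_size=40))
    def test_spacings_consistent_with_positions(self, seq):
        gaps = cysteine_spacings(seq)
        n_cys = seq.count("C")
        assert len(gaps) == max(0, n_cys - 1)
        if n_cys >= 2:
            positions = [i for i, c in enumerate(seq) if c == "C"]
            assert sum(gaps) + (n_cys - 1) == positions[-1] - positions[0]


class TestCap18:
    def test_consensus_is_present(self, motif):
        score, status = cap18_score(motif.consensus, motif)
        assert status == Cap18Status.present
        assert score == pytest.approx(float(motif.profile.max(axis=1).sum()))

    def test_mutated_anchors_block_present(self, motif):
        seq = list(motif.consensus)
        for p in motif.anchor_positions:
            seq[p] = "D"
        _, status = cap18_score("".join(seq), motif)
        assert status != Cap18Status.present

    def test_shuffled_consensus_rarely_scores(self, motif):
        rng = np.random.default_rng(99)
        non_absent = 0
        chars = list(motif.consensus)
        for _ in range(200):
            rng.shuffle(chars)
            _, status = cap18_score("".join(chars), motif)
            if status != Cap18Status.absent:
                non_absent += 1
        assert non_absent <= 10  # <=5% of 200

    def test_thresholds_ordered(self, motif):
        assert motif.theta_present > motif.theta_similar
        with pytest.raises(CathmineError):
            Cap18Motif(
                profile=motif.profile,
                anchor_positions=motif.anchor_positions,
                theta_present=1.0,
                theta_similar=2.0,
                consensus=motif.consensus,
            )


class TestSecondaryStructure:
    def test_polyalanine_single_helix(self):
        ss = secondary_structure("A" * 20)
        feats = peptide_features("A" * 20)
        assert set(ss) == {"H"}
        assert feats.helix_segments == 1

    def test_helix_breakers_make_no_helix(self):
        ss = secondary_structure("PG" * 10)
        assert "H" not in ss

    def test_override_respected_verbatim(self):
        ss = secondary_structure("A" * 10, override="HHHHHCCTTE")
        assert ss == "HHHHHCCTTE"
        with pytest.raises(CathmineError):
            secondary_structure("A" * 10, override="HHH")

    def test_short_runs_demoted(self):
        # two helix residues in a coil context cannot form a segment
        ss = secondary_structure("PPGGAAPPGG")
        assert "H" not in ss


# constructed fixtures, one per structural type
HELIX = "LKKLAEKLAEAAKKLL"  # strong amphipathic helix block
TYPE_FIXTURES = {
    PeptideType.T8: "RC" + "RKLLRKIGEKLR" + "GN" + "CR",  # 2 Cys, 14 between
    PeptideType.T6: "RRPPIRRPPIRRPPLR",  # Pro- and Arg-rich
    PeptideType.T7: "GRRRRWGRRRRWGRRR",  # Arg-rich, Pro-free
}


def _cap(status):
    return status


class TestClassify:
    def test_type8_two_cysteines_14_spacer(self):
        seq = TYPE_FIXTURES[PeptideType.T8]
        feats = peptide_features(seq)
        assert len(feats.cys_positions) == 2
        assert feats.cys_spacings == [14]
        assert classify(feats, Cap18Status.absent) == PeptideType.T8

    def test_type6_pro_and_arg_rich(self):
        feats = peptide_features(TYPE_FIXTURES[PeptideType.T6])
        assert feats.pro_fraction >= 0.15 and feats.arg_fraction >= 0.20
        assert classify(feats, Cap18Status.absent) == PeptideType.T6

    def test_type7_arg_rich_pro_free(self):
        feats = peptide_features(TYPE_FIXTURES[PeptideType.T7])
        assert classify(feats, Cap18Status.absent) == PeptideType.T7

    def test_cap18_switch_T1_vs_T3(self):
        feats = peptide_features(HELIX)
        assert feats.helix_segments == 1 and feats.strand_segments == 0
        assert classify(feats, Cap18Status.present) == PeptideType.T1
        assert classify(feats, Cap18Status.absent) == PeptideType.T3
        # 'similar' routes with the CAP18-positive branch
        assert classify(feats, Cap18Status.similar) == PeptideType.T1

    def test_helix_turn_helix_T2_vs_T5(self):
        seq = HELIX + "NPGN" + HELIX
        feats = peptide_features(seq)
        assert feats.helix_segments == 2 and feats.turn_segments >= 1
        assert classify(feats, Cap18Status.present) == PeptideType.T2
        assert classify(feats, Cap18Status.absent) == PeptideType.T5

    def test_helix_plus_strand_T4(self):
        seq = HELIX + "GGNG" + "VIYVIYVI"
        feats = peptide_features(seq)
        assert feats.helix_segments >= 1 and feats.strand_segments >= 1
        assert classify(feats, Cap18Status.absent) == PeptideType.T4

    def test_all_eight_types_reachable(self):
        seen = set()
        cases = [
            (TYPE_FIXTURES[PeptideType.T8], Cap18Status.absent),
            (TYPE_FIXTURES[PeptideType.T6], Cap18Status.absent),
            (TYPE_FIXTURES[PeptideType.T7], Cap18Status.absent),
            (HELIX, Cap18Status.present),
            (HELIX, Cap18Status.absent),
            (HELIX + "NPGN" + HELIX, Cap18Status.present),
            (HELIX + "NPGN" + HELIX, Cap18Status.absent),
            (HELIX + "GGNG" + "VIYVIYVI", Cap18Status.absent),
        ]
        for seq, cap in cases:
            seen.add(classify(peptide_features(seq), cap))
        assert seen == {
            PeptideType.T1, PeptideType.T2, PeptideType.T3, PeptideType.T4,
            PeptideType.T5, PeptideType.T6, PeptideType.T7, PeptideType.T8,
        }

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=4, max_size=40),
        cap=st.sampled_from(list(Cap18Status)),
    )
    def test_total_function(self, seq, cap):
        assert classify(peptide_features(seq), cap) in PeptideType
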