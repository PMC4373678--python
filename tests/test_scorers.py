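"""The ten evidence scorers, singly and composed."""

import dataclasses

import pytest

from mpsscore import EvidenceError, parse_mutation_label
from mpsscore.evidence import Alignment, CodonUsageTable, ResidueAnnotation, SiteConfig, StabilityCalls
from mpsscore.scorers import (
    ScorerResult,
    charge_class,
    score_all,
    score_p1_translation,
    score_p2_aggregation,
    score_p3_stability,
    score_p4_secondary_structure,
    score_p5_catalytic_proximity,
    score_p6_glycosylation,
    score_p7_flexibility,
    score_p8_surface,
    score_p9_conservation,
    score_p10_physiology,
)


def mut(label):
    return parse_mutation_label(label)


def make_codon_table(**abundances):
    from Bio.Data.CodonTable import standard_dna_table

    return CodonUsageTable(
        abundance=dict(abundances),
        amino_acid={c: standard_dna_table.forward_table[c] for c in abundances},
    )


class TestTranslationRate:
    def test_rare_mutant_codon_scores(self):
        table = make_codon_table(CGC=10.0, CAC=2.0)  # Arg, His
        m = dataclasses.replace(mut("Arg1His"), wt_codon="CGC", mut_codon="CAC")
        res = score_p1_translation(m, cds="CGC", codon_table=table, ratio_threshold=0.5)
        assert res.score == 1 and res.rationale["mut_abundance"] == 2.0

    @pytest.mark.parametrize("mut_ab", [10.0, 20.0, 5.0])
    def test_equal_or_more_abundant_mutant_scores_zero(self, mut_ab):
        table = make_codon_table(CGC=10.0, CAC=mut_ab)
        m = dataclasses.replace(mut("Arg1His"), wt_codon="CGC", mut_codon="CAC")
        assert score_p1_translation(m, "CGC", table).score == 0

    def test_threshold_is_strict(self):
        table = make_codon_table(CGC=10.0, CAC=5.0)
        m = dataclasses.replace(mut("Arg1His"), wt_codon="CGC", mut_codon="CAC")
        assert score_p1_translation(m, "CGC", table, ratio_threshold=0.5).score == 0

    def test_cds_wt_codon_mismatch_rejected(self):
        table = make_codon_table(CGC=10.0, CAC=2.0)
        with pytest.raises(EvidenceError, match="does not encode"):
            score_p1_translation(mut("His1Arg"), "CGC", table)


class TestAggregation:
    def test_lowered_propensity_scores_zero(self):
        # Trp -> Ser strictly lowers a3v; no hot-spot change possible
        seq = "S" * 10 + "W" + "S" * 10
        assert score_p2_aggregation(mut("Trp11Ser"), seq).score == 0

    def test_new_hot_spot_at_site_scores(self):
        # D9: IIII_DIII with X->W bridges two sub-threshold runs into a spot
        seq = "DDDDDIIDIIDDDDDDDDDDDDDDDDDDDD"
        res = score_p2_aggregation(mut("Asp8Trp"), seq)
        assert res.score == 1
        assert res.rationale["new_hot_spot"] or res.rationale["delta_na4vss"] > 0

    def test_synthetic_sgsh_ser66trp_regression(self):
        from mpsscore.fixtures import synthetic_sgsh_like_sequence

        seq = synthetic_sgsh_like_sequence()
        assert seq[65] == "S"
        assert score_p2_aggregation(mut("Ser66Trp"), seq).score == 1

    def test_position_out_of_range(self):
        with pytest.raises(EvidenceError):
            score_p2_aggregation(mut("Ser99Trp"), "S" * 20)


class TestStability:
    def test_direct_class_pass_through(self):
        calls = StabilityCalls(classes={"Arg245His": 2})
        assert score_p3_stability(mut("Arg245His"), calls).score == 2

    @pytest.mark.parametrize("value, expected", [(-1.5, 2), (-0.7, 1), (0.3, 0), (-0.5, 0)])
    def test_raw_value_mapping(self, value, expected):
        calls = StabilityCalls(raw_values={"Arg245His": value})
        res = score_p3_stability(mut("Arg245His"), calls, thresholds=(-1.0, -0.5))
        assert res.score == expected

    def test_missing_call_rejected(self):
        with pytest.raises(EvidenceError, match="no stability call"):
            score_p3_stability(mut("Arg245His"), StabilityCalls())


def ann(ss, rsa=0.5, position=1):
    return {position: ResidueAnnotation(position=position, ss=ss, rsa=rsa)}


class TestSecondaryStructure:
    def test_coil_always_zero(self):
        assert score_p4_secondary_structure(mut("Ala1Pro"), ann("C")).score == 0

    @pytest.mark.parametrize("label", ["Ala1Pro", "Ala1Gly"])
    def test_helix_breaker_residues(self, label):
        assert score_p4_secondary_structure(mut(label), ann("H")).score == 1

    def test_strand_propensity_breaker_clause(self):
        # Val (P_beta 1.70) -> Asp (P_beta 0.54 <= 0.75)
        res = score_p4_secondary_structure(mut("Val1Asp"), ann("E"))
        assert res.score == 1 and res.rationale["element"] == "E"

    def test_conservative_helix_substitution_zero(self):
        assert score_p4_secondary_structure(mut("Leu1Met"), ann("H")).score == 0

    def test_missing_annotation(self):
        with pytest.raises(EvidenceError):
            score_p4_secondary_structure(mut("Ala9Pro"), ann("H"))


def linear_structure(n, spacing=4.0):
    from mpsscore.evidence import Atom

    return [
        Atom(chain="A", resnum=i, resname="ALA", name="CA", x=spacing * (i - 1), y=0.0, z=0.0)
        for i in range(1, n + 1)
    ]


class TestCatalyticProximity:
    @pytest.mark.parametrize(
        "position, cutoff, expected",
        [(2, 8.0, 1),     # 4 A away
         (6, 8.0, 0),     # 20 A away
         (3, 8.0, 1)],    # exactly at the 8 A cutoff: inclusive
    )
    def test_distance_rule(self, position, cutoff, expected):
        sites = SiteConfig(catalytic_residues=[1], proximity_cutoff=cutoff)
        m = mut(f"Ala{position}Ser")
        res = score_p5_catalytic_proximity(m, linear_structure(10), sites)
        assert res.score == expected

    def test_empty_catalytic_list_rejected(self):
        with pytest.raises(EvidenceError):
            score_p5_catalytic_proximity(mut("Ala2Ser"), linear_structure(5), SiteConfig())


class TestGlycosylation:
    def test_sequon_destroyed(self):
        res = score_p6_glycosylation(mut("Ser7Ala"), "AAAANAS", SiteConfig())
        assert res.score == 1 and res.rationale["sequons_destroyed"] == [5]

    def test_sequon_created(self):
        # NCA -> NCT creates N-C-T
        res = score_p6_glycosylation(mut("Ala7Thr"), "AAAANCA", SiteConfig())
        assert res.score == 1 and res.rationale["sequons_created"] == [5]

    def test_proline_x_blocks_sequon(self):
        # N-P-S is not a sequon, so destroying the S changes nothing
        assert score_p6_glycosylation(mut("Ser7Ala"), "AAAANPS", SiteConfig()).score == 0

    def test_near_configured_asn(self):
        sites = SiteConfig(glycosylated_asn=[41])
        seq = "A" * 50
        assert score_p6_glycosylation(mut("Ala42Lys"), seq, sites, sequon_window=2).score == 1
        assert score_p6_glycosylation(mut("Ala44Lys"), seq, sites, sequon_window=2).score == 0


class TestFlexibility:
    @pytest.mark.parametrize(
        "label, expected",
        [("Ala30Pro", 1), ("Arg182Cys", 1), ("Thr139Met", 0), ("Gly33Arg", 1), ("Ser298Pro", 1)],
    )
    def test_pgc_rule_matches_reference_rows(self, label, expected):
        assert score_p7_flexibility(mut(label)).score == expected


class TestSurface:
    def test_buried_hydrophobic_to_charged(self):
        res = score_p8_surface(mut("Leu1Arg"), ann("C", rsa=0.05))
        assert res.score == 1
        assert res.rationale["buried_class_swap"] and res.rationale["charge_change"]

    def test_exposed_conservative_polar_swap_zero(self):
        assert score_p8_surface(mut("Ser1Thr"), ann("C", rsa=0.6)).score == 0

    def test_charge_loss_scores_anywhere(self):
        assert score_p8_surface(mut("Asp1Asn"), ann("C", rsa=0.6)).score == 1
        assert score_p8_surface(mut("Asp1Asn"), ann("C", rsa=0.05)).score == 1

    def test_charge_classes(self):
        assert [charge_class(a) for a in "DEKRHS"] == [-1, -1, 1, 1, 1, 0]


class TestConservation:
    def make_msa(self, column):
        # target AAAAA...; homolog residues at position 3 given by `column`
        seqs = {"t": "AAAAA"}
        for i, c in enumerate(column):
            seqs[f"h{i}"] = "AA" + c + "AA"
        return Alignment(sequences=seqs, target_id="t")

    def test_fully_conserved(self):
        msa = self.make_msa("AAAAA")
        assert score_p9_conservation(mut("Ala3Val"), msa).score == 1

    def test_fully_divergent(self):
        msa = self.make_msa("VVVVV")
        assert score_p9_conservation(mut("Ala3Val"), msa).score == 0

    @pytest.mark.parametrize("threshold, expected", [(0.6, 1), (0.7, 0)])
    def test_threshold_boundary(self, threshold, expected):
        msa = self.make_msa("AAAVV")  # 3/5 identity
        res = score_p9_conservation(mut("Ala3Val"), msa, identity_threshold=threshold)
        assert res.score == expected and res.rationale["identity_fraction"] == 0.6

    def test_gaps_excluded_from_denominator(self):
        msa = self.make_msa("AA---")  # 2/2 non-gap match
        assert score_p9_conservation(mut("Ala3Val"), msa).rationale["identity_fraction"] == 1.0


class TestPhysiology:
    def test_listed_site_membership(self):
        sites = SiteConfig(ca_ligands=[5])
        assert score_p10_physiology(mut("Ala5Ser"), None, sites).score == 1

    def test_far_from_all_sites(self):
        sites = SiteConfig(dimer_interface=[10], proximity_cutoff=8.0)
        assert score_p10_physiology(mut("Ala1Ser"), linear_structure(10), sites).score == 0

    def test_proximity_to_listed_site(self):
        sites = SiteConfig(dimer_interface=[2], proximity_cutoff=8.0)
        assert score_p10_physiology(mut("Ala3Ser"), linear_structure(10), sites).score == 1

    def test_both_lists_empty_rejected(self):
        with pytest.raises(EvidenceError):
            score_p10_physiology(mut("Ala1Ser"), None, SiteConfig(catalytic_residues=[1]))


class TestScoreAll:
    def test_engineered_totals(self, toy_bundle, toy_truth):
        for label, expected in toy_truth.items():
            if "total" not in expected:
                continue
            outcome = score_all(parse_mutation_label(label), toy_bundle)
            assert outcome.scores.total == expected["total"], label

    def test_planted_features_fire(self, toy_bundle, toy_truth):
        scorers = {
            3: lambda m: score_p3_stability(m, toy_bundle.stability),
            4: lambda m: score_p4_secondary_structure(m, toy_bundle.annotations),
            5: lambda m: score_p5_catalytic_proximity(m, toy_bundle.structure, toy_bundle.sites),
            6: lambda m: score_p6_glycosylation(m, toy_bundle.protein_seq, toy_bundle.sites),
            7: lambda m: score_p7_flexibility(m),
            8: lambda m: score_p8_surface(m, toy_bundle.annotations),
            9: lambda m: score_p9_conservation(m, toy_bundle.msa),
            10: lambda m: score_p10_physiology(m, toy_bundle.structure, toy_bundle.sites),
        }
        for label, expected in toy_truth.items():
            m = parse_mutation_label(label)
            for parameter, want in expected["params"].items():
                assert scorers[parameter](m).score == want, (label, parameter)

    def test_rationales_cover_all_parameters(self, toy_bundle):
        outcome = score_all(parse_mutation_label("Ala22Pro"), toy_bundle)
        assert [r.parameter for r in outcome.rationales] == list(range(1, 11))
        assert 0 <= outcome.scores.total <= 11

    def test_determinism(self, toy_bundle):
        m = parse_mutation_label("Thr36Ser")
        assert score_all(m, toy_bundle).scores == score_all(m, toy_bundle).scores

    def test_sequence_local_parameters_ignore_remote_evidence(self, toy_bundle):
        """Parameters 1, 6, 7 depend only on sequence-level inputs."""
        m = parse_mutation_label("Thr43Ser")
        base = score_all(m, toy_bundle).scores
        # perturb remote evidence: drop structure atoms beyond residue 45,
        # flip a remote annotation, and shuffle a remote MSA column
        perturbed = dataclasses.replace(
            toy_bundle,
            structure=[a for a in toy_bundle.structure if a.resnum <= 45],
            annotations={
                **toy_bundle.annotations,
                10: ResidueAnnotation(position=10, ss="C", rsa=0.9),
            },
        )
        other = score_all(m, perturbed).scores
        for p in (1, 6, 7):
            assert other[p] == base[p]

    def test_error_annotated_with_parameter(self, toy_bundle):
        bundle = dataclasses.replace(toy_bundle, stability=StabilityCalls())
        with pytest.raises(EvidenceError, match="parameter 3"):
            score_all(parse_mutation_label("Thr43Ser"), bundle)


def test_scorer_result_range_enforced():
    with pytest.raises(ValueError):
        ScorerResult(parameter=7, score=2)
    ScorerResult(parameter=3, score=2)
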