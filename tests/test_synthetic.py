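"""Generator behaviour: identity ranges, planted sites, determinism,
Mendelian pedigrees and phenotype effect recovery."""

import numpy as np
import pytest
from scipy import stats

from polyko.genotyping import call_alleles
from polyko.guides import locate_guide
from polyko.inheritance import PlantGenotype
from polyko.paralogs import pairwise_identity_matrix
from polyko.synthetic import (
    FamilySpec,
    IndelSpectrum,
    PhenotypeEffectSpec,
    PlantedSite,
    simulate_chromatogram,
    simulate_gene_family,
    simulate_nhej_alleles,
    simulate_pedigree,
    simulate_phenotypes,
)

PROTO = "GTCGACTGGACATCAGCTTG"


class TestGeneFamily:
    def test_zero_divergence_gives_identical_copies(self):
        fam = simulate_gene_family(
            FamilySpec(ancestral_length=300, n_copies=2,
                       target_identity_range=(1.0, 1.0), seed=1)
        )
        assert fam.members[0].cds_sequence == fam.members[1].cds_sequence

    def test_pairwise_identities_inside_target_range(self):
        fam = simulate_gene_family(
            FamilySpec(ancestral_length=600, n_copies=4,
                       target_identity_range=(0.89, 0.99), seed=7)
        )
        iu = np.triu_indices(4, 1)
        vals = fam.identity_matrix[iu]
        assert len(vals) == 6
        assert (vals >= 0.89).all() and (vals <= 0.99).all()
        # self-consistency with the discovery module's identity matrix
        recomputed = pairwise_identity_matrix(fam.members)
        np.testing.assert_allclose(recomputed, fam.identity_matrix)

    def test_planted_snp_at_position_10_from_pam(self, snp_family):
        st = snp_family.attrs["site_start"]
        ref = snp_family.members[0].cds_sequence
        snp = snp_family.members[1].cds_sequence
        diffs = [i for i in range(23) if ref[st + i] != snp[st + i]]
        # position 10 from the PAM is protospacer string index 20 - 10
        assert diffs == [10]
        for other in (snp_family.members[2], snp_family.members[3]):
            window = other.cds_sequence[st : st + 23]
            assert window == ref[st : st + 23]

    def test_unreachable_identity_range_raises(self):
        with pytest.raises(ValueError, match="unreachable"):
            simulate_gene_family(
                FamilySpec(ancestral_length=200, n_copies=8,
                           target_identity_range=(0.85, 0.85), seed=0)
            )

    def test_same_seed_is_byte_identical(self):
        spec = dict(ancestral_length=400, n_copies=3,
                    target_identity_range=(0.9, 0.98))
        a = simulate_gene_family(FamilySpec(**spec, seed=5))
        b = simulate_gene_family(FamilySpec(**spec, seed=5))
        assert [m.cds_sequence for m in a.members] == [m.cds_sequence for m in b.members]


class TestIndelSpectrum:
    def test_default_sums_to_one_and_excludes_zero(self):
        s = IndelSpectrum()
        assert abs(sum(s.probs.values()) - 1.0) < 1e-9
        assert 0 not in s.probs
        assert s.insertion_probs == {1: pytest.approx(0.3)}
        assert set(s.deletion_probs) == {-k for k in range(1, 11)}

    def test_invalid_spectra_rejected(self):
        with pytest.raises(ValueError):
            IndelSpectrum({0: 1.0})
        with pytest.raises(ValueError):
            IndelSpectrum({1: 0.5})


class TestNhejAlleles:
    def test_zero_alleles_is_empty(self, snp_family, designed_guide):
        assert simulate_nhej_alleles(
            snp_family.members[0].cds_sequence, designed_guide, 0) == []

    def test_eight_distinct_single_indel_alleles(self, snp_family, designed_guide):
        locus = snp_family.members[0].cds_sequence
        alleles = simulate_nhej_alleles(locus, designed_guide, 8, seed=5)
        assert len(set(alleles)) == 8
        cut, _ = locate_guide(locus, designed_guide)
        for a in alleles:
            call = call_alleles(a, locus, guide=designed_guide)
            assert len(call.events) == 1
            # events sit at the cut window
            assert abs(call.events[0].position) <= 6

    def test_forced_6bp_deletion_is_in_frame(self, snp_family, designed_guide):
        locus = snp_family.members[0].cds_sequence
        alleles = simulate_nhej_alleles(
            locus, designed_guide, 1, spectrum=IndelSpectrum({-6: 1.0}), seed=1)
        assert len(alleles) == 1
        assert len(alleles[0]) == len(locus) - 6
        call = call_alleles(alleles[0], locus, guide=designed_guide)
        assert call.events[0].kind == "deletion"
        assert call.events[0].length == 6
        assert call.frame_consequence == "in-frame"

    def test_too_small_spectrum_errors(self, snp_family, designed_guide):
        locus = snp_family.members[0].cds_sequence
        with pytest.raises(ValueError, match="distinct"):
            # a single fixed deletion cannot give 3 distinct sequences
            simulate_nhej_alleles(locus, designed_guide, 3,
                                  spectrum=IndelSpectrum({-3: 1.0}), seed=0)


class TestChromatogram:
    def test_noiseless_single_allele_round_trips(self):
        seq = "ACGTTGCAGGTACCGT" * 5
        trace = simulate_chromatogram([seq], [1.0], noise_sd=0.0)
        assert trace.base_call()[: len(seq)] == seq

    def test_empty_allele_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_chromatogram([], [])

    def test_weights_must_be_a_distribution(self):
        with pytest.raises(ValueError):
            simulate_chromatogram(["ACGT"], [0.5])

    def test_same_seed_same_trace(self):
        seq = "ACGTACGTACGTACGTACGT" * 3
        a = simulate_chromatogram([seq], [1.0], noise_sd=0.1, seed=3)
        b = simulate_chromatogram([seq], [1.0], noise_sd=0.1, seed=3)
        np.testing.assert_array_equal(a.channels, b.channels)


class TestPedigree:
    def _founder(self, germline=None):
        return PlantGenotype(
            plant_id="F", generation="T1",
            loci={"A": ("A1", "A2", "A3", "Ah"), "E": ("E1", "E2", "Eh")},
            transgenic=True, tdna_count=1,
            germline=germline,
        )

    def test_homozygous_nontransgenic_founder_breeds_true(self):
        founder = PlantGenotype("F", "T1", {"A": ("A1", "A1")}, transgenic=False)
        ped = simulate_pedigree(founder, 2, 20, seed=0)
        for p in ped.plants:
            assert p.loci["A"] == ("A1", "A1")
            assert not p.transgenic

    def test_hemizygous_tdna_segregates_3_to_1(self):
        germ = {"A": ("A1", "Ah"), "E": ("Eh", "Eh")}
        ped = simulate_pedigree(self._founder(germ), 1, 400, seed=2)
        t2 = ped.generation("T2")
        frac = sum(p.transgenic for p in t2) / len(t2)
        # binomial 95% CI around 0.75 at n=400
        assert abs(frac - 0.75) < 1.96 * np.sqrt(0.75 * 0.25 / 400) + 1e-9

    def test_germline_excluded_alleles_never_transmitted(self):
        germ = {"A": ("A1", "Ah"), "E": ("Eh", "Eh")}
        ped = simulate_pedigree(self._founder(germ), 2, 50, seed=3)
        descendants = [p for p in ped.plants if p.plant_id != "F"]
        assert descendants
        for p in descendants:
            assert set(p.loci["E"]) == {"Eh"}

    def test_mendelian_allele_frequencies_chi_square(self):
        founder = PlantGenotype("F", "T1", {"A": ("A1", "Ah")}, transgenic=False)
        ped = simulate_pedigree(founder, 1, 1000, seed=4)
        counts = {"A1": 0, "Ah": 0}
        for p in ped.generation("T2"):
            for a in p.loci["A"]:
                counts[a] += 1
        chi2, p_val = stats.chisquare(list(counts.values()))
        assert p_val >= 0.01

    def test_de_novo_edits_require_transgene(self):
        founder = PlantGenotype("F", "T1", {"A": ("Ah", "Ah")}, transgenic=False,
                                tdna_count=0)
        ped = simulate_pedigree(founder, 2, 50, seed=5, de_novo_rate=0.5)
        for p in ped.plants:
            assert set(p.loci["A"]) == {"Ah"}

    def test_zero_generations_rejected(self):
        with pytest.raises(ValueError):
            simulate_pedigree(self._founder(), 0, 10)


class TestPhenotypes:
    def test_null_effects_leave_means_at_control(self):
        spec = PhenotypeEffectSpec(control_means={"t": 10.0}, effects={},
                                   cv=0.05, n_replicates=50, seed=0)
        table = simulate_phenotypes(["control", "mutant"], spec)
        means = table.groupby("line")["value"].mean()
        assert abs(means["mutant"] - means["control"]) < 0.5

    def test_pi_threefold_effect_recovered(self):
        spec = PhenotypeEffectSpec(
            control_means={"inorganic_P": 1.0},
            effects={"triple": {"inorganic_P": 3.0}},
            cv=0.05, n_replicates=5, seed=11,
        )
        table = simulate_phenotypes(["control", "triple"], spec)
        means = table.groupby("line")["value"].mean()
        fold = means["triple"] / means["control"]
        assert abs(fold - 3.0) <= 0.3

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeEffectSpec(control_means={"t": -1.0}, effects={})
        with pytest.raises(ValueError):
            PhenotypeEffectSpec(control_means={"t": 1.0}, effects={}, cv=1.5)
        with pytest.raises(ValueError):
            PhenotypeEffectSpec(control_means={"t": 1.0}, effects={},
                                n_replicates=1)
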