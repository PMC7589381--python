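"""Guide enumeration, conservation scoring, filtering and off-target scan."""

import re

import numpy as np
import pytest

from polyko._seq import random_dna, revcomp
from polyko.guides import (
    GuideCandidate,
    design_guides,
    enumerate_sites,
    filter_candidates,
    off_target_scan,
    score_conservation,
)
from polyko.paralogs import GeneFamily, ParalogRecord, pairwise_identity_matrix
from polyko.synthetic import FamilySpec, PlantedSite, simulate_gene_family

PROTO = "GTCGACTGGACATCAGCTTG"


def _family_from_seqs(seqs: dict[str, str]) -> GeneFamily:
    members = [
        ParalogRecord(id=k, contig=k, start=0, end=len(v), strand="+",
                      cds_sequence=v)
        for k, v in seqs.items()
    ]
    return GeneFamily("fam", members, pairwise_identity_matrix(members))


class TestEnumerateSites:
    def test_single_forward_site_with_zero_gc(self):
        sites = enumerate_sites("A" * 20 + "TGG")
        fwd = [s for s in sites if s.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].protospacer == "A" * 20
        assert fwd[0].pam == "TGG"
        assert fwd[0].gc_percent == 0.0

    def test_strand_symmetry_of_protospacer_multiset(self):
        seq = random_dna(500, np.random.default_rng(5))
        a = sorted(s.protospacer for s in enumerate_sites(seq))
        b = sorted(s.protospacer for s in enumerate_sites(revcomp(seq)))
        assert a == b

    def test_count_matches_regex_scan_oracle(self):
        seq = random_dna(1000, np.random.default_rng(8))
        expected = len(re.findall("(?=[ACGT]{21}GG)", seq))
        expected += len(re.findall("(?=CC[ACGT]{21})", seq))
        assert len(enumerate_sites(seq)) == expected

    def test_short_sequence_gives_empty_list(self):
        assert enumerate_sites("ACGTACGT") == []


class TestScoreConservation:
    def _candidate_on(self, fam):
        st = fam.attrs["site_start"]
        ref = fam.members[0]
        return GuideCandidate(
            protospacer=ref.cds_sequence[st : st + 20],
            pam=ref.cds_sequence[st + 20 : st + 23],
            reference_paralog=ref.id, site_start=st, site_end=st + 23,
            strand="+", gc_percent=55.0,
        )

    def test_identical_copies_have_empty_profiles(self):
        site = PlantedSite(PROTO, "TGG")
        fam = simulate_gene_family(
            FamilySpec(ancestral_length=300, n_copies=3,
                       target_identity_range=(1.0, 1.0), site_spec=site, seed=0))
        c = score_conservation(self._candidate_on(fam), fam)
        assert all(v == [] for v in c.mismatch_profiles.values())
        assert all(p == c.pam for p in c.pam_profiles.values())

    def test_planted_snp_profile_is_position_10(self, snp_family):
        c = score_conservation(self._candidate_on(snp_family), snp_family)
        snp_id = snp_family.members[1].id
        assert c.mismatch_profiles[snp_id] == [10]
        for m in snp_family.members[2:]:
            assert c.mismatch_profiles[m.id] == []

    def test_ruined_pam_flags_copy_non_targetable(self):
        base = random_dna(200, np.random.default_rng(1)) + PROTO + "TGG" \
            + random_dna(200, np.random.default_rng(2))
        broken = base.replace(PROTO + "TGG", PROTO + "TGT")
        fam = _family_from_seqs({"ok": base, "broken": broken})
        st = base.find(PROTO)
        c = GuideCandidate(PROTO, "TGG", "ok", st, st + 23, "+", 55.0)
        score_conservation(c, fam)
        assert c.mismatch_profiles["broken"] is None

    def test_candidate_off_reference_rejected(self, snp_family):
        c = GuideCandidate("A" * 20, "TGG", snp_family.members[0].id,
                           0, 23, "+", 0.0)
        with pytest.raises(ValueError, match="locate"):
            score_conservation(c, snp_family)


class TestFilterCandidates:
    def _cand(self, gc=55.0, profiles=None, pam="TGG"):
        c = GuideCandidate(PROTO, pam, "ref", 0, 23, "+", gc)
        c.mismatch_profiles = profiles if profiles is not None else {"p2": []}
        c.pam_profiles = {k: pam for k in c.mismatch_profiles}
        return c

    def test_gc_exactly_40_rejected_strict_inequality(self):
        assert filter_candidates([self._cand(gc=40.0)]) == []
        assert len(filter_candidates([self._cand(gc=40.1)])) == 1

    def test_one_snp_at_position_10_accepted(self):
        c = self._cand(profiles={"p2": [10]})
        assert filter_candidates([c]) == [c]

    def test_seed_snp_or_two_snps_rejected(self):
        assert filter_candidates([self._cand(profiles={"p2": [5]})]) == []
        assert filter_candidates([self._cand(profiles={"p2": [11, 15]})]) == []

    def test_non_targetable_paralog_rejected(self):
        assert filter_candidates([self._cand(profiles={"p2": None})]) == []

    def test_pam_mismatch_rejected(self):
        c = self._cand(profiles={"p2": []})
        c.pam_profiles = {"p2": "AGG"}  # differs from candidate's TGG
        assert filter_candidates([c]) == []

    def test_monotone_in_mismatch_tolerance(self):
        cands = [
            self._cand(profiles={"p2": []}),
            self._cand(profiles={"p2": [12]}),
            self._cand(profiles={"p2": [10, 19]}),
        ]
        strict = filter_candidates(cands, max_mismatches=0)
        loose = filter_candidates(cands, max_mismatches=1)
        looser = filter_candidates(cands, max_mismatches=2)
        assert set(map(id, strict)) <= set(map(id, loose)) <= set(map(id, looser))


class TestOffTargetScan:
    def _cand(self):
        return GuideCandidate(PROTO, "TGG", "ref", 300, 323, "+", 55.0)

    def test_family_loci_only_genome_passes(self):
        rng = np.random.default_rng(3)
        contig = random_dna(300, rng) + PROTO + "TGG" + random_dna(300, rng)
        c = self._cand()
        hits = off_target_scan(c, {"c1": contig}, [("c1", 300, 323)])
        assert hits == []
        assert c.off_target_hits == 0

    def test_one_mismatch_copy_with_intact_pam_is_a_hit(self):
        rng = np.random.default_rng(4)
        near = "A" + PROTO[1:] if PROTO[0] != "A" else "C" + PROTO[1:]
        decoy = random_dna(200, rng) + near + "TGG" + random_dna(200, rng)
        hits = off_target_scan(self._cand(), {"decoy": decoy}, [])
        assert len(hits) == 1
        assert hits[0].start == 200
        assert hits[0].mismatches == 1

    def test_planted_copy_with_bad_pam_is_not_a_hit(self):
        rng = np.random.default_rng(5)
        decoy = random_dna(200, rng) + PROTO + "TGT" + random_dna(200, rng)
        hits = off_target_scan(self._cand(), {"decoy": decoy}, [])
        planted = [h for h in hits if h.start == 200 and h.strand == "+"]
        assert planted == []

    def test_reverse_strand_hit_found(self):
        rng = np.random.default_rng(6)
        decoy = random_dna(150, rng) + revcomp(PROTO + "CGG") + random_dna(150, rng)
        hits = off_target_scan(self._cand(), {"decoy": decoy}, [])
        assert any(h.strand == "-" and h.start == 150 for h in hits)

    def test_equals_bruteforce_hamming_oracle(self):
        rng = np.random.default_rng(7)
        genome = {"g": random_dna(20000, rng)}
        c = self._cand()
        hits = off_target_scan(c, genome, [], max_mm=3)

        oracle = set()
        for cname, contig in genome.items():
            for strand, s in (("+", contig), ("-", revcomp(contig))):
                for i in range(len(s) - 22):
                    if s[i + 21 : i + 23] != "GG":
                        continue
                    mm = sum(a != b for a, b in zip(s[i : i + 20], PROTO))
                    if mm <= 3:
                        start = i if strand == "+" else len(s) - i - 23
                        oracle.add((cname, start, strand, mm))
        assert {(h.contig, h.start, h.strand, h.mismatches) for h in hits} == oracle


class TestDesignGuides:
    def test_planted_unique_site_in_identical_family_is_returned(self):
        site = PlantedSite(PROTO, "TGG")
        fam = simulate_gene_family(
            FamilySpec(ancestral_length=300, n_copies=2,
                       target_identity_range=(1.0, 1.0), site_spec=site, seed=4))
        genome = {m.contig: m.cds_sequence for m in fam.members}
        accepted = design_guides(fam, genome)
        assert any(c.protospacer == PROTO for c in accepted)

    def test_snp_site_accepted_but_rejected_at_seed_boundary_20(
            self, snp_family, planted_genome):
        st = snp_family.attrs["site_start"]
        with_default = design_guides(snp_family, planted_genome, seed_boundary=10)
        planted = [c for c in with_default
                   if c.site_start == st and c.strand == "+"]
        assert len(planted) == 1
        # no SNP tolerated anywhere: the planted site (1 mismatch) must go
        strict = design_guides(snp_family, planted_genome, seed_boundary=21)
        assert all(c.total_mismatches == 0 for c in strict)

    def test_off_target_kills_the_only_candidate(self):
        site = PlantedSite(PROTO, "TGG")
        fam = simulate_gene_family(
            FamilySpec(ancestral_length=300, n_copies=2,
                       target_identity_range=(1.0, 1.0), site_spec=site, seed=4))
        genome = {m.contig: m.cds_sequence for m in fam.members}
        # plant a near-copy of every family site in a decoy contig
        rng = np.random.default_rng(9)
        decoy = random_dna(100, rng)
        for c in design_guides(fam, genome):
            decoy += c.protospacer + "TGG" + random_dna(20, rng)
        genome["decoy"] = decoy
        log: list[str] = []
        accepted = design_guides(fam, genome, log=log)
        assert accepted == []
        assert any("design failed" in line for line in log)

    def test_ranking_prefers_fewer_mismatches(self, snp_family, planted_genome):
        accepted = design_guides(snp_family, planted_genome)
        mms = [c.total_mismatches for c in accepted]
        assert mms == sorted(mms)
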