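"""Block anchoring, hairpin validation, mature/star/isomiR calling."""

import numpy as np
import pytest
from scipy.stats import binom

from seedmir._seq import revcomp
from seedmir.discover import (AnchorBlock, ContigHit, DiscoveryParams,
                              MatureLocus, PrecursorCandidate,
                              call_mature_star_isomirs, classify_precursor,
                              discover_precursors, extract_window,
                              find_blocks, first_nucleotide_profile,
                              hairpin_metrics, map_tags, novel_family_filter,
                              validate_hairpin)
from seedmir.folding import fold, pair_table, terminal_loop
from seedmir.preprocess import SmallRNATag
from seedmir.simulate import simulate_hairpin


def tag(seq, n=1, lib="A"):
    return SmallRNATag(sequence=seq, counts={lib: n})


def hit(t, contig="c", start=0, strand="+"):
    return ContigHit(t, contig, start, start + len(t.sequence), strand)


class TestMapTags:
    CONTIG = ("GGCATCGGATCAATCGGATCGGATTGACAGAAGAGAGTGAGCACAGGATCCGGATC"
              "GGATCCGGATTAAGGCCTTAAGGCCAATT")

    def test_plus_strand_hit(self):
        t = tag(self.CONTIG[25:46])
        [h] = map_tags([t], {"c1": self.CONTIG})
        assert (h.start, h.end, h.strand) == (25, 46, "+")

    def test_minus_strand_hit(self):
        t = tag(revcomp(self.CONTIG[30:51]))
        [h] = map_tags([t], {"c1": self.CONTIG})
        assert (h.start, h.end, h.strand) == (30, 51, "-")
        assert revcomp(self.CONTIG[h.start:h.end]) == t.sequence

    def test_absent_tag_no_hits(self):
        assert map_tags([tag("T" * 21)], {"c1": self.CONTIG}) == []


class TestFindBlocks:
    def test_eleven_reads_one_block_passes(self):
        t = tag("A" * 21, n=12)
        result = find_blocks([hit(t, start=50)])["c"]
        assert result.passed and len(result.blocks) == 1

    def test_ten_reads_fails(self):
        t = tag("A" * 21, n=10)
        result = find_blocks([hit(t, start=50)])["c"]
        assert not result.passed

    def test_three_blocks_fail(self):
        hits = [hit(tag("A" * 21, n=4), start=s) for s in (10, 100, 200)]
        result = find_blocks(hits)["c"]
        assert len(result.blocks) == 3 and not result.passed

    def test_opposite_strands_fail(self):
        hits = [hit(tag("A" * 21, n=6), start=10),
                hit(tag("C" * 21, n=6), start=60, strand="-")]
        result = find_blocks(hits)["c"]
        assert not result.passed
        assert "strand" in result.reasons[0]

    def test_chaining_is_transitive(self):
        # starts 10, 13, 16: pairwise gap 3 chains all three into one block
        hits = [hit(tag("A" * 21, n=4), start=s) for s in (10, 13, 16)]
        result = find_blocks(hits, chain_gap=3)["c"]
        assert len(result.blocks) == 1 and result.passed


class TestExtractWindow:
    CONTIG = "A" * 400

    def blocks(self, *ivals, strand="+"):
        return [AnchorBlock("c", s, e, strand) for s, e in ivals]

    def test_flank_arithmetic(self):
        _, iv = extract_window(self.CONTIG, self.blocks((50, 71), (120, 141)))
        assert iv == (30, 161)

    def test_clipping_at_contig_start(self):
        _, iv = extract_window(self.CONTIG, self.blocks((5, 26)))
        assert iv[0] == 0

    def test_short_contig_used_whole(self):
        contig = "ACGT" * 50
        seq, iv = extract_window(contig, self.blocks((50, 71)))
        assert iv == (0, len(contig)) and seq == contig

    def test_minus_strand_is_revcomp_of_plus(self):
        contig = "".join(np.array(list("ACGT"))[
            np.random.default_rng(1).integers(0, 4, 400)])
        plus, iv_p = extract_window(contig, self.blocks((100, 121)))
        minus, iv_m = extract_window(contig,
                                     self.blocks((100, 121), strand="-"))
        assert iv_p == iv_m and minus == revcomp(plus)


class TestFold:
    def test_homopolymer_unstructured(self):
        structure, mfe = fold("A" * 60)
        assert structure == "." * 60 and mfe == 0.0

    def test_simulated_hairpin_pairs(self):
        hp = simulate_hairpin(8, 21, 8, star_mismatches=2)
        structure, mfe = fold(hp.sequence)
        assert len(structure) == len(hp.sequence)
        pt = pair_table(structure)  # raises on unbalanced brackets
        arm = range(*hp.arm5p_interval)
        paired = sum(1 for i in arm if pt[i] != -1)
        assert paired >= 17
        assert mfe < 0

    def test_invalid_symbols_rejected(self):
        with pytest.raises(ValueError):
            fold("ACGTNNACGT" * 6)


class TestHairpinMetrics:
    def test_threshold_case(self):
        seq = "GC" * 25 + "AT" * 25  # L=100, GC 50%
        amfe, mfei, gc = hairpin_metrics(-42.5, seq)
        assert (amfe, mfei, gc) == (-42.5, -0.85, 50.0)

    def test_length_scaling(self):
        seq = ("GC" * 25 + "AT" * 25) * 2  # L=200
        amfe, mfei, gc = hairpin_metrics(-42.5, seq)
        assert (amfe, mfei) == (-21.25, -0.425)

    def test_zero_mfe(self):
        amfe, mfei, _ = hairpin_metrics(0.0, "GCAT" * 25)
        assert (amfe, mfei) == (0.0, 0.0)

    def test_zero_gc_is_error(self):
        with pytest.raises(ValueError):
            hairpin_metrics(-1.0, "AT" * 30)


def _candidate_from_hairpin(seed=8, mm=2):
    hp = simulate_hairpin(seed, 21, 8, star_mismatches=mm)
    seq = hp.sequence
    cand = PrecursorCandidate(id="x", contig_id="c", interval=(0, len(seq)),
                              strand="+", sequence=seq)
    cand.dot_bracket, cand.mfe = fold(seq)
    cand.amfe, cand.mfei, cand.gc = hairpin_metrics(cand.mfe, seq)
    return hp, cand


class TestValidateHairpin:
    def test_simulated_hairpin_passes(self):
        hp, cand = _candidate_from_hairpin()
        ok, reasons = validate_hairpin(cand, hp.arm5p_interval)
        assert ok, reasons

    def test_mature_in_terminal_loop_fails(self):
        hp, cand = _candidate_from_hairpin()
        loop = terminal_loop(cand.dot_bracket)
        mid = (loop[0] + loop[1]) // 2
        ok, reasons = validate_hairpin(cand, (mid - 10, mid + 11))
        assert not ok

    def test_weak_mfei_fails(self):
        hp, cand = _candidate_from_hairpin()
        cand.mfei = -0.5
        ok, reasons = validate_hairpin(cand, hp.arm5p_interval)
        assert not ok and any("MFEI" in r for r in reasons)


class TestMatureStarIsomirs:
    def _setup(self):
        hp = simulate_hairpin(12, 21, 10, star_mismatches=2)
        seq = hp.sequence
        cand = PrecursorCandidate(id="p", contig_id="c",
                                  interval=(0, len(seq)), strand="+",
                                  sequence=seq)
        cand.dot_bracket, cand.mfe = fold(seq)
        return hp, cand, seq

    def test_dominant_plus_offset_isomirs(self):
        hp, cand, seq = self._setup()
        mature = tag(seq[0:21], n=50)
        iso_a = tag(seq[1:22], n=5)
        iso_b = tag(seq[0:20], n=3)
        hits = [hit(mature), hit(iso_a, start=1), hit(iso_b)]
        loci = call_mature_star_isomirs(cand, hits)
        [l5] = [l for l in loci if l.arm == "5p"]
        assert l5.sequence == mature.sequence
        assert {s for s, _, _ in l5.isomirs} == {iso_a.sequence,
                                                 iso_b.sequence}

    def test_five_three_pair_reported(self):
        hp, cand, seq = self._setup()
        a5 = hp.arm5p_interval
        a3 = hp.arm3p_interval
        hits = [hit(tag(seq[a5[0]:a5[1]], n=40), start=a5[0]),
                hit(tag(seq[a3[0]:a3[1]], n=8), start=a3[0])]
        loci = call_mature_star_isomirs(cand, hits)
        arms = {l.arm: l for l in loci}
        assert set(arms) == {"5p", "3p"}
        assert arms["5p"].star_sequence == arms["3p"].sequence
        assert arms["3p"].star_sequence == arms["5p"].sequence

    def test_count_tie_breaks_lexicographically(self):
        hp, cand, seq = self._setup()
        t1 = tag(seq[0:21], n=10)
        t2 = tag(seq[1:22], n=10)
        hits = [hit(t1), hit(t2, start=1)]
        loci = call_mature_star_isomirs(cand, hits)
        [l5] = [l for l in loci if l.arm == "5p"]
        assert l5.sequence == min(t1.sequence, t2.sequence)


class TestClassification:
    BNA = {"bna-miR159a": "TTTGGATTGAAGGGAGCTCTA"}
    PLANT = {"bna-miR159a": "TTTGGATTGAAGGGAGCTCTA",
             "ath-miR172a": "AGAATCTTGATGATGCTGCAT"}

    def _cand(self, mature):
        cand = PrecursorCandidate(id="p", contig_id="c", interval=(0, 50),
                                  strand="+", sequence="A" * 50)
        cand.loci = [MatureLocus("p", "5p", mature, (0, 21), {"A": 5})]
        return cand

    def test_known_bna(self):
        assert classify_precursor(self._cand(self.BNA["bna-miR159a"]),
                                  self.BNA, self.PLANT) == "known_bna"

    def test_known_plant_only(self):
        assert classify_precursor(self._cand(self.PLANT["ath-miR172a"]),
                                  self.BNA, self.PLANT) == "known_plant"

    def test_novel(self):
        assert classify_precursor(self._cand("ACGTACGTACGTACGTACGTA"),
                                  self.BNA, self.PLANT) == "novel"

    def test_one_mismatch_to_known_is_novel(self):
        near = self.PLANT["ath-miR172a"][:-1] + "G"
        assert classify_precursor(self._cand(near),
                                  self.BNA, self.PLANT) == "novel"


class TestNovelFamilyFilter:
    def test_mature_in_both_libraries_accepts(self):
        assert novel_family_filter({"A": 5, "B": 3}, star_present=False)

    def test_one_library_with_star_accepts(self):
        assert novel_family_filter({"A": 5, "B": 0}, star_present=True)

    def test_one_library_no_star_rejects(self):
        assert not novel_family_filter({"A": 5, "B": 0}, star_present=False)


class TestFirstNucleotide:
    def locus(self, seq):
        return MatureLocus("p", "5p", seq, (0, len(seq)), {"A": 1})

    def test_tally(self):
        loci = [self.locus(s) for s in ("TAGCTAGCTAGCTAGCTAGCT",
                                        "TGGCTAGCTAGCTAGCTAGCT",
                                        "AAGCTAGCTAGCTAGCTAGCT")]
        assert first_nucleotide_profile(loci) == {"A": 1, "C": 0, "G": 0,
                                                  "U": 2}

    def test_empty(self):
        assert first_nucleotide_profile([]) == {"A": 0, "C": 0, "G": 0,
                                                "U": 0}

    def test_u_bias_within_binomial_interval(self):
        rng = np.random.default_rng(23)
        n, p = 50, 0.8
        loci = []
        for i in range(n):
            first = "T" if rng.random() < p else "A"
            hp = simulate_hairpin(int(rng.integers(2**31)), 21, 8,
                                  first_base=first)
            loci.append(self.locus(hp.arm5p))
        u = first_nucleotide_profile(loci)["U"]
        assert binom.ppf(0.005, n, p) <= u <= binom.ppf(0.995, n, p)


class TestEndToEnd:
    def test_planted_recovery_and_decoys(self, small_study, small_candidates):
        truth = {t.contig_id: t for t in small_study.truths}
        accepted = [c for c in small_candidates if c.accepted]
        correct = sum(
            1 for c in accepted
            if (t := truth.get(c.contig_id)) is not None
            and c.dominant_locus is not None
            and c.dominant_locus.sequence == t.mature_seq
            and c.dominant_locus.arm == t.mature_arm)
        assert correct >= 0.9 * len(small_study.truths)
        assert all(c.contig_id in truth for c in accepted)

    def test_candidates_satisfy_their_own_predicates(self, small_candidates):
        params = DiscoveryParams()
        for c in small_candidates:
            if not c.accepted or c.status != "full_length":
                continue
            assert abs(c.mfei) >= params.min_mfei
            assert c.mfe <= 0
            ok, reasons = validate_hairpin(c, c.dominant_locus.interval,
                                           params.min_mfei,
                                           params.min_paired_frac,
                                           params.max_loop_overlap)
            assert ok, reasons

    def test_mature_interval_roundtrip(self, small_study, small_candidates):
        for c in small_candidates:
            if not c.accepted or c.dominant_locus is None:
                continue
            s, e = c.to_contig_coords(c.dominant_locus.interval)
            contig = small_study.contigs[c.contig_id]
            piece = contig[s:e]
            if c.strand == "-":
                piece = revcomp(piece)
            assert piece == c.dominant_locus.sequence

    def test_strand_invariance(self, small_study, small_tags):
        truth = small_study.truths[0]
        contig = small_study.contigs[truth.contig_id]
        refs = small_study.references
        fwd = discover_precursors(small_tags, {"c": contig},
                                  refs.bna_matures, refs.plant_matures)
        rev = discover_precursors(small_tags, {"c": revcomp(contig)},
                                  refs.bna_matures, refs.plant_matures)
        assert len(fwd) == len(rev) == 1
        assert fwd[0].strand != rev[0].strand
        assert fwd[0].sequence == rev[0].sequence
        assert fwd[0].dominant_locus.sequence == rev[0].dominant_locus.sequence
        assert fwd[0].accepted == rev[0].accepted
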