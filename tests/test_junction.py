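"""Six-frame ORF scanning and insertion-border characterization."""

import re

import numpy as np
import pytest
from Bio.Seq import Seq

from eventscreen.errors import AmbiguousAnchorError, InvariantError
from eventscreen.junction import (
    OrfHit, characterize_borders, junction_spanning_orfs, six_frame_orfs,
)
from eventscreen.seqcore import SequenceRecord, revcomp_str
from eventscreen.synth import (
    EventRecipe, make_event, plant_junction_orf, random_dna,
)


def orf_oracle(residues: str, min_aa: int) -> set[tuple[str, int, int, int]]:
    """Independent oracle: translate all six frames with Biopython and
    find M...* runs; returns (strand, frame, 0-based codon start on the
    scanned strand, aa length) for each most-upstream-ATG ORF."""
    found = set()
    for strand, text in (("+", residues), ("-", revcomp_str(residues))):
        for frame in range(3):
            usable = (len(text) - frame) // 3 * 3
            pep = str(Seq(text[frame : frame + usable]).translate())
            offset = 0
            for segment in re.finditer(r"[^*]*\*", pep):
                m = segment.group().find("M")
                if m != -1:
                    aa_len = len(segment.group()) - 1 - m
                    if aa_len >= min_aa:
                        found.add((strand, frame, frame + 3 * (segment.start() + m), aa_len))
    return found


def hits_as_oracle_tuples(hits, n):
    out = set()
    for h in hits:
        if h.strand == "+":
            start0 = h.start - 1
        else:
            start0 = n - h.end  # position on the reverse-complement string
        out.add((h.strand, h.frame, start0, h.length_aa))
    return out


class TestSixFrameOrfs:
    def test_minimal_hand_checked(self):
        (hit,) = six_frame_orfs(SequenceRecord("x", "ATGAAATAA"), min_aa=2)
        assert (hit.strand, hit.start, hit.end) == ("+", 1, 9)
        assert (hit.length_bp, hit.length_aa, hit.peptide) == (9, 2, "MK")

    def test_reverse_strand_forward_axis_coordinates(self):
        # reverse-strand ORF: forward sequence carries revcomp(ATG AAA TAA)
        residues = "CC" + revcomp_str("ATGAAATAA") + "GGG"
        (hit,) = six_frame_orfs(SequenceRecord("x", residues), min_aa=2)
        assert hit.strand == "-"
        assert (hit.start, hit.end) == (3, 11)
        assert hit.peptide == "MK"

    def test_too_short_sequence_empty(self):
        assert six_frame_orfs(SequenceRecord("x", "ATGTAA"), min_aa=5) == []

    def test_orf_without_stop_not_reported(self):
        assert six_frame_orfs(SequenceRecord("x", "ATGAAAAAA"), min_aa=1) == []

    def test_nested_starts_reported_from_first_atg_by_default(self):
        residues = "ATGATGAAATAA"
        (hit,) = six_frame_orfs(SequenceRecord("x", residues), min_aa=1)
        assert hit.start == 1 and hit.peptide == "MMK"
        both = six_frame_orfs(SequenceRecord("x", residues), min_aa=1, all_starts=True)
        assert {h.start for h in both} == {1, 4}

    @pytest.mark.parametrize("length_bp, length_aa", [(207, 68), (240, 79)])
    def test_stop_inclusive_length_arithmetic(self, length_bp, length_aa):
        """The bp <-> aa convention: length_aa = length_bp/3 - 1."""
        rng = np.random.default_rng(5)
        codons = []
        while len(codons) < length_aa - 1:
            c = random_dna(rng, 3)
            if c not in ("TAA", "TAG", "TGA"):
                codons.append(c)
        orf = "ATG" + "".join(codons) + "TAA"
        assert len(orf) == length_bp
        hits = six_frame_orfs(SequenceRecord("x", "TAA" + orf), min_aa=length_aa)
        match = [h for h in hits if h.strand == "+" and h.start == 4]
        assert match and match[0].length_aa == length_aa

    def test_matches_bruteforce_oracle_on_random(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            residues = random_dna(rng, 3000)
            rec = SequenceRecord("r", residues)
            hits = six_frame_orfs(rec, min_aa=30)
            assert hits_as_oracle_tuples(hits, len(residues)) == orf_oracle(residues, 30)
            for h in hits:
                assert h.length_aa == h.length_bp // 3 - 1

    def test_orfhit_invariants_enforced(self):
        with pytest.raises(InvariantError):
            OrfHit("+", 0, 1, 9, 9, 3, "MK")  # wrong aa count
        with pytest.raises(InvariantError):
            OrfHit("+", 0, 1, 9, 9, 2, "KK")  # must start with M


@pytest.fixture(scope="module")
def planted():
    recipe = EventRecipe(
        seed=17, host_len=1600, tdna_elements=(("tdna", 700),),
        lb_truncation=5, rb_truncation=9, host_deletion=4,
        insertion_point=700, flank5_len=400, flank3_len=500,
    )
    bundle = make_event(recipe)
    bundle = plant_junction_orf(bundle, "5p", "-", length_aa=40)
    bundle = plant_junction_orf(bundle, "3p", "+", length_aa=35)
    return bundle


class TestJunctionSpanning:

    def test_planted_orfs_found_with_spans(self, planted):
        hits = junction_spanning_orfs(planted.insertion_event(), min_aa=30)
        by_strand = {h.strand: h for h in hits}
        truth_new = {
            (o["strand"], o["start"], o["end"]) for o in planted.truth["planted_orfs"]
        }
        assert {(h.strand, h.start, h.end) for h in hits} >= truth_new
        minus = [h for h in hits if h.strand == "-" and "junction5" in h.spans]
        plus = [h for h in hits if h.strand == "+" and "junction3" in h.spans]
        assert len(minus) == 1 and minus[0].length_aa == 40
        assert len(plus) == 1 and plus[0].length_aa == 35

    def test_subset_of_six_frame_and_monotone_in_min_aa(self, planted):
        event = planted.insertion_event()
        allhits = {
            (h.strand, h.start, h.end) for h in six_frame_orfs(event.event_seq, 30)
        }
        spanning = junction_spanning_orfs(event, 30)
        assert {(h.strand, h.start, h.end) for h in spanning} <= allhits
        assert len(junction_spanning_orfs(event, 36)) <= len(spanning)
        assert junction_spanning_orfs(event, 200) == []

    def test_insert_internal_orf_excluded(self):
        # an ORF strictly inside the insert does not straddle a junction
        rng = np.random.default_rng(3)
        recipe = EventRecipe(
            seed=23, host_len=1200, tdna_elements=(("tdna", 600),),
            lb_truncation=0, rb_truncation=0, host_deletion=0,
            insertion_point=500, flank5_len=300, flank3_len=300,
        )
        bundle = make_event(recipe)
        event = bundle.insertion_event()
        inside = [
            h for h in six_frame_orfs(event.event_seq, 5)
            if h.start > event.junction5 and h.end < event.junction3
        ]
        spanning_keys = {
            (h.strand, h.start, h.end) for h in junction_spanning_orfs(event, 5)
        }
        for h in inside:
            assert (h.strand, h.start, h.end) not in spanning_keys


class TestCharacterizeBorders:
    def test_zero_truncation_zero_deletion(self):
        recipe = EventRecipe(
            seed=2, host_len=1000, tdna_elements=(("tdna", 400),),
            lb_truncation=0, rb_truncation=0, host_deletion=0,
            insertion_point=450, flank5_len=200, flank3_len=250,
        )
        bundle = make_event(recipe)
        ev = characterize_borders(bundle.host, bundle.tdna, bundle.event)
        assert (ev.lb_truncation, ev.rb_truncation, ev.host_deletion) == (0, 0, 0)
        assert ev.five_prime_flank_len == 200 and ev.three_prime_flank_len == 250

    def test_recovery_on_random_recipes(self):
        rng = np.random.default_rng(13)
        for i in range(25):
            recipe = EventRecipe(
                seed=1000 + i,
                host_len=1500,
                tdna_elements=(("tdna", int(rng.integers(300, 700)),),),
                lb_truncation=int(rng.integers(0, 51)),
                rb_truncation=int(rng.integers(0, 51)),
                host_deletion=int(rng.integers(0, 31)),
                insertion_point=int(rng.integers(400, 900)),
                flank5_len=int(rng.integers(120, 350)),
                flank3_len=int(rng.integers(120, 350)),
            )
            bundle = make_event(recipe)
            ev = characterize_borders(bundle.host, bundle.tdna, bundle.event)
            assert ev.lb_truncation == recipe.lb_truncation
            assert ev.rb_truncation == recipe.rb_truncation
            assert ev.host_deletion == recipe.host_deletion
            assert ev.five_prime_flank_len == recipe.flank5_len
            assert ev.three_prime_flank_len == recipe.flank3_len

    def test_locus_anchors_give_deletion(self):
        recipe = EventRecipe(
            seed=5, host_len=1200, tdna_elements=(("tdna", 500),),
            lb_truncation=11, rb_truncation=23, host_deletion=15,
            insertion_point=600, flank5_len=300, flank3_len=280,
        )
        bundle = make_event(recipe)
        ev = characterize_borders(bundle.host, bundle.tdna, bundle.event)
        left, right = ev.locus
        assert right.start - left.end - 1 == 15
        assert left.length == 300 and right.length == 280

    def test_ambiguous_insert_raises(self):
        rng = np.random.default_rng(8)
        host = random_dna(rng, 600)
        unit = random_dna(rng, 60)
        tdna = SequenceRecord("t", unit + random_dna(rng, 50) + unit)
        event = SequenceRecord("e", host[100:200] + unit + host[300:400])
        with pytest.raises(AmbiguousAnchorError):
            characterize_borders(SequenceRecord("h", host), tdna, event)

    def test_foreign_insert_raises(self):
        rng = np.random.default_rng(9)
        host = random_dna(rng, 600)
        tdna = SequenceRecord("t", random_dna(rng, 300))
        event = SequenceRecord(
            "e", host[50:250] + random_dna(rng, 200) + host[300:500]
        )
        with pytest.raises(AmbiguousAnchorError):
            characterize_borders(SequenceRecord("h", host), tdna, event)
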