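"""Insertion-event geometry and junction-spanning ORF discovery.

A single-copy T-DNA insertion is modeled as an assembled event sequence

    event = 5'-flank + truncated-T-DNA + 3'-flank

where the flanks are exact substrings of the host locus, the insert is an
exact contiguous substring of the T-DNA reference, integration may have
trimmed bases from the left/right border ends of the T-DNA (border
truncations) and removed host bases at the insertion point (host
deletion).  :func:`characterize_borders` recovers that geometry by exact
maximal substring anchoring; sequencing error is out of scope (the event
sequence is treated as finished).

The ORF scan enumerates maximal ATG-to-stop open reading frames in all
six reading frames.  ``length_bp`` includes the stop codon, so a
207 bp ORF encodes 68 residues and a 240 bp ORF encodes 79
(``length_aa = length_bp/3 - 1``).  The default minimum of 30 aa follows
the usual lower size bound argued for protein allergens (two epitopes of
roughly 15 residues each).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from Bio.Seq import Seq

from .errors import AmbiguousAnchorError, DataError, InvariantError
from .seqcore import GenomicInterval, SequenceRecord, revcomp_str

_STOPS = ("TAA", "TAG", "TGA")

DEFAULT_MIN_AA = 30


@dataclass(frozen=True)
class OrfHit:
    """A start-to-stop ORF reported in forward-axis coordinates.

    ``start``/``end`` are 1-based inclusive and include the stop codon;
    for reverse-strand hits ``start`` is still the smaller forward-axis
    coordinate (the ORF reads right-to-left).  ``frame`` is the offset of
    the reading frame on its own strand (0, 1 or 2).
    """

    strand: Literal["+", "-"]
    frame: int
    start: int
    end: int
    length_bp: int
    length_aa: int
    peptide: str
    spans: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.length_bp != self.end - self.start + 1 or self.length_bp % 3:
            raise InvariantError("OrfHit: inconsistent coordinates / length")
        if self.length_aa != self.length_bp // 3 - 1:
            raise InvariantError("OrfHit: length_aa must be length_bp/3 - 1")
        if not self.peptide.startswith("M") or "*" in self.peptide:
            raise InvariantError("OrfHit: peptide must start with M, no internal stop")


def _scan_strand(residues: str, min_aa: int, all_starts: bool) -> list[tuple[int, int, int, str]]:
    """Scan one strand; returns (frame, start0, end0, peptide) with 0-based
    [start0, end0) coordinates on the given string."""
    n = len(residues)
    hits = []
    for frame in range(3):
        starts: list[int] = []
        for pos in range(frame, n - 2, 3):
            codon = residues[pos : pos + 3]
            if codon in _STOPS:
                for s in starts:
                    aa_len = (pos - s) // 3
                    if aa_len >= min_aa:
                        pep = str(Seq(residues[s:pos]).translate())
                        hits.append((frame, s, pos + 3, pep))
                    if not all_starts:
                        break  # only the most upstream ATG per stop
                starts = []
            elif codon == "ATG" and (all_starts or not starts):
                starts.append(pos)
    return hits


def six_frame_orfs(
    seq: SequenceRecord, min_aa: int = DEFAULT_MIN_AA, all_starts: bool = False
) -> list[OrfHit]:
    """Every maximal ATG-to-stop ORF of >= ``min_aa`` residues, six frames.

    Nested ORFs sharing a stop are reported only from their most upstream
    ATG unless ``all_starts`` is set.  ORFs lacking an in-frame stop
    within the sequence are not ORFs under the start-to-stop definition
    and are never reported.
    """
    if seq.alphabet != "dna":
        raise DataError("six_frame_orfs requires a DNA record")
    if min_aa < 1:
        raise DataError("min_aa must be >= 1")
    n = len(seq)
    hits: list[OrfHit] = []
    for frame, s0, e0, pep in _scan_strand(seq.residues, min_aa, all_starts):
        hits.append(
            OrfHit("+", frame, s0 + 1, e0, e0 - s0, (e0 - s0) // 3 - 1, pep)
        )
    rc = revcomp_str(seq.residues)
    for frame, s0, e0, pep in _scan_strand(rc, min_aa, all_starts):
        # map [s0, e0) on the reverse strand back to forward-axis 1-based
        start = n - e0 + 1
        end = n - s0
        hits.append(OrfHit("-", frame, start, end, e0 - s0, (e0 - s0) // 3 - 1, pep))
    hits.sort(key=lambda h: (h.start, h.end, h.strand, h.frame))
    return hits


@dataclass(frozen=True)
class InsertionEvent:
    """Recovered (or planted) geometry of a single-copy insertion event."""

    event_seq: SequenceRecord
    five_prime_flank_len: int
    three_prime_flank_len: int
    insert_len: int
    junction5: int  # last bp of the 5' flank
    junction3: int  # first bp of the 3' flank
    lb_truncation: int
    rb_truncation: int
    host_deletion: int
    locus: tuple[GenomicInterval, GenomicInterval] | None = None

    def __post_init__(self) -> None:
        if (
            self.five_prime_flank_len + self.insert_len + self.three_prime_flank_len
            != len(self.event_seq)
        ):
            raise InvariantError("InsertionEvent: flank + insert lengths != event length")
        if self.junction5 != self.five_prime_flank_len:
            raise InvariantError("InsertionEvent: junction5 must equal 5' flank length")
        if self.junction3 != self.junction5 + self.insert_len + 1:
            raise InvariantError("InsertionEvent: junction3 != junction5 + insert + 1")
        if min(self.lb_truncation, self.rb_truncation, self.host_deletion) < 0:
            raise InvariantError("InsertionEvent: negative truncation/deletion")

    def geometry_dict(self) -> dict:
        d = {
            "event_id": self.event_seq.id,
            "event_len": len(self.event_seq),
            "five_prime_flank_len": self.five_prime_flank_len,
            "three_prime_flank_len": self.three_prime_flank_len,
            "insert_len": self.insert_len,
            "junction5": self.junction5,
            "junction3": self.junction3,
            "lb_truncation": self.lb_truncation,
            "rb_truncation": self.rb_truncation,
            "host_deletion": self.host_deletion,
        }
        if self.locus is not None:
            d["locus"] = [
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end}
                for iv in self.locus
            ]
        return d


def junction_spanning_orfs(
    event: InsertionEvent, min_aa: int = DEFAULT_MIN_AA, all_starts: bool = False
) -> list[OrfHit]:
    """ORFs whose interval (stop codon included) straddles a junction.

    An ORF spans the 5' junction iff its forward-axis interval contains
    the breakpoint between ``junction5`` and ``junction5 + 1``, i.e.
    ``start <= junction5 < end``; analogously for the 3' junction with
    the breakpoint just before ``junction3``.  The same containment rule
    applies on both strands.
    """
    j5, j3 = event.junction5, event.junction3
    out: list[OrfHit] = []
    for hit in six_frame_orfs(event.event_seq, min_aa, all_starts=all_starts):
        spans = set()
        if hit.start <= j5 < hit.end:
            spans.add("junction5")
        if hit.start <= j3 - 1 < hit.end:
            spans.add("junction3")
        if spans:
            out.append(
                OrfHit(
                    hit.strand, hit.frame, hit.start, hit.end,
                    hit.length_bp, hit.length_aa, hit.peptide,
                    spans=frozenset(spans),
                )
            )
    return out


def _longest_prefix_in(text: str, host: str) -> int:
    """Length of the longest prefix of ``text`` occurring in ``host``."""
    lo, hi = 0, len(text)
    # monotone: if a prefix of length k occurs, so does every shorter one
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if host.find(text[:mid]) != -1:
            lo = mid
        else:
            hi = mid - 1
    return lo


def _unique_find(haystack: str, needle: str, what: str) -> int:
    """0-based position of the unique occurrence; typed error otherwise."""
    first = haystack.find(needle)
    if first == -1:
        raise AmbiguousAnchorError(f"{what}: not found on its reference")
    if haystack.find(needle, first + 1) != -1:
        raise AmbiguousAnchorError(f"{what}: multiple placements on its reference")
    return first


def characterize_borders(
    host_locus: SequenceRecord,
    tdna_ref: SequenceRecord,
    event_seq: SequenceRecord,
) -> InsertionEvent:
    """Recover insertion geometry by exact maximal flank anchoring.

    The 5' flank is the longest event prefix found in the host locus, the
    3' flank the longest event suffix; the remaining middle must be one
    contiguous, uniquely-placed substring of the T-DNA reference.  Border
    truncations are the T-DNA bases missing at either end of that
    placement, and the host deletion is the host bases between the two
    flank anchors that appear in neither flank.  Any ambiguity (multiple
    maximal placements, non-substring insert, mis-ordered anchors) raises
    :class:`AmbiguousAnchorError` rather than guessing.
    """
    for rec, label in ((host_locus, "host"), (tdna_ref, "tdna"), (event_seq, "event")):
        if rec.alphabet != "dna":
            raise DataError(f"characterize_borders: {label} must be DNA")
    ev, host, tdna = event_seq.residues, host_locus.residues, tdna_ref.residues

    f5 = _longest_prefix_in(ev, host)
    f3 = _longest_prefix_in(ev[::-1], host[::-1])  # longest suffix via reversal
    if f5 == 0 or f3 == 0:
        raise AmbiguousAnchorError("event has no host-anchored flank on one side")
    if f5 + f3 >= len(ev):
        raise AmbiguousAnchorError("flank anchors overlap; no insert remains")

    insert = ev[f5 : len(ev) - f3]
    ins_pos = _unique_find(tdna, insert, "insert")
    lb_trunc = ins_pos
    rb_trunc = len(tdna) - (ins_pos + len(insert))

    h5 = _unique_find(host, ev[:f5], "5' flank")
    h3 = _unique_find(host, ev[len(ev) - f3 :], "3' flank")
    h5_end = h5 + f5  # 0-based exclusive
    if h3 < h5_end:
        raise AmbiguousAnchorError("flank anchors are mis-ordered on the host locus")
    deletion = h3 - h5_end

    locus = (
        GenomicInterval(host_locus.id, h5 + 1, h5_end),
        GenomicInterval(host_locus.id, h3 + 1, h3 + f3),
    )
    return InsertionEvent(
        event_seq=event_seq,
        five_prime_flank_len=f5,
        three_prime_flank_len=f3,
        insert_len=len(insert),
        junction5=f5,
        junction3=f5 + len(insert) + 1,
        lb_truncation=lb_trunc,
        rb_truncation=rb_trunc,
        host_deletion=deletion,
        locus=locus,
    )
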