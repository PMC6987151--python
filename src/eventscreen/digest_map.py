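"""In-silico restriction digestion and Southern fragment prediction.

Models the desk arithmetic behind Southern-blot expectations for a
single-copy transgene insertion: where the enzymes cut, which fragments a
labelled probe would detect, and hence how many insert copies a
single-cutter enzyme implies.

Two fragment-length conventions are supported.  The default,
``site-position`` mode, reports an inter-site fragment as the difference
of the printed site start positions (an internal fragment bounded by
sites at 199 and 8946 is 8747 bp), which is how such fragments are
conventionally quoted on construct maps.  ``cut-offset`` mode places each
boundary at the enzyme's actual top-strand scission point within the
recognition site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import yaml

from .errors import ConfigError, DataError
from .seqcore import DNA_ALPHABET, SequenceRecord, revcomp_str

FragmentMode = Literal["site-position", "cut-offset"]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease: recognition sequence and top-strand cut offset."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not (4 <= len(self.recognition) <= 8):
            raise ConfigError(
                f"enzyme {self.name!r}: recognition length must be 4..8"
            )
        bad = set(self.recognition) - (DNA_ALPHABET - {"N"})
        if bad:
            raise ConfigError(
                f"enzyme {self.name!r}: recognition restricted to A/C/G/T, got {sorted(bad)}"
            )
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise ConfigError(f"enzyme {self.name!r}: cut_offset out of range")

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == revcomp_str(self.recognition)


#: Enzymes used for transgene copy-number and insert-integrity blots.
BUILTIN_ENZYMES: Mapping[str, RestrictionEnzyme] = {
    "HindIII": RestrictionEnzyme("HindIII", "AAGCTT", 1),
    "SphI": RestrictionEnzyme("SphI", "GCATGC", 5),
    "AscI": RestrictionEnzyme("AscI", "GGCGCGCC", 2),
    "XmaI": RestrictionEnzyme("XmaI", "CCCGGG", 1),
}


def load_enzymes_yaml(path: str | Path) -> dict[str, RestrictionEnzyme]:
    """Load user enzyme definitions: ``{name: {recognition: ..., cut_offset: ...}}``."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping of enzyme definitions")
    enzymes = {}
    for name, spec in data.items():
        enzymes[name] = RestrictionEnzyme(
            name=name,
            recognition=str(spec["recognition"]).upper(),
            cut_offset=int(spec.get("cut_offset", 0)),
        )
    return enzymes


def get_enzymes(names: Iterable[str], extra: Mapping[str, RestrictionEnzyme] | None = None) -> list[RestrictionEnzyme]:
    table = dict(BUILTIN_ENZYMES)
    if extra:
        table.update(extra)
    out = []
    for name in names:
        if name not in table:
            raise ConfigError(f"unknown enzyme {name!r}; known: {sorted(table)}")
        out.append(table[name])
    return out


@dataclass(frozen=True)
class DigestFragment:
    """One fragment of a digest; ``start``/``end`` are 1-based on the parent.

    For circular parents a fragment may wrap the origin, in which case
    ``end < start`` and ``length`` still counts the bases walked from
    ``start`` forward through the origin to ``end``.
    """

    start: int
    end: int
    length: int
    sequence: str
    uncut: bool = False
    probes_bound: frozenset[str] = frozenset()


@dataclass(frozen=True)
class ProbeSpec:
    """A hybridization probe with its exact-match overlap threshold."""

    name: str
    sequence: str
    min_overlap: int = 50

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ConfigError(f"probe {self.name!r}: min_overlap must be >= 1")
        if len(self.sequence) < self.min_overlap:
            raise DataError(
                f"probe {self.name!r}: shorter ({len(self.sequence)}) than its "
                f"min_overlap ({self.min_overlap})"
            )


def find_sites(seq: SequenceRecord, enzyme: RestrictionEnzyme) -> list[int]:
    """1-based start positions of every recognition-site occurrence.

    The forward strand is scanned; for a non-palindromic enzyme the
    reverse-complement of the site is scanned as well (all positions are
    reported on the forward axis).  ``N`` never matches.  On circular
    records, occurrences spanning the origin are included, reported by
    their (forward-axis) start position.
    """
    if seq.alphabet != "dna":
        raise DataError("find_sites requires a DNA record")
    patterns = [enzyme.recognition]
    if not enzyme.is_palindromic:
        patterns.append(revcomp_str(enzyme.recognition))
    k = len(enzyme.recognition)
    text = seq.residues
    if seq.is_circular and len(text) >= k:
        text = text + seq.residues[: k - 1]
    positions: set[int] = set()
    for pat in patterns:
        idx = text.find(pat)
        while idx != -1:
            positions.add(idx + 1)
            idx = text.find(pat, idx + 1)
    return sorted(p for p in positions if p <= len(seq))


def _cut_coords(
    seq: SequenceRecord, enzymes: Iterable[RestrictionEnzyme], mode: FragmentMode
) -> list[int]:
    """Cut coordinates: the first base of the downstream fragment."""
    coords: set[int] = set()
    for enzyme in enzymes:
        for site in find_sites(seq, enzyme):
            if mode == "site-position":
                cut = site
            else:
                cut = site + enzyme.cut_offset
            # wrap cuts landing past the end of a circular parent
            if cut > len(seq):
                if seq.is_circular:
                    cut -= len(seq)
                else:
                    continue
            if cut > 1 or seq.is_circular:
                coords.add(cut)
    return sorted(coords)


def digest(
    seq: SequenceRecord,
    enzymes: list[RestrictionEnzyme],
    mode: FragmentMode = "site-position",
) -> list[DigestFragment]:
    """Digest a record with one or more enzymes.

    Linear parents with k cuts yield k+1 fragments (empty ones are
    impossible because a cut coordinate of 1 does not split a linear
    molecule); circular parents yield k fragments, or one full-length
    fragment flagged ``uncut`` when no site exists.  Fragment lengths
    always sum to the parent length.
    """
    if not enzymes:
        raise ConfigError("digest requires at least one enzyme")
    n = len(seq)
    residues = seq.residues
    cuts = _cut_coords(seq, enzymes, mode)
    fragments: list[DigestFragment] = []
    if seq.is_circular:
        if not cuts:
            return [DigestFragment(1, n, n, residues, uncut=True)]
        for i, start in enumerate(cuts):
            nxt = cuts[(i + 1) % len(cuts)]
            end = nxt - 1 if nxt > 1 else n
            if i + 1 < len(cuts):
                frag_seq = residues[start - 1 : nxt - 1]
                fragments.append(DigestFragment(start, nxt - 1, len(frag_seq), frag_seq))
            else:  # wraps the origin back to the first cut
                frag_seq = residues[start - 1 :] + residues[: cuts[0] - 1]
                end = cuts[0] - 1 if cuts[0] > 1 else n
                fragments.append(DigestFragment(start, end, len(frag_seq), frag_seq))
        return fragments
    bounds = [1] + cuts + [n + 1]
    for start, nxt in zip(bounds[:-1], bounds[1:]):
        if nxt <= start:
            continue
        frag_seq = residues[start - 1 : nxt - 1]
        fragments.append(DigestFragment(start, nxt - 1, len(frag_seq), frag_seq))
    return fragments


def probe_binds(fragment_seq: str, probe: ProbeSpec) -> bool:
    """True iff >= ``min_overlap`` contiguous bases of the probe (either
    orientation) match the fragment exactly."""
    k = probe.min_overlap
    for oriented in (probe.sequence, revcomp_str(probe.sequence)):
        if len(oriented) == k:
            if oriented in fragment_seq:
                return True
            continue
        for off in range(len(oriented) - k + 1):
            if fragment_seq.find(oriented[off : off + k]) != -1:
                return True
    return False


def predict_southern(
    event: SequenceRecord,
    enzymes: list[RestrictionEnzyme],
    probes: list[ProbeSpec],
    mode: FragmentMode = "site-position",
) -> dict[str, list[int]]:
    """Predicted hybridizing fragment lengths per probe.

    The number of hybridizing fragments for a single-cutter enzyme is the
    usual copy-number readout: a single-copy intact insert gives exactly
    one fragment per insert-internal probe, and a probe for sequence
    absent from the event (e.g. plasmid backbone) gives none.
    """
    for probe in probes:
        if set(probe.sequence) - DNA_ALPHABET:
            raise DataError(f"probe {probe.name!r}: not a DNA sequence")
    fragments = digest(event, enzymes, mode=mode)
    result: dict[str, list[int]] = {}
    for probe in probes:
        hits = [f.length for f in fragments if probe_binds(f.sequence, probe)]
        result[probe.name] = sorted(hits)
    return result


def southern_table(
    event: SequenceRecord,
    enzymes: list[RestrictionEnzyme],
    probes: list[ProbeSpec],
    mode: FragmentMode = "site-position",
) -> list[dict]:
    """Flat rows (probe, enzymes, fragment start/end/length) for TSV output."""
    fragments = digest(event, enzymes, mode=mode)
    enzyme_label = "+".join(e.name for e in enzymes)
    rows = []
    for probe in probes:
        bound = [f for f in fragments if probe_binds(f.sequence, probe)]
        if not bound:
            rows.append(
                {"probe": probe.name, "enzymes": enzyme_label, "start": None,
                 "end": None, "length": 0, "n_fragments": 0}
            )
        for frag in bound:
            rows.append(
                {"probe": probe.name, "enzymes": enzyme_label, "start": frag.start,
                 "end": frag.end, "length": frag.length, "n_fragments": len(bound)}
            )
    return rows
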