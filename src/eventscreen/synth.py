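"""Seeded generators for every input the pipeline consumes, with ground truth.

All generators are pure functions of their seed and recipe (bit-identical
reruns) and return truth records listing every planted quantity, so each
analysis stage can be tested as a generator/analyzer round trip without
any external data:

* :func:`make_event` - host locus, T-DNA reference and assembled event
  sequence for a single-copy insertion with chosen border truncations and
  host deletion.  The generator redraws junction-adjacent bases so the
  retained T-DNA ends differ from the adjacent host bases; without that,
  1 bp of junction microhomology would make the maximal-flank parse of
  the event ambiguous and exact recovery of planted truncations
  impossible.
* :func:`plant_junction_orf` - overwrites minimal bases so a requested
  ATG-to-stop ORF straddles a junction on a chosen strand (with an
  in-frame guard stop just upstream so the ORF is reported from its
  planted start).
* :func:`make_protein_db` - synthetic allergen/toxin database stand-ins
  with homologs planted at exact identity (substitutions never restore
  the original residue, mutated positions spread evenly so the planted
  window aligns end to end).
* :func:`make_segregation_panel` - multinomial genotype draws rendered as
  multiplex-PCR band patterns.
* :func:`make_expression_table` - lognormal protein-concentration
  replicates around stated means.

The ``gr2e`` preset bundles the published event geometry: a 12,772 bp
event comprising a 1,988 bp 5' flank, an 8,996 bp insert (11 bp left- and
23 bp right-border truncations of a 9,030 bp T-DNA) and a 1,788 bp
3' flank, with a 15 bp host deletion; unique AscI (position 199) and XmaI
(position 8946) sites inside the T-DNA; and dough-stage expression means
of 359 / 68 / 2397 ng/g FWT for the three introduced proteins.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .digest_map import BUILTIN_ENZYMES, ProbeSpec, find_sites
from .errors import ConfigError, DataError, PlantingError
from .junction import InsertionEvent, junction_spanning_orfs
from .screen import load_matrix
from .seqcore import FeatureAnnotation, GenomicInterval, SequenceRecord, revcomp_str

DNA_BASES = "ACGT"
AA20 = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = ("TAA", "TAG", "TGA")

#: Approximate background amino-acid composition of globular proteins
#: (Robinson-Robinson style), as an alternative to the uniform default.
ROBINSON_FREQS: Mapping[str, float] = {
    "A": 0.078, "C": 0.019, "D": 0.054, "E": 0.063, "F": 0.039,
    "G": 0.074, "H": 0.022, "I": 0.051, "K": 0.057, "L": 0.090,
    "M": 0.022, "N": 0.045, "P": 0.052, "Q": 0.043, "R": 0.051,
    "S": 0.071, "T": 0.058, "V": 0.064, "W": 0.013, "Y": 0.032,
}


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    """i.i.d. random DNA with the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(DNA_BASES), size=n, p=p))


def random_protein(
    rng: np.random.Generator, n: int, freqs: Literal["uniform", "robinson"] = "uniform"
) -> str:
    if freqs == "uniform":
        return "".join(rng.choice(list(AA20), size=n))
    p = np.array([ROBINSON_FREQS[a] for a in AA20])
    return "".join(rng.choice(list(AA20), size=n, p=p / p.sum()))


def _mutate_base(rng: np.random.Generator, current: str, forbidden: set[str]) -> str:
    choices = [b for b in DNA_BASES if b != current and b not in forbidden]
    if not choices:
        raise PlantingError("no admissible base for junction redraw")
    return choices[rng.integers(len(choices))]


def _scrub_patterns(seq: list[str], patterns: Sequence[str], rng: np.random.Generator) -> None:
    """Remove every occurrence of the patterns by mutating a middle base."""
    text = "".join(seq)
    for _ in range(10 * len(text)):
        hit = None
        for pat in patterns:
            idx = text.find(pat)
            if idx != -1:
                hit = (idx, pat)
                break
        if hit is None:
            return
        idx, pat = hit
        pos = idx + len(pat) // 2
        seq[pos] = _mutate_base(rng, seq[pos], set())
        text = "".join(seq)
    raise PlantingError("could not scrub recognition sites")


@dataclass(frozen=True)
class EventRecipe:
    """Ground-truth geometry for a synthetic single-copy insertion event."""

    seed: int
    host_len: int
    tdna_elements: tuple[tuple[str, int], ...]
    lb_truncation: int
    rb_truncation: int
    host_deletion: int
    insertion_point: int  # 1-based host position of the first deleted/post-junction base
    flank5_len: int
    flank3_len: int
    gc: float = 0.5
    enzyme_sites: tuple[tuple[str, int], ...] = ()  # (enzyme name, 1-based T-DNA pos)
    ensure_no_junction_orfs_min_aa: int | None = None

    @property
    def tdna_len(self) -> int:
        return sum(length for _, length in self.tdna_elements)

    @property
    def insert_len(self) -> int:
        return self.tdna_len - self.lb_truncation - self.rb_truncation

    @property
    def event_len(self) -> int:
        return self.flank5_len + self.insert_len + self.flank3_len

    def __post_init__(self) -> None:
        if min(self.host_len, self.flank5_len, self.flank3_len) <= 0:
            raise ConfigError("recipe lengths must be positive")
        if min(self.lb_truncation, self.rb_truncation, self.host_deletion) < 0:
            raise ConfigError("truncations and deletion must be >= 0")
        if self.insert_len < 3:
            raise ConfigError("truncations leave no usable insert")
        if self.insertion_point - self.flank5_len < 1:
            raise ConfigError("5' flank does not fit in the host locus")
        if self.insertion_point + self.host_deletion + self.flank3_len - 1 > self.host_len:
            raise ConfigError("deletion + 3' flank do not fit in the host locus")
        for name, pos in self.enzyme_sites:
            site = BUILTIN_ENZYMES[name].recognition
            if not (1 <= pos and pos + len(site) - 1 <= self.tdna_len):
                raise ConfigError(f"enzyme site {name} at {pos} outside the T-DNA")


@dataclass
class EventBundle:
    """Generated sequences plus the planted ground truth."""

    host: SequenceRecord
    tdna: SequenceRecord
    event: SequenceRecord
    truth: dict

    def insertion_event(self) -> InsertionEvent:
        """The ground-truth geometry as an InsertionEvent (no inference)."""
        t = self.truth
        locus = None
        if "flank5_host" in t:
            locus = (
                GenomicInterval("host_locus", *t["flank5_host"]),
                GenomicInterval("host_locus", *t["flank3_host"]),
            )
        return InsertionEvent(
            event_seq=self.event,
            five_prime_flank_len=t["flank5_len"],
            three_prime_flank_len=t["flank3_len"],
            insert_len=t["insert_len"],
            junction5=t["junction5"],
            junction3=t["junction3"],
            lb_truncation=t["lb_truncation"],
            rb_truncation=t["rb_truncation"],
            host_deletion=t["host_deletion"],
            locus=locus,
        )

    def write(self, outdir: str | Path) -> None:
        from .seqcore import write_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([self.host], outdir / "host.fasta")
        write_fasta([self.tdna], outdir / "tdna.fasta")
        write_fasta([self.event], outdir / "event.fasta")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2) + "\n")


def _assemble(host: list[str], tdna: list[str], recipe: EventRecipe) -> str:
    ip0 = recipe.insertion_point - 1
    flank5 = "".join(host[ip0 - recipe.flank5_len : ip0])
    insert = "".join(tdna[recipe.lb_truncation : recipe.tdna_len - recipe.rb_truncation])
    flank3 = "".join(host[ip0 + recipe.host_deletion : ip0 + recipe.host_deletion + recipe.flank3_len])
    return flank5 + insert + flank3


def make_event(recipe: EventRecipe, max_tries: int = 60) -> EventBundle:
    """Generate (host, T-DNA, event, truth) for a recipe; seed-deterministic.

    Structural guarantees (enforced constructively, with bounded redraws):
    the flanks occur uniquely in the host locus, the insert occurs
    uniquely in the T-DNA reference, planted enzyme sites are the only
    occurrences of their recognition sequences in the T-DNA, and the
    junctions carry no 1 bp microhomology, so the event parses uniquely.
    """
    site_patterns = sorted({BUILTIN_ENZYMES[name].recognition for name, _ in recipe.enzyme_sites})
    for attempt in range(max_tries):
        rng = np.random.default_rng([attempt, recipe.seed])
        tdna = list(random_dna(rng, recipe.tdna_len, recipe.gc))
        host = list(random_dna(rng, recipe.host_len, recipe.gc))
        if site_patterns:
            _scrub_patterns(tdna, site_patterns, rng)
            for name, pos in recipe.enzyme_sites:
                site = BUILTIN_ENZYMES[name].recognition
                tdna[pos - 1 : pos - 1 + len(site)] = list(site)

        ip0 = recipe.insertion_point - 1
        lb, rb, dele = recipe.lb_truncation, recipe.rb_truncation, recipe.host_deletion
        tl = recipe.tdna_len
        # forbid 1 bp junction microhomology: retained T-DNA ends must differ
        # from the host base adjacent to each flank anchor
        if tdna[lb] == host[ip0]:
            tdna[lb] = _mutate_base(rng, tdna[lb], {host[ip0]})
        left_host = host[ip0 + dele - 1] if dele > 0 else host[ip0 - 1]
        if tdna[tl - rb - 1] == left_host:
            tdna[tl - rb - 1] = _mutate_base(rng, tdna[tl - rb - 1], {left_host})

        if not _event_ok(host, tdna, recipe, site_patterns):
            continue
        event_str = _assemble(host, tdna, recipe)
        bundle = _finish_bundle(host, tdna, event_str, recipe, attempt)
        if recipe.ensure_no_junction_orfs_min_aa is not None:
            baseline = junction_spanning_orfs(
                bundle.insertion_event(), recipe.ensure_no_junction_orfs_min_aa
            )
            if baseline:
                continue
            bundle.truth["baseline_junction_orfs"] = []
        return bundle
    raise PlantingError(f"make_event: no admissible draw in {max_tries} attempts")


def _event_ok(host: list[str], tdna: list[str], recipe: EventRecipe,
              site_patterns: Sequence[str]) -> bool:
    host_s, tdna_s = "".join(host), "".join(tdna)
    ip0 = recipe.insertion_point - 1
    flank5 = host_s[ip0 - recipe.flank5_len : ip0]
    flank3 = host_s[ip0 + recipe.host_deletion : ip0 + recipe.host_deletion + recipe.flank3_len]
    insert = tdna_s[recipe.lb_truncation : recipe.tdna_len - recipe.rb_truncation]
    if host_s.count(flank5) != 1 or host_s.count(flank3) != 1:
        return False
    if tdna_s.count(insert) != 1:
        return False
    for name, pos in recipe.enzyme_sites:
        if find_sites(SequenceRecord("t", tdna_s), BUILTIN_ENZYMES[name]) != [pos]:
            return False
    return True


def _finish_bundle(host: list[str], tdna: list[str], event_str: str,
                   recipe: EventRecipe, attempt: int) -> EventBundle:
    ip0 = recipe.insertion_point - 1
    truth = {
        "seed": recipe.seed,
        "attempt": attempt,
        "host_len": recipe.host_len,
        "tdna_len": recipe.tdna_len,
        "event_len": recipe.event_len,
        "flank5_len": recipe.flank5_len,
        "flank3_len": recipe.flank3_len,
        "insert_len": recipe.insert_len,
        "lb_truncation": recipe.lb_truncation,
        "rb_truncation": recipe.rb_truncation,
        "host_deletion": recipe.host_deletion,
        "insertion_point": recipe.insertion_point,
        "junction5": recipe.flank5_len,
        "junction3": recipe.flank5_len + recipe.insert_len + 1,
        "flank5_host": [ip0 - recipe.flank5_len + 1, ip0],
        "flank3_host": [
            ip0 + recipe.host_deletion + 1,
            ip0 + recipe.host_deletion + recipe.flank3_len,
        ],
        "enzyme_sites_tdna": {name: pos for name, pos in recipe.enzyme_sites},
        "elements": [list(e) for e in recipe.tdna_elements],
        "planted_orfs": [],
    }
    return EventBundle(
        host=SequenceRecord("host_locus", "".join(host)),
        tdna=SequenceRecord("tdna_ref", "".join(tdna)),
        event=SequenceRecord("event", event_str),
        truth=truth,
    )


def _event_pos_to_ref(p: int, truth: dict) -> tuple[str, int]:
    """Map a 1-based event position to ('host', 0-based) or ('tdna', 0-based)."""
    j5, j3 = truth["junction5"], truth["junction3"]
    ip0 = truth["insertion_point"] - 1
    if p <= j5:
        return "host", ip0 - truth["flank5_len"] + (p - 1)
    if p < j3:
        return "tdna", truth["lb_truncation"] + (p - j5 - 1)
    return "host", ip0 + truth["host_deletion"] + (p - j3)


def plant_junction_orf(
    bundle: EventBundle,
    junction: Literal["5p", "3p"],
    strand: Literal["+", "-"],
    length_aa: int,
    min_aa: int = 30,
    insert_overlap_bp: int = 30,
    max_tries: int = 50,
) -> EventBundle:
    """Overwrite minimal bases so one ATG-to-stop ORF straddles a junction.

    The ORF is written with an in-frame guard stop immediately upstream so
    the scan reports it from the planted ATG.  After planting, the host
    and T-DNA references are co-edited so the event still parses exactly,
    and the junction ORF set is re-verified to equal the previously
    planted set plus the new ORF; otherwise the codons are redrawn
    (bounded retries).
    """
    if length_aa < 1:
        raise ConfigError("length_aa must be >= 1")
    truth = bundle.truth
    orf_bp = 3 * (length_aa + 1)
    j5, j3 = truth["junction5"], truth["junction3"]
    if junction == "5p":
        start = j5 - (orf_bp - insert_overlap_bp)  # mostly in the 5' flank
    else:
        start = j3 - insert_overlap_bp  # mostly in the 3' flank
    end = start + orf_bp - 1
    guard_lo = start - 3 if strand == "+" else start
    guard_hi = end if strand == "+" else end + 3
    if guard_lo < 1 or guard_hi > truth["event_len"]:
        raise PlantingError("requested ORF does not fit in the event")
    j_pos = j5 if junction == "5p" else j3 - 1
    if not (start <= j_pos < end):
        raise PlantingError("requested ORF does not straddle the junction")

    expected_before = {
        (o["strand"], o["start"], o["end"]) for o in truth["planted_orfs"]
    }
    baseline = {
        (h.strand, h.start, h.end)
        for h in junction_spanning_orfs(bundle.insertion_event(), min_aa)
    }

    for attempt in range(max_tries):
        rng = np.random.default_rng([attempt, truth["seed"], orf_bp, 5 if junction == "5p" else 3])
        codons = []
        for _ in range(length_aa - 1):
            while True:
                codon = random_dna(rng, 3)
                if codon not in _STOPS and codon != "ATG":
                    break
            codons.append(codon)
        stop = _STOPS[rng.integers(3)]
        guard = _STOPS[rng.integers(3)]
        orf_dna = "ATG" + "".join(codons) + stop
        if strand == "+":
            block = guard + orf_dna  # guard stop upstream, forward axis
            block_start = start - 3
        else:
            block = revcomp_str(guard + orf_dna)  # guard upstream on minus strand
            block_start = start

        host = list(bundle.host.residues)
        tdna = list(bundle.tdna.residues)
        for offset, base in enumerate(block):
            which, idx = _event_pos_to_ref(block_start + offset, truth)
            (host if which == "host" else tdna)[idx] = base
        candidate = _try_rebuild(host, tdna, truth, rng)
        if candidate is None:
            continue
        host_s, tdna_s, event_str = candidate

        new_truth = dict(truth)
        peptide = str(Seq(orf_dna).translate())[:-1]
        new_truth["planted_orfs"] = truth["planted_orfs"] + [
            {
                "junction": junction, "strand": strand, "start": start, "end": end,
                "length_bp": orf_bp, "length_aa": length_aa, "peptide": peptide,
            }
        ]
        new_bundle = EventBundle(
            host=SequenceRecord("host_locus", host_s),
            tdna=SequenceRecord("tdna_ref", tdna_s),
            event=SequenceRecord("event", event_str),
            truth=new_truth,
        )
        found = {
            (h.strand, h.start, h.end)
            for h in junction_spanning_orfs(new_bundle.insertion_event(), min_aa)
        }
        new_key = (strand, start, end)
        # the planted ORFs must all be found; pre-existing baseline ORFs may
        # have been destroyed by the overwrite, but nothing new may appear
        if new_key not in found or not expected_before <= found:
            continue
        if found - (baseline | expected_before | {new_key}):
            continue
        if not _sites_intact(tdna_s, truth):
            continue
        return new_bundle
    raise PlantingError(f"plant_junction_orf: no clean placement in {max_tries} attempts")


def _sites_intact(tdna_s: str, truth: dict) -> bool:
    for name, pos in truth["enzyme_sites_tdna"].items():
        if find_sites(SequenceRecord("t", tdna_s), BUILTIN_ENZYMES[name]) != [pos]:
            return False
    return True


def _try_rebuild(host: list[str], tdna: list[str], truth: dict,
                 rng: np.random.Generator) -> tuple[str, str, str] | None:
    """Re-assemble after edits, restoring the no-microhomology guarantee.

    When a junction constraint is broken by an edit and the adjacent host
    base is inside the deleted segment (invisible in the event), that
    host base is redrawn; otherwise the attempt is rejected.
    """
    ip0 = truth["insertion_point"] - 1
    lb, rb, dele = truth["lb_truncation"], truth["rb_truncation"], truth["host_deletion"]
    tl = truth["tdna_len"]
    if tdna[lb] == host[ip0]:
        if dele == 0:
            return None
        host[ip0] = _mutate_base(rng, host[ip0], {tdna[lb]})
    left_idx = ip0 + dele - 1 if dele > 0 else ip0 - 1
    if tdna[tl - rb - 1] == host[left_idx]:
        if dele == 0:
            return None
        host[left_idx] = _mutate_base(rng, host[left_idx], {tdna[tl - rb - 1]})

    recipe_like = dataclasses.replace(
        _recipe_from_truth(truth)
    )
    host_s, tdna_s = "".join(host), "".join(tdna)
    if not _event_ok(host, tdna, recipe_like, []):
        return None
    event_str = _assemble(host, tdna, recipe_like)
    return host_s, tdna_s, event_str


def _recipe_from_truth(truth: dict) -> EventRecipe:
    return EventRecipe(
        seed=truth["seed"],
        host_len=truth["host_len"],
        tdna_elements=(("tdna", truth["tdna_len"]),),
        lb_truncation=truth["lb_truncation"],
        rb_truncation=truth["rb_truncation"],
        host_deletion=truth["host_deletion"],
        insertion_point=truth["insertion_point"],
        flank5_len=truth["flank5_len"],
        flank3_len=truth["flank3_len"],
    )


# ---------------------------------------------------------------------------
# protein databases with planted homologs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomologPlant:
    """Instruction to embed a query-derived homolog in a database entry."""

    mode: Literal["window80", "kmer8", "strong_full"]
    source_query_start: int = 1  # 1-based
    target_identity_pct: float = 100.0
    span_aa: int = 80

    def __post_init__(self) -> None:
        if self.mode == "window80" and self.span_aa != 80:
            raise ConfigError("window80 plants use an 80-aa span")
        if self.mode == "kmer8" and self.span_aa < 8:
            raise ConfigError("kmer8 plants need a span of >= 8")
        if not (0 <= self.target_identity_pct <= 100):
            raise ConfigError("identity must be in [0, 100]")


def _even_positions(n_pick: int, lo: int, hi: int) -> list[int]:
    """n_pick distinct, evenly spread integers in [lo, hi] (Bresenham spread)."""
    width = hi - lo + 1
    if n_pick > width:
        raise ConfigError("more positions requested than available")
    return [lo + int((i + 0.5) * width / n_pick) for i in range(n_pick)]


def _mild_substitution(orig: str, matrix_name: str = "BLOSUM50") -> str:
    """The residue (!= orig) with the largest non-positive substitution score.

    Near-zero mismatch scores keep every prefix and suffix of the planted
    window non-negative under the scoring matrix, so the optimal local
    alignment spans the full window without end-trimming and the planted
    identity fraction is exactly what the screen sees; shifted windows,
    which would have to drag the alignment through negatively-scoring
    random context to reach the required segment length, cannot.
    """
    mat, index = load_matrix(matrix_name)
    best, best_key = None, None
    for aa in AA20:
        if aa == orig:
            continue
        score = int(mat[index[orig], index[aa]])
        if score > 0:
            continue
        key = (-score, aa)
        if best_key is None or key < best_key:
            best, best_key = aa, key
    return best


def make_protein_db(
    seed: int,
    n_entries: int,
    length_range: tuple[int, int],
    plants: Sequence[HomologPlant] = (),
    query: str = "",
    freqs: Literal["uniform", "robinson"] = "uniform",
    kmer_len: int = 8,
) -> tuple[list[SequenceRecord], dict]:
    """Background protein database with homologs planted at exact identity.

    Truth lists, per entry, the plant (if any), whether the planted window
    exceeds the 35 % / 80 aa criterion, and the exact shared-k-mer status
    against the query (computed by direct string comparison).
    """
    if n_entries < 1:
        raise ConfigError("n_entries must be >= 1")
    if plants and not query:
        raise ConfigError("plants require a query sequence")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    records: list[SequenceRecord] = []
    for i in range(n_entries):
        n = int(rng.integers(lo, hi + 1))
        records.append(SequenceRecord(f"db_{i:04d}", random_protein(rng, n, freqs), "protein"))

    entry_truth: list[dict] = [
        {"id": rec.id, "plant": None, "expect_window_flag": False} for rec in records
    ]
    if len(plants) > n_entries:
        raise ConfigError("more plants than database entries")
    target_indices = rng.choice(n_entries, size=len(plants), replace=False)
    for plant, idx in zip(plants, target_indices):
        s0 = plant.source_query_start - 1
        span = query[s0 : s0 + plant.span_aa] if plant.mode != "strong_full" else query
        if plant.mode != "strong_full" and len(span) != plant.span_aa:
            raise ConfigError("query span shorter than requested plant span")
        if plant.mode == "kmer8":
            embedded = span[:kmer_len]
            n_match = kmer_len
        else:
            n_match = int(round(plant.target_identity_pct / 100.0 * len(span)))
            n_mut = len(span) - n_match
            seq = list(span)
            if n_mut:
                for pos in _even_positions(n_mut, 1, len(span) - 2):
                    seq[pos] = _mild_substitution(seq[pos])
            embedded = "".join(seq)
        entry = list(records[idx].residues)
        if len(entry) < len(embedded):
            entry = list(random_protein(rng, len(embedded) + 20, freqs))
        off = int(rng.integers(0, len(entry) - len(embedded) + 1))
        entry[off : off + len(embedded)] = list(embedded)
        records[idx] = SequenceRecord(records[idx].id, "".join(entry), "protein")
        entry_truth[idx]["plant"] = {
            "mode": plant.mode,
            "offset": off + 1,
            "identities": n_match,
            "span_aa": len(embedded),
            "identity_pct": 100.0 * n_match / len(embedded),
        }
        entry_truth[idx]["expect_window_flag"] = (
            plant.mode != "kmer8" and 100.0 * n_match / len(embedded) > 35.0
        )

    query_kmers = {
        query[i : i + kmer_len] for i in range(max(0, len(query) - kmer_len + 1))
    }
    for rec, et in zip(records, entry_truth):
        shared = sorted(
            {rec.residues[i : i + kmer_len] for i in range(len(rec.residues) - kmer_len + 1)}
            & query_kmers
        )
        et["shared_kmers"] = shared
        et["expect_kmer_hit"] = bool(shared)
    truth = {
        "seed": seed,
        "n_entries": n_entries,
        "freqs": freqs,
        "entries": entry_truth,
        "any_window_flag": any(e["expect_window_flag"] for e in entry_truth),
        "any_kmer_hit": any(e["expect_kmer_hit"] for e in entry_truth),
    }
    return records, truth


# ---------------------------------------------------------------------------
# segregation panels and expression tables
# ---------------------------------------------------------------------------

_BANDS: Mapping[str, tuple[bool, bool]] = {
    "homozygous": (True, False),
    "hemizygous": (True, True),
    "null": (False, True),
}


def make_segregation_panel(
    seed: int, n_plants: int, true_ratio: Sequence[int]
) -> tuple[list[tuple[bool, bool]], dict]:
    """Multinomial genotype draws rendered as multiplex-PCR band patterns.

    A 3-term ratio draws homozygous : hemizygous : null (selfed cross), a
    2-term ratio hemizygous : null (backcross).
    """
    if n_plants < 1:
        raise ConfigError("n_plants must be >= 1")
    ratio = np.asarray(true_ratio, dtype=float)
    if len(ratio) == 3:
        classes = ("homozygous", "hemizygous", "null")
    elif len(ratio) == 2:
        classes = ("hemizygous", "null")
    else:
        raise ConfigError("true_ratio must have 2 or 3 terms")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_plants, ratio / ratio.sum())
    genotypes = np.repeat(np.array(classes), counts)
    rng.shuffle(genotypes)
    patterns = [_BANDS[g] for g in genotypes]
    truth = {
        "seed": seed,
        "n_plants": n_plants,
        "classes": list(classes),
        "true_ratio": [float(r) for r in ratio],
        "counts": {c: int(k) for c, k in zip(classes, counts)},
    }
    return patterns, truth


def write_panel_tsv(patterns: Sequence[tuple[bool, bool]], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("plant_id\tevent_band\twt_band\n")
        for i, (event_band, wt_band) in enumerate(patterns, start=1):
            handle.write(f"plant_{i:04d}\t{int(event_band)}\t{int(wt_band)}\n")


def read_panel_tsv(path: str | Path) -> list[tuple[bool, bool]]:
    patterns = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "plant_id")):
            continue
        _, eb, wb = line.split("\t")
        patterns.append((bool(int(eb)), bool(int(wb))))
    if not patterns:
        raise DataError(f"{path}: empty segregation panel")
    return patterns


def make_expression_table(
    seed: int,
    means: Mapping[tuple[str, str], float],
    cv: float = 0.15,
    n_reps: int = 3,
) -> pd.DataFrame:
    """Lognormal concentration replicates around per-(protein, tissue) means.

    The lognormal is parameterized so the arithmetic mean equals the
    stated mean and the coefficient of variation equals ``cv``; cv = 0
    returns the means themselves.
    """
    if cv < 0 or n_reps < 1:
        raise ConfigError("cv must be >= 0 and n_reps >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for (protein, tissue), mean in means.items():
        if mean <= 0:
            raise DataError("expression means must be positive")
        if cv == 0:
            draws = np.full(n_reps, float(mean))
        else:
            sigma2 = np.log1p(cv**2)
            mu = np.log(mean) - sigma2 / 2
            draws = rng.lognormal(mu, np.sqrt(sigma2), size=n_reps)
        for rep, value in enumerate(draws, start=1):
            rows.append(
                {"protein": protein, "tissue": tissue, "rep": rep,
                 "concentration_ng_per_g": float(value)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the GR2E preset
# ---------------------------------------------------------------------------

GR2E_TDNA_LEN = 9030
GR2E_SITES = (("AscI", 199), ("HindIII", 2500), ("SphI", 6500), ("XmaI", 8946))
GR2E_ELEMENTS = (
    ("LB", 25), ("Zmpsy1_cassette", 2375), ("SSU-crtI_cassette", 4000),
    ("pmi_cassette", 2500), ("RB", 130),
)
GR2E_EXPRESSION_MEANS: Mapping[tuple[str, str], float] = {
    ("ZmPSY1", "dough"): 359.0, ("CRTI", "dough"): 68.0, ("PMI", "dough"): 2397.0,
    ("ZmPSY1", "mature"): 245.0, ("CRTI", "mature"): 30.0, ("PMI", "mature"): 1282.0,
    ("PMI", "straw"): 482.0,
}
#: Probe spans on the T-DNA reference (1-based inclusive), one per gene cassette,
#: all inside the AscI..XmaI internal fragment and clear of every planted site.
GR2E_PROBE_SPANS = {"Zmpsy1": (800, 1299), "SSU-crtI": (3500, 3999), "pmi": (7000, 7499)}
#: Chromosome mapping of the preset host segment: the host record is the
#: minus strand of the reference region, so local position p maps to
#: chromosome coordinate GR2E_CHROM_C - p.
GR2E_CHROM = "Chr3"
GR2E_CHROM_C = 24_703_053


def gr2e_recipe(seed: int) -> EventRecipe:
    """The published event geometry: 1,988 + 8,996 + 1,788 = 12,772 bp."""
    return EventRecipe(
        seed=seed,
        host_len=4791,
        tdna_elements=GR2E_ELEMENTS,
        lb_truncation=11,
        rb_truncation=23,
        host_deletion=15,
        insertion_point=2489,  # flank5 occupies host 501..2488
        flank5_len=1988,
        flank3_len=1788,
        enzyme_sites=GR2E_SITES,
        ensure_no_junction_orfs_min_aa=30,
    )


def local_to_chrom(interval: Sequence[int]) -> GenomicInterval:
    """Map a host-local 1-based interval to preset chromosome coordinates."""
    lo, hi = interval
    return GenomicInterval(GR2E_CHROM, GR2E_CHROM_C - hi, GR2E_CHROM_C - lo)


def gr2e_probes(bundle: EventBundle, min_overlap: int = 50, backbone_seed: int = 77) -> list[ProbeSpec]:
    """Gene-cassette probes cut from the T-DNA plus a backbone probe absent
    from the event (its detection count must be zero)."""
    tdna = bundle.tdna.residues
    probes = [
        ProbeSpec(name, tdna[lo - 1 : hi], min_overlap)
        for name, (lo, hi) in GR2E_PROBE_SPANS.items()
    ]
    rng = np.random.default_rng(backbone_seed)
    backbone = random_dna(rng, 500)
    probes.append(ProbeSpec("backbone", backbone, min_overlap))
    return probes


def gr2e_bundle(seed: int) -> EventBundle:
    """Full preset: event geometry plus the two published junction ORFs
    (68 aa reverse-strand at the 5' junction, 79 aa forward-strand at the
    3' junction, i.e. 207 bp and 240 bp)."""
    bundle = make_event(gr2e_recipe(seed))
    bundle = plant_junction_orf(bundle, "5p", "-", length_aa=68)
    bundle = plant_junction_orf(bundle, "3p", "+", length_aa=79)
    bundle.truth["chrom_map"] = {
        "chrom": GR2E_CHROM,
        "constant": GR2E_CHROM_C,
        "strand": "-",
        "flank5_chrom": dataclasses.astuple(local_to_chrom(bundle.truth["flank5_host"]))[1:],
        "flank3_chrom": dataclasses.astuple(local_to_chrom(bundle.truth["flank3_host"]))[1:],
    }
    return bundle
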