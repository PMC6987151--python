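"""Protein safety screens: local alignment, Codex allergenicity criteria
and toxin E-value screening.

Two internationally adopted allergenicity criteria are implemented
against a protein database in FASTA form:

* **window80** - a query is flagged if any 80-residue segment aligns to a
  database entry with strictly more than 35 % identity.  Every 80-aa
  query window (step 1) is optimally locally aligned to every entry;
  identity is counted over alignment columns including gaps, and a
  passing hit must additionally span at least ``min(80, window length)``
  alignment columns — "over a segment of 80 or more amino acids".
  Queries shorter than 80 residues are screened by full-length alignment
  at the same threshold.
* **kmer8** - any exact match of 8 contiguous residues between query and
  any database entry, exhaustively over all query/subject offset pairs
  via a precomputed 8-mer index.

Toxin screening uses the optimal local alignment score converted to an
expectation value ``E(S) = K * m * n * exp(-lambda * S)`` with Gumbel
parameters fitted to scores of the query against residue-shuffled copies
of the database (:func:`calibrate_evalue`); a hit is significant below
``1e-5``.  These E-values are shuffle-calibrated, not the regression
statistics of any particular search program, so only threshold decisions
— not third-party E-values — should be compared against them.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.stats import gumbel_r

from ._align import sw_fill, sw_score
from .errors import AlphabetError, CalibrationError, ConfigError, DataError, InvariantError
from .seqcore import SequenceRecord


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and scoring parameters for the safety screens."""

    identity_threshold_pct: float = 35.0  # strict >
    window_aa: int = 80
    kmer_len: int = 8
    evalue_threshold: float = 1e-5
    matrix: str = "BLOSUM50"
    gap_open: int = 10
    gap_extend: int = 2
    window_step: int = 1

    def __post_init__(self) -> None:
        if not (self.window_aa >= self.kmer_len >= 1):
            raise ConfigError("require window_aa >= kmer_len >= 1")
        if self.identity_threshold_pct < 0 or self.evalue_threshold <= 0:
            raise ConfigError("thresholds must be positive")
        if self.window_step < 1:
            raise ConfigError("window_step must be >= 1")


@functools.lru_cache(maxsize=8)
def load_matrix(name: str) -> tuple[np.ndarray, dict[str, int]]:
    """A substitution matrix as (dense int32 array, residue -> index map).

    ``name`` is either a matrix shipped with Biopython (e.g. BLOSUM50)
    or a path to an NCBI-format matrix text file.
    """
    if Path(name).is_file():
        arr = substitution_matrices.read(name)
    else:
        try:
            arr = substitution_matrices.load(name)
        except FileNotFoundError as exc:
            raise ConfigError(f"unknown substitution matrix {name!r}") from exc
    alphabet = "".join(arr.alphabet)
    dense = np.asarray(arr, dtype=np.int32)
    index = {ch: i for i, ch in enumerate(alphabet) if ch != "*"}
    return dense, index


def _encode(seq: str, index: dict[str, int], label: str) -> np.ndarray:
    try:
        return np.array([index[ch] for ch in seq], dtype=np.int8)
    except KeyError as exc:
        raise AlphabetError(f"{label}: residue {exc.args[0]!r} not in scoring matrix") from exc


@dataclass(frozen=True)
class AlignmentResult:
    """An optimal local alignment and its summary statistics."""

    raw_score: int
    identities: int
    aln_len: int  # aligned columns, gaps included
    identity_pct: float
    q_range: tuple[int, int]  # 1-based inclusive; (0, 0) for an empty alignment
    s_range: tuple[int, int]
    evalue: float | None = None
    q_aln: str = ""
    s_aln: str = ""


@dataclass(frozen=True)
class EvalueCalibration:
    """Gumbel parameters for converting alignment scores to E-values."""

    lam: float
    K: float
    n_shuffles: int
    seed: int
    matrix: str
    gap_open: int
    gap_extend: int
    query_len: int
    db_total_len: int

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise CalibrationError("calibration requires lambda > 0 and K > 0")

    def evalue(self, score: float, m: int | None = None, n: int | None = None) -> float:
        m = self.query_len if m is None else m
        n = self.db_total_len if n is None else n
        return float(self.K * m * n * np.exp(-self.lam * score))

    def matches(self, cfg: ScreenConfig) -> bool:
        return (
            self.matrix == cfg.matrix
            and self.gap_open == cfg.gap_open
            and self.gap_extend == cfg.gap_extend
        )


HitKind = Literal["window80", "full_align", "kmer8", "toxin_evalue"]


@dataclass(frozen=True)
class ScreenHit:
    """One screening observation (alignment window, k-mer match, or E-value)."""

    query_id: str
    subject_id: str
    kind: HitKind
    passed: bool
    window_start: int | None = None  # 1-based query offset (window80 / kmer8)
    alignment: AlignmentResult | None = None
    kmer: str | None = None
    kmer_s_start: int | None = None  # 1-based subject offset (kmer8)


def _as_protein(query: str | SequenceRecord, default_id: str = "query") -> tuple[str, str]:
    if isinstance(query, SequenceRecord):
        if query.alphabet != "protein":
            raise AlphabetError("expected a protein record")
        return query.id, query.residues
    return default_id, query


def local_align(
    query: str | SequenceRecord,
    subject: str | SequenceRecord,
    cfg: ScreenConfig = ScreenConfig(),
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment under the config's matrix
    and affine gap penalties.

    Deterministic: among equal-scoring cells the end cell with the
    smallest (query, subject) coordinates is chosen, and traceback
    prefers substitution over closing a query gap over closing a subject
    gap.
    """
    _, q = _as_protein(query)
    _, s = _as_protein(subject, "subject")
    if not q or not s:
        raise DataError("local_align requires non-empty sequences")
    mat, index = load_matrix(cfg.matrix)
    a = _encode(q, index, "query")
    b = _encode(s, index, "subject")
    H, E, F = sw_fill(a, b, mat, cfg.gap_open, cfg.gap_extend)
    best = int(H.max())
    if best == 0:
        return AlignmentResult(0, 0, 0, 0.0, (0, 0), (0, 0))
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)  # row-major: smallest (i, j)
    return _traceback(q, s, a, b, mat, cfg, H, E, F, int(i), int(j))


def _traceback(q, s, a, b, mat, cfg, H, E, F, i, j) -> AlignmentResult:
    go_ge = cfg.gap_open + cfg.gap_extend
    ge = cfg.gap_extend
    qi_end, sj_end = i, j
    q_cols: list[str] = []
    s_cols: list[str] = []
    identities = 0
    state = "H"
    while True:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            if i > 0 and j > 0 and h == H[i - 1, j - 1] + mat[a[i - 1], b[j - 1]]:
                q_cols.append(q[i - 1])
                s_cols.append(s[j - 1])
                if q[i - 1] == s[j - 1]:
                    identities += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = "E"
            elif h == F[i, j]:
                state = "F"
            else:  # pragma: no cover
                raise InvariantError("local alignment traceback lost its path")
        elif state == "E":  # gap in the query, consuming subject
            q_cols.append("-")
            s_cols.append(s[j - 1])
            if E[i, j] == H[i, j - 1] - go_ge:
                state = "H"
            j -= 1
        else:  # state == "F": gap in the subject, consuming query
            q_cols.append(q[i - 1])
            s_cols.append("-")
            if F[i, j] == H[i - 1, j] - go_ge:
                state = "H"
            i -= 1
    aln_len = len(q_cols)
    return AlignmentResult(
        raw_score=int(H[qi_end, sj_end]),
        identities=identities,
        aln_len=aln_len,
        identity_pct=100.0 * identities / aln_len if aln_len else 0.0,
        q_range=(i + 1, qi_end),
        s_range=(j + 1, sj_end),
        q_aln="".join(reversed(q_cols)),
        s_aln="".join(reversed(s_cols)),
    )


def _window_passes(aln: AlignmentResult, window_len: int, cfg: ScreenConfig) -> bool:
    required = min(cfg.window_aa, window_len)
    return aln.aln_len >= required and aln.identity_pct > cfg.identity_threshold_pct


def window80_scan(
    query: str | SequenceRecord,
    db: Sequence[SequenceRecord],
    cfg: ScreenConfig = ScreenConfig(),
) -> list[ScreenHit]:
    """Sliding-window identity screen against every database entry.

    Returns every passing hit plus, per database entry, the best
    non-passing window (highest identity, then score) so that borderline
    evidence is visible, and one full-length query alignment per entry.
    """
    if not db:
        raise DataError("window80_scan requires a non-empty database")
    qid, q = _as_protein(query)
    if not q:
        raise DataError("window80_scan requires a non-empty query")
    if len(q) >= cfg.window_aa:
        windows = [
            (off + 1, q[off : off + cfg.window_aa])
            for off in range(0, len(q) - cfg.window_aa + 1, cfg.window_step)
        ]
    else:
        windows = [(1, q)]
    hits: list[ScreenHit] = []
    for entry in db:
        best_fail: ScreenHit | None = None
        best_fail_key = None
        for start, window in windows:
            aln = local_align(window, entry.residues, cfg)
            hit = ScreenHit(
                query_id=qid,
                subject_id=entry.id,
                kind="window80",
                passed=_window_passes(aln, len(window), cfg),
                window_start=start,
                alignment=aln,
            )
            if hit.passed:
                hits.append(hit)
            else:
                # retain the failing window closest to flagging: segment
                # length satisfied first, then identity, then score
                key = (
                    aln.aln_len >= min(cfg.window_aa, len(window)),
                    aln.identity_pct,
                    aln.raw_score,
                )
                if best_fail_key is None or key > best_fail_key:
                    best_fail, best_fail_key = hit, key
        if best_fail is not None:
            hits.append(best_fail)
        full = local_align(q, entry.residues, cfg)
        hits.append(
            ScreenHit(
                query_id=qid,
                subject_id=entry.id,
                kind="full_align",
                passed=_window_passes(full, len(q), cfg),
                window_start=1,
                alignment=full,
            )
        )
    return hits


def kmer8_scan(
    query: str | SequenceRecord,
    db: Sequence[SequenceRecord],
    cfg: ScreenConfig = ScreenConfig(),
) -> list[ScreenHit]:
    """Exhaustive exact k-mer matches between query and database.

    One hit per (query offset, entry, subject offset) triple, found via a
    precomputed k-mer index of the database; duplicate-free by
    construction.  A query shorter than k yields no hits.
    """
    qid, q = _as_protein(query)
    k = cfg.kmer_len
    index: dict[str, list[tuple[str, int]]] = {}
    for entry in db:
        residues = entry.residues
        for off in range(len(residues) - k + 1):
            index.setdefault(residues[off : off + k], []).append((entry.id, off + 1))
    hits: list[ScreenHit] = []
    for q_off in range(len(q) - k + 1):
        kmer = q[q_off : q_off + k]
        for subject_id, s_off in index.get(kmer, ()):
            hits.append(
                ScreenHit(
                    query_id=qid,
                    subject_id=subject_id,
                    kind="kmer8",
                    passed=True,
                    window_start=q_off + 1,
                    kmer=kmer,
                    kmer_s_start=s_off,
                )
            )
    return hits


def calibrate_evalue(
    query: str | SequenceRecord,
    db: Sequence[SequenceRecord],
    cfg: ScreenConfig = ScreenConfig(),
    n_shuffles: int = 200,
    seed: int = 0,
) -> EvalueCalibration:
    """Fit Gumbel E-value parameters by residue-shuffling the database.

    Each of ``n_shuffles`` rounds independently permutes the residues of
    every database entry (preserving composition and length) and records
    the maximal local-alignment score of the query against the shuffled
    database; a Gumbel law fitted to those maxima yields ``lambda`` and
    ``K`` such that ``E(S) = K * m * n * exp(-lambda * S)``.
    Deterministic given the seed.
    """
    if n_shuffles < 100:
        raise ConfigError("calibration requires n_shuffles >= 100")
    _, q = _as_protein(query)
    mat, index = load_matrix(cfg.matrix)
    a = _encode(q, index, "query")
    encoded = [_encode(e.residues, index, e.id) for e in db]
    n_total = sum(len(e) for e in encoded)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_shuffles)
    for r in range(n_shuffles):
        best = 0
        for enc in encoded:
            shuffled = rng.permutation(enc)
            score = int(sw_score(a, shuffled, mat, cfg.gap_open, cfg.gap_extend))
            if score > best:
                best = score
        maxima[r] = best
    if np.ptp(maxima) == 0:
        raise CalibrationError("degenerate score distribution: all shuffle maxima equal")
    loc, scale = gumbel_r.fit(maxima)
    if scale <= 0:
        raise CalibrationError("Gumbel fit returned a non-positive scale")
    lam = 1.0 / scale
    K = float(np.exp(loc / scale)) / (len(q) * n_total)
    return EvalueCalibration(
        lam=lam,
        K=K,
        n_shuffles=n_shuffles,
        seed=seed,
        matrix=cfg.matrix,
        gap_open=cfg.gap_open,
        gap_extend=cfg.gap_extend,
        query_len=len(q),
        db_total_len=n_total,
    )


def toxin_screen(
    query: str | SequenceRecord,
    toxin_db: Sequence[SequenceRecord],
    cfg: ScreenConfig,
    cal: EvalueCalibration,
) -> list[ScreenHit]:
    """Full-length local alignment per toxin entry, judged by E-value.

    A hit passes iff its E-value falls below the configured threshold
    (default 1e-5); an empty pass set is the "no significant similarity"
    verdict.  All passing hits plus the single best non-passing hit are
    returned so near-threshold alignments can be reviewed.
    """
    if not cal.matches(cfg):
        raise ConfigError("calibration was fitted under different scoring parameters")
    qid, q = _as_protein(query)
    mat, index = load_matrix(cfg.matrix)
    a = _encode(q, index, "query")
    n_total = sum(len(e.residues) for e in toxin_db)
    hits: list[ScreenHit] = []
    best_fail: ScreenHit | None = None
    for entry in toxin_db:
        b = _encode(entry.residues, index, entry.id)
        score = int(sw_score(a, b, mat, cfg.gap_open, cfg.gap_extend))
        ev = cal.evalue(score, m=len(q), n=n_total)
        passed = ev < cfg.evalue_threshold
        if passed or best_fail is None or ev < best_fail.alignment.evalue:
            aln = replace(local_align(q, entry.residues, cfg), evalue=ev)
            hit = ScreenHit(
                query_id=qid, subject_id=entry.id, kind="toxin_evalue",
                passed=passed, alignment=aln,
            )
            if passed:
                hits.append(hit)
            else:
                best_fail = hit
    if best_fail is not None:
        hits.append(best_fail)
    return hits


@dataclass(frozen=True)
class ScreenReport:
    """Combined allergenicity verdict with full per-hit evidence."""

    query_id: str
    window_hits: tuple[ScreenHit, ...]
    kmer_hits: tuple[ScreenHit, ...]

    @property
    def flagged_window80(self) -> bool:
        return any(h.passed for h in self.window_hits)

    @property
    def flagged_kmer8(self) -> bool:
        return any(h.passed for h in self.kmer_hits)

    @property
    def flag(self) -> bool:
        return self.flagged_window80 or self.flagged_kmer8

    def summary(self) -> dict:
        return {
            "query_id": self.query_id,
            "window80_flag": self.flagged_window80,
            "kmer8_flag": self.flagged_kmer8,
            "flag": self.flag,
            "n_window_pass": sum(h.passed for h in self.window_hits),
            "n_kmer_matches": len(self.kmer_hits),
        }


def allergen_screen(
    query: str | SequenceRecord,
    allergen_db: Sequence[SequenceRecord],
    cfg: ScreenConfig = ScreenConfig(),
) -> ScreenReport:
    """Run both Codex criteria; the overall verdict flags if either does."""
    qid, _ = _as_protein(query)
    return ScreenReport(
        query_id=qid,
        window_hits=tuple(window80_scan(query, allergen_db, cfg)),
        kmer_hits=tuple(kmer8_scan(query, allergen_db, cfg)),
    )


def hits_to_rows(hits: Iterable[ScreenHit]) -> list[dict]:
    """Flatten hits for TSV output."""
    rows = []
    for hit in hits:
        aln = hit.alignment
        rows.append(
            {
                "query": hit.query_id,
                "subject": hit.subject_id,
                "kind": hit.kind,
                "window_start": hit.window_start,
                "identity_pct": round(aln.identity_pct, 2) if aln else None,
                "aln_len": aln.aln_len if aln else None,
                "score": aln.raw_score if aln else None,
                "evalue": aln.evalue if aln else None,
                "kmer": hit.kmer,
                "pass": hit.passed,
            }
        )
    return rows
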