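# Methods

This note records the models, conventions and parameter choices behind
each stage, what the synthetic generators do and do not emulate, and the
known limitations.

## Coordinates and sequence model

All coordinates are 1-based inclusive, matching how restriction-site
positions, element maps and flank coordinate ranges are printed in
molecular-characterization reports; BED export converts to 0-based
half-open at the boundary only. DNA records admit `A C G T N`; other
ambiguity codes are rejected at parse time, and `N` never matches a
recognition site or k-mer, so digest and scan results are deterministic
functions of the input. Interval length is `end − start + 1`, and the
host deletion at an insertion locus is read off two flank anchor ranges
as the bases strictly between them (`right.start − left.end − 1`).

## In-silico digestion and Southern prediction

Recognition sites are exact string matches on the forward strand
(plus the reverse complement for non-palindromic enzymes; the four
built-ins — HindIII, SphI, AscI, XmaI — are all palindromic). Circular
records include origin-spanning occurrences.

Fragment lengths are reported in **site-position** mode by default: the
boundary between two fragments sits at the first base of the recognition
site, so an internal fragment bounded by sites at positions 199 and 8946
is `8946 − 199 = 8747` bp. This is the convention in which such
fragments are quoted on construct maps, and it is the one the package's
headline number reproduces. An exact **cut-offset** mode places the
boundary at the enzyme's top-strand scission point instead; the two modes
differ by at most the site length per boundary.

Probe hybridization is modeled as exact contiguous identity: a probe
detects a fragment iff ≥ `min_overlap` (default 50) consecutive bases of
the probe, in either orientation, occur in the fragment. No thermodynamic
or mismatch-tolerant model is attempted — partial cross-hybridization
(e.g. between a transgene and a diverged endogenous homolog) is outside
the default model, which is why predictions are exact counts rather than
band intensities. Copy number is then the number of hybridizing fragments
for a single-cutter enzyme, and "backbone absent" is the prediction of
zero fragments for backbone probes.

## Junction characterization

The event is modeled as `flank5 + insert + flank3` with the flanks exact
substrings of the host locus and the insert an exact contiguous substring
of the T-DNA reference. `characterize_borders` takes the longest event
prefix found anywhere in the host as the 5′ flank and the longest suffix
as the 3′ flank (binary search over prefix length; occurrences must be
unique), requires the remaining middle to be a uniquely-placed T-DNA
substring, and reads the border truncations off the placement and the
host deletion off the gap between the two flank anchors. Anything
ambiguous — multiple placements, a non-substring insert, mis-ordered
anchors — raises a typed error rather than guessing. Sequencing error is
deliberately out of scope: the event sequence is treated as finished, so
exact anchoring is the correct tool and alignment would only blur the
boundary. The flip side is that 1 bp of junction microhomology (the host
base adjacent to a junction equalling the retained T-DNA end base) makes
the parse genuinely ambiguous; the generator (below) never emits such
events, and on real data the error message is the honest answer.

## ORF scanning

"Start-to-stop ORF" means ATG through the first in-frame stop, both
strands, all three frames per strand; alternative start codons are not
considered, and an open frame that runs off the end of the sequence is
not an ORF. Reported lengths include the stop codon, so
`length_aa = length_bp/3 − 1` (207 bp ↔ 68 aa, 240 bp ↔ 79 aa). Nested
ORFs sharing a stop are reported from their most upstream ATG by default
(`all_starts=True` reports every ATG). The default minimum of 30 residues
follows the usual lower size bound argued for protein allergens: an
allergen needs at least two antibody-binding epitopes of roughly 15
residues each.

An ORF "spans" a junction iff its forward-axis interval, stop codon
included, contains the breakpoint between the two adjacent bases — the
strictest checkable reading, applied identically on both strands.

## Local alignment and the safety screens

The aligner is affine-gap Smith–Waterman (Gotoh recurrences) over
BLOSUM50 with gap cost `10 + 2k` for a gap of length k — the standard
protein-search defaults for this matrix family. The dynamic program runs
as a numba kernel; traceback is value-based in Python. Determinism: among
equal-scoring cells the end cell with the row-major-smallest coordinates
is chosen and traceback prefers substitution over closing a query gap
over closing a subject gap. (Ties are thus broken on end rather than
start coordinates; computing starts for every tied maximum would require
a traceback per tied cell for no practical benefit.) Identity percent is
counted over alignment columns including gaps, and the column count is
recorded so the alternative denominator can be recomputed.

**Window screen.** Every 80-residue query window (step 1) is locally
aligned to every database entry; queries shorter than 80 residues are
aligned full length; one full-length query alignment per entry is always
evaluated as well. A hit passes iff identity is strictly greater than
35 % **and** the alignment spans at least `min(80, window length)`
columns. The segment-length condition is integral to the criterion ("over
any segment of 80 or more amino acids"): optimal local alignments of
unrelated 80-mers are short and frequently exceed 35 % identity over a
dozen columns, so without it every null database would flag. Output
retains all passing hits plus, per entry, the failing window closest to
flagging (segment length satisfied first, then identity, then score) and
the full-length alignment, so borderline evidence is reviewable.

**8-mer screen.** Exhaustive exact matches over all query/subject offset
pairs via a precomputed database 8-mer index; any match is a flag by
definition of the criterion.

**Toxin screen.** One full-length local alignment per database entry,
converted to an expectation value `E(S) = K·m·n·e^{−λS}` (m query length,
n total database residues). λ and K come from fitting a Gumbel law to the
maxima of the query's alignment scores against `n_shuffles ≥ 100`
independently residue-shuffled copies of the database
(`scipy.stats.gumbel_r` fit; λ = 1/scale, K = e^{loc/scale}/(m·n)). The
calibration is query-specific by construction — Gumbel location depends
on query composition, and reusing one query's calibration for another is
measurably anticonservative — so the screen calibrates per query. A hit
is significant below 10⁻⁵. These shuffle-calibrated E-values are not the
regression statistics of any particular search program; threshold
decisions on planted/synthetic cases are asserted, numerical E-values are
not comparable across tools. A conservatism check (200 seeded null
trials, each with its own calibration) keeps the empirical
P(min E < α) within 2α for α ∈ {0.05, 0.01}.

## Exposure and segregation

Daily intake is `U/(365·BW)·1000` g/kg-BW/day (253 kg/yr at 57.7 kg gives
12.0), overridable by a chosen upper bound (12.5 g/kg-BW/day is the
preset's assumption set, with 100 % of intake from the event and the
highest measured dough-stage concentrations). Exposure is
`C × intake × fraction / 1000` µg/kg-BW/day; intake is printed to one
decimal and exposure to two, with unrounded values retained. The margin
of exposure divides a tolerated dose (mg/kg) by the dietary exposure
(µg/kg) after unit alignment.

Zygosity calls come from a three-primer multiplex pattern: event amplicon
only → homozygous, both → hemizygous, wild-type only → null, neither →
failed assay (excluded from counts with a logged warning). Segregation
uses the plain Pearson χ² against ratio-scaled expectations, no
continuity correction, df = classes − 1, rejecting above the critical
value at α = 0.05 (3.84 for two classes). For three-class 1:2:1 tests the
statistically correct df = 2 cutoff (5.99) is applied, and the
presence/absence collapse (carriers vs nulls, df = 1, 3.84) is reported
alongside, since published decision rules sometimes quote only the
two-class critical value for selfed generations; both numbers appear in
every report so the decision rule is transparent.

## Synthetic generators

Every generator is a pure function of its seed and recipe; truth JSON
records each planted quantity.

* **Events.** Host and T-DNA backgrounds are i.i.d. uniform with a
  GC-content knob. The generator enforces, constructively: unique flank
  and insert placements; planted restriction sites as the only
  occurrences of their recognition sequences in the T-DNA (stray
  occurrences are scrubbed before planting); and no 1 bp junction
  microhomology — the retained T-DNA end bases are redrawn to differ from
  the adjacent host bases, which is exactly the condition making the
  maximal-flank parse unique. Random DNA's stop-codon density is what
  keeps long spurious junction ORFs rare; the preset additionally redraws
  until the baseline junction-ORF count at 30 aa is zero, so the planted
  ORFs are exactly the junction ORFs found.
* **Planted junction ORFs** are written with an in-frame guard stop
  immediately upstream of the planted ATG (so the scan reports the ORF
  from its planted start), co-edited into host and T-DNA so the event
  still parses exactly, and re-verified: all planted ORFs must be found
  and no unintended new junction ORF may appear (a pre-existing
  background ORF may be overwritten); otherwise codons are redrawn, with
  bounded retries.
* **Protein databases.** Background entries are i.i.d. uniform over the
  20 residues (a Robinson–Robinson-style composition is available).
  Planted window homologs embed a query span mutated at evenly spread
  interior positions (ends kept matching), with each substitution chosen
  as the residue whose BLOSUM50 score against the original is the largest
  non-positive value and never the original residue. This keeps every
  prefix/suffix of the planted window non-negative under the matrix, so
  the optimal local alignment spans the window end to end and the screen
  sees exactly the planted identity count — which is what makes the
  28/80 (35.0 %, no flag) vs 29/80 (36.25 %, flag) boundary sharp.
  Shared-8-mer status against the query is recorded in truth by direct
  string comparison, independent of the screening index.
* **Panels and expression.** Genotypes are multinomial draws rendered as
  band patterns; expression replicates are lognormal with the arithmetic
  mean pinned to the stated mean and a CV knob (CV 0 returns the means).

What the generators do **not** emulate: sequencing error, repeats or
real genome composition, multi-locus insertions, partial digestion,
hybridization thermodynamics, realistic protein domain structure or
phylogenetic correlation in databases, linkage or segregation distortion.
Passing tests therefore demonstrate the correctness of the arithmetic,
scanning, alignment and decision logic under clean, fully-specified
conditions — not robustness to the noise sources real data add.

## Problem sizes and numerical choices

The test suite and the reproduction script run on one CPU in a few
minutes total. Sizes used: the preset event (12,772 bp host/T-DNA/event
triple) for end-to-end checks; 100 seeded events for border-recovery;
50 random 5 kb sequences for the six-frame oracle; 30 random pairs for
the alignment oracle; 50 seeded 100-entry databases for the null allergen
screen; a 200-entry database for the null toxin screen; 100–150 shuffles
per E-value calibration; 2,000 multinomial draws at n = 100 for the
type-I check. Screening databases in the preset pipeline are 60-entry
synthetic stand-ins — real allergen/toxin databases are licensed
collections and are deliberately not bundled; the format is plain protein
FASTA, so substituting a real database is a file path.

Degenerate inputs: an all-identical shuffle score distribution aborts
calibration with a typed error; a circular molecule with no sites returns
one full-length fragment flagged `uncut`; a zygosity pattern with neither
amplicon is excluded from counts rather than silently dropped.

## Known limitations

* The two copy-number fragment sizes that depend on unannotated flanking
  sites in the surrounding genome are reproduced only qualitatively (one
  fragment per probe), not numerically — their values are properties of
  the random flanks.
* E-values are calibration-relative; only threshold behavior is
  meaningful.
* `characterize_borders` is exact-match only and refuses ambiguous
  events; it is not a read-mapping or assembly tool.
* The allergenicity screen implements the two sequence criteria only; no
  epitope prediction or structural assessment.
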