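#!/usr/bin/env python
"""Generate the synthetic single-copy insertion event with the published
geometry and report what was planted.

Writes host/T-DNA/event FASTA plus the ground-truth JSON under
results/event/, and prints the planted geometry: a 12,772 bp event made
of a 1,988 bp 5' flank, an 8,996 bp insert (9,030 bp T-DNA minus 11 bp
left- and 23 bp right-border truncations) and a 1,788 bp 3' flank, with
15 bp of host sequence deleted at the insertion point.
"""

import argparse
import json
from pathlib import Path

from eventscreen.seqcore import interval_length
from eventscreen.synth import gr2e_bundle, gr2e_probes, local_to_chrom
from eventscreen.seqcore import write_fasta
from eventscreen.seqcore import SequenceRecord

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results/event"))
args = parser.parse_args()

bundle = gr2e_bundle(args.seed)
bundle.write(args.outdir)
write_fasta(
    [SequenceRecord(p.name, p.sequence) for p in gr2e_probes(bundle)],
    args.outdir / "probes.fasta",
)

t = bundle.truth
flank5 = local_to_chrom(t["flank5_host"])
flank3 = local_to_chrom(t["flank3_host"])
print(f"event: {t['event_len']} bp = {t['flank5_len']} (5' flank) "
      f"+ {t['insert_len']} (insert) + {t['flank3_len']} (3' flank)")
print(f"border truncations: LB {t['lb_truncation']} bp, RB {t['rb_truncation']} bp; "
      f"host deletion {t['host_deletion']} bp")
print(f"flank anchors on the reference: {flank5.chrom}:{flank5.start}-{flank5.end} "
      f"({interval_length(flank5)} bp) and {flank3.chrom}:{flank3.start}-{flank3.end} "
      f"({interval_length(flank3)} bp)")
print(f"planted junction ORFs: "
      + ", ".join(f"{o['length_bp']} bp / {o['length_aa']} aa ({o['strand']}, {o['junction']})"
                  for o in t["planted_orfs"]))
print(f"outputs in {args.outdir}")
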