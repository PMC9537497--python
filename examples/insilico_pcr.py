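"""Predict PCR products on a circular plasmid.

Plants a forward primer site at position 1,000 and a reverse site whose
5' end sits at 3,499, then runs in-silico PCR (<= 2 mismatches, exact
3-base 3' clamp). The product length convention — 5' end of the forward
site to the 5' end of the reverse site, both primers included — makes
the expected product exactly 2,500 bp, and the prediction is invariant
when the circular record is rotated.
"""

import numpy as np

from plascomp.pcr import in_silico_pcr
from plascomp.records import PlasmidRecord, PrimerPair, revcomp

rng = np.random.default_rng(11)
seq = list("".join(rng.choice(list("ACGT"), size=5000)))
fw = "ACTTCGACCAATGCCCCATT"
rv = "GGACACCCTCATCCTTAGCG"
seq[1000 : 1000 + len(fw)] = fw
seq[3500 - len(rv) : 3500] = revcomp(rv)
record = PlasmidRecord("demo", "".join(seq), "circular")
pair = PrimerPair("fw", fw, "rv", rv)

for amp in in_silico_pcr(record, pair):
    print(f"product: start {amp.start}, end {amp.end}, {amp.length_bp} bp")
rotated = record.rotated(2600)
for amp in in_silico_pcr(rotated, pair):
    print(f"after rotation: start {amp.start}, end {amp.end}, "
          f"{amp.length_bp} bp (spans the origin)")
print(
    "\nProduct lengths are unchanged by rotation of the circular record; "
    "an origin-spanning product simply reports an end past the record "
    "length."
)
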