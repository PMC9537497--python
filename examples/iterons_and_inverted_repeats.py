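"""Find a tandem iteron array and a planted inverted-repeat pair.

Iterons are short tandem direct repeats near a replication origin; here
three 17-mer units (the middle copy differing from the flanks at one
position) separated by 7- and 6-nt spacers are planted and recovered.
A 25-bp inverted-repeat pair — the kind of terminal repeat that
brackets a transposon — is planted and recovered separately.
"""

import numpy as np

from plascomp.records import revcomp
from plascomp.repeats import find_direct_repeats, find_ir_pairs

rng = np.random.default_rng(0)
dna = lambda n: "".join(rng.choice(list("ACGT"), size=n))

unit_a = "TCGTGCTATCAGGAGTA"
unit_b = "TCGTGCTATCGGGAGTA"
# guard bases around the array keep chance flank matches from
# stretching the repeat unit beyond its true 17-mer length
seq = dna(299) + "G" + unit_a + "GATCCAT" + unit_b + "ACGGTC" + unit_a + "T" + dna(299)

arrays = find_direct_repeats(seq, unit_len_range=(15, 20), max_spacer=10,
                             max_mismatch=1)
for a in arrays:
    print(
        f"iteron array: {a.n_copies} x {a.unit_len}-mer at {a.positions}, "
        f"spacers {a.spacer_lens}, <= {a.max_mismatch_to_first} mismatch "
        f"to the first copy"
    )
    print("  units:", " / ".join(a.units))

ir = dna(25)
seq2 = dna(400) + ir + dna(900) + revcomp(ir) + dna(400)
pairs = find_ir_pairs(seq2, min_len=20, max_len=30, max_mismatch=1)
for p in pairs:
    print(
        f"IR pair: left {p.left}, right {p.right}, {p.ir_len} bp, "
        f"{p.mismatches} mismatches"
    )
print(
    "\nThe direct-repeat array is the iteron signature of a replication "
    "origin; the IR pair is the terminal-repeat signature used to "
    "delineate transposable elements."
)
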