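"""Scan a sequence for recombination signal sequences.

An RSS is CACAGTG-heptamer + 12 or 23 bp spacer + ACAAAAACC-nonamer;
V(D)J recombination joins one 12-spacer to one 23-spacer signal (the
12/23 rule). The scanner tolerates mismatches but, by default, insists
on the 5'-CAC heptamer bases that RAG recombinase requires.
"""

import numpy as np

import trlocus as trl
from trlocus.genome import revcomp
from trlocus.rss import DEFAULT_HEPTAMER, DEFAULT_NONAMER

rng = np.random.default_rng(7)
bg = "".join(rng.choice(list("ACGT"), size=400))
v_style = DEFAULT_HEPTAMER + bg[:23] + DEFAULT_NONAMER           # 23-spacer, downstream of a V
j_style = revcomp(DEFAULT_NONAMER) + bg[30:42] + revcomp(DEFAULT_HEPTAMER)  # 12-spacer, upstream of a J
seq = bg[:150] + v_style + bg[150:300] + j_style + bg[300:]

hits = trl.scan_rss(trl.GenomeSequence("demo", seq))
print(f"{len(hits)} RSS hits")
for h in hits:
    print(f"  {h.strand} strand, {h.spacer_class}-spacer, heptamer "
          f"{h.heptamer_interval}, {h.total_mismatches} mismatches, "
          f"CAC intact: {h.cac_intact}")
# The + hit could serve a plus-strand V as its downstream signal, the -
# hit a plus-strand J as its upstream signal; together they satisfy the
# 12/23 rule:
print("12/23-compatible pair:", trl.check_12_23_pair(hits[0], hits[1]))
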