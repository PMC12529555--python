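"""Generate a synthetic T-cell-receptor locus with known truth.

Plants V (leader + intron + V exon + 23-RSS), D (12/23-RSS flanked),
J (12-RSS + FGXG exon) and C (C-Ig/M1/M2) segments on a background
contig and writes the genome as FASTA with the truth as GFF3.
"""

from collections import Counter

import trlocus as trl

spec = trl.SyntheticLocusSpec(
    n_v=10, n_d=3, n_j=6, n_c=2, pseudogene_fraction=0.25, seed=42
)
genome, truth = trl.build_locus(spec)
trl.write_fasta(genome, "/tmp/synthetic_locus.fa")
trl.write_truth_gff3(truth, genome.name, "/tmp/synthetic_truth.gff3")

print(f"genome: {genome.name}, {len(genome):,} bp")
print(f"planted segments: {Counter(t.segment_type for t in truth)}")
n_pseudo = sum(t.expected_functionality == "P" for t in truth)
print(f"pseudogenes planted: {n_pseudo} "
      f"({[t.planted_defects[0] for t in truth if t.planted_defects]})")
# Each truth record carries exact coordinates, so detector output can be
# scored base-for-base; the defect list says which classifier rule the
# gene must trip.
for t in truth[:3]:
    print(f"  {t.gene_id} {t.segment_type} {t.start}-{t.end} "
          f"{t.expected_functionality} {t.planted_defects}")
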