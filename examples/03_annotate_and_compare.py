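"""Annotate a synthetic locus blind and score against the truth.

The pipeline sees only the genome, the protein references and the
expression table — not the planted coordinates — and is scored by
exact-coordinate precision and recall.
"""

import trlocus as trl
from trlocus.synthetic import truth_annotation

spec = trl.SyntheticLocusSpec(n_v=10, n_d=3, n_j=6, n_c=2, seed=8)
genome, truth = trl.build_locus(spec)
refs = trl.reference_set(truth)

ann = trl.annotate_genome(
    genome, refs, expression=trl.expression_from_truth(truth), locus_label="SYN"
)
rep = trl.compare_to_truth(ann, truth_annotation(truth, genome.name), tolerance=0)
print(rep.per_type)
print(f"precision={rep.precision}  recall={rep.recall}  (tolerance 0 bp)")
# 1.0/1.0 means every planted gene model was rebuilt base-exactly from
# homology + RSS evidence alone and nothing spurious was emitted.
trl.write_gff3(ann, "/tmp/annotated.gff3")
print("wrote /tmp/annotated.gff3")
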