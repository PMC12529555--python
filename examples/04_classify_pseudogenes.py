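"""Classify gene segments functional (F) or pseudogene (P).

A functional V needs an open reading frame across both exons, GT..AG
splice sites, Cys23/Trp41/Trp52/Cys104, a leader, a CAC-intact
23-spacer RSS — and, under the strictest policy, transcription
evidence for both the V region and its signal peptide.
"""

import trlocus as trl
from trlocus.functionality import ClassifierConfig, classify_segment

spec = trl.SyntheticLocusSpec(
    n_v=8, n_d=0, n_j=4, n_c=0, pseudogene_fraction=0.5, seed=3
)
genome, truth = trl.build_locus(spec)
segs = trl.segments_from_truth(truth, genome.name)
expr = trl.expression_from_truth(truth)

for t, seg in zip(truth, segs):
    call = classify_segment(seg, genome, expr)
    flag = "" if call.verdict == t.expected_functionality else "  <- disagrees!"
    print(f"{t.gene_id:6s} planted={t.planted_defects or '()'} "
          f"-> {call.verdict} {list(call.reasons)}{flag}")

# A structurally intact but transcriptionally silent gene flips from P
# to F when expression evidence is not required:
g2, truth2 = trl.build_locus(trl.SyntheticLocusSpec(
    n_v=2, n_d=0, n_j=0, n_c=0, pseudogene_fraction=0.5,
    defect_mix={"no_expression": 1.0}, seed=1,
))
t, seg = next((t, s) for t, s in
              zip(truth2, trl.segments_from_truth(truth2, g2.name))
              if t.planted_defects)
expr2 = trl.expression_from_truth(truth2)
strict = classify_segment(seg, g2, expr2)
relaxed = classify_segment(
    seg, g2, expr2, ClassifierConfig(expression_policy="structural_only")
)
print(f"\n{t.gene_id} (intact structure, never transcribed): "
      f"{strict.verdict} {list(strict.reasons)} under the strict policy, "
      f"{relaxed.verdict} under structural_only")
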