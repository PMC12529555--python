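# trlocus

Germline T-cell-receptor (TR) locus annotation for comparative
immunogenomics: recombination-signal-sequence (RSS) detection under
the 12/23 rule, V/D/J/C gene-model construction from homology and RSS
evidence, IMGT-style functional/pseudogene classification, and the
locus-level statistics used when describing adaptive-immune loci in
new genome assemblies.

It is written for researchers curating TR (or, with adjusted
references, immunoglobulin) loci in non-model vertebrates — the
setting where automated annotation misses lineage-specific V(D)J
genes and where questions like "is the γ locus really absent?" or
"is this structurally perfect V gene actually expressed?" decide the
biology.

## The model in brief

A recombination-competent gene segment is flanked by an RSS:
heptamer (consensus `CACAGTG`) + 12- or 23-bp spacer + nonamer
(consensus `ACAAAAACC`). RAG-mediated recombination joins one
12-spacer to one 23-spacer signal (the **12/23 rule**). A V gene is
leader exon + GT..AG intron + V exon + downstream 23-RSS; a J gene is
upstream 12-RSS + exon encoding the FGXG di-glycine bulge + splice
donor; a D gene is a short segment between a 12- and a 23-RSS; a C
gene contributes C-Ig, transmembrane (M1) and cytoplasmic (M2) exons.

A segment is **functional (F)** when it has an open reading frame,
proper splice sites, a CAC-intact RSS of the right spacer class, the
conserved V residues Cys23/Trp41/Trp52/Cys104 (IMGT numbering) or the
J motif — and, under the strictest policy, transcription evidence for
both the V region and its signal peptide; otherwise it is a
**pseudogene (P)**, with every failing rule recorded as a stable
reason code.

The statistics layer computes per-type inventories and F/P ratios,
locus spans, V-intron lengths, Wilcoxon rank-sum comparisons (exact or
tie-corrected asymptotic) and Fisher exact tests with conditional-MLE
odds ratio and exact confidence intervals (the R `fisher.test`
convention). See `docs/methods.md` for the full account.

## Worked example

A synthetic locus with known truth, annotated blind and scored
(`examples/03_annotate_and_compare.py`):

```python
import trlocus as trl
from trlocus.synthetic import truth_annotation

spec = trl.SyntheticLocusSpec(n_v=10, n_d=3, n_j=6, n_c=2, seed=8)
genome, truth = trl.build_locus(spec)
refs = trl.reference_set(truth)
ann = trl.annotate_genome(genome, refs,
                          expression=trl.expression_from_truth(truth))
rep = trl.compare_to_truth(ann, truth_annotation(truth, genome.name),
                           tolerance=0)
print(rep.per_type)
print(f"precision={rep.precision}  recall={rep.recall}")
```

prints

```
              n_truth  n_predicted  n_matched
segment_type
C                   2            2          2
D                   3            3          3
J                   6            6          6
V                  10           10         10
precision=1.0  recall=1.0
```

meaning every planted segment was rebuilt base-exactly from homology
and RSS evidence alone, with nothing spurious. The statistics layer on
the packaged published-inventory fixtures
(`examples/05_locus_statistics.py`) prints, among others:

```
TRAV    46 functional / 15 pseudogenes / 61 total   75.41% functional   F/P 3.06
TRBV    18 functional /  5 pseudogenes / 23 total   78.26% functional   F/P 3.6
TRAV long-intron Fisher: p=0.01035, OR=0.0, 95% CI (0.0, 0.66)
```

— the F/P ratios say functional genes dominate both V inventories, and
the Fisher result says long V-introns (>650 bp) are significantly
depleted among pseudogenes.

The `examples/` scripts cover each capability: simulation, RSS
scanning, blind annotation, pseudogene classification and locus
statistics. A thin CLI wraps the same pipeline:

```bash
trlocus simulate --n-v 5 --n-j 3 --seed 7 --fasta-out g.fa --truth-out t.gff3
trlocus annotate --fasta g.fa --truth t.gff3 --gff-out pred.gff3
trlocus stats --gff pred.gff3
trlocus compare --pred pred.gff3 --truth t.gff3
```

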