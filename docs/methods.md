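# Methods

## Scope and model

`trlocus` annotates germline T-cell-receptor (TR) loci: it detects
recombination signal sequences (RSS), builds V/D/J/C gene models from
protein homology plus RSS geometry, classifies each model functional
(F) or pseudogene (P) by IMGT-style criteria, and computes the
locus-level statistics used in comparative immunogenomics (gene
inventories, F/P ratios, locus spans, V-intron length analyses). It is
a desk-scale reimplementation of the curation workflow used for large
vertebrate genomes; everything is exercised on synthetic loci with
exact planted truth and on fixtures encoding published axolotl TR
inventories.

## RSS detection

An RSS is modelled as heptamer + spacer + nonamer with the canonical
vertebrate consensus (CACAGTG / ACAAAAACC) and spacer classes 12 and
23 bp, each tolerating ±1 bp. Scoring is mismatch counting against
the consensus: at most 1 heptamer mismatch with the 5'-CAC bases
required exact (RAG recombinase cannot engage a CAC-less heptamer,
which is also a pseudogenization criterion downstream), and at most 3
nonamer mismatches. The strict-heptamer/permissive-nonamer asymmetry
mirrors the relative information content of the two motifs. No trained
profile is shipped because none is published for these loci; the
mismatch budgets are the operational substitute for a profile-HMM
score threshold, and the scanner is verified against an exhaustive
per-offset oracle on sequences up to tens of kb.

A hit's `strand` is the strand on which the motifs read in consensus
order; a plus-pattern hit serves a plus-strand gene as its downstream
(V/D 3') signal and a minus-pattern hit as its upstream (J/D 5')
signal. Overlapping same-strand candidates (e.g. the ±1 bp spacer
variants of one physical signal) are collapsed to the
lowest-total-mismatch hit, ties broken by spacer closest to nominal,
then smaller start.

## Gene-model construction

*Seeding.* Protein references are aligned to all six translated frames
with Biopython's `PairwiseAligner` (local mode, BLASTP scoring).
Full-length references use a score cutoff of 100; short references
(leader peptides, transmembrane/cytoplasmic exons, < 40 aa) use 45,
since a perfect 15-residue match cannot reach the full-length cutoff.
Tabular seeds from an external aligner can be imported instead.

*V assembly.* The seeded interval is the V exon. The leader is the
nearest upstream candidate satisfying the gene structure: a GT..AG
intron of 60–3000 bp ending immediately before the V exon, preceded by
the closest in-frame ATG within 12–120 bp of leader. The nearest
downstream 23-spacer RSS within 10 bp of the coding end is linked.
Missing parts are left absent for the classifier rather than rejected.

*J/D discovery* is RSS-driven so lineage-specific genes without close
homologs are found: each upstream-oriented 12-RSS opens a J candidate
read in frame from the heptamer edge to the first codon-boundary GT
donor (8–40 codons), emitted when the FGXG motif or a J reference
matches, with motif presence recorded as evidence (canonical /
non-canonical) rather than used as a filter. D candidates are 1–40 bp
segments with a 5' upstream 12-RSS and 3' downstream 23-RSS (flank
classes configurable; the human-TRB order is the default since the
published loci state both classes but not their order). An empty D
list is a meaningful negative — the configuration of a locus that
truly lacks D genes.

*Reduction.* Overlapping same-type, same-strand models collapse to the
highest-scoring one (V/C: alignment score; J/D: fewest flank-RSS
mismatches), ties broken by length then leftmost. D candidates nested
in another gene model on the same strand are removed as chance RSS
pairings inside coding sequence. V models without an overlapping
signal-peptide homology hit are flagged `sp_unconfirmed` but retained;
the expression policy decides their fate. Reduction is idempotent and
never increases the model count.

*Presence reporting.* A reference set (e.g. a whole locus, or a single
gene like a pre-TCRα ortholog) is declared absent when no seed clears
the cutoffs; the report carries the best sub-threshold score and which
flanking-marker references were located, supporting
"synteny conserved, gene absent" conclusions.

## Functionality classification

Type-specific rules, each failure a stable reason code:

* V — leader present and starting ATG; GT..AG splice sites; ORF across
  the spliced exons (length divisible by three, no internal stop);
  Cys23, Trp41, Trp52, Cys104 at IMGT positions of the V-exon
  translation; downstream 23-RSS present with intact CAC.
* J — ORF; FGXG (X any residue) present; upstream 12-RSS intact.
  Under the lenient switch a missing motif is a warning, not a P call
  — needed because real loci contain J genes with variant motifs
  (e.g. FKKG) that are otherwise intact.
* D — both flanking RSSs present, classes jointly satisfying 12/23.
* C — required exon roles present (C-Ig, M1, M2).

IMGT positions are checked by fixed offset into the V-exon translation
(the synthetic V exon encodes the V region from its first codon); in
annotation mode the seed alignment anchors the exon at codon
resolution so the same offsets apply.

The default expression policy is the strictest one: a structurally
intact V lacking transcription evidence for the V region
(`expression_absent`) or for its signal peptide
(`sp_expression_absent`) is a pseudogene. `structural_only` and
`require_gene_expression` are available for genomes without expression
data. Genes absent from the evidence table count as not expressed
under expression-requiring policies. The F-set is monotone across the
three policies (strictest ⊆ middle ⊆ structural), a property the test
suite asserts.

## Locus statistics

* F/P ratios are truncated at two decimals by default (46/15 → 3.06,
  matching published tables, which evidently truncate rather than
  round); rounding is configurable.
* Wilcoxon rank-sum: exact null distribution for combined n ≤ 30
  without ties, otherwise normal approximation with tie and continuity
  corrections; the method used is recorded. Exact mode equals a
  full-permutation oracle; the asymptotic mode's type-I error at the
  group sizes of interest (46 vs 15) is calibrated by simulation.
* Fisher exact test: two-sided p by the probability-mass rule (sum of
  fixed-margin tables no more probable than observed, via scipy);
  odds ratio by conditional maximum likelihood; 95% CI by inverting
  the one-sided exact conditional tests on the Fisher noncentral
  hypergeometric distribution. This is the convention of R's
  `fisher.test`: a table with an empty cell reports OR 0 (or ∞) with a
  finite opposite bound. The inversion here solves the tail equations
  to full numerical precision, so bounds can differ from R's printed
  values by up to ~1% (R's `uniroot` tolerance); e.g. the exact upper
  bound 234.0 where R prints 233.15.
* The long-intron contingency (threshold strictly > 650 bp) excludes V
  genes without a measurable intron — in particular leaderless
  pseudogenes. This exclusion is why the published TRAV analysis
  (p=0.01035, OR 0.0, CI 0.0–0.66) is reproduced by margins 46
  functional vs 11 (not 15) pseudogenes with k=19 long-intron
  functional genes, the unique configuration matching the printed
  values; the package's enumeration check asserts that uniqueness.

## Synthetic loci

The generator plants the canonical germline architecture (all genes on
the plus strand; minus-strand handling is exercised by annotating
reverse complements): V = ATG leader (16 codons), GT..AG intron
(log-normal, median 240 bp, clipped to 80–3000 — spanning both the
"typical" 80–250 bp regime and the long-intron regime), 110-codon V
exon with the four conserved residues, abutting 23-RSS; J = upstream
12-RSS, 14–18 codon exon with FGXG four codons from its end, GT donor;
D = 10–20 bp between 12- and 23-RSS; C = 100/25/20-codon C-Ig/M1/M2
exons with 80–300 bp introns. Background and spacers are i.i.d.
nucleotides at 42% GC; intergenic gaps are log-normal (median 600 bp)
clipped to 400–3000 bp so neighbouring genes remain separable by the
C-exon grouping threshold (350 bp).

Pseudogene defects are minimal edits that each trip exactly one
classifier rule: a single-base deletion past the Cys104 codon
(frameshift), one codon to TAA (premature stop), omission of leader
and intron (missing leader), heptamer CAC→GAC (RSS defect), a silent
row in the expression table, and FKKG in place of FGXG. Defects are
assigned per gene type as round(n × pseudogene_fraction), drawn from
the configured mix restricted to type-compatible kinds.

Three planting constraints make *exact* coordinate recovery well-posed
rather than probabilistic: planted V-introns contain no internal GT
dinucleotide (so the nearest-donor search is unambiguous), leaders no
internal in-frame ATG, and J exons no valine codon (GTN at a codon
boundary would mimic the splice donor). Real genomes offer no such
guarantees; passing the zero-noise recovery suite therefore
demonstrates correctness of the coordinate arithmetic and evidence
integration, not expected field performance on a real assembly, where
homology noise, decoy splice signals and diverged RSSs dominate.

Deliberately not modelled: transcription (expression evidence is an
input table), somatic V(D)J recombination products, RNA-seq coverage,
sequencing/assembly error, GC heterogeneity and repeats.

## Fixtures for the published inventories

`table_fixture("TRA" | "TRD" | "TRB")` encodes the published axolotl
gene inventories (per-type functional/pseudogene counts) with
placeholder coordinates; only counts and flags are meaningful. Two
published idiosyncrasies are preserved rather than resolved: the TRB
table's six TRBC total alongside prose describing five functional
constant genes (the fixture follows the table), and TRD J genes called
functional despite Jδ1's FKKG motif (exposed as the strict/lenient
motif switch).

## Problem sizes and defaults

The recovery suite uses a 50-segment locus (25 V, 5 D, 15 J, 5 C,
~55 kb), annotated in a few seconds; oracle equivalence suites use
10 kb sequences (RSS), margins ≤ 60 (Fisher) and combined n ≤ 12
(Wilcoxon permutation); the type-I calibration uses 1000 replicates at
46 vs 15. These sizes were chosen so the whole suite runs in well
under a minute while still covering every code path at the published
group sizes.

## Known limitations

* The seeder reports the best local alignment per reference and frame;
  a multi-copy gene family matching a single reference in one frame
  yields one seed. Synthetic references are per-gene, so this does not
  affect the recovery suites.
* Conserved-residue lookup assumes the V exon starts at an IMGT-
  numbered residue; heavily diverged leaders that shift the V-region
  start would need reference-anchored renumbering.
* The published genome-scale quantities that require the real assembly
  and per-gene supplementary coordinates (e.g. mean V-intron lengths
  of 758/142/237 bp) are out of scope; the statistics layer reproduces
  everything derivable from the printed tables and coordinates.
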