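"""End-to-end annotation: genome + protein references -> classified locus.

The stages mirror germline-locus curation practice: RSS scan, homology
seeding of V and C exons, V-model assembly (leader + intron + V exon +
downstream 23-RSS), RSS-driven J and D discovery, redundancy
reduction with signal-peptide confirmation, and F/P classification.
"""

from __future__ import annotations

import logging
from typing import Optional

from .functionality import ClassifierConfig, ExpressionEvidence, classify_annotation
from .genome import GenomeSequence
from .models import (
    DDetectionParams,
    JDetectionParams,
    LocusAnnotation,
    SeedingConfig,
    assemble_c_genes,
    assemble_v_gene,
    detect_d_candidates,
    detect_j_genes,
    reduce_and_confirm,
    seed_hits,
)
from .rss import RssParams, scan_rss
from .synthetic import ReferenceSet

logger = logging.getLogger(__name__)

__all__ = ["annotate_genome"]


def annotate_genome(
    genome: GenomeSequence,
    references: ReferenceSet,
    expression: Optional[ExpressionEvidence] = None,
    seeding: SeedingConfig = SeedingConfig(),
    rss_params: RssParams = RssParams(),
    classifier: ClassifierConfig = ClassifierConfig(),
    j_params: JDetectionParams = JDetectionParams(),
    d_params: DDetectionParams = DDetectionParams(),
    c_gene_max_span: int = 350,
    locus_label: str = "",
) -> LocusAnnotation:
    """Annotate one contig and classify every model.

    V gene ids inherit their seeding reference id, so expression
    evidence keyed by reference gene carries through to classification.
    """
    for name, value in (
        ("min_alignment_score", seeding.min_alignment_score),
        ("max_intron_span", seeding.max_intron_span),
        ("heptamer", rss_params.heptamer_consensus),
        ("nonamer", rss_params.nonamer_consensus),
        ("max_heptamer_mismatches", rss_params.max_heptamer_mismatches),
        ("max_nonamer_mismatches", rss_params.max_nonamer_mismatches),
        ("expression_policy", classifier.expression_policy),
    ):
        logger.info("annotate_genome %s=%s", name, value)

    rss_hits = scan_rss(genome, rss_params)
    logger.info("RSS scan: %d hits", len(rss_hits))

    segments = []
    if references.v:
        v_seeds = seed_hits(genome, references.v, seeding)
        logger.info("V seeding: %d seeds", len(v_seeds))
        for s in v_seeds:
            segments.append(
                assemble_v_gene(s, rss_hits, genome, seeding, gene_id=s.reference_id)
            )
    sp_hits = seed_hits(genome, references.sp, seeding) if references.sp else []

    segments += detect_j_genes(genome, rss_hits, j_references=None, params=j_params)
    segments += detect_d_candidates(genome, rss_hits, d_params)
    if references.c:
        c_seeds = seed_hits(genome, references.c, seeding)
        segments += assemble_c_genes(
            c_seeds, references.c_roles, genome.name, max_gene_span=c_gene_max_span
        )

    final = reduce_and_confirm(segments, sp_hits)
    for seg in final:
        seg.locus_label = locus_label
        logger.debug(
            "model %s %s [%d-%d] strand=%s source=%s",
            seg.gene_id, seg.segment_type, seg.start, seg.end, seg.strand, seg.source,
        )
    ann = LocusAnnotation(
        contig=genome.name,
        records=final,
        locus_label=locus_label,
        metadata={"pipeline": "annotate_genome"},
    )
    classify_annotation(ann, genome, expression, classifier)
    for seg in ann.records:
        logger.debug(
            "classified %s -> %s (%s)", seg.gene_id, seg.functionality,
            ";".join(seg.reasons) or "no failing rule",
        )
    return ann
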