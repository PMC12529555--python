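"""Readers and writers for FASTA, GFF3 and BED, plus the
truth-vs-prediction comparison used on synthetic loci.

GFF3 output uses Sequence Ontology feature types (``V_gene_segment``,
``D_gene_segment``, ``J_gene_segment``, ``C_gene_segment``) with exon
and RSS child features; attribute values are percent-encoded per the
GFF3 specification. Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GenomeSequence
from .models import Exon, GeneSegment, LocusAnnotation
from .rss import RSS
from .synthetic import TruthRecord

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
    "write_truth_gff3",
    "read_truth_gff3",
    "ComparisonReport",
    "compare_to_truth",
]

_SO_TYPE = {
    "V": "V_gene_segment",
    "D": "D_gene_segment",
    "J": "J_gene_segment",
    "C": "C_gene_segment",
}
_TYPE_FROM_SO = {v: k for k, v in _SO_TYPE.items()}


def write_fasta(genome: GenomeSequence, path) -> None:
    SeqIO.write([SeqRecord(Seq(genome.seq), id=genome.name, description="")], path, "fasta")


def read_fasta(path) -> list[GenomeSequence]:
    return [GenomeSequence(r.id, str(r.seq)) for r in SeqIO.parse(path, "fasta")]


# ---------------------------------------------------------------------------
# GFF3


def _feature(seqid, ftype, start, end, strand, attrs) -> gffutils.Feature:
    return gffutils.Feature(
        seqid=seqid,
        source="trlocus",
        featuretype=ftype,
        start=int(start),
        end=int(end),
        score=".",
        strand=strand,
        frame=".",
        attributes={k: [str(v)] for k, v in attrs.items() if v is not None},
    )


def _rss_to_feature(contig, h: RSS, parent: str, i: int) -> gffutils.Feature:
    return _feature(
        contig,
        "recombination_signal_sequence",
        h.start,
        h.end,
        h.strand,
        {
            "ID": f"{parent}_rss{i}",
            "Parent": parent,
            "spacer_class": h.spacer_class,
            "spacer_len": h.spacer_len,
            "heptamer_mismatches": h.heptamer_mismatches,
            "nonamer_mismatches": h.nonamer_mismatches,
            "cac_intact": int(h.cac_intact),
            "orientation": h.orientation,
        },
    )


def _rss_from_feature(f) -> RSS:
    start, end, strand = f.start, f.end, f.strand
    spacer_len = int(f.attributes["spacer_len"][0])
    if strand == "+":
        hept = (start, start + 6)
        nona = (end - 8, end)
        spacer = (start + 7, start + 6 + spacer_len)
    else:
        hept = (end - 6, end)
        nona = (start, start + 8)
        spacer = (start + 9, start + 8 + spacer_len)
    ori = f.attributes.get("orientation", [None])[0]
    return RSS(
        contig=f.seqid,
        strand=strand,
        spacer_class=int(f.attributes["spacer_class"][0]),
        heptamer_interval=hept,
        spacer_interval=spacer,
        nonamer_interval=nona,
        heptamer_mismatches=int(f.attributes["heptamer_mismatches"][0]),
        nonamer_mismatches=int(f.attributes["nonamer_mismatches"][0]),
        cac_intact=bool(int(f.attributes["cac_intact"][0])),
        orientation=ori,
    )


def write_gff3(ann: LocusAnnotation, path) -> None:
    """Serialize an annotation; lossless for coordinates, strand, type,
    functionality, reasons, warnings, motif evidence and RSS links."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seg in ann.records:
            attrs = {
                "ID": seg.gene_id,
                "locus_label": seg.locus_label or None,
                "segment_type": seg.segment_type,
                "functionality": seg.functionality,
                "source_stage": seg.source,
            }
            if seg.reasons:
                attrs["reasons"] = ",".join(seg.reasons)
            if seg.warnings:
                attrs["warnings"] = ",".join(seg.warnings)
            if seg.motif_evidence:
                attrs["motif_evidence"] = seg.motif_evidence
            if seg.sp_confirmed is not None:
                attrs["sp_confirmed"] = int(seg.sp_confirmed)
            fh.write(
                str(
                    _feature(
                        seg.contig,
                        _SO_TYPE[seg.segment_type],
                        seg.start,
                        seg.end,
                        seg.strand,
                        attrs,
                    )
                )
                + "\n"
            )
            for e in seg.exons:
                fh.write(
                    str(
                        _feature(
                            seg.contig,
                            "exon",
                            e.start,
                            e.end,
                            seg.strand,
                            {
                                "ID": f"{seg.gene_id}_{e.role}",
                                "Parent": seg.gene_id,
                                "exon_role": e.role,
                            },
                        )
                    )
                    + "\n"
                )
            for i, h in enumerate(seg.rss_links, 1):
                fh.write(str(_rss_to_feature(seg.contig, h, seg.gene_id, i)) + "\n")


def _validate_gff3_lines(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 fields, got {len(f)}")
            try:
                start, end = int(f[3]), int(f[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise ValueError(f"{path}:{lineno}: bad interval [{f[3]}, {f[4]}]")


def _load_db(path):
    _validate_gff3_lines(path)
    return gffutils.create_db(
        str(path), ":memory:", merge_strategy="error", keep_order=True
    )


def read_gff3(path) -> LocusAnnotation:
    """Parse an annotation written by :func:`write_gff3`.

    Malformed lines raise with the offending line number; features of
    unrecognized type that still declare a ``segment_type`` attribute
    are passed through with a warning, others are skipped.
    """
    db = _load_db(path)
    records: list[GeneSegment] = []
    contig = ""
    for f in db.all_features(order_by=("seqid", "start")):
        if f.featuretype in ("exon", "recombination_signal_sequence"):
            continue
        if f.featuretype in _TYPE_FROM_SO:
            seg_type = _TYPE_FROM_SO[f.featuretype]
        elif "segment_type" in f.attributes:
            seg_type = f.attributes["segment_type"][0]
            _warnings.warn(
                f"unknown feature type {f.featuretype!r}; "
                f"using segment_type={seg_type!r}"
            )
        else:
            _warnings.warn(f"skipping feature of unknown type {f.featuretype!r}")
            continue
        contig = f.seqid
        exons = []
        rss_links = []
        for c in db.children(f, order_by="start"):
            if c.featuretype == "exon":
                exons.append(Exon(c.attributes["exon_role"][0], c.start, c.end))
            elif c.featuretype == "recombination_signal_sequence":
                rss_links.append(_rss_from_feature(c))
        attr = lambda k, d=None: f.attributes[k][0] if k in f.attributes else d
        seg = GeneSegment(
            gene_id=attr("ID"),
            segment_type=seg_type,
            contig=f.seqid,
            strand=f.strand,
            exons=exons or [Exon(_so_default_role(seg_type), f.start, f.end)],
            locus_label=attr("locus_label", ""),
            rss_links=rss_links,
            functionality=attr("functionality", "unclassified"),
            reasons=attr("reasons", "").split(",") if attr("reasons") else [],
            warnings=attr("warnings", "").split(",") if attr("warnings") else [],
            source=attr("source_stage", "homology"),
            motif_evidence=attr("motif_evidence"),
        )
        sp = attr("sp_confirmed")
        if sp is not None:
            seg.sp_confirmed = bool(int(sp))
        records.append(seg)
    return LocusAnnotation(contig=contig, records=records)


def _so_default_role(seg_type: str) -> str:
    return {"V": "V_EXON", "J": "J_EXON", "D": "D_REGION", "C": "C_IG"}[seg_type]


# ---------------------------------------------------------------------------
# truth GFF3


def write_truth_gff3(truth: Sequence[TruthRecord], contig: str, path) -> None:
    """Truth annotation as GFF3 (``ID=`` and ``locus_type=`` attributes,
    1-based inclusive); lossless for every TruthRecord field."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in truth:
            attrs = {
                "ID": t.gene_id,
                "locus_type": t.segment_type,
                "expected_functionality": t.expected_functionality,
                "planted_defects": ",".join(t.planted_defects) or None,
                "intron_length": t.intron_length,
                "proteins": ",".join(f"{k}:{v}" for k, v in t.proteins.items()) or None,
            }
            fh.write(
                str(
                    _feature(contig, _SO_TYPE[t.segment_type], t.start, t.end, t.strand, attrs)
                )
                + "\n"
            )
            for e in t.exons:
                fh.write(
                    str(
                        _feature(
                            contig,
                            "exon",
                            e.start,
                            e.end,
                            t.strand,
                            {
                                "ID": f"{t.gene_id}_{e.role}",
                                "Parent": t.gene_id,
                                "exon_role": e.role,
                            },
                        )
                    )
                    + "\n"
                )
            for i, h in enumerate(t.rss, 1):
                fh.write(str(_rss_to_feature(contig, h, t.gene_id, i)) + "\n")


def read_truth_gff3(path) -> list[TruthRecord]:
    db = _load_db(path)
    out = []
    for f in db.all_features(order_by=("seqid", "start")):
        if f.featuretype not in _TYPE_FROM_SO:
            continue
        attr = lambda k, d=None: f.attributes[k][0] if k in f.attributes else d
        exons = []
        rss = []
        for c in db.children(f, order_by="start"):
            if c.featuretype == "exon":
                exons.append(Exon(c.attributes["exon_role"][0], c.start, c.end))
            elif c.featuretype == "recombination_signal_sequence":
                rss.append(_rss_from_feature(c))
        proteins = {}
        if attr("proteins"):
            for pair in attr("proteins").split(","):
                k, v = pair.split(":", 1)
                proteins[k] = v
        il = attr("intron_length")
        out.append(
            TruthRecord(
                gene_id=attr("ID"),
                segment_type=_TYPE_FROM_SO[f.featuretype],
                start=f.start,
                end=f.end,
                strand=f.strand,
                planted_defects=tuple(
                    attr("planted_defects", "").split(",") if attr("planted_defects") else ()
                ),
                expected_functionality=attr("expected_functionality"),
                exons=tuple(exons),
                rss=tuple(rss),
                proteins=proteins,
                intron_length=int(il) if il is not None else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# truth-vs-prediction comparison


@dataclass
class ComparisonReport:
    n_truth: int
    n_predicted: int
    n_matched: int
    precision: Optional[float]  # None when nothing was predicted
    recall: float
    per_type: pd.DataFrame = field(repr=False)
    coordinate_tolerance: int = 0


def compare_to_truth(
    pred: LocusAnnotation, truth: LocusAnnotation, tolerance: int = 0
) -> ComparisonReport:
    """Greedy one-to-one matching of same-type segments whose start and
    end offsets are each within ``tolerance`` bp."""
    rows = []
    total_m = 0
    types = sorted(
        {s.segment_type for s in truth.records} | {s.segment_type for s in pred.records}
    )
    for st in types:
        t_segs = sorted(truth.of_type(st), key=lambda s: (s.start, s.end))
        p_segs = sorted(pred.of_type(st), key=lambda s: (s.start, s.end))
        used = [False] * len(p_segs)
        m = 0
        for t in t_segs:
            for i, p in enumerate(p_segs):
                if used[i]:
                    continue
                if abs(p.start - t.start) <= tolerance and abs(p.end - t.end) <= tolerance:
                    used[i] = True
                    m += 1
                    break
        total_m += m
        rows.append(
            {
                "segment_type": st,
                "n_truth": len(t_segs),
                "n_predicted": len(p_segs),
                "n_matched": m,
            }
        )
    per_type = pd.DataFrame(rows).set_index("segment_type")
    n_t, n_p = len(truth.records), len(pred.records)
    return ComparisonReport(
        n_truth=n_t,
        n_predicted=n_p,
        n_matched=total_m,
        precision=(total_m / n_p) if n_p else None,
        recall=(total_m / n_t) if n_t else 0.0,
        per_type=per_type,
        coordinate_tolerance=tolerance,
    )
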