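"""Functional (F) vs pseudogene (P) classification of gene segments.

A V, D or J segment is functional when its coding region has an open
reading frame, proper splice sites, and a recombination signal of the
correct spacer class with an intact 5'-CAC-3' heptamer; V exons must
additionally carry the four IMGT-conserved residues (Cys23, Trp41,
Trp52, Cys104) and a leader exon, and J exons the FGXG di-glycine
bulge. On top of the structural rules an expression-evidence policy
can demand transcription of the V region and of its signal peptide —
a structurally immaculate gene that is never expressed is still called
a pseudogene under the strictest policy.

Every failing rule is recorded as a stable reason code (see
``REASON_CODES``); some codes carry a ``:<detail>`` suffix such as the
IMGT position of a missing conserved residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional

from Bio.Seq import Seq

from .genome import GenomeSequence
from .models import GeneSegment, LocusAnnotation
from .rss import RSS

__all__ = [
    "REASON_CODES",
    "ClassifierConfig",
    "FunctionalityCall",
    "ExpressionEvidence",
    "classify_segment",
    "classify_annotation",
    "find_nglyc_sites",
    "has_reason",
]

#: The documented reason-code enumeration. Codes marked (+detail)
#: append ':<detail>' — an IMGT position or an exon role.
REASON_CODES = (
    "missing_leader",
    "start_codon_missing",
    "splice_donor_invalid",
    "splice_acceptor_invalid",
    "frameshift",
    "premature_stop",
    "conserved_residue_missing",  # +detail: IMGT position
    "rss_absent",
    "rss_heptamer_cac",
    "rss_spacer_class",
    "j_motif_absent",
    "expression_absent",
    "sp_expression_absent",
    "missing_exon",  # +detail: exon role
)

EXPRESSION_POLICIES = (
    "structural_only",
    "require_gene_expression",
    "require_gene_and_sp_expression",
)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ClassifierConfig:
    conserved_v_residues: Mapping[int, str] = field(
        default_factory=lambda: {23: "C", 41: "W", 52: "W", 104: "C"}
    )
    j_motif: str = "FGXG"  # X matches any residue
    j_motif_strict: bool = True
    require_rss: bool = True
    require_splice_sites: bool = True
    expression_policy: str = "require_gene_and_sp_expression"
    nglyc_pattern: str = "N[^P][ST]"
    c_required_roles: tuple[str, ...] = ("C_IG", "M1", "M2")

    def __post_init__(self) -> None:
        if self.expression_policy not in EXPRESSION_POLICIES:
            raise ValueError(f"unknown expression_policy {self.expression_policy!r}")
        if not self.j_motif:
            raise ValueError("j_motif must be nonempty")
        if any(p <= 0 for p in self.conserved_v_residues):
            raise ValueError("IMGT positions must be positive")

    @property
    def j_motif_regex(self) -> str:
        return self.j_motif.replace("X", ".")


@dataclass(frozen=True)
class FunctionalityCall:
    verdict: str  # F | P
    reasons: tuple[str, ...]
    warnings: tuple[str, ...]
    policy_used: str


@dataclass
class ExpressionEvidence:
    """Per-gene transcription evidence: V region and signal peptide.

    Genes absent from the table default to not-expressed under
    expression-requiring policies (no evidence is negative evidence in
    this policy — the table is expected to cover the locus).
    """

    table: dict[str, tuple[bool, bool]] = field(default_factory=dict)

    def lookup(self, gene_id: str) -> tuple[bool, bool]:
        return self.table.get(gene_id, (False, False))

    @classmethod
    def from_tsv(cls, path) -> "ExpressionEvidence":
        table = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for line in fh:
                f = line.rstrip("\n").split("\t")
                table[f[idx["gene_id"]]] = (
                    f[idx["v_expressed"]] == "1",
                    f[idx["sp_expressed"]] == "1",
                )
        return cls(table)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tv_expressed\tsp_expressed\n")
            for gid, (v, sp) in self.table.items():
                fh.write(f"{gid}\t{int(v)}\t{int(sp)}\n")


def has_reason(call: FunctionalityCall, code: str) -> bool:
    return any(r == code or r.startswith(code + ":") for r in call.reasons)


def classify_segment(
    seg: GeneSegment,
    genome: GenomeSequence,
    expression: Optional[ExpressionEvidence] = None,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> FunctionalityCall:
    """Apply the type-specific rule set and return the verdict with all
    failing rules listed (ordered, stable)."""
    for e in seg.exons:
        if e.start < 1 or e.end > len(genome):
            raise ValueError(
                f"{seg.gene_id}: exon {e} outside contig of length {len(genome)}"
            )
    reasons: list[str] = []
    warnings: list[str] = []
    if seg.segment_type == "V":
        _classify_v(seg, genome, expression, cfg, reasons, warnings)
    elif seg.segment_type == "J":
        _classify_j(seg, genome, cfg, reasons, warnings)
    elif seg.segment_type == "D":
        _classify_d(seg, cfg, reasons)
    elif seg.segment_type == "C":
        _classify_c(seg, cfg, reasons)
    else:
        raise ValueError(f"unknown segment type {seg.segment_type!r}")
    return FunctionalityCall(
        verdict="P" if reasons else "F",
        reasons=tuple(reasons),
        warnings=tuple(warnings),
        policy_used=cfg.expression_policy,
    )


def classify_annotation(
    ann: LocusAnnotation,
    genome: GenomeSequence,
    expression: Optional[ExpressionEvidence] = None,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> LocusAnnotation:
    """Classify every record in place and return the annotation."""
    for seg in ann.records:
        call = classify_segment(seg, genome, expression, cfg)
        seg.functionality = call.verdict
        seg.reasons = list(call.reasons)
        seg.warnings = sorted(set(seg.warnings) | set(call.warnings))
    return ann


# ---------------------------------------------------------------------------


def _translate(nt: str) -> str:
    trimmed = nt[: len(nt) - len(nt) % 3]
    return str(Seq(trimmed).translate())


def _splice_dinucleotides(
    seg: GeneSegment, genome: GenomeSequence, e_left, e_right
) -> tuple[str, str]:
    """(donor, acceptor) of the intron between two exons, read in
    transcription orientation."""
    i_start, i_end = e_left.end + 1, e_right.start - 1
    if seg.strand == "+":
        donor = genome.fetch(i_start, i_start + 1)
        acceptor = genome.fetch(i_end - 1, i_end)
    else:
        donor = genome.fetch(i_end - 1, i_end, "-")
        acceptor = genome.fetch(i_start, i_start + 1, "-")
    return donor, acceptor


def _rss_checks(
    link: Optional[RSS], expected_class: int, reasons: list[str], cfg: ClassifierConfig
) -> None:
    if not cfg.require_rss:
        return
    if link is None:
        reasons.append("rss_absent")
        return
    if not link.cac_intact:
        reasons.append("rss_heptamer_cac")
    if link.spacer_class != expected_class:
        reasons.append("rss_spacer_class")


def _classify_v(seg, genome, expression, cfg, reasons, warnings) -> None:
    l1 = seg.exon("L1")
    v_exon = seg.exon("V_EXON")
    if v_exon is None:
        reasons.append("missing_exon:V_EXON")
        return
    v_nt = genome.fetch(v_exon.start, v_exon.end, seg.strand)
    coding = v_nt

    if l1 is None:
        reasons.append("missing_leader")
    else:
        l_nt = genome.fetch(l1.start, l1.end, seg.strand)
        coding = l_nt + v_nt
        if not l_nt.startswith("ATG"):
            reasons.append("start_codon_missing")
        if cfg.require_splice_sites:
            left, right = sorted((l1, v_exon), key=lambda e: e.start)
            donor, acceptor = _splice_dinucleotides(seg, genome, left, right)
            if donor != "GT":
                reasons.append("splice_donor_invalid")
            if acceptor != "AG":
                reasons.append("splice_acceptor_invalid")

    if len(coding) % 3 != 0:
        reasons.append("frameshift")
    if "*" in _translate(coding):
        reasons.append("premature_stop")

    v_prot = _translate(v_nt)
    for pos in sorted(cfg.conserved_v_residues):
        want = cfg.conserved_v_residues[pos]
        if pos > len(v_prot) or v_prot[pos - 1] != want:
            reasons.append(f"conserved_residue_missing:{pos}")

    link = next((h for h in seg.rss_links), None)
    _rss_checks(link, 23, reasons, cfg)

    if cfg.expression_policy != "structural_only":
        v_expr, sp_expr = (expression or ExpressionEvidence()).lookup(seg.gene_id)
        if not v_expr:
            reasons.append("expression_absent")
        if cfg.expression_policy == "require_gene_and_sp_expression" and not sp_expr:
            if v_expr:
                reasons.append("sp_expression_absent")
            # when the V region itself is silent, expression_absent covers it


def _classify_j(seg, genome, cfg, reasons, warnings) -> None:
    j_exon = seg.exon("J_EXON")
    if j_exon is None:
        reasons.append("missing_exon:J_EXON")
        return
    nt = genome.fetch(j_exon.start, j_exon.end, seg.strand)
    if len(nt) % 3 != 0:
        reasons.append("frameshift")
    prot = _translate(nt)
    if "*" in prot:
        reasons.append("premature_stop")
    if re.search(cfg.j_motif_regex, prot) is None:
        if cfg.j_motif_strict:
            reasons.append("j_motif_absent")
        else:
            warnings.append("j_motif_non_canonical")
    link = next((h for h in seg.rss_links), None)
    _rss_checks(link, 12, reasons, cfg)


def _classify_d(seg, cfg, reasons) -> None:
    if not cfg.require_rss:
        return
    up = next((h for h in seg.rss_links if h.orientation == "upstream_of_gene"), None)
    down = next((h for h in seg.rss_links if h.orientation == "downstream_of_gene"), None)
    if up is None:
        reasons.append("rss_missing_5prime")
    if down is None:
        reasons.append("rss_missing_3prime")
    if up and down and {up.spacer_class, down.spacer_class} != {12, 23}:
        reasons.append("rss_spacer_class")
    for h in (up, down):
        if h is not None and not h.cac_intact:
            reasons.append("rss_heptamer_cac")
            break


def _classify_c(seg, cfg, reasons) -> None:
    present = {e.role for e in seg.exons}
    for role in cfg.c_required_roles:
        if role not in present:
            reasons.append(f"missing_exon:{role}")


# ---------------------------------------------------------------------------


def find_nglyc_sites(
    protein: str, cfg: ClassifierConfig = ClassifierConfig()
) -> list[tuple[int, str]]:
    """All N-glycosylation sequons N-X-[S/T], X != P, in a protein.

    Returns 1-based positions with the four-residue context, the
    convention used when reporting sites as e.g. "42-45 (NDTE)".
    Overlapping sequons are all reported.
    """
    bad = set(protein) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    out = []
    for m in re.finditer(f"(?=({cfg.nglyc_pattern}))", protein):
        pos = m.start() + 1
        out.append((pos, protein[m.start() : m.start() + 4]))
    return out
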