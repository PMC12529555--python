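"""Synthetic T-cell-receptor locus generator with known truth.

Builds a contig containing planted V, D, J and C gene segments in the
canonical germline architecture:

* V — leader (L1) exon starting ATG, a GT..AG V-intron, a V exon whose
  translation carries the IMGT-conserved Cys23/Trp41/Trp52/Cys104, and
  a directly abutting downstream 23-spacer RSS;
* D — a short segment flanked by a 5' 12-spacer and a 3' 23-spacer RSS;
* J — an upstream 12-spacer RSS, an exon encoding the FGXG di-glycine
  bulge, and a GT splice donor;
* C — C-Ig, M1 (transmembrane) and M2 (cytoplasmic) exons.

A configurable fraction of V and J genes receive pseudogenizing
defects (frameshift, premature stop, missing leader, CAC-less RSS
heptamer, absent expression, non-canonical J motif). The truth records
carry exact planted coordinates, defect lists and the intended protein
sequences, so the generator doubles as the reference database for
round-trip annotation runs.

Planting is deterministic for a given spec + seed, and deliberately
avoids decoy signals that would make exact coordinate recovery
ill-posed: planted V-introns contain no internal GT dinucleotide,
leaders no internal in-frame ATG, and J exons no valine codon (GTN at
a codon boundary would mimic the splice donor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .functionality import ExpressionEvidence
from .genome import GenomeSequence, revcomp
from .models import Exon, GeneSegment, LocusAnnotation
from .rss import DEFAULT_HEPTAMER, DEFAULT_NONAMER, RSS

__all__ = [
    "SyntheticLocusSpec",
    "TruthRecord",
    "ReferenceSet",
    "build_locus",
    "segments_from_truth",
    "expression_from_truth",
    "reference_set",
    "truth_annotation",
    "table_fixture",
]

DEFECT_KINDS = (
    "frameshift",
    "premature_stop",
    "missing_leader",
    "rss_cac_defect",
    "no_expression",
    "missing_j_motif",
)
_V_DEFECTS = ("frameshift", "premature_stop", "missing_leader", "rss_cac_defect", "no_expression")
_J_DEFECTS = ("premature_stop", "rss_cac_defect", "missing_j_motif")

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}


@dataclass(frozen=True)
class SyntheticLocusSpec:
    """Planting plan for one synthetic locus.

    Distribution descriptors are ``(name, params)`` pairs; currently
    ``("lognormal", {"median": bp, "sigma": s})`` (lengths clipped to
    the stated bounds) and ``("fixed", {"value": bp})`` are supported.
    """

    n_v: int = 25
    n_d: int = 5
    n_j: int = 15
    n_c: int = 5
    pseudogene_fraction: float = 0.0
    defect_mix: dict = field(
        default_factory=lambda: {k: 1.0 for k in DEFECT_KINDS}
    )
    v_intron_length_dist: tuple = ("lognormal", {"median": 240.0, "sigma": 0.5})
    intergenic_length_dist: tuple = ("lognormal", {"median": 600.0, "sigma": 0.4})
    gc_background: float = 0.42
    seed: int = 0
    locus_label: str = "SYN"
    contig_name: str = "synthetic_locus"
    genome_size_cap: int = 2_000_000
    v_exon_codons: int = 110
    leader_codons: int = 16  # incl. the initiator Met

    def __post_init__(self) -> None:
        if min(self.n_v, self.n_d, self.n_j, self.n_c) < 0:
            raise ValueError("gene counts must be >= 0")
        if not 0.0 <= self.pseudogene_fraction <= 1.0:
            raise ValueError("pseudogene_fraction must be in [0, 1]")
        if any(w < 0 for w in self.defect_mix.values()):
            raise ValueError("defect weights must be nonnegative")
        if self.pseudogene_fraction > 0 and not any(self.defect_mix.values()):
            raise ValueError("defect_mix must not be all zero when defects are requested")
        unknown = set(self.defect_mix) - set(DEFECT_KINDS)
        if unknown:
            raise ValueError(f"unknown defect kinds: {sorted(unknown)}")


@dataclass(frozen=True)
class TruthRecord:
    """One planted segment with its exact coordinates and provenance."""

    gene_id: str
    segment_type: str  # V | D | J | C
    start: int
    end: int
    strand: str
    planted_defects: tuple[str, ...]
    expected_functionality: str  # F | P
    exons: tuple[Exon, ...]
    rss: tuple[RSS, ...] = ()
    proteins: dict = field(default_factory=dict)  # intended (pre-defect) translations
    intron_length: Optional[int] = None


@dataclass(frozen=True)
class ReferenceSet:
    """Protein references derived from a truth set, usable as the
    homology database for a round-trip annotation run."""

    v: dict[str, str]
    sp: dict[str, str]
    j: dict[str, str]
    c: dict[str, str]
    c_roles: dict[str, str]


# ---------------------------------------------------------------------------
# sampling helpers


def _sample_length(rng, dist, lo: int, hi: int) -> int:
    name, p = dist
    if name == "fixed":
        x = p["value"]
    elif name == "lognormal":
        x = rng.lognormal(np.log(p["median"]), p["sigma"])
    else:
        raise ValueError(f"unknown distribution {name!r}")
    return int(np.clip(round(x), lo, hi))


def _bg(rng, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _bg_no_gt(rng, n: int, gc: float) -> str:
    """Background with no GT dinucleotide (intron interiors)."""
    out = []
    prev = ""
    for _ in range(n):
        while True:
            b = _bg(rng, 1, gc)
            if not (prev == "G" and b == "T"):
                break
        out.append(b)
        prev = b
    return "".join(out)


def _codon(rng, aa: str) -> str:
    opts = _CODONS[aa]
    return opts[rng.integers(len(opts))]


def _protein(rng, n: int, exclude: str = "") -> str:
    pool = [a for a in _AA if a not in exclude]
    return "".join(rng.choice(pool, size=n))


def _encode(rng, protein: str) -> str:
    return "".join(_codon(rng, a) for a in protein)


def _rss_plus(contig, hept_start: int, spacer_class: int, heptamer: str, spacer: str) -> RSS:
    """Truth RSS for a downstream (plus-pattern) signal starting at hept_start."""
    s = len(spacer)
    return RSS(
        contig=contig,
        strand="+",
        spacer_class=spacer_class,
        heptamer_interval=(hept_start, hept_start + 6),
        spacer_interval=(hept_start + 7, hept_start + 6 + s),
        nonamer_interval=(hept_start + 7 + s, hept_start + 15 + s),
        heptamer_mismatches=sum(a != b for a, b in zip(heptamer, DEFAULT_HEPTAMER)),
        nonamer_mismatches=0,
        cac_intact=heptamer.startswith("CAC"),
    )


def _rss_minus(contig, non_start: int, spacer_class: int, heptamer: str, spacer: str) -> RSS:
    """Truth RSS for an upstream (minus-pattern) signal whose revcomp
    layout starts at non_start on the plus strand."""
    s = len(spacer)
    return RSS(
        contig=contig,
        strand="-",
        spacer_class=spacer_class,
        heptamer_interval=(non_start + 9 + s, non_start + 15 + s),
        spacer_interval=(non_start + 9, non_start + 8 + s),
        nonamer_interval=(non_start, non_start + 8),
        heptamer_mismatches=sum(a != b for a, b in zip(heptamer, DEFAULT_HEPTAMER)),
        nonamer_mismatches=0,
        cac_intact=heptamer.startswith("CAC"),
    )


# ---------------------------------------------------------------------------
# the generator


def build_locus(spec: SyntheticLocusSpec) -> tuple[GenomeSequence, list[TruthRecord]]:
    """Generate a genome and its truth annotation from a planting plan.

    Plan order along the contig is all V, then D, then J, then C genes,
    separated by intergenic background. Identical spec (including seed)
    yields byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_background
    pieces: list[str] = []
    pos = 1
    truth: list[TruthRecord] = []

    def emit(s: str) -> int:
        nonlocal pos
        pieces.append(s)
        start = pos
        pos += len(s)
        if pos - 1 > spec.genome_size_cap:
            raise ValueError(
                f"planted locus exceeds genome_size_cap={spec.genome_size_cap}"
            )
        return start

    def intergenic() -> None:
        # floor of 400 bp keeps neighbouring genes separable: C-gene exon
        # grouping uses a 350 bp gap threshold and C introns stay <= 300 bp
        emit(_bg(rng, _sample_length(rng, spec.intergenic_length_dist, 400, 3000), gc))

    defect_plan = _assign_defects(rng, spec)

    intergenic()
    for i in range(spec.n_v):
        truth.append(_plant_v(rng, spec, emit, f"V_{i + 1:03d}", defect_plan["V"][i]))
        intergenic()
    for i in range(spec.n_d):
        truth.append(_plant_d(rng, spec, emit, f"D_{i + 1:03d}"))
        intergenic()
    for i in range(spec.n_j):
        truth.append(_plant_j(rng, spec, emit, f"J_{i + 1:03d}", defect_plan["J"][i]))
        intergenic()
    for i in range(spec.n_c):
        truth.append(_plant_c(rng, spec, emit, f"C_{i + 1:03d}"))
        intergenic()

    genome = GenomeSequence(spec.contig_name, "".join(pieces))
    return genome, truth


def _assign_defects(rng, spec) -> dict[str, list[tuple[str, ...]]]:
    plan = {"V": [()] * spec.n_v, "J": [()] * spec.n_j}
    for seg_type, n, compatible in (
        ("V", spec.n_v, _V_DEFECTS),
        ("J", spec.n_j, _J_DEFECTS),
    ):
        n_pseudo = int(round(n * spec.pseudogene_fraction))
        if n_pseudo == 0:
            continue
        weights = np.array([spec.defect_mix.get(k, 0.0) for k in compatible])
        if weights.sum() == 0:
            continue
        weights = weights / weights.sum()
        which = rng.choice(n, size=n_pseudo, replace=False)
        for g in sorted(which):
            plan[seg_type][g] = (str(rng.choice(list(compatible), p=weights)),)
    return plan


def _plant_v(rng, spec, emit, gene_id, defects) -> TruthRecord:
    contig = spec.contig_name
    gc = spec.gc_background
    leader_aa = "M" + _protein(rng, spec.leader_codons - 1, exclude="M")
    v_aa = list(_protein(rng, spec.v_exon_codons))
    for p, a in ((23, "C"), (41, "W"), (52, "W"), (104, "C")):
        v_aa[p - 1] = a
    v_aa = "".join(v_aa)
    leader_nt = _encode(rng, leader_aa)
    v_nt = _encode(rng, v_aa)
    intron_len = _sample_length(rng, spec.v_intron_length_dist, 80, 3000)
    intron = "GT" + _bg_no_gt(rng, intron_len - 4, gc) + "AG"

    heptamer = DEFAULT_HEPTAMER
    if "premature_stop" in defects:
        k = 60  # codon index, past Trp52, before Cys104? no: keep past 52
        v_nt = v_nt[: 3 * k] + "TAA" + v_nt[3 * k + 3 :]
    if "frameshift" in defects:
        cut = 3 * 105  # single-base deletion past the Cys104 codon
        v_nt = v_nt[:cut] + v_nt[cut + 1 :]
    if "rss_cac_defect" in defects:
        heptamer = "GAC" + DEFAULT_HEPTAMER[3:]
    spacer = _bg(rng, 23, gc)
    rss_nt = heptamer + spacer + DEFAULT_NONAMER

    exons: list[Exon] = []
    if "missing_leader" in defects:
        v_start = emit(v_nt)
        exons.append(Exon("V_EXON", v_start, v_start + len(v_nt) - 1))
        planted_intron = None
    else:
        l_start = emit(leader_nt)
        emit(intron)
        v_start = emit(v_nt)
        exons = [
            Exon("L1", l_start, l_start + len(leader_nt) - 1),
            Exon("V_EXON", v_start, v_start + len(v_nt) - 1),
        ]
        planted_intron = intron_len
    rss_start = emit(rss_nt)
    rss = _rss_plus(contig, rss_start, 23, heptamer, spacer)

    return TruthRecord(
        gene_id=gene_id,
        segment_type="V",
        start=exons[0].start,
        end=exons[-1].end,
        strand="+",
        planted_defects=defects,
        expected_functionality="P" if defects else "F",
        exons=tuple(exons),
        rss=(rss.with_orientation("downstream_of_gene"),),
        proteins={"V_EXON": v_aa, "L1": leader_aa},
        intron_length=planted_intron,
    )


def _plant_j(rng, spec, emit, gene_id, defects) -> TruthRecord:
    contig = spec.contig_name
    gc = spec.gc_background
    n_codons = int(rng.integers(14, 19))
    # no valine anywhere (a GTN codon would plant a decoy splice donor)
    aa = list(_protein(rng, n_codons, exclude="V"))
    motif = ["F", "G", str(rng.choice([a for a in _AA if a not in "VP"])), "G"]
    if "missing_j_motif" in defects:
        motif = ["F", "K", "K", "G"]
    aa[n_codons - 6 : n_codons - 2] = motif
    j_aa = "".join(aa)
    j_nt = _encode(rng, j_aa)
    if "premature_stop" in defects:
        j_nt = j_nt[:3] + "TAA" + j_nt[6:]

    heptamer = DEFAULT_HEPTAMER
    if "rss_cac_defect" in defects:
        heptamer = "GAC" + DEFAULT_HEPTAMER[3:]
    spacer = _bg(rng, 12, gc)
    rss_nt = revcomp(DEFAULT_NONAMER) + revcomp(spacer) + revcomp(heptamer)

    rss_start = emit(rss_nt)
    j_start = emit(j_nt)
    emit("GT")  # splice donor into the constant exon
    rss = _rss_minus(contig, rss_start, 12, heptamer, spacer)
    return TruthRecord(
        gene_id=gene_id,
        segment_type="J",
        start=j_start,
        end=j_start + len(j_nt) - 1,
        strand="+",
        planted_defects=defects,
        expected_functionality="P" if defects else "F",
        exons=(Exon("J_EXON", j_start, j_start + len(j_nt) - 1),),
        rss=(rss.with_orientation("upstream_of_gene"),),
        proteins={"J_EXON": j_aa},
    )


def _plant_d(rng, spec, emit, gene_id) -> TruthRecord:
    contig = spec.contig_name
    gc = spec.gc_background
    d_len = int(rng.integers(10, 21))
    d_nt = _bg(rng, d_len, gc)
    spacer5 = _bg(rng, 12, gc)
    spacer3 = _bg(rng, 23, gc)
    up_nt = revcomp(DEFAULT_NONAMER) + revcomp(spacer5) + revcomp(DEFAULT_HEPTAMER)
    down_nt = DEFAULT_HEPTAMER + spacer3 + DEFAULT_NONAMER

    up_start = emit(up_nt)
    d_start = emit(d_nt)
    down_start = emit(down_nt)
    up = _rss_minus(contig, up_start, 12, DEFAULT_HEPTAMER, spacer5)
    down = _rss_plus(contig, down_start, 23, DEFAULT_HEPTAMER, spacer3)
    return TruthRecord(
        gene_id=gene_id,
        segment_type="D",
        start=d_start,
        end=d_start + d_len - 1,
        strand="+",
        planted_defects=(),
        expected_functionality="F",
        exons=(Exon("D_REGION", d_start, d_start + d_len - 1),),
        rss=(
            up.with_orientation("upstream_of_gene"),
            down.with_orientation("downstream_of_gene"),
        ),
    )


def _plant_c(rng, spec, emit, gene_id) -> TruthRecord:
    gc = spec.gc_background
    profiles = (("C_IG", 100), ("M1", 25), ("M2", 20))
    exons = []
    proteins = {}
    for k, (role, n_aa) in enumerate(profiles):
        if k:
            ilen = int(rng.integers(80, 301))
            emit("GT" + _bg(rng, ilen - 4, gc) + "AG")
        aa = _protein(rng, n_aa)
        nt = _encode(rng, aa)
        start = emit(nt)
        exons.append(Exon(role, start, start + len(nt) - 1))
        proteins[role] = aa
    return TruthRecord(
        gene_id=gene_id,
        segment_type="C",
        start=exons[0].start,
        end=exons[-1].end,
        strand="+",
        planted_defects=(),
        expected_functionality="F",
        exons=tuple(exons),
        proteins=proteins,
    )


# ---------------------------------------------------------------------------
# derived views


def segments_from_truth(
    truth: Sequence[TruthRecord], contig: str, locus_label: str = "SYN"
) -> list[GeneSegment]:
    """Gene segments with planted exon structure and RSS links, for
    classifying the truth directly (no detection noise)."""
    return [
        GeneSegment(
            gene_id=t.gene_id,
            segment_type=t.segment_type,
            contig=contig,
            strand=t.strand,
            exons=list(t.exons),
            locus_label=locus_label,
            rss_links=list(t.rss),
            source="truth",
        )
        for t in truth
    ]


def expression_from_truth(truth: Sequence[TruthRecord]) -> ExpressionEvidence:
    """Expression table consistent with the planting plan: every V gene
    is transcribed (V region and signal peptide) unless planted with the
    no_expression defect."""
    table = {}
    for t in truth:
        if t.segment_type == "V":
            expressed = "no_expression" not in t.planted_defects
            table[t.gene_id] = (expressed, expressed)
    return ExpressionEvidence(table)


def reference_set(truth: Sequence[TruthRecord]) -> ReferenceSet:
    """Protein reference database derived from the intended (pre-defect)
    translations of a truth set."""
    v, sp, j, c, roles = {}, {}, {}, {}, {}
    for t in truth:
        if t.segment_type == "V":
            v[t.gene_id] = t.proteins["V_EXON"]
            if "L1" in t.proteins:
                sp[f"{t.gene_id}_SP"] = t.proteins["L1"]
        elif t.segment_type == "J":
            j[t.gene_id] = t.proteins["J_EXON"]
        elif t.segment_type == "C":
            for role, aa in t.proteins.items():
                rid = f"{t.gene_id}_{role}"
                c[rid] = aa
                roles[rid] = role
    return ReferenceSet(v=v, sp=sp, j=j, c=c, c_roles=roles)


def truth_annotation(
    truth: Sequence[TruthRecord], contig: str, locus_label: str = "SYN"
) -> LocusAnnotation:
    """The truth as a classified LocusAnnotation (expected verdicts)."""
    segs = segments_from_truth(truth, contig, locus_label)
    for seg, t in zip(segs, truth):
        seg.functionality = t.expected_functionality
        seg.reasons = list(t.planted_defects)
    return LocusAnnotation(
        contig=contig,
        records=segs,
        locus_label=locus_label,
        metadata={"source": "truth"},
    )


# ---------------------------------------------------------------------------
# printed-inventory fixtures


#: (segment_type, n_functional, n_pseudogene) rows of the published
#: axolotl TRA-TRD and TRB locus inventories.
_TABLE_COUNTS = {
    "TRA": (("V", 46, 15), ("J", 33, 3), ("C", 1, 0)),
    "TRD": (("V", 1, 1), ("J", 2, 0), ("C", 1, 0), ("D", 0, 0)),
    "TRB": (("V", 18, 5), ("D", 5, 0), ("J", 17, 0), ("C", 6, 0)),
}

_ROLE_FOR_TYPE = {"V": "V_EXON", "J": "J_EXON", "D": "D_REGION", "C": "C_IG"}


def table_fixture(locus_label: str) -> LocusAnnotation:
    """The published gene inventory of one axolotl locus (TRA, TRD or
    TRB) as a LocusAnnotation.

    Counts and functionality flags follow the printed per-type tables;
    coordinates are evenly spaced placeholders. This is the acceptance
    fixture for the locus-level statistics.
    """
    if locus_label not in _TABLE_COUNTS:
        raise ValueError(f"unknown locus label {locus_label!r}")
    records = []
    pos = 1000
    for seg_type, n_f, n_p in _TABLE_COUNTS[locus_label]:
        for i in range(n_f + n_p):
            start, end = pos, pos + 399
            pos += 1000
            records.append(
                GeneSegment(
                    gene_id=f"{locus_label}{seg_type}_{i + 1:03d}",
                    segment_type=seg_type,
                    contig=f"{locus_label}_fixture",
                    strand="+",
                    exons=[Exon(_ROLE_FOR_TYPE[seg_type], start, end)],
                    locus_label=locus_label,
                    functionality="F" if i < n_f else "P",
                    source="fixture",
                )
            )
    return LocusAnnotation(
        contig=f"{locus_label}_fixture",
        records=records,
        locus_label=locus_label,
        metadata={"source": "published inventory"},
    )
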