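"""Gene-model construction: homology seeding, V assembly, RSS-driven
J/D discovery, redundancy reduction and presence reporting."""

import numpy as np
import pytest

import trlocus as trl
from trlocus.genome import revcomp
from trlocus.models import (
    DDetectionParams,
    SeedingConfig,
    assemble_v_gene,
    detect_d_candidates,
    detect_j_genes,
    locus_presence,
    reduce_and_confirm,
    seed_hits,
)
from trlocus.rss import DEFAULT_HEPTAMER, DEFAULT_NONAMER, scan_rss
from trlocus.synthetic import _CODONS

from conftest import random_dna


def encode(protein: str, rng) -> str:
    return "".join(_CODONS[a][rng.integers(len(_CODONS[a]))] for a in protein)


def smith_waterman(a: str, b: str, matrix, gap_open=-12, gap_extend=-1):
    """Independent affine-gap local-alignment oracle (plain DP)."""
    n, m = len(a), len(b)
    NEG = -10**9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG, dtype=float)
    F = np.full((n + 1, m + 1), NEG, dtype=float)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = H[i - 1][j - 1] + matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


@pytest.fixture(scope="module")
def seed_case():
    rng = np.random.default_rng(17)
    prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTWY"), size=100))
    nt = encode(prot, rng)
    left, right = random_dna(rng, 800), random_dna(rng, 800)
    genome = trl.GenomeSequence("s", left + nt + right)
    interval = (len(left) + 1, len(left) + len(nt))
    return rng, prot, genome, interval


def test_exact_planting_single_seed(seed_case):
    _, prot, genome, interval = seed_case
    seeds = seed_hits(genome, {"ref1": prot})
    assert len(seeds) == 1
    s = seeds[0]
    assert (s.start, s.end) == interval
    assert s.strand == "+" and s.percent_identity == 100.0
    assert s.reference_id == "ref1"


def test_mutated_homolog_detected_and_scores_match_dp_oracle(seed_case):
    """~70% amino-acid identity still seeds; the aligner's local score
    on the planted window equals a plain dynamic-programming oracle."""
    rng, prot, genome, interval = seed_case
    from Bio.Align import substitution_matrices

    mutated = list(prot)
    pos = rng.choice(100, size=30, replace=False)
    for p in pos:
        mutated[p] = str(rng.choice([a for a in "ACDEFGHIKLMNPQRSTWY" if a != prot[p]]))
    mutated = "".join(mutated)
    seeds = seed_hits(genome, {"mut": mutated})
    assert len(seeds) == 1
    s = seeds[0]
    assert s.strand == "+"
    assert (s.start, s.end) == interval  # substitutions keep the window
    assert 60.0 <= s.percent_identity <= 80.0

    window_prot = prot  # translation of the planted window, frame 0
    blosum = substitution_matrices.load("BLOSUM62")
    oracle = smith_waterman(window_prot, mutated, blosum)
    assert s.score == pytest.approx(oracle)


def test_minus_strand_planting(seed_case):
    rng, prot, genome, interval = seed_case
    flipped = trl.GenomeSequence("s_rc", revcomp(genome.seq))
    seeds = seed_hits(flipped, {"ref1": prot})
    assert len(seeds) == 1
    L = len(genome)
    assert seeds[0].strand == "-"
    assert (seeds[0].start, seeds[0].end) == (L - interval[1] + 1, L - interval[0] + 1)


def test_no_homolog_no_seeds_and_empty_refs_rejected(rng):
    genome = trl.GenomeSequence("r", random_dna(rng, 2000))
    rng2 = np.random.default_rng(5)
    prot = "".join(rng2.choice(list("ACDEFGHIKLMNPQRSTWY"), size=100))
    assert seed_hits(genome, {"q": prot}) == []
    with pytest.raises(ValueError):
        seed_hits(genome, {})


class TestVAssembly:
    def test_planted_v_assembles_exactly(self, small_locus):
        _, genome, truth = small_locus
        refs = trl.reference_set(truth)
        hits = scan_rss(genome)
        t = next(t for t in truth if t.segment_type == "V")
        (seed,) = seed_hits(genome, {t.gene_id: refs.v[t.gene_id]})
        seg = assemble_v_gene(seed, hits, genome, gene_id=t.gene_id)
        assert [tuple(e) for e in seg.exons] == [tuple(e) for e in t.exons]
        assert len(seg.rss_links) == 1
        assert seg.rss_links[0].heptamer_interval == t.rss[0].heptamer_interval
        assert seg.rss_links[0].orientation == "downstream_of_gene"

    def test_missing_rss_leaves_model_without_link(self, small_locus):
        _, genome, truth = small_locus
        refs = trl.reference_set(truth)
        t = next(t for t in truth if t.segment_type == "V")
        (seed,) = seed_hits(genome, {t.gene_id: refs.v[t.gene_id]})
        seg = assemble_v_gene(seed, [], genome, gene_id=t.gene_id)  # no RSS evidence
        assert seg.rss_links == []
        assert seg.exon("L1") is not None

    def test_seed_at_contig_edge_has_no_leader(self, rng):
        rng2 = np.random.default_rng(8)
        prot = "".join(rng2.choice(list("ACDEFGHIKLMNPQRSTWY"), size=60))
        nt = encode(prot, rng2)
        genome = trl.GenomeSequence("edge", nt + random_dna(rng2, 300))
        (seed,) = seed_hits(genome, {"v": prot}, SeedingConfig(min_alignment_score=50))
        seg = assemble_v_gene(seed, [], genome)
        assert seg.exon("L1") is None  # classifier will flag missing_leader


class TestJDetection:
    def test_planted_j_canonical_motif(self, small_locus):
        _, genome, truth = small_locus
        hits = scan_rss(genome)
        segs = detect_j_genes(genome, hits)
        t_j = [t for t in truth if t.segment_type == "J"]
        assert {(s.start, s.end) for s in segs} >= {(t.start, t.end) for t in t_j}
        by_span = {(s.start, s.end): s for s in segs}
        for t in t_j:
            s = by_span[(t.start, t.end)]
            assert s.motif_evidence == "canonical"
            assert s.rss_links[0].spacer_class == 12
            assert s.rss_links[0].orientation == "upstream_of_gene"

    def test_fkkg_j_emitted_via_homology_as_non_canonical(self):
        """A J with the FKKG variant of the di-glycine bulge is still
        modelled when a J reference matches, with non-canonical motif
        evidence recorded rather than the gene being dropped."""
        rng = np.random.default_rng(21)
        j_aa = "".join(rng.choice([a for a in "ACDEFGHIKLMNPQRSTWY" if a != "V"], size=16))
        j_aa = j_aa[:10] + "FKKG" + j_aa[14:]
        j_nt = encode(j_aa, rng)
        rss = revcomp(DEFAULT_NONAMER) + revcomp(random_dna(rng, 12)) + revcomp(DEFAULT_HEPTAMER)
        seq = random_dna(rng, 300) + rss + j_nt + "GT" + random_dna(rng, 300)
        genome = trl.GenomeSequence("jd", seq)
        hits = scan_rss(genome)
        assert detect_j_genes(genome, hits) == []  # no motif, no reference
        segs = detect_j_genes(genome, hits, j_references={"jref": j_aa})
        assert len(segs) == 1
        assert segs[0].motif_evidence == "non_canonical"

    def test_region_with_only_23_rss_yields_no_j(self, rng):
        seq = random_dna(rng, 200) + DEFAULT_HEPTAMER + random_dna(rng, 23) + DEFAULT_NONAMER + random_dna(rng, 200)
        genome = trl.GenomeSequence("no_j", seq)
        assert detect_j_genes(genome, scan_rss(genome)) == []


class TestDDetection:
    def test_planted_translocon_d_recovered(self):
        spec = trl.SyntheticLocusSpec(n_v=0, n_d=5, n_j=0, n_c=0, seed=13)
        genome, truth = trl.build_locus(spec)
        segs = detect_d_candidates(genome, scan_rss(genome))
        assert {(s.start, s.end) for s in segs} == {(t.start, t.end) for t in truth}
        for s in segs:
            assert trl.check_12_23_pair(*s.rss_links)

    def test_trd_style_region_has_no_d(self):
        """V- and J-serving RSSs alone never produce a D candidate —
        the configuration in which a locus genuinely lacks D genes."""
        spec = trl.SyntheticLocusSpec(n_v=2, n_d=0, n_j=2, n_c=0, seed=19)
        genome, truth = trl.build_locus(spec)
        segs = detect_d_candidates(genome, scan_rss(genome))
        v_j_spans = {(t.start, t.end) for t in truth}
        assert all((s.start, s.end) not in v_j_spans for s in segs)
        assert segs == []

    def test_distance_bound(self, rng):
        up = revcomp(DEFAULT_NONAMER) + revcomp(random_dna(rng, 12)) + revcomp(DEFAULT_HEPTAMER)
        down = DEFAULT_HEPTAMER + random_dna(rng, 23) + DEFAULT_NONAMER
        near = random_dna(rng, 300) + up + random_dna(rng, 20) + down + random_dna(rng, 300)
        far = random_dna(rng, 300) + up + random_dna(rng, 80) + down + random_dna(rng, 300)
        assert len(detect_d_candidates(trl.GenomeSequence("n", near), scan_rss(trl.GenomeSequence("n", near)))) == 1
        assert detect_d_candidates(trl.GenomeSequence("f", far), scan_rss(trl.GenomeSequence("f", far))) == []

    def test_invariant_under_wrong_class_rss(self):
        """Adding signals that violate the class/orientation scheme
        never changes the candidate set."""
        import dataclasses

        spec = trl.SyntheticLocusSpec(n_v=0, n_d=3, n_j=0, n_c=0, seed=23)
        genome, _ = trl.build_locus(spec)
        hits = scan_rss(genome)
        base = detect_d_candidates(genome, hits)
        # class-swapped copies: a 12-spacer where a 23 is required and
        # vice versa can never serve as a D flank
        wrong = [
            dataclasses.replace(h, spacer_class=23 if h.spacer_class == 12 else 12)
            for h in hits
            if (h.strand, h.spacer_class) in (("-", 12), ("+", 23))
        ]
        again = detect_d_candidates(genome, list(hits) + wrong)
        assert {(s.start, s.end) for s in again} == {(s.start, s.end) for s in base}


class TestReduceAndConfirm:
    def _v(self, start, end, score, strand="+", seg_type="V"):
        return trl.GeneSegment(
            gene_id=f"g{start}",
            segment_type=seg_type,
            contig="x",
            strand=strand,
            exons=[trl.Exon("V_EXON", start, end)],
            score=score,
        )

    def test_identical_models_collapse(self):
        a, b = self._v(10, 100, 50.0), self._v(10, 100, 40.0)
        out = reduce_and_confirm([a, b])
        assert len(out) == 1 and out[0].score == 50.0

    def test_non_overlapping_passthrough_and_idempotence(self):
        segs = [self._v(10, 100, 5.0), self._v(200, 300, 6.0)]
        out = reduce_and_confirm(segs)
        assert [(s.start, s.end) for s in out] == [(10, 100), (200, 300)]
        again = reduce_and_confirm(out)
        assert [(s.start, s.end) for s in again] == [(s.start, s.end) for s in out]
        assert len(again) <= len(out)

    def test_unconfirmed_v_flagged_but_retained(self):
        v = self._v(10, 100, 5.0)
        out = reduce_and_confirm([v], sp_hits=[])
        assert len(out) == 1
        assert "sp_unconfirmed" in out[0].warnings
        assert out[0].sp_confirmed is False

    def test_overlapping_sp_hit_confirms(self):
        v = self._v(10, 100, 5.0)
        v.exons.insert(0, trl.Exon("L1", 1, 9))
        sp = trl.HomologySeed("x", 2, 8, "+", "sp1", 100.0, 60.0, 1)
        out = reduce_and_confirm([v], sp_hits=[sp])
        assert out[0].sp_confirmed is True
        assert "sp_unconfirmed" not in out[0].warnings

    def test_nested_d_candidate_removed(self):
        v = self._v(10, 400, 500.0)
        d = self._v(50, 60, 0.0, seg_type="D")
        out = reduce_and_confirm([v, d])
        assert [s.segment_type for s in out] == ["V"]


class TestLocusPresence:
    def test_planted_reference_present(self, seed_case):
        _, prot, genome, _ = seed_case
        rep = locus_presence(genome, {"target": prot})
        assert rep.present and rep.n_hits == 1

    def test_absent_locus_with_conserved_flanking_markers(self, rng):
        """Flanking markers found, target absent: the negative-search
        configuration used to argue true locus loss."""
        rng2 = np.random.default_rng(31)
        aas = "ACDEFGHIKLMNPQRSTWY"
        m1, m2, target = (
            "".join(rng2.choice(list(aas), size=90)) for _ in range(3)
        )
        seq = (
            random_dna(rng2, 400)
            + encode(m1, rng2)
            + random_dna(rng2, 800)
            + encode(m2, rng2)
            + random_dna(rng2, 400)
        )
        genome = trl.GenomeSequence("flank", seq)
        rep = locus_presence(genome, {"target": target}, markers={"m1": m1, "m2": m2})
        assert not rep.present
        assert rep.best_score < 100.0
        assert rep.marker_hits == {"m1": True, "m2": True}

    def test_empty_reference_set_is_an_error(self, rng):
        genome = trl.GenomeSequence("e", random_dna(rng, 500))
        with pytest.raises(ValueError):
            locus_presence(genome, {})
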