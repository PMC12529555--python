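"""Locus statistics: published-inventory summaries, spans, intron
arithmetic, and the exact tests against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

import trlocus as trl
from trlocus.stats import (
    ContingencyTable,
    StatsConfig,
    fisher_exact,
    intron_lengths,
    locus_span,
    long_intron_table,
    summarize_locus,
    wilcoxon_rank_sum,
)
from trlocus.synthetic import SyntheticLocusSpec, build_locus, table_fixture, truth_annotation


# ---------------------------------------------------------------------------
# independent oracles


def fisher_p_oracle(table) -> float:
    """Two-sided Fisher p by enumerating every table with the observed
    margins and summing hypergeometric probabilities <= the observed."""
    (a, b), (c, d) = table
    N, K, n = a + b + c + d, a + b, a + c
    lo, hi = max(0, K + n - N), min(K, n)
    p_obs = hypergeom.pmf(a, N, K, n)
    return float(
        sum(
            p
            for x in range(lo, hi + 1)
            if (p := hypergeom.pmf(x, N, K, n)) <= p_obs * (1 + 1e-7)
        )
    )


def wilcoxon_p_oracle(a, b) -> float:
    """Exact two-sided rank-sum p by full enumeration of all group
    assignments of the combined sample."""
    combined = sorted(a + b)
    ranks = {v: r + 1 for r, v in enumerate(combined)}  # tie-free inputs
    w_obs = sum(ranks[v] for v in a)
    n_a = len(a)
    stats = [
        sum(ranks[combined[i]] for i in idx)
        for idx in itertools.combinations(range(len(combined)), n_a)
    ]
    mu = sum(stats) / len(stats)
    dev = abs(w_obs - mu)
    extreme = sum(abs(s - mu) >= dev - 1e-12 for s in stats)
    return extreme / len(stats)


# ---------------------------------------------------------------------------


class TestSummaries:
    def test_tra_inventory_matches_published_table(self):
        s = summarize_locus(table_fixture("TRA"))
        trav = s.row("TRAV")
        assert trav["n_functional"] == 46 and trav["n_total"] == 61
        assert trav["pct_functional"] == pytest.approx(75.4, abs=0.1)
        assert trav["pct_pseudogene"] == pytest.approx(24.59, abs=0.1)
        assert trav["fp_ratio"] == 3.06  # 46/15 truncated, not rounded
        traj = s.row("TRAJ")
        assert traj["pct_functional"] == pytest.approx(91.6, abs=0.1)
        assert traj["pct_pseudogene"] == pytest.approx(8.3, abs=0.1)

    def test_trb_inventory_matches_published_table(self):
        s = summarize_locus(table_fixture("TRB"))
        assert s.row("TRBV")["fp_ratio"] == 3.6
        assert s.row("TRBV")["pct_functional"] == pytest.approx(78.26, abs=0.1)
        assert s.row("TRBC")["n_total"] == 6
        assert s.row("TRBJ")["n_functional"] == 17

    def test_zero_pseudogene_type_is_flagged_undefined(self):
        s = summarize_locus(table_fixture("TRB"))
        assert math.isnan(s.row("TRBD")["fp_ratio"])
        assert s.row("TRBD")["pct_functional"] == 100.0

    def test_totals_conserved_and_percentages_sum_to_100(self):
        for locus in ("TRA", "TRB", "TRD"):
            ann = table_fixture(locus)
            s = summarize_locus(ann)
            assert s.table["n_total"].sum() == len(ann)
            assert (s.table["n_functional"] + s.table["n_pseudogene"]).equals(
                s.table["n_total"]
            )
            for _, row in s.table.iterrows():
                assert row["pct_functional"] + row["pct_pseudogene"] == pytest.approx(
                    100.0, abs=0.02
                )

    def test_unclassified_segment_is_an_error(self, small_locus):
        _, genome, truth = small_locus
        ann = truth_annotation(truth, genome.name)
        ann.records[0].functionality = "unclassified"
        with pytest.raises(ValueError):
            summarize_locus(ann)


class TestLocusSpan:
    @pytest.mark.parametrize(
        "start, end, expected",
        [(264.6, 285.3, 20.7), (30.03, 34.85, 4.82), (5.0, 5.0, 0.0)],
    )
    def test_published_spans(self, start, end, expected):
        assert locus_span(start, end, "Mbp") == pytest.approx(expected)

    def test_translation_invariance(self):
        assert locus_span(10.0 + 3.7, 20.0 + 3.7) == pytest.approx(locus_span(10.0, 20.0))

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            locus_span(10.0, 5.0)


class TestIntronLengths:
    def _v_with_exons(self, gid, e1, e2):
        return trl.GeneSegment(
            gene_id=gid, segment_type="V", contig="x", strand="+",
            exons=[trl.Exon("L1", *e1), trl.Exon("V_EXON", *e2)],
            functionality="F",
        )

    def test_arithmetic_and_adjacency(self):
        ann = trl.LocusAnnotation(
            "x",
            [
                self._v_with_exons("a", (1, 100), (201, 300)),
                self._v_with_exons("b", (1, 100), (101, 200)),
            ],
        )
        lens = intron_lengths(ann)
        assert lens["a"] == 100 and lens["b"] == 0

    def test_planted_lengths_recovered_exactly(self):
        spec = SyntheticLocusSpec(
            n_v=6, n_d=0, n_j=0, n_c=0,
            v_intron_length_dist=("fixed", {"value": 240}), seed=4,
        )
        genome, truth = build_locus(spec)
        ann = truth_annotation(truth, genome.name)
        lens = intron_lengths(ann)
        planted = {t.gene_id: t.intron_length for t in truth}
        assert dict(lens) == pytest.approx(planted)
        assert lens.mean() == 240.0

    def test_leaderless_gene_excluded(self):
        seg = trl.GeneSegment(
            gene_id="nl", segment_type="V", contig="x", strand="+",
            exons=[trl.Exon("V_EXON", 50, 400)], functionality="P",
        )
        ann = trl.LocusAnnotation("x", [seg])
        assert len(intron_lengths(ann)) == 0


class TestWilcoxon:
    def test_identical_groups_p_is_one(self):
        assert wilcoxon_rank_sum([5, 5, 5], [5, 5, 5]).p_value == pytest.approx(1.0)

    def test_separated_groups_match_permutation_oracle(self):
        a, b = [1, 2, 3], [10, 11, 12]
        res = wilcoxon_rank_sum(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(wilcoxon_p_oracle(a, b))
        assert res.p_value == pytest.approx(0.1)  # 2/20 assignments as extreme

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n_a=st.integers(2, 6),
        n_b=st.integers(2, 6),
    )
    def test_exact_mode_equals_full_permutation_oracle(self, seed, n_a, n_b):
        rng = np.random.default_rng(seed)
        vals = rng.choice(1000, size=n_a + n_b, replace=False).tolist()
        a, b = vals[:n_a], vals[n_a:]
        res = wilcoxon_rank_sum(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(wilcoxon_p_oracle(a, b))

    def test_large_or_tied_samples_use_corrected_approximation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=46).tolist()
        b = rng.normal(size=15).tolist()
        res = wilcoxon_rank_sum(a, b)
        assert res.method == "asymptotic_tie_corrected"
        assert 0.0 <= res.p_value <= 1.0
        tied = wilcoxon_rank_sum([1, 2, 2, 3], [2, 4, 5])
        assert tied.method == "asymptotic_tie_corrected"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1, 2])


class TestFisher:
    def test_symmetric_table(self):
        res = fisher_exact([[1, 1], [1, 1]])
        assert res.p_value == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        a=st.integers(0, 15),
        b=st.integers(0, 15),
        c=st.integers(0, 15),
        d=st.integers(0, 15),
    )
    def test_p_matches_margin_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        table = [[a, b], [c, d]]
        assert fisher_exact(table).p_value == pytest.approx(fisher_p_oracle(table))

    def test_large_margin_tables_match_oracle(self):
        for table in ([[19, 27], [0, 11]], [[10, 36], [5, 10]], [[30, 0], [2, 28]]):
            assert fisher_exact(table).p_value == pytest.approx(fisher_p_oracle(table))

    @pytest.mark.parametrize(
        "table, p, orr, lo, hi",
        [
            # frozen from R fisher.test
            ([[3, 7], [5, 2]], 0.1534348005, 0.19278486, 0.01161206, 2.03340444),
            ([[2, 9], [6, 4]], 0.0804953560, 0.16427288, 0.01127133, 1.44706753),
            ([[12, 2], [3, 9]], 0.0043141742, 15.44495703, 1.89994381, 224.29099794),
        ],
    )
    def test_conditional_mle_and_exact_ci_match_r(self, table, p, orr, lo, hi):
        res = fisher_exact(table)
        assert res.p_value == pytest.approx(p, rel=1e-6)
        assert res.odds_ratio == pytest.approx(orr, rel=1e-4)
        # R's own CI roots carry ~1e-3 relative error from uniroot
        assert res.ci_low == pytest.approx(lo, rel=2e-2)
        assert res.ci_high == pytest.approx(hi, rel=2e-2)

    def test_zero_cell_boundary_gives_null_or_and_finite_upper(self):
        """A table with no long-intron pseudogenes: conditional MLE 0,
        lower bound 0, finite exact upper bound."""
        res = fisher_exact([[0, 11], [19, 27]])
        assert res.odds_ratio == 0.0
        assert res.ci_low == 0.0
        assert res.ci_high == pytest.approx(0.6628, abs=5e-4)
        assert res.p_value == pytest.approx(0.0103489, abs=1e-6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -2], [3, 4]])


class TestLongIntronTable:
    def _locus(self, lengths_f, lengths_p, n_leaderless_p=0):
        recs = []
        pos = 1
        for i, (ln, func) in enumerate(
            [(x, "F") for x in lengths_f] + [(x, "P") for x in lengths_p]
        ):
            e1 = (pos, pos + 47)
            e2 = (pos + 48 + ln, pos + 48 + ln + 329)
            recs.append(
                trl.GeneSegment(
                    gene_id=f"v{i}", segment_type="V", contig="x", strand="+",
                    exons=[trl.Exon("L1", *e1), trl.Exon("V_EXON", *e2)],
                    functionality=func,
                )
            )
            pos = e2[1] + 500
        for j in range(n_leaderless_p):
            recs.append(
                trl.GeneSegment(
                    gene_id=f"nl{j}", segment_type="V", contig="x", strand="+",
                    exons=[trl.Exon("V_EXON", pos, pos + 329)], functionality="P",
                )
            )
            pos += 1000
        return trl.LocusAnnotation("x", recs)

    def test_planted_counts_recovered(self):
        ann = self._locus([800] * 10 + [200] * 36, [300] * 15)
        t = long_intron_table(ann)
        assert t.counts == ((10, 36), (0, 15))

    def test_all_short_introns(self):
        t = long_intron_table(self._locus([100, 200], [300]))
        assert t.counts == ((0, 2), (0, 1))

    def test_threshold_boundary_and_zero(self):
        ann = self._locus([650, 651], [])
        assert long_intron_table(ann).counts == ((1, 1), (0, 0))
        t0 = long_intron_table(ann, StatsConfig(long_intron_threshold=1))
        assert t0.counts == ((2, 0), (0, 0))

    def test_genes_without_intron_excluded(self):
        ann = self._locus([700], [200], n_leaderless_p=4)
        t = long_intron_table(ann)
        assert t.as_array().sum() == 2
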