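"""Locus-level statistics on the published axolotl inventories.

The packaged fixtures encode the published TRA-TRD and TRB gene
inventories; the statistics layer reproduces the printed percentages,
F/P ratios, locus spans and the long-intron Fisher analysis.
"""

import trlocus as trl
from trlocus.stats import fisher_exact, locus_span, summarize_locus
from trlocus.synthetic import table_fixture

for locus in ("TRA", "TRB"):
    print(f"--- {locus} inventory ---")
    print(summarize_locus(table_fixture(locus)).table.to_string())

print(f"\nTRA-TRD locus span: {locus_span(264.6, 285.3, 'Mbp'):.1f} Mbp "
      "(chr13p 264.6-285.3)")
print(f"TRB locus span:     {locus_span(30.03, 34.85, 'Mbp'):.2f} Mbp "
      "(chr3p 30.03-34.85)")

# Long V-introns (>650 bp) vs functionality in TRAV: 46 functional genes
# (19 with long introns) against 11 pseudogenes with measurable introns
# (none long). Rows: pseudogene, functional; columns: long, short.
res = fisher_exact([[0, 11], [19, 27]])
print(f"\nTRAV long-intron Fisher: p={res.p_value:.5f}, "
      f"OR={res.odds_ratio}, 95% CI ({res.ci_low:.1f}, {res.ci_high:.2f})")
print("-> long introns are significantly depleted among pseudogenes")
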