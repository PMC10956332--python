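#!/usr/bin/env python
"""C-value (haploid genome size) order statistics.

Averages duplicate database-style entries per species, converts the
focal order's mean to Mbp (1 pg = 978 Mbp), checks normality with
Shapiro-Wilk, compares the focal order (Flatfish) against every other
order with Mann-Whitney, and reports global 5th/10th/90th percentile
cutoffs with each order's share of the small-genome tail.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import RESULTS, SYNTH

from genarch import annotation_io as aio
from genarch import comparative_stats as cs

FOCAL = "Flatfish"


def main() -> None:
    records = aio.read_cvalue_table(SYNTH / "cvalues.tsv")
    means = cs.species_mean_cvalues(records)
    print(f"{len(records)} database rows -> {len(means)} species")

    pooled = [r.c_value_pg for r in means]
    non_normal = cs.normality_gate(pooled)
    print(f"Shapiro-Wilk gate on pooled species means: "
          f"{'non-normal -> Mann-Whitney' if non_normal else 'normal'}")

    comps = cs.compare_focal_order(means, FOCAL, test="mannwhitney")
    rows = []
    for c in comps:
        rows.append({"focal_order": c.focal_order, "other_order": c.other_order,
                     "focal_mean_pg": round(c.focal_mean_pg, 4),
                     "other_mean_pg": round(c.other_mean_pg, 4),
                     "u": c.test.u_statistic, "p_value": f"{c.test.p_value:.3g}",
                     "method": c.test.method, "significance": c.significance_label})
        direction = "smaller" if c.other_mean_pg < c.focal_mean_pg else "larger"
        print(f"{FOCAL} ({c.focal_mean_pg:.3f} pg, "
              f"{cs.pg_to_mbp(c.focal_mean_pg):.0f} Mbp) vs {c.other_order} "
              f"({c.other_mean_pg:.3f} pg, {direction}): "
              f"p = {c.test.p_value:.3g} {c.significance_label}")
    aio.write_tsv(rows, RESULTS / "cvalue_order_comparisons.tsv")

    report = cs.order_percentile_report(means, qs=(0.05, 0.10, 0.90),
                                        within_order=FOCAL)
    for q, cut in sorted(report.cutoffs.items()):
        print(f"global {q * 100:.0f}th percentile cutoff: {cut:.3f} pg")
    print(f"{FOCAL} within-order percentiles: "
          + ", ".join(f"p{q * 100:.0f}={v:.3f} pg"
                      for q, v in sorted(report.within_order.items())))
    aio.write_tsv(report.order_shares, RESULTS / "cvalue_percentile_shares.tsv")


if __name__ == "__main__":
    main()
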