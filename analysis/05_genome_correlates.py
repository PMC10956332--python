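#!/usr/bin/env python
"""Genome-size correlates and the cross-species report.

Joins the per-species outputs — total exon/intron bp from the size
analysis, TE content from the repeat analysis — into one table, then
asks whether genome size tracks TE percentage, total intron size and
total exon size (Spearman), mirroring the standard genome-architecture
correlation panel.  Writes the assembled per-species report with the
correlation footer.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import RESULTS, SPECIES_PANEL

from genarch import annotation_io as aio
from genarch import comparative_stats as cs
from genarch import feature_sizes as fs
from genarch import report as rep
from genarch import repeat_content as rc


def main() -> None:
    sizes_df = aio.read_tsv(RESULTS / "feature_sizes_long.tsv")
    repeats_df = aio.read_tsv(RESULTS / "repeat_content.tsv")
    mobile = repeats_df[repeats_df["class"] == "Mobile"].set_index("species")

    rows = []
    stats = []
    for label, _order, genome_bp, _te, _scale in SPECIES_PANEL:
        grp = sizes_df[sizes_df["species"] == label]

        def arr(feature):
            v = grp.loc[grp["feature"] == feature, "size_bp"].to_numpy("int64")
            return v[v > 0]

        tab = fs.FeatureSizeTable(label, arr("gene"), arr("exon"), arr("intron"),
                                  convention="paper")
        te_pct = float(mobile.loc[label, "pct_genome"])
        summary = rc.RepeatSummary(
            species_label=label, genome_size_bp=genome_bp, per_class={},
            total_masked_bp=0, total_pct_genome=0.0, mobile_masked_bp=0,
            mobile_pct_genome=te_pct, overlap_mode="raw", max_divergence=20.0,
            n_hits_used=0, n_hits_excluded_divergence=0)
        rows.append(rep.species_report_row(tab, summary, genome_bp))
        stats.append(cs.SpeciesGenomeStats(label, genome_bp, te_pct,
                                           tab.total_intron_bp, tab.total_exon_bp))

    table, footer = rep.assemble_report(rows)
    aio.atomic_write_text(RESULTS / "species_report.tsv",
                          rep.report_to_tsv_text(table, footer))

    results = cs.genome_correlates(stats)
    out_rows = []
    for key, res in results.items():
        out_rows.append({"pair": f"genome_size~{key}", "rho": round(res.rho, 3),
                         "p_value": f"{res.p_value:.3g}", "n": res.n})
        print(f"genome size ~ {key}: Spearman rho = {res.rho:.3f} "
              f"(p = {res.p_value:.3g}, n = {res.n})")
    aio.write_tsv(out_rows, RESULTS / "genome_correlates.tsv")
    print(f"report: {len(rows)} species -> {RESULTS / 'species_report.tsv'}")


if __name__ == "__main__":
    main()
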