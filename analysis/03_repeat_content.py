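#!/usr/bin/env python
"""Repeat-element content across the synthetic panel.

Reads each species' RepeatMasker-style table, applies the 20%
divergence cutoff, and tallies masked bp per class both as percent of
genome and percent of repeat content (the two panels of the standard
cross-species repeat figure).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import RESULTS, SPECIES_PANEL, SYNTH

from genarch import annotation_io as aio
from genarch import repeat_content as rc


def main() -> None:
    rows = []
    for label, _order, genome_bp, target_te, _scale in SPECIES_PANEL:
        hits = aio.read_repeatmasker_out(SYNTH / label / "repeats.out")
        summary = rc.repeat_summary(hits, genome_bp, species_label=label,
                                    overlap_mode="raw", max_divergence=20.0)
        for cls in rc.REPEAT_CLASSES:
            c = summary.per_class[cls]
            rows.append({"species": label, "genome_size_bp": genome_bp,
                         "class": cls, "masked_bp": c.masked_bp,
                         "pct_genome": round(c.pct_genome, 3),
                         "pct_of_repeats": round(c.pct_of_repeats, 3)})
        rows.append({"species": label, "genome_size_bp": genome_bp,
                     "class": "Mobile", "masked_bp": summary.mobile_masked_bp,
                     "pct_genome": round(summary.mobile_pct_genome, 3),
                     "pct_of_repeats": None})
        rows.append({"species": label, "genome_size_bp": genome_bp,
                     "class": "Total", "masked_bp": summary.total_masked_bp,
                     "pct_genome": round(summary.total_pct_genome, 3),
                     "pct_of_repeats": None})
        print(f"{label}: TE {summary.mobile_pct_genome:.1f}% of genome "
              f"(target before divergence filter {target_te:.1f}%), "
              f"{summary.n_hits_excluded_divergence} hits > 20% diverged excluded")
    aio.write_tsv(rows, RESULTS / "repeat_content.tsv")


if __name__ == "__main__":
    main()
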