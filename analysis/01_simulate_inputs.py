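#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes, per species in the panel: a GFF3 annotation with log-normal
exon/intron sizes and a RepeatMasker-style .out table hitting that
species' target repeat content; plus one C-value table covering five
orders with known means.  Everything is seeded, so re-running
reproduces the same bytes.
"""

import math
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import (CVALUE_ORDERS, EXON_MU, EXON_SIGMA, INTRON_SIGMA,
                          N_GENES, SEED, SPECIES_PANEL, SYNTH)

from genarch import synthetic_data as sd


def main() -> None:
    for i, (label, _order, genome_bp, te_pct, intron_scale) in enumerate(SPECIES_PANEL):
        out = SYNTH / label
        out.mkdir(parents=True, exist_ok=True)
        ann = sd.AnnotationSpec(
            n_genes=N_GENES,
            exon_size_mu=EXON_MU, exon_size_sigma=EXON_SIGMA,
            intron_size_mu=math.log(intron_scale), intron_size_sigma=INTRON_SIGMA,
            seed=SEED + i,
        )
        _, truth = sd.gen_annotation(ann, out / "annotation.gff3")
        reps = sd.RepeatSpec(
            genome_size_bp=genome_bp,
            target_pct={"DNA": te_pct * 0.4, "LINE": te_pct * 0.3,
                        "SINE": te_pct * 0.1, "LTR": te_pct * 0.2,
                        "Other": 4.0},
            mean_hit_len=300,
            seed=SEED + 100 + i,
        )
        sd.gen_repeatmasker(reps, out / "repeats.out")
        print(f"{label}: {truth.n_genes} genes, {truth.n_introns} introns, "
              f"genome {genome_bp/1e3:.0f} kb, target TE {te_pct:.1f}%")

    cval = sd.CValueSpec(
        orders=[sd.OrderSpec(name, n, mean, sdev) for name, n, mean, sdev in CVALUE_ORDERS],
        duplicates_per_species=2,
        seed=SEED + 500,
    )
    _, truth = sd.gen_cvalues(cval, SYNTH / "cvalues.tsv")
    means = ", ".join(f"{o}={m:.3f}" for o, m in truth.order_means.items())
    print(f"C-value table: {sum(o[1] for o in CVALUE_ORDERS)} species; "
          f"order means (pg): {means}")


if __name__ == "__main__":
    main()
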