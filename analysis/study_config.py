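"""Shared study conditions for the analysis scripts.

A desk-scale synthetic panel of 9 "species" across 3 orders.  Genome
size varies ~6x across the panel, and both transposable-element content
and intron sizes grow with genome size — the architecture signal the
correlation analysis is designed to detect — while exon sizes stay
compact and roughly constant, as they do in real fish genomes.
"""

import math
from pathlib import Path

SEED = 20261001 % 2**31
RESULTS = Path(__file__).resolve().parent.parent / "results"
SYNTH = RESULTS / "synth"

# label, order, genome_size_bp, TE % of genome, intron-size scale (bp)
SPECIES_PANEL = [
    ("Flat_small", "Flatfish", 300_000, 6.0, 300),
    ("Flat_mid", "Flatfish", 420_000, 9.0, 420),
    ("Flat_big", "Flatfish", 560_000, 13.0, 540),
    ("Puffer_tiny", "Puffer", 250_000, 5.0, 250),
    ("Puffer_small", "Puffer", 330_000, 7.5, 330),
    ("Puffer_mid", "Puffer", 450_000, 10.0, 430),
    ("Carp_big", "Carp", 900_000, 22.0, 800),
    ("Carp_bigger", "Carp", 1_200_000, 28.0, 1000),
    ("Carp_huge", "Carp", 1_500_000, 34.0, 1200),
]

N_GENES = 250
EXON_MU = math.log(130.0)
EXON_SIGMA = 0.5
INTRON_SIGMA = 1.1

# C-value panel: order, n_species, mean pg, sd pg (flatfish small,
# puffers smallest, carps large — the qualitative ordering seen in fish)
CVALUE_ORDERS = [
    ("Flatfish", 16, 0.73, 0.10),
    ("Puffer", 12, 0.62, 0.08),
    ("Carp", 14, 1.70, 0.35),
    ("Salmonid", 12, 2.90, 0.50),
    ("Cichlid", 14, 1.00, 0.15),
]
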