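"""Cross-species report assembly.

Joins per-species feature-size tables and repeat summaries into one
comparison table (one row per species: gene counts, size medians/IQRs,
tail quantiles, repeat content, totals), with genome-size correlations
appended as a footer when enough species carry both size and repeat
columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import MISSING
from .comparative_stats import SpeciesGenomeStats, genome_correlates
from .distribution_stats import quantile
from .feature_sizes import FeatureSizeTable
from .repeat_content import RepeatSummary

__all__ = ["SpeciesReportRow", "species_report_row", "assemble_report"]

REPORT_COLUMNS = [
    "species", "genome_size_bp", "gene_count",
    "gene_median", "gene_iqr",
    "exon_median", "exon_iqr", "exon_q01", "exon_q80", "exon_q99",
    "intron_median", "intron_iqr", "intron_q01", "intron_q80", "intron_q99",
    "te_pct", "total_exon_bp", "total_intron_bp",
]


@dataclass
class SpeciesReportRow:
    species: str
    genome_size_bp: int | None
    gene_count: int
    gene_median: float | None
    gene_iqr: float | None
    exon_median: float | None
    exon_iqr: float | None
    exon_q01: float | None
    exon_q80: float | None
    exon_q99: float | None
    intron_median: float | None
    intron_iqr: float | None
    intron_q01: float | None
    intron_q80: float | None
    intron_q99: float | None
    te_pct: float | None
    total_exon_bp: int
    total_intron_bp: int


def _dist_cols(values: np.ndarray, tail_qs: bool) -> list[float | None]:
    if values.size == 0:
        return [None] * (5 if tail_qs else 2)
    med = quantile(values, 0.5)
    iqr = quantile(values, 0.75) - quantile(values, 0.25)
    if not tail_qs:
        return [med, iqr]
    return [med, iqr, quantile(values, 0.01), quantile(values, 0.80),
            quantile(values, 0.99)]


def species_report_row(
    sizes: FeatureSizeTable,
    repeats: RepeatSummary | None = None,
    genome_size_bp: int | None = None,
) -> SpeciesReportRow:
    """One comparison-table row from a species' per-stage outputs.

    ``genome_size_bp`` falls back to the repeat summary's genome size;
    the TE percentage is the mobile-element fraction (DNA + LINE + SINE
    + LTR) of the genome.
    """
    if genome_size_bp is None and repeats is not None:
        genome_size_bp = repeats.genome_size_bp
    g = _dist_cols(sizes.gene_sizes, tail_qs=False)
    e = _dist_cols(sizes.exon_sizes, tail_qs=True)
    i = _dist_cols(sizes.intron_sizes, tail_qs=True)
    return SpeciesReportRow(
        species=sizes.species_label,
        genome_size_bp=genome_size_bp,
        gene_count=sizes.gene_count,
        gene_median=g[0], gene_iqr=g[1],
        exon_median=e[0], exon_iqr=e[1], exon_q01=e[2], exon_q80=e[3], exon_q99=e[4],
        intron_median=i[0], intron_iqr=i[1], intron_q01=i[2], intron_q80=i[3],
        intron_q99=i[4],
        te_pct=repeats.mobile_pct_genome if repeats is not None else None,
        total_exon_bp=sizes.total_exon_bp,
        total_intron_bp=sizes.total_intron_bp,
    )


def assemble_report(
    rows: list[SpeciesReportRow],
) -> tuple[pd.DataFrame, dict | None]:
    """Stack per-species rows; compute the correlation footer if possible.

    Returns the table (missing cells NaN; writers render them as '.')
    and, when >= 3 species have genome size, TE % and both totals, a
    footer dict of the three Spearman results.
    """
    seen: set[str] = set()
    for r in rows:
        if r.species in seen:
            raise ValueError(f"duplicate species_label {r.species!r}")
        seen.add(r.species)
    table = pd.DataFrame([vars(r) for r in rows], columns=REPORT_COLUMNS)

    complete = [
        r for r in rows
        if r.genome_size_bp is not None and r.te_pct is not None
        and r.total_intron_bp is not None and r.total_exon_bp is not None
    ]
    footer = None
    if len(complete) >= 3:
        stats = [
            SpeciesGenomeStats(
                species_label=r.species,
                genome_size_bp=int(r.genome_size_bp),
                te_pct=float(r.te_pct),
                total_intron_bp=int(r.total_intron_bp),
                total_exon_bp=int(r.total_exon_bp),
            )
            for r in complete
        ]
        footer = genome_correlates(stats)
    return table, footer


def render_footer_lines(footer: dict) -> list[str]:
    """Correlation footer as comment lines for the TSV report."""
    lines = []
    for key, res in footer.items():
        lines.append(
            f"# spearman genome_size~{key}: rho={res.rho:.3f} p={res.p_value:.3g} n={res.n}"
        )
    return lines


def report_to_tsv_text(table: pd.DataFrame, footer: dict | None) -> str:
    text = table.to_csv(sep="\t", index=False, na_rep=MISSING)
    if footer:
        text += "\n".join(render_footer_lines(footer)) + "\n"
    return text
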