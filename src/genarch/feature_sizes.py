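"""Gene models from GFF3 records and gene/exon/intron size computation.

Sizes follow one of two conventions, applied consistently:

``paper``
    Literal coordinate differences: a feature spanning (start, end) has
    size ``end - start`` and the intron between consecutive exons has size
    ``next.start - prev.end``.  This is the convention behind the
    published per-species quantile tables.
``biological``
    Standard lengths on 1-based inclusive coordinates: ``end - start + 1``
    for genes/exons and ``next.start - prev.end - 1`` for introns.

The two differ by exactly 1 bp per feature; pick one and say which you
used when comparing numbers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal

import numpy as np

from .annotation_io import GffRecord

__all__ = [
    "Convention",
    "FeatureConfig",
    "TranscriptModel",
    "GeneModel",
    "FeatureSizeTable",
    "BuildStats",
    "build_gene_models",
    "gene_span_size",
    "exon_sizes",
    "intron_sizes",
    "transcript_span_size",
    "feature_size_table",
    "feature_rows",
]

Convention = Literal["paper", "biological"]

CONVENTIONS = ("paper", "biological")


def _check_convention(convention: str) -> None:
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}, got {convention!r}")


@dataclass
class FeatureConfig:
    """Which GFF3 feature types play which role in the gene hierarchy."""

    gene_types: frozenset[str] = frozenset({"gene"})
    transcript_types: frozenset[str] = frozenset({"mRNA", "transcript"})
    part_types: frozenset[str] = frozenset({"exon"})
    part_fallback_types: frozenset[str] = frozenset({"CDS"})


DEFAULT_CONFIG = FeatureConfig()


@dataclass
class TranscriptModel:
    """A transcript with its ordered exon coordinate pairs (1-based incl.)."""

    transcript_id: str
    gene_id: str
    seqid: str
    strand: str
    exons: list[tuple[int, int]]
    has_overlapping_exons: bool = False

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: needs >= 1 exon")
        self.exons = sorted(self.exons)
        for k in range(1, len(self.exons)):
            if self.exons[k][0] <= self.exons[k - 1][1]:
                self.has_overlapping_exons = True
                break


@dataclass
class GeneModel:
    """A gene locus: its own span plus one or more transcript models."""

    gene_id: str
    seqid: str
    start: int
    end: int
    strand: str
    transcripts: list[TranscriptModel]


@dataclass
class BuildStats:
    """QC counters accumulated while assembling gene models."""

    orphan_transcripts: int = 0
    orphan_parts: int = 0
    genes_without_transcripts: int = 0
    transcripts_without_parts: int = 0
    transcripts_with_overlapping_exons: int = 0


@dataclass
class FeatureSizeTable:
    """Pooled per-species size arrays plus totals and drop counters."""

    species_label: str
    gene_sizes: np.ndarray
    exon_sizes: np.ndarray
    intron_sizes: np.ndarray
    convention: str
    dropped_nonpositive: Counter = field(default_factory=Counter)

    @property
    def gene_count(self) -> int:
        return int(self.gene_sizes.size)

    @property
    def total_exon_bp(self) -> int:
        return int(self.exon_sizes.sum()) if self.exon_sizes.size else 0

    @property
    def total_intron_bp(self) -> int:
        return int(self.intron_sizes.sum()) if self.intron_sizes.size else 0


# ---------------------------------------------------------------------------
# model assembly

def build_gene_models(
    records: Iterable[GffRecord],
    config: FeatureConfig = DEFAULT_CONFIG,
) -> tuple[list[GeneModel], BuildStats]:
    """Assemble gene -> transcript -> exon hierarchies from parsed records.

    Exons with multiple ``Parent`` values contribute to every parent
    transcript.  Transcripts whose parent gene is absent become
    single-transcript genes with a synthesized gene id.  Transcripts with
    no exon children fall back to their CDS children; with neither they
    are dropped and counted.  Genes left with zero usable transcripts are
    dropped and counted.
    """
    stats = BuildStats()
    gene_recs: dict[str, GffRecord] = {}
    tx_recs: dict[str, GffRecord] = {}
    tx_parent: dict[str, list[str]] = {}
    parts: dict[str, list[tuple[int, int]]] = {}
    fallback_parts: dict[str, list[tuple[int, int]]] = {}
    tx_order: list[str] = []

    for rec in records:
        if rec.feature_type in config.gene_types:
            for gid in rec.ids or [f"{rec.seqid}:{rec.start}-{rec.end}"]:
                gene_recs[gid] = rec
        elif rec.feature_type in config.transcript_types:
            for tid in rec.ids or [f"tx:{rec.seqid}:{rec.start}-{rec.end}"]:
                if tid not in tx_recs:
                    tx_order.append(tid)
                tx_recs[tid] = rec
                tx_parent[tid] = rec.parents
        elif rec.feature_type in config.part_types:
            for pid in rec.parents:
                parts.setdefault(pid, []).append((rec.start, rec.end))
        elif rec.feature_type in config.part_fallback_types:
            for pid in rec.parents:
                fallback_parts.setdefault(pid, []).append((rec.start, rec.end))

    # parts pointing at unknown transcripts
    known = set(tx_recs)
    for pid, plist in list(parts.items()) + list(fallback_parts.items()):
        if pid not in known:
            stats.orphan_parts += len(plist)

    by_gene: dict[str, list[TranscriptModel]] = {g: [] for g in gene_recs}
    synthesized: dict[str, GffRecord] = {}

    for tid in tx_order:
        rec = tx_recs[tid]
        exons = parts.get(tid)
        if not exons:
            exons = fallback_parts.get(tid)
            if not exons:
                stats.transcripts_without_parts += 1
                continue
        parent_genes = [p for p in tx_parent[tid] if p in gene_recs]
        if not parent_genes:
            stats.orphan_transcripts += 1
            gid = f"gene:{tid}"
            synthesized[gid] = rec
            by_gene.setdefault(gid, [])
            parent_genes = [gid]
        for gid in parent_genes:
            tm = TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                seqid=rec.seqid,
                strand=rec.strand,
                exons=list(exons),
            )
            if tm.has_overlapping_exons:
                stats.transcripts_with_overlapping_exons += 1
            by_gene[gid].append(tm)

    genes: list[GeneModel] = []
    for gid, txs in by_gene.items():
        if not txs:
            stats.genes_without_transcripts += 1
            continue
        rec = gene_recs.get(gid, synthesized.get(gid))
        genes.append(
            GeneModel(
                gene_id=gid,
                seqid=rec.seqid,
                start=rec.start,
                end=rec.end,
                strand=rec.strand,
                transcripts=txs,
            )
        )
    return genes, stats


# ---------------------------------------------------------------------------
# size formulas

def gene_span_size(gene: GeneModel, convention: Convention = "paper") -> int:
    """Size of the genomic locus from the gene record's own coordinates."""
    _check_convention(convention)
    size = gene.end - gene.start
    return size + 1 if convention == "biological" else size


def exon_sizes(transcript: TranscriptModel, convention: Convention = "paper") -> list[int]:
    """Per-exon sizes in exon order (ascending start, strand-symmetric)."""
    _check_convention(convention)
    off = 1 if convention == "biological" else 0
    return [e - s + off for s, e in transcript.exons]


def intron_sizes(transcript: TranscriptModel, convention: Convention = "paper") -> list[int]:
    """Sizes of the k-1 gaps between the k sorted exons.

    Under the paper convention an intron is ``next.start - prev.end``;
    biological subtracts one more.  Overlapping or book-ended exons yield
    non-positive values here; pooling into a table drops and counts them.
    """
    _check_convention(convention)
    off = 1 if convention == "biological" else 0
    ex = transcript.exons
    return [ex[k][0] - ex[k - 1][1] - off for k in range(1, len(ex))]


def transcript_span_size(transcript: TranscriptModel, convention: Convention = "paper") -> int:
    """Span of the transcript's exon extent (first exon start to last end)."""
    _check_convention(convention)
    span = transcript.exons[-1][1] - transcript.exons[0][0]
    return span + 1 if convention == "biological" else span


# ---------------------------------------------------------------------------
# pooling

def feature_size_table(
    genes: Iterable[GeneModel],
    species_label: str,
    convention: Convention = "paper",
) -> FeatureSizeTable:
    """Pool gene, exon and intron sizes across all transcripts of all genes.

    Every transcript contributes (no canonical-transcript selection), so
    exons shared between isoforms are counted once per isoform.
    Non-positive sizes under the chosen convention are excluded from the
    arrays and tallied in ``dropped_nonpositive``.
    """
    _check_convention(convention)
    dropped: Counter = Counter()
    g_sizes: list[int] = []
    e_sizes: list[int] = []
    i_sizes: list[int] = []
    for gene in genes:
        gs = gene_span_size(gene, convention)
        if gs > 0:
            g_sizes.append(gs)
        else:
            dropped["gene"] += 1
        for tx in gene.transcripts:
            for s in exon_sizes(tx, convention):
                if s > 0:
                    e_sizes.append(s)
                else:
                    dropped["exon"] += 1
            for s in intron_sizes(tx, convention):
                if s > 0:
                    i_sizes.append(s)
                else:
                    dropped["intron"] += 1
    return FeatureSizeTable(
        species_label=species_label,
        gene_sizes=np.asarray(g_sizes, dtype=np.int64),
        exon_sizes=np.asarray(e_sizes, dtype=np.int64),
        intron_sizes=np.asarray(i_sizes, dtype=np.int64),
        convention=convention,
        dropped_nonpositive=dropped,
    )


def feature_rows(
    genes: Iterable[GeneModel],
    species_label: str,
    convention: Convention = "paper",
) -> Iterator[dict]:
    """Long-format rows (one per feature) for the TSV export.

    Columns: species, gene_id, transcript_id, feature, ordinal, size_bp,
    convention.  Non-positive sizes are emitted too (QC filtering is the
    pooling step's job); ordinals are 1-based within their parent.
    """
    _check_convention(convention)
    for gene in genes:
        yield {
            "species": species_label,
            "gene_id": gene.gene_id,
            "transcript_id": MISSING_TX,
            "feature": "gene",
            "ordinal": 1,
            "size_bp": gene_span_size(gene, convention),
            "convention": convention,
        }
        for tx in gene.transcripts:
            for k, s in enumerate(exon_sizes(tx, convention), 1):
                yield {
                    "species": species_label,
                    "gene_id": gene.gene_id,
                    "transcript_id": tx.transcript_id,
                    "feature": "exon",
                    "ordinal": k,
                    "size_bp": s,
                    "convention": convention,
                }
            for k, s in enumerate(intron_sizes(tx, convention), 1):
                yield {
                    "species": species_label,
                    "gene_id": gene.gene_id,
                    "transcript_id": tx.transcript_id,
                    "feature": "intron",
                    "ordinal": k,
                    "size_bp": s,
                    "convention": convention,
                }


MISSING_TX = "."
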