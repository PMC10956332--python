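"""Ground-truthed synthetic inputs for every pipeline stage.

Generates GFF3 annotations (gene -> mRNA -> exon hierarchies with
log-normal exon/intron sizes), RepeatMasker ``.out`` tables with known
per-class masked content, and C-value tables with known order means —
so parsing, size inference, repeat summaries and the order-comparison
statistics can all be tested against known generating parameters
without any external downloads.

Size distributions are log-normal: empirical exon/intron size
distributions are unimodal and right-skewed on a log axis, with exons
compact (median near 130 bp) and introns heavy-tailed.  The defaults
here are stylized study conditions, not fits to any particular genome.

One global integer seed drives each generator through a fixed per-file
offset, so adding a generator never perturbs existing outputs, and the
same seed always yields byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation_io as aio
from .annotation_io import CValueRecord, GffRecord, RepeatHit
from .repeat_content import REPEAT_CLASSES

__all__ = [
    "AnnotationSpec",
    "RepeatSpec",
    "OrderSpec",
    "CValueSpec",
    "AnnotationTruth",
    "RepeatTruth",
    "CValueTruth",
    "gen_annotation",
    "gen_repeatmasker",
    "gen_cvalues",
]

# fixed per-generator seed offsets (kept below 2**31 after adding a seed)
_SEED_ANNOTATION = 101
_SEED_REPEATS = 211
_SEED_CVALUES = 307
_SEED_MOD = 2**31


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng((int(seed) + offset) % _SEED_MOD)


# ---------------------------------------------------------------------------
# annotations


@dataclass
class AnnotationSpec:
    """Parameters of a synthetic genome annotation.

    Exon/intron/intergenic sizes are log-normal on the natural log of bp;
    draws are ceiled to integers >= 1 (sizes are biological lengths,
    i.e. end - start + 1).  Exon counts per gene are uniform integers in
    ``exon_count_range`` (inclusive); a fixed count is (k, k).
    """

    n_genes: int = 1000
    exon_count_range: tuple[int, int] = (2, 8)
    exon_size_mu: float = math.log(130.0)
    exon_size_sigma: float = 0.5
    intron_size_mu: float = math.log(500.0)
    intron_size_sigma: float = 1.2
    intergenic_mu: float = math.log(2000.0)
    intergenic_sigma: float = 0.8
    n_seqids: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.exon_count_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid exon_count_range {self.exon_count_range}")
        for name in ("exon_size_sigma", "intron_size_sigma", "intergenic_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_seqids < 1:
            raise ValueError("n_seqids must be >= 1")


@dataclass
class AnnotationTruth:
    """Sizes actually drawn, in generation order (biological lengths)."""

    gene_sizes: np.ndarray
    exon_sizes: np.ndarray
    intron_sizes: np.ndarray
    n_genes: int
    n_exons: int
    n_introns: int

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [("gene", s) for s in self.gene_sizes]
            + [("exon", s) for s in self.exon_sizes]
            + [("intron", s) for s in self.intron_sizes]
        )
        return pd.DataFrame(rows, columns=["feature", "size_bp"])


def _draw_sizes(rng: np.random.Generator, mu: float, sigma: float, n: int) -> np.ndarray:
    raw = rng.lognormal(mean=mu, sigma=sigma, size=n)
    return np.maximum(1, np.ceil(raw)).astype(np.int64)


def gen_annotation(
    spec: AnnotationSpec,
    gff_path: str | Path | None = None,
) -> tuple[list[GffRecord], AnnotationTruth]:
    """Generate a synthetic annotation and its ground truth.

    Genes are laid down left to right on each seqid (split into
    contiguous blocks across ``n_seqids``), separated by log-normal
    intergenic gaps, so coordinates never overlap.  The GFF3 is written
    when ``gff_path`` is given; records are returned either way.
    """
    spec.validate()
    rng = _rng(spec.seed, _SEED_ANNOTATION)
    lo, hi = spec.exon_count_range

    records: list[GffRecord] = []
    gene_sizes: list[int] = []
    all_exon_sizes: list[int] = []
    all_intron_sizes: list[int] = []

    per_seqid = int(math.ceil(spec.n_genes / spec.n_seqids))
    gene_no = 0
    for si in range(spec.n_seqids):
        seqid = f"chr{si + 1}"
        cursor = 0  # last used coordinate on this seqid
        n_here = min(per_seqid, spec.n_genes - gene_no)
        for _ in range(n_here):
            gene_no += 1
            k = int(rng.integers(lo, hi + 1))
            exon_lens = _draw_sizes(rng, spec.exon_size_mu, spec.exon_size_sigma, k)
            intron_lens = _draw_sizes(
                rng, spec.intron_size_mu, spec.intron_size_sigma, k - 1
            )
            gap = int(
                max(1, math.ceil(rng.lognormal(spec.intergenic_mu, spec.intergenic_sigma)))
            )
            strand = "+" if rng.random() < 0.5 else "-"

            start = cursor + gap + 1
            exons: list[tuple[int, int]] = []
            pos = start
            for j in range(k):
                e_end = pos + int(exon_lens[j]) - 1
                exons.append((pos, e_end))
                if j < k - 1:
                    pos = e_end + int(intron_lens[j]) + 1
            end = exons[-1][1]
            cursor = end

            gid = f"gene{gene_no:06d}"
            tid = f"transcript{gene_no:06d}"
            records.append(
                GffRecord(seqid, "genarch_synth", "gene", start, end, ".", strand,
                          ".", {"ID": [gid]})
            )
            records.append(
                GffRecord(seqid, "genarch_synth", "mRNA", start, end, ".", strand,
                          ".", {"ID": [tid], "Parent": [gid]})
            )
            for j, (es, ee) in enumerate(exons, 1):
                records.append(
                    GffRecord(seqid, "genarch_synth", "exon", es, ee, ".", strand,
                              ".", {"ID": [f"{tid}.exon{j}"], "Parent": [tid]})
                )
            gene_sizes.append(end - start + 1)
            all_exon_sizes.extend(int(v) for v in exon_lens)
            all_intron_sizes.extend(int(v) for v in intron_lens)

    truth = AnnotationTruth(
        gene_sizes=np.asarray(gene_sizes, dtype=np.int64),
        exon_sizes=np.asarray(all_exon_sizes, dtype=np.int64),
        intron_sizes=np.asarray(all_intron_sizes, dtype=np.int64),
        n_genes=spec.n_genes,
        n_exons=len(all_exon_sizes),
        n_introns=len(all_intron_sizes),
    )
    if gff_path is not None:
        aio.write_gff3(records, gff_path)
    return records, truth


# ---------------------------------------------------------------------------
# repeats


@dataclass
class RepeatSpec:
    """Target per-class repeat content for a synthetic genome."""

    genome_size_bp: int = 100_000
    target_pct: dict[str, float] = field(
        default_factory=lambda: {"DNA": 10.0, "LINE": 5.0, "SINE": 3.0,
                                 "LTR": 4.0, "Other": 8.0}
    )
    mean_hit_len: int = 300
    seed: int = 0

    def validate(self) -> None:
        if self.genome_size_bp < 1:
            raise ValueError("genome_size_bp must be >= 1")
        if self.mean_hit_len < 1:
            raise ValueError("mean_hit_len must be >= 1")
        bad = set(self.target_pct) - set(REPEAT_CLASSES)
        if bad:
            raise ValueError(f"unknown repeat classes in target_pct: {sorted(bad)}")
        if any(p < 0 for p in self.target_pct.values()):
            raise ValueError("target percentages must be >= 0")
        if sum(self.target_pct.values()) > 80:
            raise ValueError("total target repeat content must be <= 80% of genome")


@dataclass
class RepeatTruth:
    masked_bp: dict[str, int]  # per class, all hits
    masked_bp_div20: dict[str, int]  # per class, hits with divergence <= 20


_CLASS_FAMILY = {
    "DNA": ("hAT-1", "DNA/hAT"),
    "LINE": ("L1-1", "LINE/L1"),
    "SINE": ("Alu-like", "SINE/tRNA"),
    "LTR": ("Gypsy-1", "LTR/Gypsy"),
    "Other": ("(TA)n", "Simple_repeat"),
}


def gen_repeatmasker(
    spec: RepeatSpec,
    out_path: str | Path | None = None,
) -> tuple[list[RepeatHit], RepeatTruth]:
    """Generate non-overlapping repeat hits meeting per-class bp targets.

    Hits for each class are placed sequentially along one query sequence
    with small random gaps, until the class's masked bp is within one
    ``mean_hit_len`` of its target.  Divergence values are uniform on
    (0, 25) so a 20% divergence filter removes a known subset; the truth
    records per-class masked bp before and after that filter.
    """
    spec.validate()
    rng = _rng(spec.seed, _SEED_REPEATS)
    hits: list[RepeatHit] = []
    masked: dict[str, int] = {c: 0 for c in REPEAT_CLASSES}
    masked20: dict[str, int] = {c: 0 for c in REPEAT_CLASSES}
    cursor = 0
    lo_len = max(1, spec.mean_hit_len // 2)
    hi_len = spec.mean_hit_len + spec.mean_hit_len // 2

    for cls in REPEAT_CLASSES:
        pct = float(spec.target_pct.get(cls, 0.0))
        target = int(round(pct / 100.0 * spec.genome_size_bp))
        while masked[cls] < target:
            length = int(rng.integers(lo_len, hi_len + 1))
            if masked[cls] + length > target + spec.mean_hit_len:
                length = max(1, target - masked[cls])
            gap = int(rng.integers(1, 21))
            start = cursor + gap + 1
            end = start + length - 1
            if end > spec.genome_size_bp:
                raise ValueError(
                    f"repeat targets unreachable: ran past genome end at class {cls}"
                )
            div = float(np.round(rng.uniform(0.0, 25.0), 1))
            name, family = _CLASS_FAMILY[cls]
            hits.append(
                RepeatHit(
                    query_seq="chr1",
                    query_start=start,
                    query_end=end,
                    repeat_name=name,
                    repeat_class=family,
                    divergence_pct=div,
                )
            )
            masked[cls] += length
            if div <= 20.0:
                masked20[cls] += length
            cursor = end

    truth = RepeatTruth(masked_bp=masked, masked_bp_div20=masked20)
    if out_path is not None:
        aio.write_repeatmasker_out(hits, out_path)
    return hits, truth


# ---------------------------------------------------------------------------
# C-values


@dataclass
class OrderSpec:
    name: str
    n_species: int
    mean_pg: float
    sd_pg: float
    distribution: str = "lognormal"  # or "normal"

    def validate(self) -> None:
        if self.mean_pg <= 0:
            raise ValueError(f"order {self.name}: mean_pg must be > 0")
        if self.sd_pg < 0:
            raise ValueError(f"order {self.name}: sd_pg must be >= 0")
        if self.n_species < 2:
            raise ValueError(f"order {self.name}: need >= 2 species")
        if self.distribution not in ("lognormal", "normal"):
            raise ValueError(f"order {self.name}: unknown distribution {self.distribution!r}")


@dataclass
class CValueSpec:
    """Synthetic genome-size-database export: orders with known means."""

    orders: list[OrderSpec] = field(default_factory=list)
    duplicates_per_species: int = 1
    jitter_rel_sd: float = 0.01  # relative sd of duplicate-entry jitter
    seed: int = 0

    def validate(self) -> None:
        if not self.orders:
            raise ValueError("need at least one order")
        if self.duplicates_per_species < 1:
            raise ValueError("duplicates_per_species must be >= 1")
        for o in self.orders:
            o.validate()


@dataclass
class CValueTruth:
    species_values: dict[str, float]  # drawn per-species true C-value
    order_means: dict[str, float]  # mean of species values per order


def _draw_species_value(rng: np.random.Generator, order: OrderSpec) -> float:
    if order.sd_pg == 0:
        return float(order.mean_pg)
    if order.distribution == "normal":
        while True:
            v = float(rng.normal(order.mean_pg, order.sd_pg))
            if v > 0:
                return v
    # log-normal parameterized to the requested arithmetic mean and sd
    s2 = math.log1p((order.sd_pg / order.mean_pg) ** 2)
    mu = math.log(order.mean_pg) - s2 / 2.0
    return float(rng.lognormal(mean=mu, sigma=math.sqrt(s2)))


def gen_cvalues(
    spec: CValueSpec,
    out_path: str | Path | None = None,
) -> tuple[list[CValueRecord], CValueTruth]:
    """Generate a C-value table with duplicate database-style entries.

    Each species draws one true value from its order's distribution;
    duplicate rows jitter around it with the jitter mean-centred across
    the duplicates, so the species' duplicate average equals its true
    value exactly (and sd_pg = 0 makes species means equal the order
    mean exactly).
    """
    spec.validate()
    rng = _rng(spec.seed, _SEED_CVALUES)
    records: list[CValueRecord] = []
    species_values: dict[str, float] = {}
    order_means: dict[str, float] = {}

    for order in spec.orders:
        vals = []
        for i in range(order.n_species):
            sp = f"{order.name}_sp{i + 1:03d}"
            v = _draw_species_value(rng, order)
            species_values[sp] = v
            vals.append(v)
            d = spec.duplicates_per_species
            if d == 1:
                entry_vals = np.array([v])
            else:
                jit = rng.normal(0.0, spec.jitter_rel_sd * v, size=d)
                jit -= jit.mean()  # duplicate average == species value
                entry_vals = np.maximum(v + jit, 1e-6)
            for ev in entry_vals:
                records.append(
                    CValueRecord(
                        species=sp,
                        order=order.name,
                        family=f"{order.name}idae",
                        c_value_pg=float(ev),
                    )
                )
        order_means[order.name] = float(np.mean(vals))

    truth = CValueTruth(species_values=species_values, order_means=order_means)
    if out_path is not None:
        aio.write_cvalue_table(records, out_path)
    return records, truth
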