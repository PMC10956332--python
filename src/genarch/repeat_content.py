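"""Repeat-element content summaries from RepeatMasker hits.

Hits are binned into the five reporting categories used for cross-species
comparison — DNA transposons, LINEs, SINEs, LTR elements, and Other
(simple repeats, low complexity, satellites, unknowns) — and tallied both
as percent of the genome and percent of total repeat content.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .annotation_io import RepeatHit

__all__ = [
    "REPEAT_CLASSES",
    "MOBILE_CLASSES",
    "ClassContent",
    "RepeatSummary",
    "classify_hit",
    "repeat_summary",
    "merged_length",
]

REPEAT_CLASSES = ("DNA", "LINE", "SINE", "LTR", "Other")
# the four mobile (transposable-element) classes, excluding Other
MOBILE_CLASSES = ("DNA", "LINE", "SINE", "LTR")

OverlapMode = Literal["raw", "merged"]


@dataclass
class ClassContent:
    masked_bp: int
    pct_genome: float
    pct_of_repeats: float


@dataclass
class RepeatSummary:
    species_label: str
    genome_size_bp: int
    per_class: dict[str, ClassContent]
    total_masked_bp: int
    total_pct_genome: float
    mobile_masked_bp: int  # DNA + LINE + SINE + LTR combined
    mobile_pct_genome: float
    overlap_mode: str
    max_divergence: float | None
    n_hits_used: int
    n_hits_excluded_divergence: int


def classify_hit(repeat_class: str) -> str:
    """Map a RepeatMasker class/family string to a reporting category.

    Prefix match on the class field before '/': LINE* -> LINE,
    SINE* -> SINE, LTR* -> LTR, DNA*/RC* -> DNA (rolling-circle
    transposons counted with DNA transposons), everything else -> Other.
    Uncertain calls like "DNA?/hAT?" classify by the same prefixes.
    """
    if not repeat_class:
        raise ValueError("empty repeat class string")
    head = repeat_class.split("/", 1)[0]
    for label in ("LINE", "SINE", "LTR", "DNA"):
        if head.startswith(label):
            return label
    if head.startswith("RC"):
        return "DNA"
    return "Other"


def merged_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total bases covered by the union of 1-based inclusive intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    if cur_s is not None:
        total += cur_e - cur_s + 1
    return total


def repeat_summary(
    hits: Iterable[RepeatHit],
    genome_size_bp: int,
    species_label: str = "",
    overlap_mode: OverlapMode = "raw",
    max_divergence: float | None = 20.0,
) -> RepeatSummary:
    """Per-class masked bp and percentage summary.

    ``raw`` mode sums hit lengths as RepeatMasker's own tables do;
    ``merged`` mode takes the union of per-class intervals, which
    guarantees per-class percentages <= 100.  Hits more diverged from
    their consensus than ``max_divergence`` (default 20%, the usual
    cutoff for recent, confidently-assignable repeats) are excluded;
    pass None to keep everything.
    """
    if genome_size_bp <= 0:
        raise ValueError(f"genome_size_bp must be > 0, got {genome_size_bp}")
    if overlap_mode not in ("raw", "merged"):
        raise ValueError(f"overlap_mode must be raw or merged, got {overlap_mode!r}")

    by_class: dict[str, list[RepeatHit]] = {c: [] for c in REPEAT_CLASSES}
    n_used = 0
    n_excluded = 0
    for hit in hits:
        if max_divergence is not None and hit.divergence_pct > max_divergence:
            n_excluded += 1
            continue
        by_class[classify_hit(hit.repeat_class)].append(hit)
        n_used += 1

    masked: dict[str, int] = {}
    for cls, cls_hits in by_class.items():
        if overlap_mode == "raw":
            masked[cls] = sum(h.length_bp for h in cls_hits)
        else:
            masked[cls] = merged_length(
                (h.query_start, h.query_end) for h in cls_hits
            )

    total = sum(masked.values())
    per_class = {
        cls: ClassContent(
            masked_bp=bp,
            pct_genome=100.0 * bp / genome_size_bp,
            pct_of_repeats=(100.0 * bp / total) if total > 0 else 0.0,
        )
        for cls, bp in masked.items()
    }
    mobile_bp = sum(masked[c] for c in MOBILE_CLASSES)
    return RepeatSummary(
        species_label=species_label,
        genome_size_bp=int(genome_size_bp),
        per_class=per_class,
        total_masked_bp=total,
        total_pct_genome=100.0 * total / genome_size_bp,
        mobile_masked_bp=mobile_bp,
        mobile_pct_genome=100.0 * mobile_bp / genome_size_bp,
        overlap_mode=overlap_mode,
        max_divergence=max_divergence,
        n_hits_used=n_used,
        n_hits_excluded_divergence=n_excluded,
    )
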