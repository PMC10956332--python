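"""Cross-species statistics.

Covers the C-value workflow (pg <-> Mbp conversion, per-species
averaging, Shapiro-Wilk normality gate, Mann-Whitney comparisons of each
order against a focal order, percentile reports) plus Spearman
correlations of genome size against repeat content and total
intron/exon size, and BUSCO completeness arithmetic.

The Mann-Whitney U statistic and its exact/approximate p-values, and the
Spearman rho/p, are implemented here directly (they are the statistics
the comparisons hinge on); rank assignment, the Shapiro-Wilk test and
normal/t tail probabilities are delegated to scipy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation_io import BuscoCounts, CValueRecord

__all__ = [
    "PG_TO_MBP",
    "MannWhitneyResult",
    "SpearmanResult",
    "OrderComparison",
    "SpeciesGenomeStats",
    "PercentileReport",
    "pg_to_mbp",
    "mbp_to_pg",
    "species_mean_cvalues",
    "mann_whitney",
    "welch_t",
    "normality_gate",
    "significance_label",
    "compare_focal_order",
    "order_percentile_report",
    "spearman",
    "genome_correlates",
    "busco_percent",
]

# 1 pg of DNA corresponds to 978 Mbp (Dolezel et al. conversion)
PG_TO_MBP = 978.0

EXACT_LIMIT = 400  # exact Mann-Whitney enumeration when n1*n2 <= this and no ties


def pg_to_mbp(c_value_pg: float) -> float:
    """Convert haploid DNA content in pg to megabase pairs (1 pg = 978 Mbp)."""
    if c_value_pg < 0:
        raise ValueError(f"C-value must be >= 0, got {c_value_pg}")
    return c_value_pg * PG_TO_MBP


def mbp_to_pg(mbp: float) -> float:
    """Inverse of :func:`pg_to_mbp`."""
    if mbp < 0:
        raise ValueError(f"genome size must be >= 0, got {mbp}")
    return mbp / PG_TO_MBP


def species_mean_cvalues(records: Iterable[CValueRecord]) -> list[CValueRecord]:
    """Average duplicate database entries per species.

    Order (and family, when present) must agree across a species'
    duplicate rows; a conflict raises, naming the species.
    """
    by_species: dict[str, list[CValueRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.species not in by_species:
            order.append(rec.species)
        by_species.setdefault(rec.species, []).append(rec)
    out = []
    for sp in order:
        recs = by_species[sp]
        orders = {r.order for r in recs}
        if len(orders) > 1:
            raise ValueError(f"species {sp!r} has conflicting order labels: {sorted(orders)}")
        families = {r.family for r in recs if r.family is not None}
        if len(families) > 1:
            raise ValueError(f"species {sp!r} has conflicting family labels: {sorted(families)}")
        out.append(
            CValueRecord(
                species=sp,
                order=recs[0].order,
                family=next(iter(families)) if families else None,
                c_value_pg=float(np.mean([r.c_value_pg for r in recs])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney

@dataclass
class MannWhitneyResult:
    u_statistic: float  # U of the first sample
    p_value: float
    method: Literal["exact", "normal_approx"]
    n1: int
    n2: int


@lru_cache(maxsize=None)
def _u_null_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Number of rank arrangements yielding each U value under H0.

    Standard recurrence N(u; n1, n2) = N(u - n2; n1-1, n2) + N(u; n1, n2-1):
    the largest x-observation either beats all n2 ys (contributing n2 to U)
    or the largest observation is a y.
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    a = _u_null_counts(n1 - 1, n2)  # length (n1-1)*n2 + 1
    b = _u_null_counts(n1, n2 - 1)  # length n1*(n2-1) + 1
    res = [0] * (n1 * n2 + 1)
    for u, c in enumerate(a):
        res[u + n2] += c
    for u, c in enumerate(b):
        res[u] += c
    return tuple(res)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Literal["two-sided"] = "two-sided",
) -> MannWhitneyResult:
    """Mann-Whitney U test for two independent samples.

    U counts pairs where x_i > y_j, plus half the tied pairs.  The
    two-sided p-value is exact (full null enumeration of U) when
    n1*n2 <= 400 and there are no ties across the pooled sample;
    otherwise a normal approximation with tie and continuity
    corrections is used.
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = int(x.size), int(y.size)

    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0  # = #{x_i > y_j} + 0.5 * #ties

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if not has_ties and n1 * n2 <= EXACT_LIMIT:
        counts = _u_null_counts(n1, n2)
        total = math.comb(n1 + n2, n1)
        ui = int(round(u))
        p_le = sum(counts[: ui + 1]) / total
        p_ge = sum(counts[ui:]) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return MannWhitneyResult(u_statistic=float(u), p_value=p,
                                 method="exact", n1=n1, n2=n2)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations identical
        return MannWhitneyResult(u_statistic=float(u), p_value=1.0,
                                 method="normal_approx", n1=n1, n2=n2)
    # continuity correction shrinks |U - mu| by 0.5
    z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(var)
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return MannWhitneyResult(u_statistic=float(u), p_value=p,
                             method="normal_approx", n1=n1, n2=n2)


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance t-test (statistic, two-sided p)."""
    res = sps.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def normality_gate(values: Sequence[float], alpha: float = 0.05) -> bool:
    """True when the sample should be treated as non-normal.

    Shapiro-Wilk p < alpha rejects normality.  Samples too small or
    degenerate to test (n < 3 or constant) return True with a warning —
    the conservative choice is the non-parametric path.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3 or np.all(arr == arr[0]):
        warnings.warn(
            "normality_gate: sample too small or constant for Shapiro-Wilk; "
            "treating as non-normal",
            stacklevel=2,
        )
        return True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns for n > 5000
        p = float(sps.shapiro(arr).pvalue)
    return p < alpha


# ---------------------------------------------------------------------------
# order comparisons

SIGNIFICANCE_LADDER = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_label(p_value: float) -> str:
    for threshold, label in SIGNIFICANCE_LADDER:
        if p_value < threshold:
            return label
    return "ns"


@dataclass
class OrderComparison:
    focal_order: str
    other_order: str
    focal_mean_pg: float
    other_mean_pg: float
    test: MannWhitneyResult
    significance_label: str
    test_name: str = "mannwhitney"


def compare_focal_order(
    records: Iterable[CValueRecord],
    focal_order: str,
    test: Literal["mannwhitney", "welch"] = "mannwhitney",
    min_species: int = 2,
) -> list[OrderComparison]:
    """Compare one focal order's per-species C-values against every other.

    ``records`` should already be species-averaged (one row per species).
    Orders with fewer than ``min_species`` species are skipped.  P-values
    are reported unadjusted, one two-sided test per order pair, with the
    standard star ladder (0.05 / 0.01 / 0.001 / 0.0001).
    """
    by_order: dict[str, list[float]] = {}
    order_seq: list[str] = []
    for rec in records:
        if rec.order not in by_order:
            order_seq.append(rec.order)
        by_order.setdefault(rec.order, []).append(rec.c_value_pg)
    if focal_order not in by_order:
        raise ValueError(f"focal order {focal_order!r} absent from records")
    focal = by_order[focal_order]
    if len(focal) < min_species:
        raise ValueError(
            f"focal order {focal_order!r} has {len(focal)} species; need >= {min_species}"
        )
    comparisons = []
    for other in order_seq:
        if other == focal_order or len(by_order[other]) < min_species:
            continue
        vals = by_order[other]
        if test == "mannwhitney":
            res = mann_whitney(focal, vals)
        elif test == "welch":
            stat, p = welch_t(focal, vals)
            res = MannWhitneyResult(
                u_statistic=stat, p_value=p, method="normal_approx",
                n1=len(focal), n2=len(vals),
            )
        else:
            raise ValueError(f"unknown test {test!r}")
        comparisons.append(
            OrderComparison(
                focal_order=focal_order,
                other_order=other,
                focal_mean_pg=float(np.mean(focal)),
                other_mean_pg=float(np.mean(vals)),
                test=res,
                significance_label=significance_label(res.p_value),
                test_name=test,
            )
        )
    return comparisons


@dataclass
class PercentileReport:
    cutoffs: dict[float, float]  # global percentile -> C-value cutoff (pg)
    order_shares: pd.DataFrame  # per-order share of species at/below lower cutoffs
    within_order: dict[float, float] | None  # percentiles within a named order
    within_order_name: str | None


def order_percentile_report(
    records: Iterable[CValueRecord],
    qs: Sequence[float] = (0.05, 0.10, 0.90),
    within_order: str | None = None,
) -> PercentileReport:
    """Global C-value percentile cutoffs and per-order shares below them.

    Cutoffs are linear-interpolation percentiles over all species means.
    For each lower-tail percentile (q < 0.5) the report gives two shares
    per order: the fraction of that order's species at or below the
    cutoff (``pct_of_order_le_pX`` — "16.3% of the order's species sit in
    the lowest 5%"), and the order's share of all sub-cutoff species
    (``pct_of_subcutoff_pX`` — the composition of the low tail).  When
    ``within_order`` is named, that order's own percentiles are included.
    """
    recs = list(records)
    if len(recs) < 10:
        raise ValueError(f"need >= 10 species, got {len(recs)}")
    values = np.array([r.c_value_pg for r in recs])
    orders = np.array([r.order for r in recs])
    cutoffs = {float(q): float(np.quantile(values, q, method="linear")) for q in qs}

    lower_qs = [q for q in cutoffs if q < 0.5]
    rows = []
    for order in dict.fromkeys(orders):
        mask = orders == order
        row: dict = {"order": order, "n_species": int(mask.sum())}
        for q in lower_qs:
            tag = int(round(q * 100))
            below = values <= cutoffs[q]
            row[f"pct_of_order_le_p{tag}"] = 100.0 * float(below[mask].mean())
            n_below = int(below.sum())
            row[f"pct_of_subcutoff_p{tag}"] = (
                100.0 * float(below[mask].sum()) / n_below if n_below else 0.0
            )
        rows.append(row)
    shares = pd.DataFrame(rows)

    within = None
    if within_order is not None:
        mask = orders == within_order
        if not mask.any():
            raise ValueError(f"order {within_order!r} absent from records")
        within = {
            float(q): float(np.quantile(values[mask], q, method="linear")) for q in qs
        }
    return PercentileReport(
        cutoffs=cutoffs,
        order_shares=shares,
        within_order=within,
        within_order_name=within_order,
    )


# ---------------------------------------------------------------------------
# Spearman correlations

@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    label: str = ""


def spearman(x: Sequence[float], y: Sequence[float], label: str = "") -> SpearmanResult:
    """Spearman rank correlation: Pearson on average ranks, two-sided p
    via the t approximation with n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need >= 3 observations, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    tie_free = np.unique(x).size == n and np.unique(y).size == n
    if tie_free:
        # classic d^2 formula: exact (rho = +/-1 comes out exactly)
        d2 = float(np.sum((rx - ry) ** 2))
        rho = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    else:
        rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho=rho, p_value=min(1.0, p), n=n, label=label)


@dataclass
class SpeciesGenomeStats:
    """Per-species quantities the genome-size correlations consume."""

    species_label: str
    genome_size_bp: int
    te_pct: float
    total_intron_bp: int
    total_exon_bp: int

    def __post_init__(self) -> None:
        if self.genome_size_bp <= 0:
            raise ValueError("genome_size_bp must be > 0")
        if not 0.0 <= self.te_pct <= 100.0:
            raise ValueError(f"te_pct out of [0,100]: {self.te_pct}")


def genome_correlates(stats: Sequence[SpeciesGenomeStats]) -> dict[str, SpearmanResult]:
    """Spearman correlations of genome size with TE %, total intron bp,
    and total exon bp across species."""
    if len(stats) < 3:
        raise ValueError(f"need >= 3 species, got {len(stats)}")
    size = [s.genome_size_bp for s in stats]
    return {
        "te_pct": spearman(size, [s.te_pct for s in stats], label="genome_size~te_pct"),
        "total_intron_bp": spearman(
            size, [s.total_intron_bp for s in stats], label="genome_size~total_intron_bp"
        ),
        "total_exon_bp": spearman(
            size, [s.total_exon_bp for s in stats], label="genome_size~total_exon_bp"
        ),
    }


# ---------------------------------------------------------------------------
# BUSCO

def busco_percent(counts: BuscoCounts) -> float:
    """Completeness: 100 * identified / total, to one decimal place."""
    return round(100.0 * counts.identified / counts.total, 1)
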