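# Methods

## Gene, exon and intron sizes

Gene models are assembled from GFF3 records as gene → transcript →
exon hierarchies. Coordinates stay in GFF3's native 1-based inclusive
convention throughout parsing; all size arithmetic happens in
`feature_sizes` under an explicit convention switch:

- **paper** (default): literal coordinate differences — gene and exon
  size `end − start`, intron size `next.start − prev.end`. This is the
  convention used for the published per-species quantile tables this
  package's procedure follows, so its outputs are comparable with them.
- **biological**: standard lengths — `end − start + 1` for genes/exons,
  `next.start − prev.end − 1` for introns.

The two differ by exactly ±1 bp per feature; the literal-difference
rule undercounts exon lengths and overcounts intron lengths by 1 bp
relative to the standard definition. Which one an external table used
is often undocumented, which is why both are first-class here and every
output row carries its convention.

Assembly rules: every transcript of a gene contributes its exons and
introns (no canonical-transcript selection — no defensible selection
rule exists without expression data); an exon naming several `Parent`
transcripts contributes to each; transcripts without exon children fall
back to CDS children; orphan transcripts become single-transcript genes
with a synthesized id. Gene size uses the gene record's own
coordinates (the annotated locus), not the union of transcript extents.
Exons are sorted by start irrespective of strand — all size formulas
are strand-symmetric. Non-positive sizes (zero-length spans,
overlapping or book-ended exons, which real annotations do contain) are
excluded from pooled arrays and tallied in QC counters instead of
raising; the counters are part of every `FeatureSizeTable`.

Key invariant (property-tested): for any transcript,
`sum(exon sizes) + sum(intron sizes) = span of the exon extent`, under
either convention applied consistently, and intron count = exon count − 1.

## Distribution summaries

Quantiles use linear interpolation on the sorted sample (position
`1 + q(n−1)`, numpy's default "type 7"); no quantile definition is ever
universal, so this choice is documented rather than assumed when
comparing with external tables. Standard deviations use the n−1
denominator. Boxplot whiskers follow Tukey's rule: fences at
quartile ± 1.5·IQR, whiskers clamped to the most extreme data inside.

KDEs are Gaussian on the log10(bp) axis, evaluated on a uniform grid
extending 3 bandwidths beyond the data range, normalized on the log10
axis. "Bandwidth" is ambiguous across plotting libraries: here the
default (`bw_mode="absolute"`) treats it as the Gaussian σ in log10
units; `"scott-factor"` treats it as a multiplier on Scott's
rule-of-thumb bandwidth, the semantics of seaborn-style `bw` factors.
The conventional plotting parameters for size distributions (σ = 0.1,
1000 grid points for exons; σ = 0.01, 5000 for introns) are the
defaults in the analysis drivers.

## Repeat content

RepeatMasker class/family strings are binned by prefix before the `/`:
`LINE*`, `SINE*`, `LTR*` to their own classes, `DNA*` and `RC*`
(rolling-circle) to DNA transposons, everything else (simple repeats,
low complexity, satellites, unknowns) to Other. "TE content" means the
four mobile classes combined; summaries report both the per-class rows
and the mobile total so either reading of a stacked-bar figure is
recoverable.

Masked bp per class is, in `raw` mode (default), the sum of hit lengths
(`end − start + 1`; RepeatMasker coordinates are 1-based inclusive,
independent of the gene-feature convention switch) — matching how
RepeatMasker's own tables tally; `merged` mode takes the per-class
interval union, which guarantees percentages ≤ 100 and is verified
against a per-base bitmap oracle in tests. Hits more than 20% diverged
from their consensus are excluded by default (the usual cutoff for
confidently-assignable, recent repeats); rows flagged `*` (lower-scoring
overlaps) are retained but carry the flag so callers can filter.

## C-value statistics

C-values (haploid DNA content, pg) convert to Mbp via 1 pg = 978 Mbp.
Duplicate database entries per species are arithmetically averaged
before any testing. The focal-order comparison runs one two-sided
Mann–Whitney U test per other order (orders with < 2 species skipped),
unadjusted p-values, significance stars at 0.05/0.01/0.001/0.0001. The
non-parametric path is the default because genome-size samples
routinely fail Shapiro–Wilk normality (the gate is available and warns
on samples too small or degenerate to test, treating them as
non-normal); Welch's t is offered as an alternative for sensitivity
checks. No multiple-testing correction is applied by default, matching
how such panels are conventionally reported; p-values are emitted so a
Holm correction can be applied downstream.

Mann–Whitney: U counts pairs with `x > y` plus half the ties. With no
ties and `n1·n2 ≤ 400` the two-sided p comes from full enumeration of
the null distribution of U (a standard recurrence; exact enumeration is
sub-second in that regime); otherwise a normal approximation with tie
and continuity corrections. The exact path is validated against a
brute-force enumeration over all rank splits, and both paths against an
independent implementation.

Percentile reports: global cutoffs are linear-interpolation percentiles
over species means. For each lower-tail cutoff two per-order shares are
reported, because "share of the 5th percentile" is genuinely ambiguous:
`pct_of_order_le_pX` (what fraction of the order's species sit at or
below the cutoff) and `pct_of_subcutoff_pX` (what fraction of all
sub-cutoff species belong to the order).

Spearman correlation is Pearson on average ranks; in the tie-free case
the classic `1 − 6Σd²/(n(n²−1))` formula is used so strictly
co-monotone inputs return ρ = ±1 exactly. Two-sided p uses the t
approximation with n−2 df. BUSCO completeness is
`100·identified/total` to one decimal; `identified` and `total` are
authoritative, and inconsistent component counts (complete + fragmented
≠ identified) are flagged, not fatal.

## Synthetic data: what it emulates, and what it does not

The generators produce the statistical structure the analyses consume,
with ground truth recorded at draw time:

- **Annotations**: gene → mRNA → exon hierarchies laid left-to-right
  with log-normal intergenic gaps, exon counts uniform in a range
  (default 2–8), exon and intron sizes log-normal on ln(bp), ceiled to
  integers ≥ 1 (as biological lengths). Defaults — exon μ = ln 130,
  σ = 0.5; intron μ = ln 500, σ = 1.2 — are stylized to the observed
  shape of fish size distributions (compact, narrow exons around
  120–130 bp; heavy-tailed introns), not fitted to any species.
  Running the full pipeline under the biological convention on
  generated files recovers the drawn sizes exactly.
- **Repeats**: non-overlapping hits placed per class until masked bp is
  within one mean hit length of the class target, divergence uniform on
  (0, 25) so the 20% filter removes a known subset.
- **C-values**: per-species values drawn per order (log-normal
  parameterized to the requested arithmetic mean/sd, or truncated
  normal); duplicate rows jitter around the species value with the
  jitter mean-centred, so duplicate averages reproduce species values
  exactly.

One global seed drives each generator through a fixed offset, so files
are byte-reproducible and adding a generator never perturbs existing
outputs.

What the generators do **not** emulate: nucleotide sequence, splice
sites, UTR/CDS structure, alternative isoforms (one transcript per
gene), phylogenetic covariance between species, realistic repeat age
landscapes, or overlapping/nested genes. Passing tests therefore
demonstrate the correctness of the measurement machinery and the
statistics under known generating conditions — they do not certify any
biological claim about real genomes, where annotation quality and
lineage structure add variance the synthetic panel lacks.

## Problem sizes and numerical choices

The shipped study and checks run at desk scale, chosen as the smallest
sizes at which the targeted properties are statistically meaningful:
parameter recovery uses 5000 genes (~20k introns), where the sample
median of the intron distribution estimates the generating median
exp(μ) to ~1% sampling error (3% tolerance ≈ 3σ) and the 99th quantile
estimates exp(μ + 2.326σ) to ~3% (10% tolerance ≈ 3σ); the
order-comparison calibration uses 200 replicate panels of 4 orders ×
15 species; Mann–Whitney exactness is enumerated for samples up to
8 × 8. The analysis panel uses 9 species × 250 genes with genome sizes
spanning ~6×, which is enough for the rank correlations to saturate.

Other numerical choices: KDE grids are evaluated by direct Gaussian
summation in grid chunks (exact, memory-bounded); quantile/percentile
functions reject empty inputs and q ∉ (0,1); single-observation
summaries report sd = 0 with a flag; constant vectors are errors for
Spearman and warnings (gated non-normal) for Shapiro–Wilk; TSV outputs
use `.` as the missing-value token and are written atomically
(temp file + rename).

## Known limitations

- The per-species numbers published for real genomes depend on
  unversioned external resources (annotation releases, genome-size
  database snapshots); this package reproduces the *procedure* and
  validates it on ground-truthed synthetic data, not those exact
  tables.
- The paper-convention ±1 bp ambiguity is irreducible without the
  original analysis code; both conventions are provided instead.
- `merged` overlap mode unions intervals within a class only; hits of
  different classes can still double-cover bases, so the cross-class
  total is a sum of per-class unions.
- The exact Mann–Whitney path requires tie-free data; tied samples use
  the corrected normal approximation even at small n.
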