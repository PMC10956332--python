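"""Readers and writers for the external formats the pipeline touches.

GFF3 genome annotations, RepeatMasker ``.out`` alignment tables, C-value
tables (species haploid DNA content in pg), BUSCO short summaries, and
plain TSV outputs.  All coordinates are kept in each format's native
convention: GFF3 and RepeatMasker query coordinates are 1-based inclusive.
Size arithmetic happens downstream with an explicit convention switch.
"""

from __future__ import annotations

import gzip
import io
import os
import re
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
from urllib.parse import quote, unquote

import pandas as pd

__all__ = [
    "GffRecord",
    "RepeatHit",
    "CValueRecord",
    "BuscoCounts",
    "GffParseError",
    "RepeatMaskerParseError",
    "SchemaError",
    "read_gff3",
    "write_gff3",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "read_cvalue_table",
    "write_cvalue_table",
    "parse_busco_summary",
    "read_tsv",
    "write_tsv",
    "atomic_write_text",
]


class GffParseError(ValueError):
    """A GFF3 line could not be parsed; carries the 1-based line number."""


class RepeatMaskerParseError(ValueError):
    """A RepeatMasker .out row could not be parsed."""


class SchemaError(ValueError):
    """A tabular input is missing required columns."""


MISSING = "."


@dataclass(frozen=True)
class GffRecord:
    """One feature line of a GFF3 file (1-based, inclusive coordinates)."""

    seqid: str
    source: str
    feature_type: str
    start: int
    end: int
    score: str
    strand: str
    phase: str
    attributes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if not self.feature_type:
            raise ValueError("feature_type must be non-empty")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")

    @property
    def ids(self) -> list[str]:
        return self.attributes.get("ID", [])

    @property
    def parents(self) -> list[str]:
        return self.attributes.get("Parent", [])


@dataclass(frozen=True)
class RepeatHit:
    """One alignment row of a RepeatMasker .out table."""

    query_seq: str
    query_start: int
    query_end: int
    repeat_name: str
    repeat_class: str
    divergence_pct: float
    overlapped: bool = False  # trailing '*' — lower-scoring overlapping hit

    def __post_init__(self) -> None:
        if self.query_start < 1:
            raise ValueError(f"query_start must be >= 1, got {self.query_start}")
        if self.query_end < self.query_start:
            raise ValueError(
                f"query_end ({self.query_end}) < query_start ({self.query_start})"
            )
        if not 0.0 <= self.divergence_pct <= 100.0:
            raise ValueError(f"divergence_pct out of [0,100]: {self.divergence_pct}")

    @property
    def length_bp(self) -> int:
        """Masked bases: coordinates are 1-based inclusive."""
        return self.query_end - self.query_start + 1


@dataclass(frozen=True)
class CValueRecord:
    """Species haploid nuclear DNA content (pg) with taxonomy."""

    species: str
    order: str
    c_value_pg: float
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.order:
            raise ValueError("order must be non-empty")
        if self.c_value_pg <= 0:
            raise ValueError(f"c_value_pg must be > 0, got {self.c_value_pg}")


@dataclass(frozen=True)
class BuscoCounts:
    """BUSCO tally: complete / fragmented / identified out of a total set."""

    complete: int
    fragmented: int
    identified: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total must be positive")
        if min(self.complete, self.fragmented, self.identified) < 0:
            raise ValueError("counts must be non-negative")
        if self.identified > self.total:
            raise ValueError("identified exceeds total")
        if self.complete + self.fragmented > self.total:
            raise ValueError("complete + fragmented exceeds total")

    @property
    def consistent(self) -> bool:
        """True when identified equals complete + fragmented."""
        return self.identified == self.complete + self.fragmented


# ---------------------------------------------------------------------------
# GFF3

_ENCODE_CHARS = "\t\n\r%;=&,"


def _decode_attr(value: str) -> str:
    return unquote(value)


def _encode_attr(value: str) -> str:
    return quote(value, safe="".join(c for c in map(chr, range(33, 127)) if c not in _ENCODE_CHARS))


def _parse_attributes(col: str, lineno: int) -> dict[str, list[str]]:
    attrs: dict[str, list[str]] = {}
    if col in ("", MISSING):
        return attrs
    for chunk in col.rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise GffParseError(f"line {lineno}: attribute without '=': {chunk!r}")
        key, _, raw = chunk.partition("=")
        attrs[key.strip()] = [_decode_attr(v) for v in raw.split(",")]
    return attrs


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def read_gff3(path: str | Path) -> list[GffRecord]:
    """Parse a (possibly gzipped) GFF3 file into records.

    Comment and directive lines are skipped; an embedded ``##FASTA``
    section terminates parsing.  Percent-encoded attribute values are
    decoded and multi-valued attributes (``Parent=a,b``) are split.

    Raises
    ------
    GffParseError
        On a line with the wrong column count or an unparseable field;
        the message names the 1-based line number.
    ValueError
        When a feature violates coordinate invariants (end < start).
    """
    records: list[GffRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise GffParseError(f"line {lineno}: non-integer coordinate") from exc
            try:
                rec = GffRecord(
                    seqid=cols[0],
                    source=cols[1],
                    feature_type=cols[2],
                    start=start,
                    end=end,
                    score=cols[5],
                    strand=cols[6],
                    phase=cols[7],
                    attributes=_parse_attributes(cols[8], lineno),
                )
            except ValueError as exc:
                raise GffParseError(f"line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def _format_attributes(attrs: dict[str, list[str]]) -> str:
    if not attrs:
        return MISSING
    return ";".join(
        f"{k}={','.join(_encode_attr(v) for v in vs)}" for k, vs in attrs.items()
    )


def write_gff3(records: Iterable[GffRecord], path: str | Path) -> None:
    """Write records as GFF3 (with the version directive), atomically."""
    lines = ["##gff-version 3"]
    for r in records:
        lines.append(
            "\t".join(
                (
                    r.seqid,
                    r.source,
                    r.feature_type,
                    str(r.start),
                    str(r.end),
                    r.score,
                    r.strand,
                    r.phase,
                    _format_attributes(r.attributes),
                )
            )
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out

RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def read_repeatmasker_out(path: str | Path) -> list[RepeatHit]:
    """Parse a RepeatMasker ``.out`` alignment table.

    The fixed header block (any leading lines whose first token is not a
    number, plus blank lines) is skipped.  Rows flagged with a trailing
    ``'*'`` (lower-scoring overlap with a higher-scoring hit) are retained
    and marked ``overlapped=True``.
    """
    hits: list[RepeatHit] = []
    seen_data = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            first_numeric = re.fullmatch(r"[\d.]+", fields[0]) is not None
            if not first_numeric:
                if seen_data:
                    raise RepeatMaskerParseError(
                        f"line {lineno}: unparseable row after data began"
                    )
                continue  # header
            seen_data = True
            if len(fields) < 11:
                raise RepeatMaskerParseError(
                    f"line {lineno}: expected >= 11 fields, got {len(fields)}"
                )
            try:
                divergence = float(fields[1])
                qstart = int(fields[5])
                qend = int(fields[6])
            except ValueError as exc:
                raise RepeatMaskerParseError(
                    f"line {lineno}: non-numeric coordinate or divergence field"
                ) from exc
            try:
                hits.append(
                    RepeatHit(
                        query_seq=fields[4],
                        query_start=qstart,
                        query_end=qend,
                        repeat_name=fields[9],
                        repeat_class=fields[10],
                        divergence_pct=divergence,
                        overlapped=fields[-1] == "*",
                    )
                )
            except ValueError as exc:
                raise RepeatMaskerParseError(f"line {lineno}: {exc}") from exc
    return hits


def write_repeatmasker_out(hits: Iterable[RepeatHit], path: str | Path) -> None:
    """Write hits in RepeatMasker .out layout (fixed header, aligned rows)."""
    buf = io.StringIO()
    buf.write(RM_HEADER)
    for i, h in enumerate(hits, 1):
        left = 0  # (left) fields are not consumed by the reader
        row = (
            f"{1000:>5} {h.divergence_pct:5.1f}  0.0  0.0  {h.query_seq:<10}"
            f"{h.query_start:>8} {h.query_end:>8} ({left})  +  "
            f"{h.repeat_name:<15} {h.repeat_class:<20} 1 {h.length_bp} (0) {i:>6}"
        )
        if h.overlapped:
            row += " *"
        buf.write(row + "\n")
    atomic_write_text(path, buf.getvalue())


# ---------------------------------------------------------------------------
# C-value tables

_CVALUE_REQUIRED = ("species", "order", "c_value_pg")


def read_cvalue_table(path: str | Path) -> list[CValueRecord]:
    """Read a species C-value table (TSV or CSV, sniffed from the header).

    Duplicate species rows are preserved; averaging is a downstream step.
    """
    with _open_text(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _CVALUE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"C-value table missing required column(s): {missing}")
    has_family = "family" in df.columns
    records = []
    for idx, row in df.iterrows():
        cv = float(row["c_value_pg"])
        if cv <= 0:
            raise ValueError(
                f"row {idx + 2}: non-positive C-value {cv} for {row['species']!r}"
            )
        fam = None
        if has_family and not pd.isna(row["family"]) and row["family"] != MISSING:
            fam = str(row["family"])
        records.append(
            CValueRecord(
                species=str(row["species"]),
                order=str(row["order"]),
                c_value_pg=cv,
                family=fam,
            )
        )
    return records


def write_cvalue_table(records: Iterable[CValueRecord], path: str | Path) -> None:
    rows = [
        {
            "species": r.species,
            "order": r.order,
            "family": r.family if r.family is not None else MISSING,
            "c_value_pg": repr(r.c_value_pg),
        }
        for r in records
    ]
    write_tsv(rows, path, columns=["species", "order", "family", "c_value_pg"])


# ---------------------------------------------------------------------------
# BUSCO short summary

_BUSCO_PATTERNS = {
    "complete": re.compile(r"^\s*(\d+)\s+Complete BUSCOs", re.M),
    "fragmented": re.compile(r"^\s*(\d+)\s+Fragmented BUSCOs", re.M),
    "total": re.compile(r"^\s*(\d+)\s+Total BUSCO groups", re.M),
}


def parse_busco_summary(text_or_path: str | Path) -> BuscoCounts:
    """Parse the count lines of a BUSCO ``short_summary.txt``.

    Accepts either the file path or the summary text itself.  Identified
    is taken as complete + fragmented.
    """
    text = str(text_or_path)
    if os.path.exists(text):
        text = Path(text).read_text()
    found: dict[str, int] = {}
    for key, pat in _BUSCO_PATTERNS.items():
        m = pat.search(text)
        if m is None:
            raise SchemaError(f"BUSCO summary: could not find the {key} count line")
        found[key] = int(m.group(1))
    return BuscoCounts(
        complete=found["complete"],
        fragmented=found["fragmented"],
        identified=found["complete"] + found["fragmented"],
        total=found["total"],
    )


# ---------------------------------------------------------------------------
# TSV plumbing

def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text via a temp file + rename so readers never see partials."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_tsv(
    rows: Sequence[dict] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write rows as UTF-8 TSV: header first, ``'.'`` for missing values.

    All rows must share one column set (the union of keys when ``columns``
    is not given); a value of None becomes the missing token.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
        if columns is not None:
            df = df[list(columns)]
    else:
        if columns is None:
            columns = []
            for row in rows:
                for k in row:
                    if k not in columns:
                        columns.append(k)
        df = pd.DataFrame(list(rows), columns=list(columns))
    text = df.to_csv(sep="\t", index=False, na_rep=MISSING)
    atomic_write_text(path, text)


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv`; ``'.'`` maps back to NaN."""
    return pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=True)
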