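"""Readers and writers for the formats the probe-design pipeline touches.

Internal coordinates are 0-based half-open everywhere.  Paper-facing formats
(RepeatMasker ``.out`` query coordinates, clone placement tables) are 1-based
inclusive and are converted exactly once, at the parse/serialize boundary.
BED is natively 0-based half-open and passes through unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

_VALID_BASES = frozenset("ACGTN")

#: Sentinel chromosome/coordinate value for clones that map to multiple sites.
MULTIPLE = "multiple"


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


def zero_based(start1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start1 - 1, end1


def one_based(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start0 + 1, end0


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}, stored upper-case."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ParseError(
                f"record {self.id!r}: illegal sequence characters {sorted(bad)!r}"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RepeatInterval:
    """One annotated repeat element, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    rep_name: str = ""
    rep_class: str = ""
    rep_family: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BacClone:
    """A BAC clone placement.

    ``start``/``end`` follow the clone-table convention: 1-based inclusive.
    Multi-mapping clones (table coordinate fields reading ``multiple``) carry
    ``start = end = None``.  The reported insert size may legitimately differ
    from the mapped span; consistency is checked by
    :func:`satprobe.clones.check_clone_consistency`, not enforced here.
    """

    name: str
    chrom: str
    band: str = ""
    start: int | None = None
    end: int | None = None
    insert_size: int = 0
    end_accessions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.start is None) != (self.end is None):
            raise ValueError(f"clone {self.name}: start/end must both be set or both absent")
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(f"clone {self.name}: start > end")

    @property
    def is_multi_mapping(self) -> bool:
        return self.start is None


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into normalized :class:`SequenceRecord` objects.

    Raises :class:`ParseError` on duplicate ids, illegal characters, or a
    non-empty file that contains no FASTA records.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq)))
    except ParseError:
        raise
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not records and path.read_text().strip():
        raise ParseError(f"{path}: no FASTA records found in non-empty file")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out dialect

_RM_HEADER_TOKENS = {"sw", "score", "bit"}


def parse_repeatmasker_out(path: str | Path) -> list[RepeatInterval]:
    """Parse a RepeatMasker ``.out``-style annotation file.

    Expected whitespace-separated columns per alignment row::

        score div del ins query qbegin qend qleft strand repeat class/family ...

    Query coordinates are 1-based inclusive and are converted to the internal
    0-based half-open convention; strand ``C`` (complement) maps to ``-``.
    The combined ``class/family`` column is split on the first ``/``.
    """
    intervals: list[RepeatInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if fields[0].lower() in _RM_HEADER_TOKENS:
                continue
            if len(fields) < 11:
                raise ParseError(f"{path}:{lineno}: expected >= 11 columns, got {len(fields)}")
            try:
                qstart = int(fields[5].replace(",", ""))
                qend = int(fields[6].replace(",", ""))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric query coordinates") from exc
            strand_raw = fields[8]
            if strand_raw == "+":
                strand = "+"
            elif strand_raw in ("C", "-"):
                strand = "-"
            else:
                raise ParseError(f"{path}:{lineno}: bad strand column {strand_raw!r}")
            rep_class, _, rep_family = fields[10].partition("/")
            start0, end0 = zero_based(qstart, qend)
            try:
                intervals.append(
                    RepeatInterval(
                        chrom=fields[4],
                        start=start0,
                        end=end0,
                        strand=strand,
                        rep_name=fields[9],
                        rep_class=rep_class,
                        rep_family=rep_family,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_repeatmasker_out(intervals: Sequence[RepeatInterval], path: str | Path) -> None:
    """Write intervals in the ``.out`` dialect accepted by :func:`parse_repeatmasker_out`."""
    with open(path, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query      position in query           matching"
            "       repeat              position in  repeat\n"
        )
        fh.write(
            "score  div. del. ins.  sequence    begin     end    (left)   repeat"
            "         class/family         begin  end (left)   ID\n"
        )
        fh.write("\n")
        for i, iv in enumerate(intervals, start=1):
            start1, end1 = one_based(iv.start, iv.end)
            strand = "+" if iv.strand == "+" else "C"
            cls = iv.rep_class if not iv.rep_family else f"{iv.rep_class}/{iv.rep_family}"
            fh.write(
                f"  500  10.0  0.0  0.0  {iv.chrom}  {start1}  {end1}  (0)  {strand}"
                f"  {iv.rep_name or 'rep'}  {cls}  1  {iv.length}  (0)  {i}\n"
            )


# ---------------------------------------------------------------------------
# BED


def parse_bed(path: str | Path) -> list[RepeatInterval]:
    """Parse BED3+ into intervals; an optional 4th column is used as rep_class."""
    intervals: list[RepeatInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "+"
            intervals.append(
                RepeatInterval(
                    chrom=fields[0], start=start, end=end, strand=strand,
                    rep_name=name, rep_class=name,
                )
            )
    return intervals


def write_bed(intervals: Iterable[RepeatInterval], path: str | Path) -> None:
    """Write BED4 (name column = rep_class). Lossless round-trip with :func:`parse_bed`."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.rep_class}\n")


# ---------------------------------------------------------------------------
# Clone placement tables

_NUMERIC_RE = re.compile(r"^[\d,]+$")


def _strip_commas(value: str) -> int:
    return int(value.replace(",", ""))


def parse_clone_table(path: str | Path) -> list[BacClone]:
    """Parse a tab-separated clone placement table.

    Columns: name, chromosome, band, start, end, insert size, end-sequence
    accessions (comma-separated).  Numeric fields may contain thousands
    separators; start/end may be the literal ``multiple`` for clones hitting
    several sites.  A single leading header line is tolerated.
    """
    clones: list[BacClone] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 tab-separated columns")
            name, chrom, band, start_s, end_s, insert_s = fields[:6]
            multi = start_s.lower() == MULTIPLE
            if not multi and not _NUMERIC_RE.match(start_s):
                if lineno == 1:  # header row
                    continue
                raise ParseError(f"{path}:{lineno}: bad start coordinate {start_s!r}")
            if not _NUMERIC_RE.match(insert_s):
                raise ParseError(f"{path}:{lineno}: non-numeric insert size {insert_s!r}")
            accessions: tuple[str, ...] = ()
            if len(fields) > 6 and fields[6]:
                accessions = tuple(a.strip() for a in fields[6].split(",") if a.strip())
            if multi:
                start = end = None
            else:
                if not _NUMERIC_RE.match(end_s):
                    raise ParseError(f"{path}:{lineno}: bad end coordinate {end_s!r}")
                start, end = _strip_commas(start_s), _strip_commas(end_s)
            clones.append(
                BacClone(
                    name=name, chrom=chrom, band=band, start=start, end=end,
                    insert_size=_strip_commas(insert_s), end_accessions=accessions,
                )
            )
    return clones


def write_clone_table(clones: Iterable[BacClone], path: str | Path, header: bool = True) -> None:
    """Write a clone table readable by :func:`parse_clone_table` (no thousands separators)."""
    with open(path, "w") as fh:
        if header:
            fh.write("BAC\tChr.\tBand\tStart (bp)\tEnd (bp)\tInsert (bp)\tBAC End Sequence Accession Number\n")
        for c in clones:
            start = MULTIPLE if c.start is None else str(c.start)
            end = MULTIPLE if c.end is None else str(c.end)
            fh.write(
                f"{c.name}\t{c.chrom}\t{c.band}\t{start}\t{end}\t{c.insert_size}\t"
                + ", ".join(c.end_accessions)
                + "\n"
            )
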