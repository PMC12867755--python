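"""File-format I/O: FASTA, GFF3, BED6-with-sequence, and count-matrix TSV.

Every reader validates strictly and every (reader, writer) pair round-trips
losslessly. Internal coordinates are 0-based half-open; GFF3 is the only
1-based inclusive surface. Files ending in ``.gz`` are read and written
through transparent gzip.
"""

from __future__ import annotations

import gzip
import io
from pathlib import Path
from typing import Iterable, List, Sequence, Union

import pandas as pd

from .core import (
    CATEGORIES,
    FormatError,
    GenomicFeature,
    MappedRead,
    NUCLEOTIDES,
    SequenceRecord,
)

PathLike = Union[str, Path]

#: Library-prep insert size bounds for small-RNA reads (nt).
DEFAULT_MIN_READ_LEN = 18
DEFAULT_MAX_READ_LEN = 40


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> List[SequenceRecord]:
    """Parse a FASTA file into validated records, preserving order.

    Raises :class:`FormatError` naming the offending line for malformed
    headers, illegal sequence characters, duplicate ids, or empty records.
    """
    records: List[SequenceRecord] = []
    seen = set()
    header: str | None = None
    header_line = 0
    chunks: List[str] = []

    def _flush(line_no: int) -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}: line {header_line}: record {header!r} has no sequence")
        records.append(SequenceRecord(id=header, seq=seq))

    with _open_text(path) as fh:
        line_no = 0
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                _flush(line_no)
                header = line[1:].split()[0] if line[1:].strip() else ""
                if not header:
                    raise FormatError(f"{path}: line {line_no}: empty FASTA header")
                if header in seen:
                    raise FormatError(f"{path}: line {line_no}: duplicate record id {header!r}")
                seen.add(header)
                header_line = line_no
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path}: line {line_no}: sequence data before first header")
                seq = line.strip().upper()
                bad = set(seq) - NUCLEOTIDES
                if bad:
                    raise FormatError(
                        f"{path}: line {line_no}: illegal sequence characters {sorted(bad)}"
                    )
                chunks.append(seq)
        _flush(line_no + 1)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def _parse_attributes(attr: str) -> dict:
    out = {}
    for field in attr.split(";"):
        field = field.strip()
        if not field:
            continue
        if "=" not in field:
            raise FormatError(f"malformed GFF3 attribute field {field!r}")
        key, value = field.split("=", 1)
        out[key] = value
    return out


def read_gff3(path: PathLike) -> List[GenomicFeature]:
    """Read a GFF3 file, converting to 0-based half-open coordinates."""
    features: List[GenomicFeature] = []
    seen = set()
    with _open_text(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: line {line_no}: expected 9 columns, got {len(cols)}")
            row = dict(zip(_GFF_COLS, cols))
            try:
                start1, end1 = int(row["start"]), int(row["end"])
            except ValueError:
                raise FormatError(f"{path}: line {line_no}: non-integer coordinates") from None
            if start1 > end1 or start1 < 1:
                raise FormatError(
                    f"{path}: line {line_no}: invalid GFF3 interval {start1}..{end1}"
                )
            if row["strand"] not in ("+", "-"):
                raise FormatError(f"{path}: line {line_no}: unknown strand {row['strand']!r}")
            if row["type"] not in CATEGORIES:
                raise FormatError(f"{path}: line {line_no}: unknown feature type {row['type']!r}")
            attrs = _parse_attributes(row["attributes"])
            fid = attrs.get("ID")
            if not fid:
                raise FormatError(f"{path}: line {line_no}: missing ID attribute")
            if fid in seen:
                raise FormatError(f"{path}: line {line_no}: duplicate feature id {fid!r}")
            seen.add(fid)
            try:
                feat = GenomicFeature(
                    contig=row["seqid"],
                    start=start1 - 1,
                    end=end1,
                    strand=row["strand"],
                    feature_id=fid,
                    category=row["type"],
                    parent_id=attrs.get("Parent"),
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {line_no}: {exc}") from None
            features.append(feat)
    return features


def write_gff3(features: Iterable[GenomicFeature], path: PathLike) -> None:
    """Write features as GFF3 (1-based inclusive), emitting the version pragma."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.feature_id}"
            if f.parent_id:
                attrs += f";Parent={f.parent_id}"
            fh.write(
                "\t".join(
                    [
                        f.contig,
                        "ectosrna",
                        f.category,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED6 with read sequence in the name column, n_loci in the score column


def read_reads_bed(
    path: PathLike,
    min_len: int = DEFAULT_MIN_READ_LEN,
    max_len: int = DEFAULT_MAX_READ_LEN,
) -> List[MappedRead]:
    """Read mapped sRNA reads from the BED6 dialect.

    Columns: contig, start, end, read sequence (name), n_loci (score),
    strand. Reads outside ``[min_len, max_len]`` or containing N are
    rejected (zero-mismatch mapping makes N impossible).
    """
    reads: List[MappedRead] = []
    with _open_text(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise FormatError(f"{path}: line {line_no}: expected 6 BED columns")
            contig, start_s, end_s, seq, score_s, strand = cols
            try:
                start, end, n_loci = int(start_s), int(end_s), int(score_s)
            except ValueError:
                raise FormatError(f"{path}: line {line_no}: non-integer field") from None
            seq = seq.upper()
            if "N" in seq:
                raise FormatError(
                    f"{path}: line {line_no}: read contains N (impossible at zero mismatches)"
                )
            length = end - start
            if not (min_len <= length <= max_len):
                raise FormatError(
                    f"{path}: line {line_no}: read length {length} outside [{min_len}, {max_len}]"
                )
            if len(seq) != length:
                raise FormatError(
                    f"{path}: line {line_no}: sequence length {len(seq)} != interval length {length}"
                )
            try:
                reads.append(
                    MappedRead(contig=contig, start=start, end=end, strand=strand,
                               seq=seq, n_loci=n_loci)
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {line_no}: {exc}") from None
    return reads


def write_reads_bed(reads: Iterable[MappedRead], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.seq}\t{r.n_loci}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# Count matrix TSV


def read_counts(path: PathLike) -> pd.DataFrame:
    """Read a features x samples count matrix (TSV, first column feature_id).

    Returns an integer DataFrame indexed by feature_id. Negative,
    non-integer, missing cells, or duplicate feature/sample names raise
    :class:`FormatError`.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: unreadable count table: {exc}") from None
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample name {dup!r}")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing cells in count table")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        raise FormatError(f"{path}: non-numeric cell in count table")
    if ((numeric % 1) != 0).any().any():
        raise FormatError(f"{path}: non-integer count")
    if (numeric < 0).any().any():
        raise FormatError(f"{path}: negative count")
    out = numeric.astype("int64")
    out.index.name = "feature_id"
    return out


def write_counts(matrix: pd.DataFrame, path: PathLike) -> None:
    matrix = matrix.copy()
    matrix.index.name = "feature_id"
    matrix.to_csv(path, sep="\t")
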