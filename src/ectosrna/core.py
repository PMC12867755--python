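"""Core domain types shared across the toolkit.

All coordinates are 0-based, half-open ``[start, end)``. GFF3 (1-based,
inclusive) is converted at the I/O boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Feature categories recognised throughout the pipeline.
CATEGORIES = ("gene", "exon", "intron", "TE", "miRNA", "intergenic_bin")

NUCLEOTIDES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (genome contig, miRNA, CDS)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq.upper()) - NUCLEOTIDES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicFeature:
    """A located, stranded annotation element.

    ``category`` is one of :data:`CATEGORIES`; exon/intron features carry the
    enclosing gene in ``parent_id``.
    """

    contig: str
    start: int
    end: int
    strand: str
    feature_id: str
    category: str
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.feature_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id!r}: strand must be + or -")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"feature {self.feature_id!r}: unknown category {self.category!r}"
            )
        if self.category in ("exon", "intron") and not self.parent_id:
            raise ValueError(
                f"{self.category} feature {self.feature_id!r} requires a gene parent_id"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MappedRead:
    """One genomic placement of an aligned small-RNA read.

    Reads were mapped with zero mismatches, so ``seq`` always equals the
    strand-aware genome substring at ``[start, end)``. ``n_loci`` is the
    total number of genomic placements of the read (multi-mappers are
    represented once per placement).
    """

    contig: str
    start: int
    end: int
    strand: str
    seq: str
    n_loci: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"read: invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError("read strand must be + or -")
        if len(self.seq) != self.end - self.start:
            raise ValueError(
                f"read at {self.contig}:{self.start}-{self.end}: sequence length "
                f"{len(self.seq)} != interval length {self.end - self.start}"
            )
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic position of the read's 5' end."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class MiRNALocus:
    """An annotated miRNA hairpin locus.

    ``arm5``/``arm3`` are the genomically left/right arms of the inverted
    repeat; ``mature_arm`` names the arm (in transcript orientation) whose
    reads dominate. ``provenance`` distinguishes previously reported loci
    from newly discovered putative ones.
    """

    locus_id: str
    contig: str
    strand: str
    arm5: Tuple[int, int]
    arm3: Tuple[int, int]
    mature_arm: str
    mature_seq: str
    star_seq: str
    mature_count: int = 0
    star_count: int = 0
    provenance: str = "putative"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("locus strand must be + or -")
        if self.mature_arm not in ("5p", "3p"):
            raise ValueError("mature_arm must be '5p' or '3p'")
        if self.provenance not in ("reported", "putative"):
            raise ValueError("provenance must be 'reported' or 'putative'")
        (a5s, a5e), (a3s, a3e) = self.arm5, self.arm3
        if not (a5s < a5e <= a3s < a3e):
            raise ValueError(
                f"locus {self.locus_id!r}: arms must be disjoint with arm5 upstream"
            )

    @property
    def start(self) -> int:
        return self.arm5[0]

    @property
    def end(self) -> int:
        return self.arm3[1]

    def as_feature(self) -> GenomicFeature:
        return GenomicFeature(
            contig=self.contig,
            start=self.start,
            end=self.end,
            strand=self.strand,
            feature_id=self.locus_id,
            category="miRNA",
        )
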