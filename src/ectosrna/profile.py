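"""Small-RNA library profiling.

Size spectra with per-length 5' nucleotide composition, genomic-origin
classification with fixed precedence (miRNA > TE > exon > intron >
intergenic), presence categories of features across a total and a
RISC-bound library, and the RISC/total per-category enrichment table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ._intervals import DisjointIntervals
from .core import GenomicFeature, MappedRead, MiRNALocus

#: Assignment precedence for reads overlapping several annotation layers.
PRECEDENCE = ("miRNA", "TE", "exon", "intron")
CATEGORIES = PRECEDENCE + ("intergenic",)

_BASE_AS_RNA = {"A": "A", "C": "C", "G": "G", "T": "U"}


@dataclass
class SizeSpectrum:
    """Read-length histogram with per-length 5' base composition.

    ``composition[length]`` maps the 5' base (T reported as U) to its
    fraction among reads of that length.
    """

    counts: Dict[int, int]
    fractions: Dict[int, float]
    composition: Dict[int, Dict[str, float]]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class OriginProfile:
    """Per-category read counts and fractions (categories partition reads)."""

    counts: Dict[str, int]
    fractions: Dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def size_spectrum(reads: Sequence[MappedRead]) -> SizeSpectrum:
    """Length histogram and per-length 5' nucleotide composition.

    The 5' base is the first base of the read sequence in read orientation;
    T is reported as U. Raises on an empty library.
    """
    if not reads:
        raise ValueError("cannot profile an empty read library")
    counts: Counter = Counter(len(r) for r in reads)
    first: Dict[int, Counter] = {}
    for r in reads:
        first.setdefault(len(r), Counter())[_BASE_AS_RNA[r.seq[0]]] += 1
    total = sum(counts.values())
    fractions = {l: c / total for l, c in counts.items()}
    composition = {
        l: {base: n / sum(fc.values()) for base, n in sorted(fc.items())}
        for l, fc in first.items()
    }
    return SizeSpectrum(dict(sorted(counts.items())), dict(sorted(fractions.items())),
                        dict(sorted(composition.items())))


class OriginIndex:
    """Interval index over annotation layers for origin classification."""

    def __init__(
        self,
        features: Sequence[GenomicFeature],
        mirna_loci: Sequence[MiRNALocus] = (),
        contigs: Optional[Iterable[str]] = None,
    ):
        by_layer: Dict[str, Dict[str, list]] = {c: {} for c in PRECEDENCE}
        known = set(contigs) if contigs is not None else set()
        for f in features:
            known.add(f.contig)
            if f.category in ("TE", "exon", "intron"):
                by_layer[f.category].setdefault(f.contig, []).append((f.start, f.end))
            elif f.category == "miRNA":
                by_layer["miRNA"].setdefault(f.contig, []).append((f.start, f.end))
        for locus in mirna_loci:
            known.add(locus.contig)
            by_layer["miRNA"].setdefault(locus.contig, []).append((locus.start, locus.end))
        self.contigs = known
        self._index = {
            cat: {c: DisjointIntervals(ivs) for c, ivs in layer.items()}
            for cat, layer in by_layer.items()
        }

    def classify_many(
        self, contigs: Sequence[str], starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Vectorized classification; overlap is >= 1 base, strand-agnostic."""
        contigs = np.asarray(contigs)
        unknown = set(contigs) - self.contigs
        if unknown:
            raise ValueError(f"reads on unknown contig(s): {sorted(unknown)}")
        out = np.full(contigs.shape, "intergenic", dtype=object)
        unassigned = np.ones(contigs.shape, dtype=bool)
        for cat in PRECEDENCE:
            layer = self._index[cat]
            for contig, index in layer.items():
                mask = unassigned & (contigs == contig)
                if not mask.any():
                    continue
                hit = index.overlaps(starts[mask], ends[mask])
                idx = np.nonzero(mask)[0][hit]
                out[idx] = cat
                unassigned[idx] = False
        return out


def classify_origin(
    read: MappedRead,
    features: Sequence[GenomicFeature],
    mirna_loci: Sequence[MiRNALocus] = (),
) -> str:
    """Assign a single read to exactly one origin category.

    Precedence on multi-layer overlaps: miRNA > TE > exon > intron;
    anything else is intergenic. For many reads build an
    :class:`OriginIndex` once and use :func:`origin_profile`.
    """
    index = OriginIndex(features, mirna_loci)
    return str(
        index.classify_many([read.contig], np.array([read.start]), np.array([read.end]))[0]
    )


def origin_profile(
    reads: Sequence[MappedRead],
    features: Sequence[GenomicFeature],
    mirna_loci: Sequence[MiRNALocus] = (),
    index: Optional[OriginIndex] = None,
) -> OriginProfile:
    """Aggregate origin classification over a library.

    Multi-mapping reads contribute at each placement (each record is one
    placement).
    """
    if not reads:
        raise ValueError("cannot profile an empty read library")
    index = index or OriginIndex(features, mirna_loci)
    contigs = np.array([r.contig for r in reads], dtype=object)
    starts = np.array([r.start for r in reads], dtype=np.int64)
    ends = np.array([r.end for r in reads], dtype=np.int64)
    labels = index.classify_many(contigs, starts, ends)
    counts = {cat: int((labels == cat).sum()) for cat in CATEGORIES}
    total = len(reads)
    return OriginProfile(counts, {c: n / total for c, n in counts.items()})


def presence_categories(
    features: Sequence[GenomicFeature],
    total_reads: Sequence[MappedRead],
    risc_reads: Sequence[MappedRead],
    min_reads: int = 1,
) -> Dict[str, str]:
    """Classify each feature by sRNA presence across the two libraries.

    Presence is >= ``min_reads`` overlapping reads (strand-agnostic).
    Returns feature_id -> one of {"total_only", "risc_only", "both",
    "none"}; the four categories partition the feature set.
    """

    def _covered(reads: Sequence[MappedRead]) -> Dict[str, np.ndarray]:
        out: Dict[str, list] = {}
        for r in reads:
            out.setdefault(r.contig, []).append((r.start, r.end))
        return {c: DisjointIntervals(ivs) for c, ivs in out.items()}

    if min_reads != 1:
        # general path: count overlapping reads per feature
        def _has(reads: Sequence[MappedRead], f: GenomicFeature) -> bool:
            n = sum(
                1 for r in reads
                if r.contig == f.contig and r.start < f.end and r.end > f.start
            )
            return n >= min_reads

        return {
            f.feature_id: {
                (True, True): "both", (True, False): "total_only",
                (False, True): "risc_only", (False, False): "none",
            }[(_has(total_reads, f), _has(risc_reads, f))]
            for f in features
        }

    total_cov = _covered(total_reads)
    risc_cov = _covered(risc_reads)
    out: Dict[str, str] = {}
    for f in features:
        s = np.array([f.start])
        e = np.array([f.end])
        in_total = f.contig in total_cov and bool(total_cov[f.contig].overlaps(s, e)[0])
        in_risc = f.contig in risc_cov and bool(risc_cov[f.contig].overlaps(s, e)[0])
        out[f.feature_id] = {
            (True, True): "both", (True, False): "total_only",
            (False, True): "risc_only", (False, False): "none",
        }[(in_total, in_risc)]
    return out


def enrichment_table(
    total_profile: OriginProfile, risc_profile: OriginProfile
) -> Dict[str, float]:
    """Per-category fraction ratio RISC/total (nan where total fraction is 0)."""
    out = {}
    for cat in CATEGORIES:
        t = total_profile.fractions.get(cat, 0.0)
        r = risc_profile.fractions.get(cat, 0.0)
        out[cat] = r / t if t > 0 else float("nan")
    return out
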